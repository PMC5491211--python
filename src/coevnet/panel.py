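"""Panel data structures, file I/O and descriptive network statistics.

The observational unit is a school cohort followed over M waves: a directed
binary network per wave (``x[i, j] = 1`` iff actor *i* provides emotional
support to actor *j*), a four-category smoking behavior score per actor per
wave (0 = never, 1 = 1-3 days, 2 = 4-21 days, 3 = 22+ days in the past 30
days), and a fixed table of actor covariates.  Actors are indexed 0..n-1 in
covariate-table row order and the roster is fixed across waves.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedStatisticError",
    "PanelValidationError",
    "DirectedNetwork",
    "BehaviorVector",
    "ActorCovariateTable",
    "CoevolutionPanel",
    "BEHAVIOR_MIN",
    "BEHAVIOR_MAX",
    "COVARIATE_COLUMNS",
    "recode_smoking_days",
    "reciprocity_index",
    "transitivity_index",
    "jaccard_index",
    "hamming_distance",
    "describe_panel",
    "read_panel",
    "write_panel",
]

BEHAVIOR_MIN = 0
BEHAVIOR_MAX = 3

#: fixed actor covariates expected by the loader, in canonical column order
COVARIATE_COLUMNS = [
    "female",
    "grade",
    "depressive_symptoms",
    "parental_support",
    "parental_monitoring",
    "home_smoking_environment",
    "parental_discussion",
    "mother_education",
]


class UndefinedStatisticError(ValueError):
    """A descriptive index is undefined for this input (e.g. empty network)."""


class PanelValidationError(ValueError):
    """Input files or arrays violate the panel data contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DirectedNetwork:
    """Binary directed adjacency among ``n_actors`` at one wave.

    ``ties[i, j] = 1`` means actor *i* provides support to actor *j*.
    Self-ties are forbidden and entries must be 0/1.
    """

    ties: np.ndarray
    wave_label: str = ""

    def __post_init__(self) -> None:
        self.ties = np.asarray(self.ties, dtype=np.int8)
        if self.ties.ndim != 2 or self.ties.shape[0] != self.ties.shape[1]:
            raise PanelValidationError("adjacency matrix must be square")
        if not np.isin(self.ties, (0, 1)).all():
            raise PanelValidationError("tie entries must be 0 or 1")
        if np.diagonal(self.ties).any():
            raise PanelValidationError(
                f"self-ties are not allowed (wave {self.wave_label!r})"
            )

    @property
    def n_actors(self) -> int:
        return self.ties.shape[0]

    @property
    def n_ties(self) -> int:
        return int(self.ties.sum())

    def edge_list(self) -> np.ndarray:
        """Return an (m, 2) array of (source, target) pairs."""
        return np.argwhere(self.ties == 1)


@dataclass
class BehaviorVector:
    """Ordinal smoking category per actor at one wave, values in {0..3}."""

    values: np.ndarray
    wave_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise PanelValidationError("behavior values must be a 1-d vector")
        if ((self.values < BEHAVIOR_MIN) | (self.values > BEHAVIOR_MAX)).any():
            bad = self.values[(self.values < BEHAVIOR_MIN) | (self.values > BEHAVIOR_MAX)]
            raise PanelValidationError(
                f"behavior values outside {{0..3}}: {sorted(set(bad.tolist()))}"
            )

    @property
    def n_actors(self) -> int:
        return self.values.shape[0]


@dataclass
class ActorCovariateTable:
    """Fixed actor covariates plus the per-period limited-nomination flag.

    ``table`` holds the columns in :data:`COVARIATE_COLUMNS` indexed by actor
    (0..n-1); ``limited_nomination_change`` is an (n, n_periods) integer array
    with values in {-1, 0, +1}: -1 means the actor changed from full to
    limited nominations over that period, +1 the reverse.
    Missing values are out of contract and rejected.
    """

    table: pd.DataFrame
    limited_nomination_change: np.ndarray

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.table.columns]
        if missing:
            raise PanelValidationError(f"covariate columns missing: {missing}")
        self.table = self.table[COVARIATE_COLUMNS].reset_index(drop=True)
        if self.table.isna().any().any():
            raise PanelValidationError("covariate table contains missing values")
        self.limited_nomination_change = np.asarray(
            self.limited_nomination_change, dtype=np.int64
        )
        if self.limited_nomination_change.ndim != 2:
            raise PanelValidationError(
                "limited_nomination_change must be (n_actors, n_periods)"
            )
        if self.limited_nomination_change.shape[0] != len(self.table):
            raise PanelValidationError(
                "limited_nomination_change rows must match covariate table"
            )
        if not np.isin(self.limited_nomination_change, (-1, 0, 1)).all():
            raise PanelValidationError(
                "limited_nomination_change values must be in {-1, 0, +1}"
            )
        if not np.isin(self.table["female"], (0, 1)).all():
            raise PanelValidationError("female must be binary 0/1")
        if not np.isin(self.table["parental_discussion"], (0, 1)).all():
            raise PanelValidationError("parental_discussion must be binary 0/1")

    @property
    def n_actors(self) -> int:
        return len(self.table)

    @property
    def n_periods(self) -> int:
        return self.limited_nomination_change.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


@dataclass
class CoevolutionPanel:
    """Aligned networks, behavior vectors and covariates over M >= 2 waves."""

    networks: list[DirectedNetwork]
    behaviors: list[BehaviorVector]
    covariates: ActorCovariateTable

    def __post_init__(self) -> None:
        if len(self.networks) < 2:
            raise PanelValidationError("a panel needs at least two waves")
        if len(self.networks) != len(self.behaviors):
            raise PanelValidationError(
                f"wave count mismatch: {len(self.networks)} networks vs "
                f"{len(self.behaviors)} behavior vectors"
            )
        n = self.covariates.n_actors
        for net, beh in zip(self.networks, self.behaviors):
            if net.n_actors != n or beh.n_actors != n:
                raise PanelValidationError("all waves must share n_actors")
        if self.covariates.n_periods < self.n_waves - 1:
            raise PanelValidationError(
                "limited_nomination_change needs one column per period "
                f"(got {self.covariates.n_periods}, need {self.n_waves - 1})"
            )

    @property
    def n_actors(self) -> int:
        return self.covariates.n_actors

    @property
    def n_waves(self) -> int:
        return len(self.networks)

    @property
    def n_periods(self) -> int:
        return self.n_waves - 1


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def recode_smoking_days(days_smoked: int) -> int:
    """Collapse past-30-day smoking frequency into the 4-category scale.

    0 days -> 0 (never), 1-3 -> 1, 4-21 -> 2, 22-30 -> 3.
    """
    days = int(days_smoked)
    if days != days_smoked or not 0 <= days <= 30:
        raise ValueError(f"days smoked must be an integer in [0, 30], got {days_smoked}")
    if days == 0:
        return 0
    if days <= 3:
        return 1
    if days <= 21:
        return 2
    return 3


def reciprocity_index(net: DirectedNetwork) -> float:
    """Proportion of ties that are reciprocated.

    Counts ordered ties i->j for which j->i also exists, divided by the
    total number of ties.  Undefined for an empty network.
    """
    x = net.ties
    n_ties = x.sum()
    if n_ties == 0:
        raise UndefinedStatisticError("reciprocity undefined for an empty network")
    mutual = int((x & x.T).sum())
    return mutual / int(n_ties)


def transitivity_index(net: DirectedNetwork) -> float:
    """Proportion of two-paths i->j->k (i, j, k distinct) closed by i->k."""
    x = net.ties.astype(np.int64)
    xx = x @ x
    # i == k two-paths sit on the diagonal of x @ x; i==j / j==k are killed
    # by the zero diagonal of x itself
    two_paths = int(xx.sum() - np.trace(xx))
    if two_paths == 0:
        raise UndefinedStatisticError("transitivity undefined without two-paths")
    closed = int((xx * x).sum())
    return closed / two_paths


def jaccard_index(net_a: DirectedNetwork, net_b: DirectedNetwork) -> float:
    """Tie-set overlap |A ∩ B| / |A ∪ B| between two waves (same roster)."""
    if net_a.n_actors != net_b.n_actors:
        raise PanelValidationError("jaccard_index needs networks of equal size")
    a, b = net_a.ties, net_b.ties
    union = int((a | b).sum())
    if union == 0:
        raise UndefinedStatisticError("jaccard undefined when both networks are empty")
    inter = int((a & b).sum())
    return inter / union


def hamming_distance(net_a: DirectedNetwork, net_b: DirectedNetwork) -> int:
    """Number of ordered dyads whose tie status differs between the waves."""
    if net_a.n_actors != net_b.n_actors:
        raise PanelValidationError("hamming_distance needs networks of equal size")
    return int((net_a.ties != net_b.ties).sum())


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


def _limited_nomination_percent(cov: ActorCovariateTable, n_periods: int
                                ) -> list[float]:
    """Percent of actors under limited nominations at each wave.

    Wave 1 is taken as all-full (the instrument artifact appeared only at
    the in-home waves); later waves accumulate the per-period change flags.
    """
    n = cov.n_actors
    limited = np.zeros(n, dtype=bool)
    out = [0.0]
    for m in range(n_periods):
        change = cov.limited_nomination_change[:, m]
        limited = limited | (change == -1)
        limited = limited & ~(change == 1)
        out.append(100.0 * limited.mean())
    return out


def describe_panel(panel: CoevolutionPanel) -> pd.DataFrame:
    """Wave-by-wave descriptive table of behavior and network structure.

    Rows: percent of actors per smoking category, outgoing tie count,
    reciprocity and transitivity indices per wave; Jaccard index and percent
    limited nominations per period (reported in the column of the period's
    end wave).  Undefined indices become NaN with a warning.
    """
    waves = [f"wave {m + 1}" for m in range(panel.n_waves)]
    rows: dict[str, list[float]] = {}
    n = panel.n_actors

    for cat, label in enumerate(
        ["0 = never", "1 = 1-3 days", "2 = 4-21 days", "3 = 22 or more days"]
    ):
        rows[label] = [
            100.0 * float((beh.values == cat).mean()) for beh in panel.behaviors
        ]
    rows["Out-going ties"] = [float(net.n_ties) for net in panel.networks]

    def _safe(fn, *args):
        try:
            return fn(*args)
        except UndefinedStatisticError as exc:
            warnings.warn(f"undefined descriptive statistic: {exc}", stacklevel=3)
            return float("nan")

    rows["Reciprocity index"] = [_safe(reciprocity_index, net) for net in panel.networks]
    rows["Transitivity index"] = [
        _safe(transitivity_index, net) for net in panel.networks
    ]
    jac = [float("nan")]
    for m in range(panel.n_periods):
        jac.append(_safe(jaccard_index, panel.networks[m], panel.networks[m + 1]))
    rows["Jaccard index"] = jac
    rows["Limited nominations (%)"] = _limited_nomination_percent(
        panel.covariates, panel.n_periods
    )

    frame = pd.DataFrame(rows, index=waves).T
    frame.index.name = f"Panel (n = {n})"
    return frame


def format_description(frame: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`describe_panel` output."""
    return frame.to_string(float_format=lambda v: f"{v:.2f}", na_rep="")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_BEHAVIOR_COL = re.compile(r"^smoke_w(\d+)$")
_LIMNOM_COL = re.compile(r"^limnom_change_p(\d+)$")


def _read_edge_list(path: Path, n_actors: int, id_map: dict[int, int], label: str
                    ) -> DirectedNetwork:
    ties = np.zeros((n_actors, n_actors), dtype=np.int8)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) != 2:
                raise PanelValidationError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                src, dst = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise PanelValidationError(f"{path}:{lineno}: non-integer ids") from exc
            for actor in (src, dst):
                if actor not in id_map:
                    raise PanelValidationError(
                        f"{path}:{lineno}: unknown actor id {actor}"
                    )
            i, j = id_map[src], id_map[dst]
            if i == j:
                raise PanelValidationError(f"{path}:{lineno}: self-tie for actor {src}")
            ties[i, j] = 1
    return DirectedNetwork(ties, wave_label=label)


def read_panel(
    network_paths: Sequence[str | Path],
    behavior_path: str | Path,
    covariate_path: str | Path,
) -> CoevolutionPanel:
    """Load a panel from edge-list files and delimited tables.

    Each network file is a two-column integer edge list (source, target; one
    file per wave, ``#`` comments allowed).  The behavior file is a CSV with
    an ``actor_id`` column and one ``smoke_w<m>`` column per wave; the
    covariate file has ``actor_id``, the :data:`COVARIATE_COLUMNS`, and one
    ``limnom_change_p<m>`` column per period.  Covariate row order defines
    the contiguous 0-based actor indexing.
    """
    cov_df = pd.read_csv(covariate_path)
    if "actor_id" not in cov_df.columns:
        raise PanelValidationError("covariate file needs an actor_id column")
    ids = cov_df["actor_id"].to_numpy()
    if len(set(ids.tolist())) != len(ids):
        raise PanelValidationError("duplicate actor_id in covariate file")
    id_map = {int(a): idx for idx, a in enumerate(ids)}
    n = len(ids)

    limnom_cols = sorted(
        (c for c in cov_df.columns if _LIMNOM_COL.match(c)),
        key=lambda c: int(_LIMNOM_COL.match(c).group(1)),
    )
    if not limnom_cols:
        raise PanelValidationError("covariate file needs limnom_change_p<m> columns")
    covariates = ActorCovariateTable(
        table=cov_df,
        limited_nomination_change=cov_df[limnom_cols].to_numpy(),
    )

    beh_df = pd.read_csv(behavior_path)
    if "actor_id" not in beh_df.columns:
        raise PanelValidationError("behavior file needs an actor_id column")
    beh_cols = sorted(
        (c for c in beh_df.columns if _BEHAVIOR_COL.match(c)),
        key=lambda c: int(_BEHAVIOR_COL.match(c).group(1)),
    )
    if len(beh_cols) != len(network_paths):
        raise PanelValidationError(
            f"wave count mismatch: {len(network_paths)} network files vs "
            f"{len(beh_cols)} behavior columns"
        )
    beh_df = beh_df.set_index("actor_id")
    try:
        beh_df = beh_df.loc[ids]
    except KeyError as exc:
        raise PanelValidationError("behavior file is missing actors") from exc

    behaviors = [
        BehaviorVector(beh_df[col].to_numpy(), wave_label=f"wave {m + 1}")
        for m, col in enumerate(beh_cols)
    ]
    networks = [
        _read_edge_list(Path(p), n, id_map, label=f"wave {m + 1}")
        for m, p in enumerate(network_paths)
    ]
    return CoevolutionPanel(networks=networks, behaviors=behaviors, covariates=covariates)


def write_panel(panel: CoevolutionPanel, out_dir: str | Path, prefix: str = "panel"
                ) -> dict[str, object]:
    """Write a panel as edge lists + behavior/covariate CSVs; returns the paths.

    The layout is the exact inverse of :func:`read_panel`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net_paths = []
    for m, net in enumerate(panel.networks, start=1):
        p = out / f"{prefix}_support_w{m}.edges"
        with open(p, "w") as fh:
            fh.write(f"# wave={m}\n")
            for src, dst in net.edge_list():
                fh.write(f"{src} {dst}\n")
        net_paths.append(p)

    beh = pd.DataFrame({"actor_id": np.arange(panel.n_actors)})
    for m, vec in enumerate(panel.behaviors, start=1):
        beh[f"smoke_w{m}"] = vec.values
    beh_path = out / f"{prefix}_behavior.csv"
    beh.to_csv(beh_path, index=False)

    cov = panel.covariates.table.copy()
    cov.insert(0, "actor_id", np.arange(panel.n_actors))
    for m in range(panel.n_periods):
        cov[f"limnom_change_p{m + 1}"] = panel.covariates.limited_nomination_change[:, m]
    cov_path = out / f"{prefix}_covariates.csv"
    cov.to_csv(cov_path, index=False)

    return {"networks": net_paths, "behavior": beh_path, "covariates": cov_path}
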