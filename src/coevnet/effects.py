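"""Effect statistics and objective functions for the two choice equations.

Actors make myopic choices by maximizing (up to logit noise) an objective
function f_i = sum_k beta_k * s_ik(state), a linear combination of effect
statistics.  Two equations co-evolve: the *network* equation governs tie
changes (whom actor i provides emotional support to) and the *behavior*
equation governs +/-1 moves on the 0-3 smoking scale.

Effect statistics follow the standard stochastic actor-oriented catalog:
structural terms (out-degree, reciprocity, transitive triplets, 3-cycles,
betweenness, degree popularity/activity/assortativity), covariate terms
(ego, alter, same-value homophily, similarity) and behavior shape/peer
influence terms.  Continuous covariates and the behavior score enter
grand-mean centered; dyadic similarity is centered by its observed mean.

This module provides, per effect, both a per-actor statistic evaluator and
a vectorized *change* evaluator giving the objective difference for every
candidate micro-step at once; the latter is the hot path of the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import yaml

from .panel import (
    ActorCovariateTable,
    BehaviorVector,
    BEHAVIOR_MAX,
    BEHAVIOR_MIN,
    CoevolutionPanel,
    COVARIATE_COLUMNS,
)

__all__ = [
    "EffectSpec",
    "ModelSpec",
    "EffectContext",
    "similarity",
    "effect_statistic",
    "behavior_effect_statistic",
    "network_objective",
    "network_objective_change",
    "network_change_vector",
    "behavior_objective",
    "behavior_candidate_objectives",
    "default_coevolution_spec",
    "jefferson_reference_theta",
]

BEHAVIOR_RANGE = float(BEHAVIOR_MAX - BEHAVIOR_MIN)

#: network effects that need no covariate
_NET_STRUCTURAL = {
    "outdegree",
    "reciprocity",
    "transitive_triplets",
    "three_cycles",
    "betweenness",
    "indegree_popularity",
    "out_in_sqrt_assortativity",
    "indegree_activity",
    "indegree_squared_activity",
    "behavior_similarity",
}
#: network effects parameterized by a covariate name
_NET_COVARIATE = {"same_covariate", "covariate_alter", "covariate_ego"}

_BEH_PLAIN = {
    "linear_shape",
    "quadratic_shape",
    "indegree",
    "average_incoming_similarity",
}
_BEH_COVARIATE = {"covariate_main"}

NETWORK_EFFECT_NAMES = _NET_STRUCTURAL | _NET_COVARIATE
BEHAVIOR_EFFECT_NAMES = _BEH_PLAIN | _BEH_COVARIATE

#: covariates usable in effects; "behavior" refers to the co-evolving
#: smoking score and "limited_nomination" to the per-period change flag
_DYNAMIC_COVARIATES = {"behavior", "limited_nomination"}


def similarity(z_i: float, z_j: float, value_range: float = BEHAVIOR_RANGE) -> float:
    """Dyadic behavior similarity sim_ij = 1 - |z_i - z_j| / range, in [0, 1]."""
    if value_range <= 0:
        raise ValueError("similarity range must be positive")
    return 1.0 - abs(z_i - z_j) / value_range


@dataclass(frozen=True)
class EffectSpec:
    """One named effect in one equation, optionally tied to a covariate."""

    name: str
    equation: str  # "network" | "behavior"
    covariate: str | None = None

    def __post_init__(self) -> None:
        if self.equation not in ("network", "behavior"):
            raise ValueError(f"unknown equation {self.equation!r}")
        catalog = NETWORK_EFFECT_NAMES if self.equation == "network" else BEHAVIOR_EFFECT_NAMES
        if self.name not in catalog:
            raise ValueError(f"unknown {self.equation} effect {self.name!r}")
        needs_cov = self.name in (_NET_COVARIATE | _BEH_COVARIATE)
        if needs_cov and not self.covariate:
            raise ValueError(f"effect {self.name!r} requires a covariate")
        if not needs_cov and self.covariate:
            raise ValueError(f"effect {self.name!r} does not take a covariate")
        if self.covariate is not None:
            allowed = set(COVARIATE_COLUMNS) | _DYNAMIC_COVARIATES
            if self.covariate not in allowed:
                raise ValueError(f"unknown covariate {self.covariate!r}")

    @property
    def key(self) -> str:
        return f"{self.name}:{self.covariate}" if self.covariate else self.name

    @property
    def label(self) -> str:
        """Human-readable label used in estimate tables."""
        cov = (self.covariate or "").replace("_", " ")
        labels = {
            "outdegree": "Out-degree (density)",
            "reciprocity": "Reciprocity",
            "transitive_triplets": "Transitive triplets",
            "three_cycles": "3-cycles",
            "betweenness": "Betweenness",
            "indegree_popularity": "In-degree popularity",
            "out_in_sqrt_assortativity": "Out-in degree^(1/2) assortativity",
            "indegree_activity": "In-degree activity",
            "indegree_squared_activity": "In-degree^2 activity",
            "behavior_similarity": "Behavior similarity",
            "same_covariate": f"Same {cov}",
            "covariate_alter": f"{cov.capitalize()} alter",
            "covariate_ego": f"{cov.capitalize()} ego",
            "linear_shape": "Behavior linear shape",
            "quadratic_shape": "Behavior quadratic shape",
            "indegree": "Behavior in-degree",
            "average_incoming_similarity": "Behavior incoming alter similarity",
            "covariate_main": cov.capitalize(),
        }
        return labels[self.name]


@dataclass
class ModelSpec:
    """Effect roster and rate-parameter structure of a co-evolution model.

    ``n_periods`` is the number of wave-to-wave transitions.  A network rate
    parameter exists per period; behavior rate parameters exist only when
    the behavior equation is active (any behavior effect, or
    ``behavior_rates_active=True``).  The full parameter vector theta is
    ordered: network rates, behavior rates, network betas, behavior betas.
    """

    network_effects: list[EffectSpec]
    behavior_effects: list[EffectSpec] = field(default_factory=list)
    n_periods: int = 2
    behavior_rates_active: bool | None = None

    def __post_init__(self) -> None:
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        for eff in self.network_effects:
            if eff.equation != "network":
                raise ValueError(f"{eff.key} is not a network effect")
        for eff in self.behavior_effects:
            if eff.equation != "behavior":
                raise ValueError(f"{eff.key} is not a behavior effect")
        for effs in (self.network_effects, self.behavior_effects):
            keys = [e.key for e in effs]
            if len(set(keys)) != len(keys):
                raise ValueError("duplicate effect within an equation")
        if self.behavior_rates_active is None:
            self.behavior_rates_active = bool(self.behavior_effects)

    # -- parameter layout ---------------------------------------------------

    @property
    def n_network_rates(self) -> int:
        return self.n_periods

    @property
    def n_behavior_rates(self) -> int:
        return self.n_periods if self.behavior_rates_active else 0

    @property
    def n_params(self) -> int:
        return (
            self.n_network_rates
            + self.n_behavior_rates
            + len(self.network_effects)
            + len(self.behavior_effects)
        )

    def param_names(self) -> list[str]:
        names = [f"Network rate (period {m + 1})" for m in range(self.n_network_rates)]
        names += [f"Behavior rate (period {m + 1})" for m in range(self.n_behavior_rates)]
        names += [e.label for e in self.network_effects]
        names += [e.label for e in self.behavior_effects]
        return names

    def is_rate(self) -> np.ndarray:
        """Boolean mask over theta marking the rate parameters."""
        mask = np.zeros(self.n_params, dtype=bool)
        mask[: self.n_network_rates + self.n_behavior_rates] = True
        return mask

    def split_theta(self, theta: np.ndarray):
        """Split theta into (net_rates, beh_rates, net_betas, beh_betas)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"theta has length {theta.shape}, model needs {self.n_params}"
            )
        a = self.n_network_rates
        b = a + self.n_behavior_rates
        c = b + len(self.network_effects)
        return theta[:a], theta[a:b], theta[b:c], theta[c:]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_periods": self.n_periods,
            "behavior_rates_active": self.behavior_rates_active,
            "network_effects": [
                {"name": e.name, **({"covariate": e.covariate} if e.covariate else {})}
                for e in self.network_effects
            ],
            "behavior_effects": [
                {"name": e.name, **({"covariate": e.covariate} if e.covariate else {})}
                for e in self.behavior_effects
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        return cls(
            network_effects=[
                EffectSpec(d["name"], "network", d.get("covariate"))
                for d in data.get("network_effects", [])
            ],
            behavior_effects=[
                EffectSpec(d["name"], "behavior", d.get("covariate"))
                for d in data.get("behavior_effects", [])
            ],
            n_periods=int(data.get("n_periods", 2)),
            behavior_rates_active=data.get("behavior_rates_active"),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# centering context
# ---------------------------------------------------------------------------


class EffectContext:
    """Centered covariates and centering constants bound to an observed panel.

    Continuous actor covariates are grand-mean centered over actors; the
    behavior score is centered by its grand mean over all actors and waves;
    dyadic similarity is centered by the mean similarity over all ordered
    pairs and waves.  Match indicators (same grade / same gender) stay raw.
    Centering constants are computed once from the observed panel and held
    fixed during simulation and estimation.
    """

    #: covariates used raw by same_covariate effects
    _UNCENTERED = {"female", "grade"}

    def __init__(
        self,
        covariates: ActorCovariateTable,
        behaviors: Iterable[BehaviorVector] | None = None,
    ) -> None:
        self.covariates = covariates
        self.raw: dict[str, np.ndarray] = {
            name: covariates.column(name) for name in COVARIATE_COLUMNS
        }
        self.centered: dict[str, np.ndarray] = {
            name: vals - vals.mean() for name, vals in self.raw.items()
        }
        limnom = covariates.limited_nomination_change.astype(float)
        self.limnom_centered = limnom - limnom.mean()

        behaviors = list(behaviors or [])
        if behaviors:
            z_all = np.concatenate([b.values for b in behaviors]).astype(float)
            self.behavior_mean = float(z_all.mean())
            sims = []
            for b in behaviors:
                z = b.values.astype(float)
                diff = np.abs(z[:, None] - z[None, :]) / BEHAVIOR_RANGE
                mask = ~np.eye(len(z), dtype=bool)
                sims.append((1.0 - diff)[mask])
            self.similarity_mean = float(np.concatenate(sims).mean())
        else:
            self.behavior_mean = 0.0
            self.similarity_mean = 0.0

    @classmethod
    def from_panel(cls, panel: CoevolutionPanel) -> "EffectContext":
        return cls(panel.covariates, panel.behaviors)

    def centered_behavior(self, z: np.ndarray) -> np.ndarray:
        return z.astype(float) - self.behavior_mean

    def actor_value(self, covariate: str, z: np.ndarray, period: int) -> np.ndarray:
        """Centered per-actor values of a covariate (or the behavior score)."""
        if covariate == "behavior":
            return self.centered_behavior(z)
        if covariate == "limited_nomination":
            return self.limnom_centered[:, period]
        return self.centered[covariate]

    def raw_value(self, covariate: str, z: np.ndarray, period: int) -> np.ndarray:
        if covariate == "behavior":
            return z.astype(float)
        if covariate == "limited_nomination":
            return self.covariates.limited_nomination_change[:, period].astype(float)
        return self.raw[covariate]


# ---------------------------------------------------------------------------
# per-actor statistics
# ---------------------------------------------------------------------------


def effect_statistic(
    effect: EffectSpec,
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    ctx: EffectContext,
    period: int = 0,
) -> float:
    """Value of one network-equation statistic s_ik for actor ``i``.

    ``x`` is the adjacency matrix (int), ``z`` the current behavior vector.
    """
    if effect.equation != "network":
        raise ValueError("use behavior_effect_statistic for behavior effects")
    r = np.asarray(x[i], dtype=np.float64)
    name = effect.name
    if name == "outdegree":
        return float(r.sum())
    c = np.asarray(x[:, i], dtype=np.float64)
    if name == "reciprocity":
        return float(r @ c)
    if name == "transitive_triplets":
        # s = sum_{j,k} x_ij x_ik x_kj
        return float(r @ (x @ r))
    if name == "three_cycles":
        return float(r @ (x @ c))
    if name == "betweenness":
        # s = sum_{j != k} x_ji x_ik (1 - x_jk)
        return float(c.sum() * r.sum() - r @ c - c @ (x @ r))
    if name == "indegree_popularity":
        return float(r @ x.sum(axis=0))
    if name == "out_in_sqrt_assortativity":
        return float(np.sqrt(r.sum()) * (r @ np.sqrt(x.sum(axis=0))))
    if name == "indegree_activity":
        return float(c.sum() * r.sum())
    if name == "indegree_squared_activity":
        return float(c.sum() ** 2 * r.sum())
    if name == "behavior_similarity":
        sim = 1.0 - np.abs(z[i] - z) / BEHAVIOR_RANGE
        return float(r @ (sim - ctx.similarity_mean))
    if name == "same_covariate":
        v = ctx.raw_value(effect.covariate, z, period)
        return float(r @ (v == v[i]).astype(float))
    if name == "covariate_alter":
        v = ctx.actor_value(effect.covariate, z, period)
        return float(r @ v)
    if name == "covariate_ego":
        v = ctx.actor_value(effect.covariate, z, period)
        return float(v[i] * r.sum())
    raise ValueError(f"unhandled network effect {name!r}")


def behavior_effect_statistic(
    effect: EffectSpec,
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    ctx: EffectContext,
    period: int = 0,
    candidate: int | None = None,
) -> float:
    """Value of one behavior-equation statistic for actor ``i``.

    If ``candidate`` is given, the statistic is evaluated with z_i replaced
    by the candidate value, all else fixed.
    """
    if effect.equation != "behavior":
        raise ValueError("use effect_statistic for network effects")
    zi = float(z[i] if candidate is None else candidate)
    zc = zi - ctx.behavior_mean
    name = effect.name
    if name == "linear_shape":
        return zc
    if name == "quadratic_shape":
        return zc * zc
    if name == "indegree":
        return zc * float(x[:, i].sum())
    if name == "average_incoming_similarity":
        supporters = np.flatnonzero(x[:, i])
        if supporters.size == 0:
            return 0.0
        sims = 1.0 - np.abs(zi - z[supporters]) / BEHAVIOR_RANGE
        return float((sims - ctx.similarity_mean).mean())
    if name == "covariate_main":
        v = ctx.actor_value(effect.covariate, z, period)
        return zc * float(v[i])
    raise ValueError(f"unhandled behavior effect {name!r}")


# ---------------------------------------------------------------------------
# objective functions and change contributions
# ---------------------------------------------------------------------------


def network_objective(
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    betas: np.ndarray,
    effects: list[EffectSpec],
    ctx: EffectContext,
    period: int = 0,
) -> float:
    """Network objective f_i = sum_k beta_k s_ik at the current state."""
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (len(effects),):
        raise ValueError("betas length must match the network effect list")
    return float(
        sum(
            b * effect_statistic(eff, x, z, i, ctx, period)
            for b, eff in zip(betas, effects)
        )
    )


def network_change_vector(
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    betas: np.ndarray,
    effects: list[EffectSpec],
    ctx: EffectContext,
    period: int = 0,
) -> np.ndarray:
    """Objective change for toggling x[i, j], vectorized over all alters j.

    Returns an array u of length n with u[j] = f_i(x with x_ij toggled)
    - f_i(x) for j != i and u[i] = 0 (the "keep" option).  This is the
    simulator's hot path; each effect contributes a closed-form delta.
    """
    n = x.shape[0]
    # views when x is already float64 (the simulator's hot path)
    r = np.asarray(x[i], dtype=np.float64)
    c = np.asarray(x[:, i], dtype=np.float64)
    delta = 1.0 - 2.0 * r  # +1 where a tie would be created, -1 where dropped
    u: np.ndarray | None = None
    shared: dict[str, np.ndarray] = {}

    def _get(key: str) -> np.ndarray:
        if key not in shared:
            if key == "x_r":
                shared[key] = x @ r
            elif key == "r_x":
                shared[key] = r @ x
            elif key == "x_c":
                shared[key] = x @ c
            elif key == "c_x":
                shared[key] = c @ x
            elif key == "indeg":
                shared[key] = x.sum(axis=0).astype(float)
        return shared[key]

    outdeg_i = r.sum()
    for beta, eff in zip(betas, effects):
        if beta == 0.0:
            continue
        name = eff.name
        if name == "outdegree":
            contrib = delta
        elif name == "reciprocity":
            contrib = delta * c
        elif name == "transitive_triplets":
            contrib = delta * (_get("x_r") + _get("r_x"))
        elif name == "three_cycles":
            contrib = delta * _get("x_c")
        elif name == "betweenness":
            contrib = delta * (c.sum() - c - _get("c_x"))
        elif name == "indegree_popularity":
            # target's in-degree after the toggle counts the new tie itself
            contrib = delta * (_get("indeg") - r + 1.0)
        elif name == "out_in_sqrt_assortativity":
            indeg = _get("indeg")
            t = r @ np.sqrt(indeg)
            add = np.sqrt(outdeg_i + 1.0) * (t + np.sqrt(indeg + 1.0))
            if outdeg_i >= 1.0:
                rem = np.sqrt(outdeg_i - 1.0) * (t - np.sqrt(indeg))
            else:
                rem = np.zeros(n)
            base = np.sqrt(outdeg_i) * t
            contrib = np.where(r == 0.0, add, rem) - base
        elif name == "indegree_activity":
            contrib = delta * c.sum()
        elif name == "indegree_squared_activity":
            contrib = delta * c.sum() ** 2
        elif name == "behavior_similarity":
            sim = 1.0 - np.abs(z[i] - z) / BEHAVIOR_RANGE
            contrib = delta * (sim - ctx.similarity_mean)
        elif name == "same_covariate":
            v = ctx.raw_value(eff.covariate, z, period)
            contrib = delta * (v == v[i]).astype(float)
        elif name == "covariate_alter":
            contrib = delta * ctx.actor_value(eff.covariate, z, period)
        elif name == "covariate_ego":
            contrib = delta * ctx.actor_value(eff.covariate, z, period)[i]
        else:  # pragma: no cover - catalog is closed
            raise ValueError(f"unhandled network effect {name!r}")
        if u is None:
            u = beta * contrib
        else:
            u += beta * contrib
    if u is None:
        u = np.zeros(n, dtype=float)
    u[i] = 0.0
    return u


def network_objective_change(
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    j: int,
    betas: np.ndarray,
    effects: list[EffectSpec],
    ctx: EffectContext,
    period: int = 0,
) -> float:
    """Objective change for toggling the single tie x[i, j] (i != j)."""
    if i == j:
        raise ValueError("cannot toggle a self-tie")
    return float(network_change_vector(x, z, i, betas, effects, ctx, period)[j])


def behavior_objective(
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    candidate: int,
    betas: np.ndarray,
    effects: list[EffectSpec],
    ctx: EffectContext,
    period: int = 0,
) -> float:
    """Behavior objective with z_i replaced by ``candidate``, all else fixed."""
    if not BEHAVIOR_MIN <= candidate <= BEHAVIOR_MAX:
        raise ValueError(f"behavior candidate {candidate} outside the 0-3 scale")
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (len(effects),):
        raise ValueError("betas length must match the behavior effect list")
    return float(
        sum(
            b * behavior_effect_statistic(eff, x, z, i, ctx, period, candidate)
            for b, eff in zip(betas, effects)
        )
    )


def behavior_candidate_objectives(
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    candidates: np.ndarray,
    betas: np.ndarray,
    effects: list[EffectSpec],
    ctx: EffectContext,
    period: int = 0,
) -> np.ndarray:
    """Behavior objective evaluated at each candidate value, vectorized."""
    zc = candidates.astype(float) - ctx.behavior_mean
    u = np.zeros(len(candidates), dtype=float)
    indeg_i: float | None = None
    for beta, eff in zip(betas, effects):
        if beta == 0.0:
            continue
        name = eff.name
        if name == "linear_shape":
            contrib = zc
        elif name == "quadratic_shape":
            contrib = zc * zc
        elif name == "indegree":
            if indeg_i is None:
                indeg_i = float(x[:, i].sum())
            contrib = zc * indeg_i
        elif name == "average_incoming_similarity":
            supporters = np.flatnonzero(x[:, i])
            if supporters.size == 0:
                contrib = np.zeros(len(candidates))
            else:
                zj = z[supporters].astype(float)
                sims = 1.0 - np.abs(candidates[:, None] - zj[None, :]) / BEHAVIOR_RANGE
                contrib = (sims - ctx.similarity_mean).mean(axis=1)
        elif name == "covariate_main":
            contrib = zc * ctx.actor_value(eff.covariate, z, period)[i]
        else:  # pragma: no cover - catalog is closed
            raise ValueError(f"unhandled behavior effect {name!r}")
        u += beta * contrib
    return u


# ---------------------------------------------------------------------------
# shipped default specification
# ---------------------------------------------------------------------------


def default_coevolution_spec(n_periods: int = 2) -> ModelSpec:
    """The full emotional-support / smoking co-evolution specification.

    20 network effects and 11 behavior effects plus per-period rates — the
    roster used in the published Add Health "Jefferson High" analysis.
    """
    ne = [
        EffectSpec("outdegree", "network"),
        EffectSpec("reciprocity", "network"),
        EffectSpec("transitive_triplets", "network"),
        EffectSpec("three_cycles", "network"),
        EffectSpec("betweenness", "network"),
        EffectSpec("indegree_popularity", "network"),
        EffectSpec("out_in_sqrt_assortativity", "network"),
        EffectSpec("indegree_activity", "network"),
        EffectSpec("indegree_squared_activity", "network"),
        EffectSpec("same_covariate", "network", "grade"),
        EffectSpec("covariate_alter", "network", "female"),
        EffectSpec("same_covariate", "network", "female"),
        EffectSpec("covariate_alter", "network", "depressive_symptoms"),
        EffectSpec("covariate_ego", "network", "depressive_symptoms"),
        EffectSpec("covariate_alter", "network", "parental_discussion"),
        EffectSpec("covariate_ego", "network", "parental_discussion"),
        EffectSpec("covariate_alter", "network", "behavior"),
        EffectSpec("covariate_ego", "network", "behavior"),
        EffectSpec("behavior_similarity", "network"),
        EffectSpec("covariate_ego", "network", "limited_nomination"),
    ]
    be = [
        EffectSpec("linear_shape", "behavior"),
        EffectSpec("quadratic_shape", "behavior"),
        EffectSpec("indegree", "behavior"),
        EffectSpec("average_incoming_similarity", "behavior"),
        EffectSpec("covariate_main", "behavior", "female"),
        EffectSpec("covariate_main", "behavior", "grade"),
        EffectSpec("covariate_main", "behavior", "depressive_symptoms"),
        EffectSpec("covariate_main", "behavior", "mother_education"),
        EffectSpec("covariate_main", "behavior", "home_smoking_environment"),
        EffectSpec("covariate_main", "behavior", "parental_support"),
        EffectSpec("covariate_main", "behavior", "parental_monitoring"),
    ]
    return ModelSpec(network_effects=ne, behavior_effects=be, n_periods=n_periods)


def jefferson_reference_theta() -> np.ndarray:
    """Published point estimates for :func:`default_coevolution_spec`.

    Ordered as the model's theta: network rates (9.60, 10.86), behavior
    rates (8.06, 12.77), then the 20 network and 11 behavior coefficients.
    Useful as a realistic simulation regime.
    """
    net_rates = [9.60, 10.86]
    beh_rates = [8.06, 12.77]
    net_betas = [
        -3.83, 3.23, 1.09, -0.64, 0.22, 0.04, 0.14, 0.22, -0.09,
        0.66, -0.04, 0.43, -0.01, -0.09, 0.23, 0.14, 0.04, 0.00, 0.45, -0.12,
    ]
    beh_betas = [-1.67, 0.66, 0.04, 0.88, -0.03, -0.03, 0.13, 0.01, 0.15, -0.05, -0.24]
    return np.array(net_rates + beh_rates + net_betas + beh_betas, dtype=float)
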