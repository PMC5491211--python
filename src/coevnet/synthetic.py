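"""Synthetic school cohorts with the statistical structure of the study site.

The original data (one large rural U.S. high school from the Add Health
saturated-network sample, n = 976, restricted access) cannot be shipped.
This module generates covariate tables, initial waves and complete
co-evolution panels whose marginal distributions match the published
descriptives of that school, so that every downstream stage — description,
simulation, estimation — can be exercised end to end.

Covariates are drawn independently across actors and variables (only the
marginals are published; no correlation structure is invented).  The
initial support network is drawn dyad by dyad with an explicit mutual-tie
component so that both the target mean out-degree and the target
reciprocity index are hit in expectation, with same-grade and same-gender
tie odds boosted to seed realistic homophily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import EffectContext, ModelSpec
from .panel import (
    ActorCovariateTable,
    BehaviorVector,
    CoevolutionPanel,
    DirectedNetwork,
)
from .simulate import simulate_panel

__all__ = [
    "PopulationPreset",
    "jefferson_preset",
    "generate_covariates",
    "generate_initial_wave",
    "generate_study",
]


@dataclass
class PopulationPreset:
    """Marginal distributions and initial-wave targets for one cohort."""

    n_actors: int
    female_prop: float
    grade_probs: np.ndarray          # grades 9..12
    parental_discussion_prop: float
    depressive_mean: float
    depressive_sd: float
    parental_support_mean: float
    parental_support_sd: float
    parental_monitoring_mean: float
    parental_monitoring_sd: float
    home_smoking_mean: float
    home_smoking_sd: float           # clamped to [0, 3]
    mother_education_probs: np.ndarray  # ordinal 1..4
    limited_nomination_props: np.ndarray  # share limited at each post-baseline wave
    smoking_probs: np.ndarray        # initial categories 0..3
    mean_out_degree: float
    reciprocity_target: float
    same_grade_odds: float = 2.0
    same_gender_odds: float = 2.0

    def __post_init__(self) -> None:
        self.grade_probs = np.asarray(self.grade_probs, dtype=float)
        self.mother_education_probs = np.asarray(self.mother_education_probs, float)
        self.limited_nomination_props = np.asarray(self.limited_nomination_props, float)
        self.smoking_probs = np.asarray(self.smoking_probs, dtype=float)
        for name in ("grade_probs", "mother_education_probs", "smoking_probs"):
            probs = getattr(self, name)
            if (probs < 0).any():
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, probs / probs.sum())
        for prop in (self.female_prop, self.parental_discussion_prop,
                     *self.limited_nomination_props):
            if not 0.0 <= prop <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")


def jefferson_preset(n_actors: int = 150) -> PopulationPreset:
    """Preset emulating the published descriptives of the study school.

    Defaults follow the reported covariate table: 48.46% female, grade
    shares 28.79/28.48/21.72/21.00, parental discussion 58.40%, depressive
    symptoms N(0.00, 0.53), parental support N(-0.04, 0.29), parental
    monitoring N(-0.04, 0.10), home smoking environment 1.42 (SD 0.73,
    clamped to [0, 3]), mother's education 9.18/49.62/36.61/4.59, limited
    nominations 4.82% then 0.41%, initial smoking categories
    42.01/21.31/9.02/27.66, mean out-degree 2.28 (2225 ties / 976 actors)
    and reciprocity index 0.30.  ``n_actors`` defaults to a desk-scale 150
    rather than the original 976; tie-count targets are per-actor and so
    scale with n.
    """
    if n_actors < 10:
        raise ValueError("presets need at least 10 actors")
    return PopulationPreset(
        n_actors=n_actors,
        female_prop=0.4846,
        grade_probs=np.array([0.2879, 0.2848, 0.2172, 0.2100]),
        parental_discussion_prop=0.5840,
        depressive_mean=0.00,
        depressive_sd=0.53,
        parental_support_mean=-0.04,
        parental_support_sd=0.29,
        parental_monitoring_mean=-0.04,
        parental_monitoring_sd=0.10,
        home_smoking_mean=1.42,
        home_smoking_sd=0.73,
        mother_education_probs=np.array([0.0918, 0.4962, 0.3661, 0.0459]),
        limited_nomination_props=np.array([0.0482, 0.0041]),
        smoking_probs=np.array([0.4201, 0.2131, 0.0902, 0.2766]),
        mean_out_degree=2.28,
        reciprocity_target=0.30,
    )


def generate_covariates(
    preset: PopulationPreset, rng: np.random.Generator
) -> ActorCovariateTable:
    """Independent per-actor draws from the preset's marginals.

    Limited-nomination status is drawn per post-baseline wave (baseline is
    all-full) and converted to the per-period change flags (-1 newly
    limited, +1 returned to full).  Flagged actors are *not* degree-capped:
    the flag exists to exercise the ego-effect plumbing, not to reproduce
    the instrument error mechanically.
    """
    n = preset.n_actors
    table = pd.DataFrame(
        {
            "female": (rng.random(n) < preset.female_prop).astype(int),
            "grade": rng.choice(np.arange(9, 13), size=n, p=preset.grade_probs),
            "depressive_symptoms": rng.normal(
                preset.depressive_mean, preset.depressive_sd, n
            ),
            "parental_support": rng.normal(
                preset.parental_support_mean, preset.parental_support_sd, n
            ),
            "parental_monitoring": rng.normal(
                preset.parental_monitoring_mean, preset.parental_monitoring_sd, n
            ),
            "home_smoking_environment": np.clip(
                rng.normal(preset.home_smoking_mean, preset.home_smoking_sd, n),
                0.0, 3.0,
            ),
            "parental_discussion": (
                rng.random(n) < preset.parental_discussion_prop
            ).astype(int),
            "mother_education": rng.choice(
                np.arange(1, 5), size=n, p=preset.mother_education_probs
            ),
        }
    )
    limited_prev = np.zeros(n, dtype=bool)
    changes = []
    for prop in preset.limited_nomination_props:
        limited_now = rng.random(n) < prop
        changes.append(limited_now.astype(int) - limited_prev.astype(int))
        limited_prev = limited_now
    change = -np.column_stack(changes)  # -1 = full -> limited
    return ActorCovariateTable(table=table, limited_nomination_change=change)


def generate_initial_wave(
    preset: PopulationPreset,
    covariates: ActorCovariateTable,
    rng: np.random.Generator,
) -> tuple[DirectedNetwork, BehaviorVector]:
    """Draw the baseline wave: behavior from the smoking category
    distribution; the network dyad by dyad.

    Each unordered dyad lands in one of {null, i->j, j->i, mutual}.  The
    expected ordered-tie total matches ``mean_out_degree * n`` and the
    expected share of reciprocated ties matches ``reciprocity_target``;
    same-grade / same-gender dyads have their tie rates multiplied by the
    homophily odds factors (renormalized so the totals are preserved).
    """
    n = preset.n_actors
    behavior = BehaviorVector(
        rng.choice(np.arange(4), size=n, p=preset.smoking_probs), wave_label="wave 1"
    )
    ties = np.zeros((n, n), dtype=np.int8)
    total_target = preset.mean_out_degree * n
    if total_target > 0:
        grade = covariates.column("grade")
        female = covariates.column("female")
        iu, ju = np.triu_indices(n, k=1)
        weight = np.where(grade[iu] == grade[ju], preset.same_grade_odds, 1.0)
        weight = weight * np.where(
            female[iu] == female[ju], preset.same_gender_odds, 1.0
        )
        # expected ordered ties per dyad, proportional to the homophily weight
        t = total_target * weight / weight.sum()
        rho = preset.reciprocity_target
        mu = np.minimum(rho * t / 2.0, 1.0)            # P(mutual)
        alpha = np.minimum((1.0 - rho) * t / 2.0, 0.5)  # P(single tie, each way)
        u = rng.random(len(iu))
        mutual = u < mu
        fwd = (~mutual) & (u < mu + alpha)
        bwd = (~mutual) & (~fwd) & (u < mu + 2 * alpha)
        ties[iu[mutual], ju[mutual]] = 1
        ties[ju[mutual], iu[mutual]] = 1
        ties[iu[fwd], ju[fwd]] = 1
        ties[ju[bwd], iu[bwd]] = 1
    return DirectedNetwork(ties, wave_label="wave 1"), behavior


def generate_study(
    theta: np.ndarray,
    model: ModelSpec,
    preset: PopulationPreset,
    rng: np.random.Generator,
    keep_trace: bool = False,
):
    """Generate a complete co-evolution panel ready for estimation.

    Covariates and the baseline wave are drawn from the preset, then the
    later waves are produced by forward simulation at ``theta``.  A pure
    function of (preset, theta, rng state).  Returns (panel, trace).
    """
    covariates = generate_covariates(preset, rng)
    network0, behavior0 = generate_initial_wave(preset, covariates, rng)
    if covariates.n_periods != model.n_periods:
        # preset carries limited-nomination props for a fixed wave design;
        # pad or trim the change flags to the model's period count
        change = covariates.limited_nomination_change
        if change.shape[1] > model.n_periods:
            change = change[:, : model.n_periods]
        else:
            pad = np.zeros((preset.n_actors, model.n_periods - change.shape[1]), int)
            change = np.hstack([change, pad])
        covariates = ActorCovariateTable(
            table=covariates.table, limited_nomination_change=change
        )
    ctx = EffectContext(covariates, [behavior0])
    return simulate_panel(
        network0, behavior0, covariates, theta, model, rng,
        ctx=ctx, keep_trace=keep_trace,
    )
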