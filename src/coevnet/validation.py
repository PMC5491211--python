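"""Built-in validation experiments: oracle agreement, choice/rate laws,
parameter recovery and directional structure contrasts.

The original study data are restricted, so the package validates itself
against what *is* checkable at desk scale: exact agreement of every effect
statistic with naive loop references, exactness of the micro-step choice
law and the Poisson opportunity law, recovery of planted parameters from
synthetic panels, and qualitative structure signatures (transitivity rises
when transitive closure is favored and cyclic closure penalized).  The
test suite and the acceptance script both drive the functions here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .effects import (
    EffectContext,
    EffectSpec,
    ModelSpec,
    behavior_effect_statistic,
    effect_statistic,
)
from .estimate import EstimationSettings, robbins_monro
from .panel import (
    ActorCovariateTable,
    BehaviorVector,
    DirectedNetwork,
    transitivity_index,
)
from .reference import naive_behavior_statistic, naive_effect_statistic
from .simulate import CoevolutionState, network_microstep, simulate_period
from .synthetic import generate_covariates, generate_initial_wave, jefferson_preset

__all__ = [
    "all_effect_specs",
    "random_state",
    "effect_oracle_agreement",
    "microstep_choice_law",
    "rate_law_check",
    "recovery_experiment",
    "transitivity_contrast",
]


def all_effect_specs() -> tuple[list[EffectSpec], list[EffectSpec]]:
    """The full 20-network / 11-behavior effect roster, as two lists."""
    from .effects import default_coevolution_spec

    spec = default_coevolution_spec()
    return spec.network_effects, spec.behavior_effects


def _covariates_for(n: int, rng: np.random.Generator, n_periods: int = 2
                    ) -> ActorCovariateTable:
    preset = jefferson_preset(max(n, 10))
    cov = generate_covariates(preset, rng)
    if n < cov.n_actors:
        cov = ActorCovariateTable(
            table=cov.table.iloc[:n].reset_index(drop=True),
            limited_nomination_change=cov.limited_nomination_change[:n],
        )
    return cov


def random_state(n: int, rng: np.random.Generator, density: float = 0.3
                 ) -> tuple[np.ndarray, np.ndarray, EffectContext]:
    """A random (network, behavior, context) triple for oracle checks."""
    x = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(x, 0)
    z = rng.integers(0, 4, size=n)
    cov = _covariates_for(n, rng)
    ctx = EffectContext(cov, [BehaviorVector(z)])
    return x, z, ctx


def _enumerate_digraphs(n: int):
    """All labeled digraphs on n nodes (zero diagonal), as adjacency arrays."""
    off_diag = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product((0, 1), repeat=len(off_diag)):
        x = np.zeros((n, n), dtype=np.int8)
        for (i, j), b in zip(off_diag, bits):
            x[i, j] = b
        yield x


def effect_oracle_agreement(
    seed: int = 0,
    exhaustive_max_n: int = 4,
    n_sampled_n5: int = 500,
    n_random_large: int = 100,
    large_n: int = 15,
    atol: float = 1e-9,
) -> dict:
    """Compare every effect statistic against its naive loop reference.

    Exhaustively enumerates all digraphs up to ``exhaustive_max_n`` actors,
    samples random digraphs at n = 5, and checks ``n_random_large`` random
    states at ``large_n`` actors.  Returns counts and the worst absolute
    discrepancy; agreement means worst <= atol.
    """
    rng = np.random.default_rng(seed)
    net_effects, beh_effects = all_effect_specs()
    worst = 0.0
    n_states = 0

    def _check(x: np.ndarray, z: np.ndarray, ctx: EffectContext) -> float:
        local_worst = 0.0
        n = x.shape[0]
        for i in range(n):
            for eff in net_effects:
                a = effect_statistic(eff, x, z, i, ctx)
                b = naive_effect_statistic(eff, x, z, i, ctx)
                local_worst = max(local_worst, abs(a - b))
            for eff in beh_effects:
                a = behavior_effect_statistic(eff, x, z, i, ctx)
                b = naive_behavior_statistic(eff, x, z, i, ctx)
                local_worst = max(local_worst, abs(a - b))
        return local_worst

    for n in range(2, exhaustive_max_n + 1):
        cov = _covariates_for(n, rng)
        for x in _enumerate_digraphs(n):
            z = rng.integers(0, 4, size=n)
            ctx = EffectContext(cov, [BehaviorVector(z)])
            worst = max(worst, _check(x, z, ctx))
            n_states += 1

    cov5 = _covariates_for(5, rng)
    for _ in range(n_sampled_n5):
        x = (rng.random((5, 5)) < rng.uniform(0.1, 0.7)).astype(np.int8)
        np.fill_diagonal(x, 0)
        z = rng.integers(0, 4, size=5)
        ctx = EffectContext(cov5, [BehaviorVector(z)])
        worst = max(worst, _check(x, z, ctx))
        n_states += 1

    for _ in range(n_random_large):
        x, z, ctx = random_state(large_n, rng)
        worst = max(worst, _check(x, z, ctx))
        n_states += 1

    return {
        "n_states": n_states,
        "n_effects": len(net_effects) + len(beh_effects),
        "worst_abs_discrepancy": float(worst),
        "agreement": bool(worst <= atol),
    }


def microstep_choice_law(
    n: int = 8,
    n_draws: int = 100_000,
    seed: int = 0,
) -> dict:
    """Empirical micro-step choice frequencies vs exact logit probabilities.

    One actor in a random state under a model with several active network
    effects makes ``n_draws`` independent choices; returns the maximum
    z-score |freq - p| / sqrt(p (1-p) / N) over the n options.
    """
    from .effects import network_change_vector

    rng = np.random.default_rng(seed)
    x, z, ctx = random_state(n, rng)
    model = ModelSpec(
        network_effects=[
            EffectSpec("outdegree", "network"),
            EffectSpec("reciprocity", "network"),
            EffectSpec("transitive_triplets", "network"),
            EffectSpec("behavior_similarity", "network"),
        ],
        n_periods=1,
    )
    theta = np.array([1.0, -1.0, 1.2, 0.8, 0.5])  # rate + 4 betas
    i = 0
    _, _, betas, _ = model.split_theta(theta)
    u = network_change_vector(x, z, i, betas, model.network_effects, ctx, 0)
    p = np.exp(u - u.max())
    p /= p.sum()

    counts = np.zeros(n)
    state = CoevolutionState(x, z)
    for _ in range(n_draws):
        trial = state.copy()
        j = network_microstep(trial, i, theta, model, ctx, 0, rng)
        counts[j] += 1
    freq = counts / n_draws
    se = np.sqrt(p * (1 - p) / n_draws)
    z_scores = np.abs(freq - p) / np.where(se > 0, se, np.inf)
    return {
        "n_draws": n_draws,
        "max_z": float(z_scores.max()),
        "max_abs_error": float(np.abs(freq - p).max()),
    }


def rate_law_check(
    lam: float = 5.0,
    n: int = 30,
    n_replicates: int = 500,
    seed: int = 0,
) -> dict:
    """Mean micro-step opportunities per actor per period vs lambda.

    With all betas zero the number of opportunities is Poisson(n * lambda)
    per period; returns the z-score of the observed mean against that law.
    """
    rng = np.random.default_rng(seed)
    model = ModelSpec(
        network_effects=[EffectSpec("outdegree", "network")], n_periods=1
    )
    theta = np.array([lam, 0.0])
    cov = _covariates_for(n, rng, n_periods=1)
    cov = ActorCovariateTable(
        table=cov.table, limited_nomination_change=cov.limited_nomination_change[:, :1]
    )
    ctx = EffectContext(cov, [BehaviorVector(np.zeros(n, dtype=int))])
    x0 = np.zeros((n, n), dtype=np.int8)
    state = CoevolutionState(x0, np.zeros(n, dtype=int))

    from .simulate import SimulationTrace

    counts = np.empty(n_replicates)
    for b in range(n_replicates):
        trace = SimulationTrace()
        simulate_period(state, theta, model, ctx, 0, rng, trace=trace)
        counts[b] = len(trace.steps)
    mean_per_actor = counts.mean() / n
    se = np.sqrt(lam / n / n_replicates)  # sd of Poisson(n*lam)/n over reps
    return {
        "lambda": lam,
        "mean_steps_per_actor": float(mean_per_actor),
        "z": float((mean_per_actor - lam) / se),
        "n_replicates": n_replicates,
    }


@dataclass
class RecoverySettings:
    """Desk-scale estimation settings for the recovery experiment."""

    settings: EstimationSettings = None

    def __post_init__(self):
        if self.settings is None:
            self.settings = EstimationSettings(
                n_phase1=40,
                phase2_subphases=4,
                phase2_initial_length=50,
                initial_gain=0.2,
                n_phase3=3000,
                polish_schedule=(200, 500, 2000),
                phase3_derivative_reps=100,
            )


def recovery_model_spec() -> ModelSpec:
    return ModelSpec(
        network_effects=[
            EffectSpec("outdegree", "network"),
            EffectSpec("reciprocity", "network"),
        ],
        n_periods=2,
    )


def recovery_true_theta() -> np.ndarray:
    """Planted values: per-period network rates 4, out-degree -2,
    reciprocity 1.5."""
    return np.array([4.0, 4.0, -2.0, 1.5])


def recovery_replicate(n_actors: int, seed: int,
                       settings: EstimationSettings | None = None) -> dict:
    """Generate one synthetic panel at the planted theta and re-estimate."""
    from .synthetic import generate_study

    model = recovery_model_spec()
    theta_true = recovery_true_theta()
    rng = np.random.default_rng(seed)
    preset = jefferson_preset(n_actors)
    panel, _ = generate_study(theta_true, model, preset, rng)
    settings = settings or RecoverySettings().settings
    result = robbins_monro(panel, model, settings=settings, rng=rng)
    err = np.abs(result.theta_hat - theta_true)
    with np.errstate(divide="ignore"):
        within = bool(np.all(err <= 3.0 * result.standard_errors))
    return {
        "theta_hat": result.theta_hat.tolist(),
        "se": result.standard_errors.tolist(),
        "conv_t": result.convergence_t.tolist(),
        "converged": result.converged,
        "within_3se": within,
        "success": within and result.converged,
    }


def recovery_experiment(
    n_actors: int = 60,
    n_replicates: int = 20,
    seed: int = 0,
    settings: EstimationSettings | None = None,
) -> dict:
    """Repeat :func:`recovery_replicate`; summarize success rates."""
    root = np.random.SeedSequence(seed)
    reps = [
        recovery_replicate(n_actors, child, settings)
        for child in root.generate_state(n_replicates, dtype=np.uint32).tolist()
    ]
    theta_true = recovery_true_theta()
    theta_mat = np.array([r["theta_hat"] for r in reps])
    return {
        "n_actors": n_actors,
        "n_replicates": n_replicates,
        "theta_true": theta_true.tolist(),
        "theta_hat_mean": theta_mat.mean(axis=0).tolist(),
        "success_rate": float(np.mean([r["success"] for r in reps])),
        "within_3se_rate": float(np.mean([r["within_3se"] for r in reps])),
        "convergence_rate": float(np.mean([r["converged"] for r in reps])),
        "replicates": reps,
    }


def transitivity_contrast(
    n_actors: int = 40,
    n_replicates: int = 200,
    seed: int = 0,
    beta_transitive: float = 1.0,
    beta_cycles: float = -0.8,
) -> dict:
    """Paired simulation contrast: does favoring transitive closure while
    penalizing 3-cycles raise the simulated transitivity index over the
    beta = 0 baseline?

    Each replicate simulates one period twice from the same start state and
    seed: once with the structural betas planted, once with all betas zero.
    Returns the mean paired difference in end-of-period transitivity.
    """
    model = ModelSpec(
        network_effects=[
            EffectSpec("outdegree", "network"),
            EffectSpec("reciprocity", "network"),
            EffectSpec("transitive_triplets", "network"),
            EffectSpec("three_cycles", "network"),
        ],
        n_periods=1,
    )
    theta_structural = np.array([4.0, -2.0, 0.5, beta_transitive, beta_cycles])
    theta_null = np.array([4.0, -2.0, 0.5, 0.0, 0.0])

    root = np.random.SeedSequence(seed)
    setup_rng = np.random.default_rng(root.spawn(1)[0])
    preset = jefferson_preset(n_actors)
    cov = generate_covariates(preset, setup_rng)
    cov = ActorCovariateTable(
        table=cov.table, limited_nomination_change=cov.limited_nomination_change[:, :1]
    )
    net0, beh0 = generate_initial_wave(preset, cov, setup_rng)
    ctx = EffectContext(cov, [beh0])
    start = CoevolutionState(net0.ties, beh0.values)

    diffs = np.empty(n_replicates)
    children = root.spawn(n_replicates + 1)[1:]
    for b, child in enumerate(children):
        vals = []
        for theta in (theta_structural, theta_null):
            end = simulate_period(
                start, theta, model, ctx, 0, np.random.default_rng(child)
            )
            try:
                vals.append(transitivity_index(DirectedNetwork(end.network)))
            except Exception:
                vals.append(np.nan)
        diffs[b] = vals[0] - vals[1]
    diffs = diffs[np.isfinite(diffs)]
    mean = float(diffs.mean())
    se = float(diffs.std(ddof=1) / np.sqrt(len(diffs)))
    return {
        "n_replicates": int(len(diffs)),
        "mean_transitivity_gain": mean,
        "se": se,
        "z": mean / se if se > 0 else np.inf,
    }
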