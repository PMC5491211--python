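"""Method-of-moments estimation by Robbins-Monro stochastic approximation.

Theta is chosen so that the expected simulated target statistics match the
observed ones.  Targets: for each evaluation effect, the statistic summed
over actors at each period's end state (summed over periods); for each
network rate, the period's tie Hamming distance; for each behavior rate,
the summed absolute behavior change.  Simulations restart every period
from the observed start-of-period state.

The procedure has the classic three phases:

1. derivative matrix D of the targets w.r.t. theta by finite differences
   with common random numbers;
2. Robbins-Monro iterations theta <- theta - a * D^-1 (S_sim - S_obs) over
   subphases of doubling length with halving gain, averaging iterates
   within each subphase, followed by Newton "polish" steps on batch-mean
   deviations (with the Jacobian re-estimated at the current theta) that
   tighten theta onto the moment-equation root;
3. at the final theta, a large simulation batch giving convergence
   t-ratios t_k = mean(S_sim,k - S_obs,k) / sd(S_sim,k) and standard
   errors sqrt(diag(D^-1 Sigma D^-T)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import (
    EffectContext,
    ModelSpec,
    behavior_effect_statistic,
    effect_statistic,
)
from .panel import CoevolutionPanel
from .simulate import CoevolutionState, simulate_period

__all__ = [
    "EstimationSettings",
    "EstimationResult",
    "observed_targets",
    "initial_theta",
    "simulated_targets",
    "robbins_monro",
    "convergence_check",
    "CONVERGENCE_T_THRESHOLD",
]

#: field-conventional bound on |convergence t-ratio| for adequate convergence
CONVERGENCE_T_THRESHOLD = 0.1


@dataclass
class EstimationSettings:
    """Tuning constants of the stochastic-approximation algorithm."""

    n_phase1: int = 60              # common-random-number FD replicates for D
    phase2_subphases: int = 4
    phase2_initial_length: int = 50  # doubles each subphase
    initial_gain: float = 0.2        # halves each subphase
    n_phase3: int = 500
    fd_step: float = 0.1             # finite-difference perturbation per parameter
    rate_floor: float = 0.01
    beta_cap: float = 20.0
    max_step: float = 1.0            # per-component cap on one RM update
    polish_schedule: tuple = (100, 400)  # sims averaged per Newton polish step
    phase3_derivative_reps: int = 20  # FD replicates to refresh D at theta-hat


@dataclass
class EstimationResult:
    """Point estimates, uncertainties and convergence diagnostics."""

    theta_hat: np.ndarray
    standard_errors: np.ndarray
    convergence_t: np.ndarray
    observed: np.ndarray
    simulated_mean: np.ndarray
    derivative: np.ndarray
    n_phase3: int
    param_names: list[str]
    model: ModelSpec
    warnings_: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(np.all(np.abs(self.convergence_t) < CONVERGENCE_T_THRESHOLD))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta_hat,
                "se": self.standard_errors,
                "conv_t": self.convergence_t,
            },
            index=self.param_names,
        )


@dataclass
class ConvergenceReport:
    passed: bool
    offenders: list[tuple[str, float]]
    threshold: float = CONVERGENCE_T_THRESHOLD

    def __str__(self) -> str:
        if self.passed:
            return f"converged: all |t| < {self.threshold}"
        lines = [f"NOT converged (threshold {self.threshold}):"]
        lines += [f"  {name}: t = {t:+.3f}" for name, t in self.offenders]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------


def _state_effect_sums(
    x: np.ndarray,
    z: np.ndarray,
    model: ModelSpec,
    ctx: EffectContext,
    period: int,
) -> np.ndarray:
    """Sum over actors of every effect statistic at one state."""
    n = x.shape[0]
    out = np.zeros(len(model.network_effects) + len(model.behavior_effects))
    k = 0
    for eff in model.network_effects:
        out[k] = sum(effect_statistic(eff, x, z, i, ctx, period) for i in range(n))
        k += 1
    for eff in model.behavior_effects:
        out[k] = sum(
            behavior_effect_statistic(eff, x, z, i, ctx, period) for i in range(n)
        )
        k += 1
    return out


def _targets_from_states(
    start_states: list[CoevolutionState],
    end_states: list[CoevolutionState],
    model: ModelSpec,
    ctx: EffectContext,
) -> np.ndarray:
    """Assemble the moment target vector from per-period start/end states."""
    t_net_rate = np.zeros(model.n_network_rates)
    t_beh_rate = np.zeros(model.n_behavior_rates)
    t_eff = np.zeros(len(model.network_effects) + len(model.behavior_effects))
    for m, (s0, s1) in enumerate(zip(start_states, end_states)):
        t_net_rate[m] = float((s0.network != s1.network).sum())
        if model.behavior_rates_active:
            t_beh_rate[m] = float(np.abs(s1.behavior - s0.behavior).sum())
        t_eff += _state_effect_sums(s1.network, s1.behavior, model, ctx, m)
    return np.concatenate([t_net_rate, t_beh_rate, t_eff])


def observed_targets(
    panel: CoevolutionPanel,
    model: ModelSpec,
    ctx: EffectContext | None = None,
) -> np.ndarray:
    """Deterministic moment targets of the observed panel."""
    if model.n_periods != panel.n_periods:
        raise ValueError("model n_periods must match the panel")
    if ctx is None:
        ctx = EffectContext.from_panel(panel)
    states = [
        CoevolutionState(net.ties, beh.values)
        for net, beh in zip(panel.networks, panel.behaviors)
    ]
    return _targets_from_states(states[:-1], states[1:], model, ctx)


def simulated_targets(
    panel: CoevolutionPanel,
    model: ModelSpec,
    theta: np.ndarray,
    ctx: EffectContext,
    rng: np.random.Generator,
) -> np.ndarray:
    """Moment targets of one forward simulation (each period restarted from
    the observed start-of-period state).

    Each period gets its own spawned substream so that, under common random
    numbers, perturbing one period's parameters leaves the other periods'
    draws untouched.
    """
    starts, ends = [], []
    period_rngs = rng.spawn(model.n_periods)
    for m in range(model.n_periods):
        s0 = CoevolutionState(panel.networks[m].ties, panel.behaviors[m].values)
        s1 = simulate_period(s0, theta, model, ctx, m, period_rngs[m])
        starts.append(s0)
        ends.append(s1)
    return _targets_from_states(starts, ends, model, ctx)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initial_theta(panel: CoevolutionPanel, model: ModelSpec) -> np.ndarray:
    """Data-driven starting point: betas 0 except out-degree at the density
    logit; rates at the observed per-actor change counts (floored at 0.1)."""
    n = panel.n_actors
    theta = np.zeros(model.n_params)
    k = 0
    any_change = False
    for m in range(model.n_network_rates):
        ham = float((panel.networks[m].ties != panel.networks[m + 1].ties).sum())
        any_change = any_change or ham > 0
        theta[k] = max(ham / n, 0.1)
        k += 1
    for m in range(model.n_behavior_rates):
        change = float(
            np.abs(panel.behaviors[m + 1].values - panel.behaviors[m].values).sum()
        )
        any_change = any_change or change > 0
        theta[k] = max(change / n, 0.1)
        k += 1
    if not any_change:
        warnings.warn("panel shows no change between waves; rates start at the floor")
    density = np.mean([net.ties.mean() for net in panel.networks])
    density = min(max(density, 1e-6), 1 - 1e-6)
    for eff in model.network_effects:
        if eff.name == "outdegree":
            theta[k] = float(np.log(density / (1 - density)))
        k += 1
    return theta


# ---------------------------------------------------------------------------
# Robbins-Monro machinery
# ---------------------------------------------------------------------------


def _clamp(theta: np.ndarray, model: ModelSpec, settings: EstimationSettings
           ) -> np.ndarray:
    rate_mask = model.is_rate()
    out = theta.copy()
    out[rate_mask] = np.maximum(out[rate_mask], settings.rate_floor)
    out[~rate_mask] = np.clip(out[~rate_mask], -settings.beta_cap, settings.beta_cap)
    return out


def _estimate_derivative(
    panel: CoevolutionPanel,
    model: ModelSpec,
    theta: np.ndarray,
    ctx: EffectContext,
    settings: EstimationSettings,
    seed_seq: np.random.SeedSequence,
    n_reps: int,
) -> np.ndarray:
    """Finite-difference Jacobian dS/dtheta with common random numbers."""
    p = model.n_params
    eps = settings.fd_step
    d_sum = np.zeros((p, p))
    # integer seeds so each run rebuilds an identical, fresh random stream
    # (SeedSequence.spawn is stateful and would desynchronize the pairs)
    rep_seeds = seed_seq.generate_state(n_reps, dtype=np.uint32).tolist()
    for rep_seed in rep_seeds:
        base = simulated_targets(
            panel, model, theta, ctx, np.random.default_rng(rep_seed)
        )
        for k in range(p):
            pert = theta.copy()
            # step away from the clamp boundary if sitting on it
            direction = -1.0 if theta[k] >= settings.beta_cap - eps else 1.0
            pert[k] += direction * eps
            pert = _clamp(pert, model, settings)
            step = pert[k] - theta[k]
            if step == 0.0:
                raise FloatingPointError(
                    f"cannot perturb parameter {k} away from its bound"
                )
            s_k = simulated_targets(
                panel, model, pert, ctx, np.random.default_rng(rep_seed)
            )
            d_sum[:, k] += (s_k - base) / step
    return d_sum / n_reps


def _solve_derivative(d: np.ndarray, names: list[str]) -> np.ndarray:
    """Invert D, failing loudly with the most collinear parameters named."""
    u, s, vt = np.linalg.svd(d)
    if s[0] == 0 or s[-1] / s[0] < 1e-12:
        weights = np.abs(vt[-1])
        worst = [names[i] for i in np.argsort(weights)[::-1][:3]]
        raise np.linalg.LinAlgError(
            "derivative matrix is singular; near-collinear effects: "
            + ", ".join(worst)
        )
    return np.linalg.inv(d)


def robbins_monro(
    panel: CoevolutionPanel,
    model: ModelSpec,
    init: np.ndarray | None = None,
    settings: EstimationSettings | None = None,
    rng: np.random.Generator | int | None = None,
) -> EstimationResult:
    """Run the three-phase stochastic approximation; returns the result."""
    settings = settings or EstimationSettings()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    seed_seq = rng.bit_generator.seed_seq.spawn(3)
    ctx = EffectContext.from_panel(panel)
    s_obs = observed_targets(panel, model, ctx)
    theta = np.asarray(
        initial_theta(panel, model) if init is None else init, dtype=float
    ).copy()
    theta = _clamp(theta, model, settings)
    names = model.param_names()
    caught: list[str] = []

    # phase 1: derivative at the start
    d_hat = _estimate_derivative(
        panel, model, theta, ctx, settings, seed_seq[0], settings.n_phase1
    )
    d_inv = _solve_derivative(d_hat, names)

    # phase 2: Robbins-Monro iterations
    phase2_rng = np.random.default_rng(seed_seq[1])
    gain = settings.initial_gain
    length = settings.phase2_initial_length
    for _ in range(settings.phase2_subphases):
        iterates = np.empty((length, model.n_params))
        for it in range(length):
            s_sim = simulated_targets(panel, model, theta, ctx, phase2_rng)
            if not np.all(np.isfinite(s_sim)):
                bad = [names[j] for j in np.flatnonzero(~np.isfinite(s_sim))]
                raise FloatingPointError(
                    f"non-finite simulated targets for: {', '.join(bad)}"
                )
            update = np.clip(
                gain * (d_inv @ (s_sim - s_obs)),
                -settings.max_step, settings.max_step,
            )
            theta = _clamp(theta - update, model, settings)
            iterates[it] = theta
        theta = _clamp(iterates.mean(axis=0), model, settings)
        gain /= 2.0
        length *= 2

    # phase 2b: Newton polish — full steps on variance-reduced deviations,
    # tightening theta onto the moment-equation root; the growing batch
    # sizes shrink the residual t-ratio noise floor (~1/sqrt(batch)).
    # The Jacobian is re-estimated at the current theta before every step:
    # the phase-1 Jacobian from the start value is too stale for full
    # Newton steps.
    deriv_seq = seed_seq[2].spawn(len(settings.polish_schedule))
    for round_idx, n_reps in enumerate(settings.polish_schedule):
        d_hat = _estimate_derivative(
            panel, model, theta, ctx, settings, deriv_seq[round_idx],
            settings.phase3_derivative_reps,
        )
        d_inv = _solve_derivative(d_hat, names)
        devs = np.mean(
            [
                simulated_targets(panel, model, theta, ctx, phase2_rng) - s_obs
                for _ in range(n_reps)
            ],
            axis=0,
        )
        update = np.clip(d_inv @ devs, -settings.max_step, settings.max_step)
        theta = _clamp(theta - update, model, settings)

    # phase 3: diagnostics at theta-hat
    phase3_rng = np.random.default_rng(seed_seq[2].spawn(2)[1])
    sims = np.empty((settings.n_phase3, model.n_params))
    for b in range(settings.n_phase3):
        sims[b] = simulated_targets(panel, model, theta, ctx, phase3_rng)
    dev = sims - s_obs
    sd = sims.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        conv_t = np.where(sd > 0, dev.mean(axis=0) / sd, np.inf * np.sign(
            dev.mean(axis=0)))
    conv_t = np.where((sd == 0) & (np.abs(dev.mean(axis=0)) < 1e-12), 0.0, conv_t)
    sigma = np.atleast_2d(np.cov(sims, rowvar=False))
    cov_theta = d_inv @ sigma @ d_inv.T
    se = np.sqrt(np.maximum(np.diagonal(cov_theta), 0.0))

    rate_mask = model.is_rate()
    if np.any(theta[rate_mask] <= settings.rate_floor + 1e-9):
        msg = "one or more rate estimates sit at the lower bound"
        warnings.warn(msg)
        caught.append(msg)

    return EstimationResult(
        theta_hat=theta,
        standard_errors=se,
        convergence_t=conv_t,
        observed=s_obs,
        simulated_mean=sims.mean(axis=0),
        derivative=d_hat,
        n_phase3=settings.n_phase3,
        param_names=names,
        model=model,
        warnings_=caught,
    )


def convergence_check(result: EstimationResult) -> ConvergenceReport:
    """Pass iff every |convergence t-ratio| is below the 0.1 convention."""
    offenders = [
        (name, float(t))
        for name, t in zip(result.param_names, result.convergence_t)
        if not abs(t) < CONVERGENCE_T_THRESHOLD
    ]
    return ConvergenceReport(passed=not offenders, offenders=offenders)
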