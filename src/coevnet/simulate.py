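"""Continuous-time micro-step simulation of network-behavior co-evolution.

Between two observation waves (a *period*, with length normalized to 1),
change opportunities arrive as a Poisson process with total intensity
n * (lambda_net + lambda_beh).  At each opportunity one process is chosen
proportionally to its rate and one actor uniformly; the actor then makes a
single myopic multinomial-logit choice — toggle one outgoing tie (or keep
the status quo) for the network process, or move one step on the 0-3
behavior scale for the behavior process.  Simulation is unconditional
(time-driven): the period ends when the clock passes 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .effects import (
    EffectContext,
    ModelSpec,
    behavior_candidate_objectives,
    network_change_vector,
)
from .panel import (
    ActorCovariateTable,
    BehaviorVector,
    BEHAVIOR_MAX,
    BEHAVIOR_MIN,
    CoevolutionPanel,
    DirectedNetwork,
)

__all__ = [
    "CoevolutionState",
    "MicroStep",
    "SimulationTrace",
    "network_microstep",
    "behavior_microstep",
    "simulate_period",
    "simulate_panel",
]

_PROB_TOL = 1e-12


@dataclass
class CoevolutionState:
    """Mutable network + behavior snapshot inside a simulation run."""

    network: np.ndarray  # (n, n) int8 adjacency, zero diagonal
    behavior: np.ndarray  # (n,) ints in {0..3}
    clock: float = 0.0

    def __post_init__(self) -> None:
        self.network = np.array(self.network, dtype=np.int8)
        self.behavior = np.array(self.behavior, dtype=np.int64)
        if self.network.shape[0] != self.network.shape[1]:
            raise ValueError("adjacency must be square")
        if self.network.shape[0] != self.behavior.shape[0]:
            raise ValueError("network and behavior dimensions disagree")
        if np.diagonal(self.network).any():
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_actors(self) -> int:
        return self.network.shape[0]

    def copy(self) -> "CoevolutionState":
        return CoevolutionState(self.network.copy(), self.behavior.copy(), self.clock)


@dataclass(frozen=True)
class MicroStep:
    """One elementary change record: who did what, when."""

    time: float
    actor: int
    kind: str  # "network" | "behavior"
    choice: int  # alter toggled (or actor itself for "keep") / new behavior value


@dataclass
class SimulationTrace:
    """Ordered micro-step log plus the final state of a run."""

    steps: list[MicroStep] = field(default_factory=list)
    final_state: CoevolutionState | None = None

    def append(self, step: MicroStep) -> None:
        if self.steps and step.time <= self.steps[-1].time:
            raise ValueError("micro-step times must be strictly increasing")
        self.steps.append(step)


def _logit_choice(utilities: np.ndarray, rng: np.random.Generator,
                  unit_draw: float | None = None) -> int:
    """Draw an index with probability proportional to exp(utility).

    Sampling by inverse CDF on the unnormalized weights; the implied
    probabilities w / w.sum() are normalized by construction.
    """
    w = np.exp(utilities - utilities.max())
    cw = w.cumsum()
    total = cw[-1]
    assert np.isfinite(total) and total > 0.0
    if unit_draw is None:
        unit_draw = rng.random()
    return int(cw.searchsorted(unit_draw * total, side="right"))


def network_microstep(
    state: CoevolutionState,
    i: int,
    theta: np.ndarray,
    model: ModelSpec,
    ctx: EffectContext,
    period: int,
    rng: np.random.Generator,
) -> int:
    """Let actor ``i`` make one network choice, mutating ``state`` in place.

    The actor weighs n options — keep everything (objective change 0) or
    toggle the tie to each of the other n-1 actors — with multinomial-logit
    probabilities on the objective change.  Returns the chosen alter
    (``i`` itself for "keep").
    """
    _, _, net_betas, _ = model.split_theta(theta)
    u = network_change_vector(
        state.network, state.behavior, i, net_betas, model.network_effects, ctx, period
    )
    j = _logit_choice(u, rng)
    if j != i:
        state.network[i, j] = 1 - state.network[i, j]
    return j


def behavior_microstep(
    state: CoevolutionState,
    i: int,
    theta: np.ndarray,
    model: ModelSpec,
    ctx: EffectContext,
    period: int,
    rng: np.random.Generator,
) -> int:
    """Let actor ``i`` make one behavior choice, mutating ``state`` in place.

    Candidates are {z_i - 1, z_i, z_i + 1} truncated to the 0-3 scale,
    weighted by exp(behavior objective).  Returns the new behavior value.
    """
    _, _, _, beh_betas = model.split_theta(theta)
    zi = int(state.behavior[i])
    candidates = np.array(
        [v for v in (zi - 1, zi, zi + 1) if BEHAVIOR_MIN <= v <= BEHAVIOR_MAX]
    )
    u = behavior_candidate_objectives(
        state.network, state.behavior, i, candidates,
        beh_betas, model.behavior_effects, ctx, period,
    )
    choice = int(candidates[_logit_choice(u, rng)])
    state.behavior[i] = choice
    return choice


def simulate_period(
    state: CoevolutionState,
    theta: np.ndarray,
    model: ModelSpec,
    ctx: EffectContext,
    period: int,
    rng: np.random.Generator,
    trace: SimulationTrace | None = None,
    debug_checks: bool = False,
    time_offset: float = 0.0,
) -> CoevolutionState:
    """Simulate one observation period; returns the state at clock 1.

    Waiting times are Exponential(n * (lambda_net + lambda_beh)); a step
    whose arrival would pass clock 1 is not taken.  The input state is not
    modified.
    """
    net_rates, beh_rates, net_betas, beh_betas = model.split_theta(theta)
    lam_net = float(net_rates[period])
    lam_beh = float(beh_rates[period]) if model.behavior_rates_active else 0.0
    if lam_net < 0 or lam_beh < 0:
        raise ValueError("rate parameters must be nonnegative")

    state = state.copy()
    state.clock = 0.0
    n = state.n_actors
    total = n * (lam_net + lam_beh)
    if total == 0.0:
        warnings.warn("both rates are zero; period returns the state unchanged")
        state.clock = 1.0
        return state

    p_net = lam_net / (lam_net + lam_beh)
    net_effects = model.network_effects
    beh_effects = model.behavior_effects
    # float64 working copy: row/column views feed BLAS without per-step casts
    x = state.network.astype(np.float64)
    z = state.behavior

    # compiled fast path: only when nothing needs the per-step trace
    if trace is None and not debug_checks and _kernel.HAVE_NUMBA:
        try:
            net_plan = _kernel.build_network_plan(
                net_effects, ctx, state.n_actors, period
            )
            beh_plan = _kernel.build_behavior_plan(
                beh_effects, ctx, state.n_actors, period
            )
        except ValueError:
            net_plan = beh_plan = None
        if net_plan is not None:
            clock = 0.0
            block = 256
            while True:
                waits = rng.exponential(1.0 / total, size=block)
                actors = rng.integers(n, size=block)
                procs = rng.random(size=block)
                choices = rng.random(size=block)
                clock, done = _kernel.run_block(
                    x, z, clock, total, p_net,
                    net_plan[0], net_betas, net_plan[1],
                    beh_plan[0], beh_betas, beh_plan[1],
                    ctx.similarity_mean, ctx.behavior_mean,
                    waits, actors, procs, choices,
                )
                if done:
                    break
            state.network = x.astype(np.int8)
            state.clock = 1.0
            return state

    # draw randomness in fixed-size blocks: waiting time, actor, process,
    # choice.  The block size must not depend on theta, or common-random-
    # number derivative estimates would desynchronize.
    block = 256
    waits = actors = procs = choices = None
    cursor = block
    while True:
        if cursor >= block:
            waits = rng.exponential(1.0 / total, size=block)
            actors = rng.integers(n, size=block)
            procs = rng.random(size=block)
            choices = rng.random(size=block)
            cursor = 0
        state.clock += waits[cursor]
        if state.clock > 1.0:
            break
        i = int(actors[cursor])
        if procs[cursor] < p_net:
            u = network_change_vector(x, z, i, net_betas, net_effects, ctx, period)
            choice = _logit_choice(u, rng, unit_draw=choices[cursor])
            if choice != i:
                x[i, choice] = 1.0 - x[i, choice]
            kind = "network"
        else:
            zi = int(z[i])
            candidates = np.array(
                [v for v in (zi - 1, zi, zi + 1) if BEHAVIOR_MIN <= v <= BEHAVIOR_MAX]
            )
            u = behavior_candidate_objectives(
                x, z, i, candidates, beh_betas, beh_effects, ctx, period
            )
            choice = int(candidates[_logit_choice(u, rng, unit_draw=choices[cursor])])
            z[i] = choice
            kind = "behavior"
        cursor += 1
        if trace is not None:
            trace.append(MicroStep(time_offset + state.clock, i, kind, choice))
        if debug_checks:
            assert not np.diagonal(x).any()
            assert z.min() >= BEHAVIOR_MIN
            assert z.max() <= BEHAVIOR_MAX
    state.network = x.astype(np.int8)
    state.clock = 1.0
    return state


def simulate_panel(
    initial_network: DirectedNetwork,
    initial_behavior: BehaviorVector,
    covariates: ActorCovariateTable,
    theta: np.ndarray,
    model: ModelSpec,
    rng: np.random.Generator,
    ctx: EffectContext | None = None,
    keep_trace: bool = False,
) -> tuple[CoevolutionPanel, SimulationTrace]:
    """Chain :func:`simulate_period` over all periods from a first wave.

    Returns the generated panel (wave snapshots) and the micro-step trace.
    If no :class:`EffectContext` is supplied, centering constants are
    computed from the initial wave alone (the forward-simulation default).
    """
    if ctx is None:
        ctx = EffectContext(covariates, [initial_behavior])
    trace = SimulationTrace()
    state = CoevolutionState(initial_network.ties, initial_behavior.values)
    networks = [DirectedNetwork(state.network.copy(), wave_label="wave 1")]
    behaviors = [BehaviorVector(state.behavior.copy(), wave_label="wave 1")]
    for period in range(model.n_periods):
        state = simulate_period(
            state, theta, model, ctx, period, rng,
            trace=trace if keep_trace else None, time_offset=float(period),
        )
        label = f"wave {period + 2}"
        networks.append(DirectedNetwork(state.network.copy(), wave_label=label))
        behaviors.append(BehaviorVector(state.behavior.copy(), wave_label=label))
    trace.final_state = state
    panel = CoevolutionPanel(networks=networks, behaviors=behaviors, covariates=covariates)
    return panel, trace
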