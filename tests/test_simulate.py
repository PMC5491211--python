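"""Micro-step choice law, rate law, period simulation and reproducibility."""

import numpy as np
import pytest

from coevnet.effects import EffectContext, EffectSpec, ModelSpec
from coevnet.panel import BehaviorVector
from coevnet.simulate import (
    CoevolutionState,
    SimulationTrace,
    behavior_microstep,
    network_microstep,
    simulate_panel,
    simulate_period,
)
from coevnet.synthetic import generate_covariates, generate_initial_wave, jefferson_preset
from coevnet.validation import microstep_choice_law, rate_law_check

from conftest import make_covariates


def _ctx(n, z=None, n_periods=2, seed=0):
    cov = make_covariates(n, n_periods=n_periods, seed=seed)
    z = np.zeros(n, dtype=int) if z is None else z
    return cov, EffectContext(cov, [BehaviorVector(z)])


def outdeg_model(n_periods=1):
    return ModelSpec(network_effects=[EffectSpec("outdegree", "network")],
                     n_periods=n_periods)


class TestNetworkMicrostep:
    def test_uniform_choice_under_zero_betas(self):
        n = 4
        _, ctx = _ctx(n)
        model = outdeg_model()
        theta = np.array([1.0, 0.0])
        rng = np.random.default_rng(0)
        counts = np.zeros(n)
        for _ in range(8000):
            state = CoevolutionState(np.zeros((n, n), dtype=np.int8),
                                     np.zeros(n, dtype=int))
            j = network_microstep(state, 0, theta, model, ctx, 0, rng)
            counts[j] += 1
        freq = counts / counts.sum()
        se = np.sqrt(0.25 * 0.75 / 8000)
        assert np.all(np.abs(freq - 0.25) < 4 * se)

    def test_two_actor_creation_probability_closed_form(self):
        """n=2, out-degree beta 0.5, no tie: P(create) = e^0.5/(1+e^0.5)."""
        _, ctx = _ctx(2)
        model = outdeg_model()
        theta = np.array([1.0, 0.5])
        rng = np.random.default_rng(1)
        n_draws = 40000
        created = 0
        for _ in range(n_draws):
            state = CoevolutionState(np.zeros((2, 2), dtype=np.int8),
                                     np.zeros(2, dtype=int))
            if network_microstep(state, 0, theta, model, ctx, 0, rng) == 1:
                created += 1
        p = np.exp(0.5) / (1 + np.exp(0.5))  # ~0.6225
        se = np.sqrt(p * (1 - p) / n_draws)
        assert created / n_draws == pytest.approx(p, abs=4 * se)

    def test_empirical_frequencies_match_exact_logit(self):
        """Monte-Carlo choice frequencies agree with the exact multinomial
        logit within binomial error (several active effects)."""
        out = microstep_choice_law(n=8, n_draws=30000, seed=2)
        assert out["max_z"] < 4.0


class TestBehaviorMicrostep:
    def test_uniform_over_neighbors_at_zero_betas(self):
        n = 3
        model = ModelSpec(
            network_effects=[EffectSpec("outdegree", "network")],
            behavior_effects=[EffectSpec("linear_shape", "behavior")],
            n_periods=1,
        )
        theta = np.zeros(model.n_params)
        _, ctx = _ctx(n, z=np.ones(n, dtype=int))
        rng = np.random.default_rng(3)
        counts = {0: 0, 1: 0, 2: 0}
        for _ in range(9000):
            state = CoevolutionState(np.zeros((n, n), dtype=np.int8),
                                     np.ones(n, dtype=int))
            counts[behavior_microstep(state, 0, theta, model, ctx, 0, rng)] += 1
        freq = np.array([counts[k] for k in (0, 1, 2)]) / 9000
        se = np.sqrt((1 / 3) * (2 / 3) / 9000)
        assert np.all(np.abs(freq - 1 / 3) < 4 * se)

    def test_boundary_truncation_at_scale_ends(self):
        n = 3
        model = ModelSpec(
            network_effects=[EffectSpec("outdegree", "network")],
            behavior_effects=[EffectSpec("linear_shape", "behavior")],
            n_periods=1,
        )
        theta = np.zeros(model.n_params)
        _, ctx = _ctx(n)
        rng = np.random.default_rng(4)
        for z0, allowed in [(0, {0, 1}), (3, {2, 3})]:
            seen = set()
            for _ in range(300):
                state = CoevolutionState(np.zeros((n, n), dtype=np.int8),
                                         np.full(n, z0, dtype=int))
                seen.add(behavior_microstep(state, 0, theta, model, ctx, 0, rng))
            assert seen == allowed


class TestSimulatePeriod:
    def test_zero_rates_leave_state_unchanged(self):
        n = 4
        _, ctx = _ctx(n)
        model = outdeg_model()
        state = CoevolutionState(np.zeros((n, n), dtype=np.int8),
                                 np.zeros(n, dtype=int))
        with pytest.warns(UserWarning, match="rates are zero"):
            out = simulate_period(state, np.array([0.0, 1.0]), model, ctx, 0,
                                  np.random.default_rng(0))
        assert np.array_equal(out.network, state.network)

    def test_mean_microstep_count_matches_rate(self):
        """Opportunities per actor per period are Poisson(lambda)."""
        out = rate_law_check(lam=5.0, n=25, n_replicates=250, seed=5)
        assert abs(out["z"]) < 4.0

    def test_hamming_drift_increases_with_rate(self):
        """At zero betas the expected wave-to-wave Hamming distance grows
        with the network rate."""
        n = 12
        _, ctx = _ctx(n, n_periods=1)
        model = outdeg_model()
        rng = np.random.default_rng(6)
        start = CoevolutionState(np.zeros((n, n), dtype=np.int8),
                                 np.zeros(n, dtype=int))
        means = []
        for lam in (1.0, 5.0, 10.0):
            dists = []
            for _ in range(120):
                end = simulate_period(start, np.array([lam, 0.0]), model, ctx, 0, rng)
                dists.append((end.network != start.network).sum())
            means.append(np.mean(dists))
        assert means[0] < means[1] < means[2]

    def test_strongly_negative_density_keeps_network_empty(self):
        n = 15
        _, ctx = _ctx(n, n_periods=1)
        model = outdeg_model()
        start = CoevolutionState(np.zeros((n, n), dtype=np.int8),
                                 np.zeros(n, dtype=int))
        end = simulate_period(start, np.array([5.0, -8.0]), model, ctx, 0,
                              np.random.default_rng(7))
        assert end.network.mean() < 0.01


class TestSimulatePanel:
    def _setup(self, n=20, seed=0):
        preset = jefferson_preset(n)
        rng = np.random.default_rng(seed)
        cov = generate_covariates(preset, rng)
        net0, beh0 = generate_initial_wave(preset, cov, rng)
        return cov, net0, beh0

    def test_seeded_runs_are_bitwise_identical(self):
        cov, net0, beh0 = self._setup()
        model = ModelSpec(
            network_effects=[EffectSpec("outdegree", "network"),
                             EffectSpec("reciprocity", "network")],
            n_periods=2,
        )
        theta = np.array([3.0, 3.0, -2.0, 1.0])
        panels = []
        traces = []
        for _ in range(2):
            panel, trace = simulate_panel(net0, beh0, cov, theta, model,
                                          np.random.default_rng(42), keep_trace=True)
            panels.append(panel)
            traces.append(trace)
        for a, b in zip(panels[0].networks, panels[1].networks):
            assert np.array_equal(a.ties, b.ties)
        assert traces[0].steps == traces[1].steps

    def test_trace_times_strictly_increasing_across_periods(self):
        cov, net0, beh0 = self._setup()
        model = outdeg_model(n_periods=2)
        theta = np.array([2.0, 2.0, -1.0])
        _, trace = simulate_panel(net0, beh0, cov, theta, model,
                                  np.random.default_rng(1), keep_trace=True)
        times = [s.time for s in trace.steps]
        assert all(b > a for a, b in zip(times, times[1:]))
        assert trace.final_state is not None

    def test_behavior_stays_on_scale_and_diagonal_zero(self):
        cov, net0, beh0 = self._setup(seed=9)
        model = ModelSpec(
            network_effects=[EffectSpec("outdegree", "network")],
            behavior_effects=[EffectSpec("linear_shape", "behavior")],
            n_periods=2,
        )
        theta = np.array([3.0, 3.0, 4.0, 4.0, -1.0, 2.0])
        panel, _ = simulate_panel(net0, beh0, cov, theta, model,
                                  np.random.default_rng(2))
        for net, beh in zip(panel.networks, panel.behaviors):
            assert not np.diagonal(net.ties).any()
            assert beh.values.min() >= 0 and beh.values.max() <= 3

    def test_positive_reciprocity_raises_simulated_reciprocity(self):
        """Paired simulation: reciprocity beta 1.5 vs 0, same seeds."""
        from coevnet.panel import reciprocity_index

        cov, net0, beh0 = self._setup(n=25, seed=3)
        model = ModelSpec(
            network_effects=[EffectSpec("outdegree", "network"),
                             EffectSpec("reciprocity", "network")],
            n_periods=1,
        )
        diffs = []
        for rep in range(60):
            vals = []
            for beta_r in (1.5, 0.0):
                theta = np.array([4.0, -2.0, beta_r])
                panel, _ = simulate_panel(net0, beh0, cov, theta, model,
                                          np.random.default_rng(1000 + rep))
                vals.append(reciprocity_index(panel.networks[1]))
            diffs.append(vals[0] - vals[1])
        mean = np.mean(diffs)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert mean > 3 * se
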