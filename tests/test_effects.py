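"""Effect statistics vs naive oracles, objective functions, change deltas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevnet.effects import (
    EffectContext,
    EffectSpec,
    ModelSpec,
    behavior_candidate_objectives,
    behavior_effect_statistic,
    behavior_objective,
    default_coevolution_spec,
    effect_statistic,
    network_change_vector,
    network_objective,
    network_objective_change,
    similarity,
)
from coevnet.panel import BehaviorVector
from coevnet.reference import naive_behavior_statistic, naive_effect_statistic
from coevnet.validation import all_effect_specs, random_state

from conftest import adjacency_from_edges, make_covariates

NET_EFFECTS, BEH_EFFECTS = all_effect_specs()


def small_state(n=5, seed=0, density=0.4):
    rng = np.random.default_rng(seed)
    return random_state(n, rng, density)


class TestSimilarity:
    @pytest.mark.parametrize(
        "zi,zj,expected", [(2, 2, 1.0), (0, 3, 0.0), (1, 3, 1 / 3), (3, 1, 1 / 3)]
    )
    def test_values(self, zi, zj, expected):
        assert similarity(zi, zj, 3) == pytest.approx(expected)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            similarity(1, 2, 0)


class TestEffectSpecValidation:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            EffectSpec("popularity_of_ego", "network")

    def test_covariate_requirements_enforced(self):
        with pytest.raises(ValueError, match="requires a covariate"):
            EffectSpec("covariate_alter", "network")
        with pytest.raises(ValueError, match="does not take"):
            EffectSpec("reciprocity", "network", "female")

    def test_duplicate_effects_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec(network_effects=[
                EffectSpec("outdegree", "network"),
                EffectSpec("outdegree", "network"),
            ])

    def test_default_spec_has_full_roster(self):
        spec = default_coevolution_spec()
        assert len(spec.network_effects) == 20
        assert len(spec.behavior_effects) == 11
        assert spec.n_params == 2 + 2 + 20 + 11

    def test_yaml_round_trip(self, tmp_path):
        spec = default_coevolution_spec()
        path = tmp_path / "model.yaml"
        spec.to_yaml(path)
        back = ModelSpec.from_yaml(path)
        assert back.to_dict() == spec.to_dict()


class TestStatisticsAgainstOracles:
    @pytest.mark.parametrize("eff", NET_EFFECTS, ids=lambda e: e.key)
    def test_network_statistics_match_naive_loops(self, eff):
        for seed in range(10):
            x, z, ctx = small_state(n=6, seed=seed)
            for i in range(6):
                assert effect_statistic(eff, x, z, i, ctx) == pytest.approx(
                    naive_effect_statistic(eff, x, z, i, ctx), abs=1e-10
                )

    @pytest.mark.parametrize("eff", BEH_EFFECTS, ids=lambda e: e.key)
    def test_behavior_statistics_match_naive_loops(self, eff):
        for seed in range(10):
            x, z, ctx = small_state(n=6, seed=seed)
            for i in range(6):
                for cand in (None, 0, 3):
                    assert behavior_effect_statistic(
                        eff, x, z, i, ctx, candidate=cand
                    ) == pytest.approx(
                        naive_behavior_statistic(eff, x, z, i, ctx, candidate=cand),
                        abs=1e-10,
                    )

    def test_tie_dependent_effects_vanish_on_empty_network(self):
        n = 5
        x = np.zeros((n, n), dtype=np.int8)
        z = np.array([0, 1, 2, 3, 1])
        ctx = EffectContext(make_covariates(n), [BehaviorVector(z)])
        for eff in NET_EFFECTS:
            assert effect_statistic(eff, x, z, 0, ctx) == 0.0

    def test_transitive_triplets_on_known_triad(self):
        # ties 1->2, 1->3, 3->2: actor 1 heads one transitive triplet
        x = adjacency_from_edges(4, [(1, 2), (1, 3), (3, 2)])
        z = np.zeros(4, dtype=int)
        ctx = EffectContext(make_covariates(4), [BehaviorVector(z)])
        eff = EffectSpec("transitive_triplets", "network")
        assert effect_statistic(eff, x, z, 1, ctx) == 1.0

    def test_betweenness_on_known_broker(self):
        # 2->1, 1->3 and 2 does not support 3: actor 1 brokers one pair
        x = adjacency_from_edges(4, [(2, 1), (1, 3)])
        z = np.zeros(4, dtype=int)
        ctx = EffectContext(make_covariates(4), [BehaviorVector(z)])
        eff = EffectSpec("betweenness", "network")
        assert effect_statistic(eff, x, z, 1, ctx) == 1.0

    def test_statistics_permutation_equivariant(self):
        x, z, ctx = small_state(n=7, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(7)
        xp = x[np.ix_(perm, perm)]
        zp = z[perm]
        cov = ctx.covariates
        table_p = cov.table.iloc[perm].reset_index(drop=True)
        from coevnet.panel import ActorCovariateTable

        cov_p = ActorCovariateTable(
            table=table_p,
            limited_nomination_change=cov.limited_nomination_change[perm],
        )
        ctx_p = EffectContext(cov_p, [BehaviorVector(zp)])
        for eff in NET_EFFECTS:
            for i in range(7):
                assert effect_statistic(
                    eff, xp, zp, int(np.flatnonzero(perm == i)[0]), ctx_p
                ) == pytest.approx(effect_statistic(eff, x, z, i, ctx), abs=1e-10)


class TestObjectives:
    def test_zero_betas_give_zero_objective(self):
        x, z, ctx = small_state()
        betas = np.zeros(len(NET_EFFECTS))
        assert network_objective(x, z, 0, betas, NET_EFFECTS, ctx) == 0.0
        assert behavior_objective(x, z, 0, 2, np.zeros(len(BEH_EFFECTS)),
                                  BEH_EFFECTS, ctx) == 0.0

    def test_outdegree_only_objective_scales_with_ties(self):
        # published density coefficient -3.83 with two out-ties
        x = adjacency_from_edges(4, [(0, 1), (0, 2)])
        z = np.zeros(4, dtype=int)
        ctx = EffectContext(make_covariates(4), [BehaviorVector(z)])
        effects = [EffectSpec("outdegree", "network")]
        val = network_objective(x, z, 0, np.array([-3.83]), effects, ctx)
        assert val == pytest.approx(-7.66)

    def test_objective_equals_weighted_oracle_sum(self):
        x, z, ctx = small_state(n=6, seed=11)
        rng = np.random.default_rng(5)
        betas = rng.normal(0, 0.7, len(NET_EFFECTS))
        for i in range(6):
            expected = sum(
                b * naive_effect_statistic(e, x, z, i, ctx)
                for b, e in zip(betas, NET_EFFECTS)
            )
            assert network_objective(x, z, i, betas, NET_EFFECTS, ctx) == pytest.approx(
                expected, abs=1e-9
            )

    def test_linear_quadratic_maximizer_matches_grid(self):
        x, z, ctx = small_state(n=5, seed=2)
        effects = [
            EffectSpec("linear_shape", "behavior"),
            EffectSpec("quadratic_shape", "behavior"),
        ]
        for b_lin, b_quad in [(1.0, -0.5), (-1.5, 0.3), (0.2, 0.2)]:
            betas = np.array([b_lin, b_quad])
            cands = np.arange(4)
            u = behavior_candidate_objectives(x, z, 0, cands, betas, effects, ctx)
            grid = [behavior_objective(x, z, 0, c, betas, effects, ctx) for c in cands]
            assert np.allclose(u, grid)

    def test_incoming_similarity_pulls_toward_supporters(self):
        # all supporters of actor 0 smoke heavily -> objective increases in z
        n = 5
        x = adjacency_from_edges(n, [(1, 0), (2, 0), (3, 0)])
        z = np.array([0, 3, 3, 3, 0])
        ctx = EffectContext(make_covariates(n), [BehaviorVector(z)])
        effects = [EffectSpec("average_incoming_similarity", "behavior")]
        u = behavior_candidate_objectives(
            x, z, 0, np.arange(4), np.array([1.0]), effects, ctx
        )
        assert np.all(np.diff(u) > 0)

    def test_candidate_out_of_scale_rejected(self):
        x, z, ctx = small_state()
        with pytest.raises(ValueError):
            behavior_objective(x, z, 0, 4, np.zeros(len(BEH_EFFECTS)), BEH_EFFECTS, ctx)


class TestChangeContributions:
    @pytest.mark.parametrize("seed", range(20))
    def test_change_vector_matches_full_recompute(self, seed):
        """Incremental objective changes equal brute-force recomputation of
        both objectives on random 12-actor states."""
        rng = np.random.default_rng(seed)
        x, z, ctx = random_state(12, rng)
        betas = rng.normal(0, 0.6, len(NET_EFFECTS))
        i = int(rng.integers(12))
        u = network_change_vector(x, z, i, betas, NET_EFFECTS, ctx)
        assert u[i] == 0.0
        before = network_objective(x, z, i, betas, NET_EFFECTS, ctx)
        for j in range(12):
            if j == i:
                continue
            x2 = x.copy()
            x2[i, j] = 1 - x2[i, j]
            after = network_objective(x2, z, i, betas, NET_EFFECTS, ctx)
            assert u[j] == pytest.approx(after - before, abs=1e-9)

    def test_toggle_involution(self):
        """The change of toggling back equals minus the original change."""
        rng = np.random.default_rng(99)
        x, z, ctx = random_state(8, rng)
        betas = rng.normal(0, 0.8, len(NET_EFFECTS))
        for j in range(1, 8):
            fwd = network_objective_change(x, z, 0, j, betas, NET_EFFECTS, ctx)
            x2 = x.copy()
            x2[0, j] = 1 - x2[0, j]
            back = network_objective_change(x2, z, 0, j, betas, NET_EFFECTS, ctx)
            assert fwd == pytest.approx(-back, abs=1e-9)

    def test_self_toggle_rejected(self):
        x, z, ctx = small_state()
        with pytest.raises(ValueError):
            network_objective_change(x, z, 2, 2, np.zeros(len(NET_EFFECTS)),
                                     NET_EFFECTS, ctx)

    def test_outdegree_only_change_is_beta(self):
        x, z, ctx = small_state(n=4, seed=0, density=0.0)
        effects = [EffectSpec("outdegree", "network")]
        u = network_change_vector(x, z, 0, np.array([0.7]), effects, ctx)
        assert np.allclose(np.delete(u, 0), 0.7)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_change_vector_property_random_states(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x, z, ctx = random_state(n, rng)
        betas = rng.normal(0, 1.0, len(NET_EFFECTS))
        i = int(rng.integers(n))
        u = network_change_vector(x, z, i, betas, NET_EFFECTS, ctx)
        before = network_objective(x, z, i, betas, NET_EFFECTS, ctx)
        j = int(rng.integers(n))
        if j == i:
            return
        x[i, j] = 1 - x[i, j]
        after = network_objective(x, z, i, betas, NET_EFFECTS, ctx)
        assert u[j] == pytest.approx(after - before, abs=1e-8)


class TestCentering:
    def test_uniform_covariate_ego_alter_reduce_to_outdegree_multiples(self):
        """With centering removed and equal covariates, ego/alter effects are
        proportional to out-degree."""
        n = 6
        cov = make_covariates(n)
        cov.table["depressive_symptoms"] = 1.7
        from coevnet.panel import ActorCovariateTable

        cov = ActorCovariateTable(
            table=cov.table,
            limited_nomination_change=cov.limited_nomination_change,
        )
        rng = np.random.default_rng(0)
        x = (rng.random((n, n)) < 0.5).astype(np.int8)
        np.fill_diagonal(x, 0)
        z = rng.integers(0, 4, n)
        ctx = EffectContext(cov, [BehaviorVector(z)])
        ctx.centered["depressive_symptoms"] = ctx.raw["depressive_symptoms"]
        ego = EffectSpec("covariate_ego", "network", "depressive_symptoms")
        alter = EffectSpec("covariate_alter", "network", "depressive_symptoms")
        out = EffectSpec("outdegree", "network")
        for i in range(n):
            d = effect_statistic(out, x, z, i, ctx)
            assert effect_statistic(ego, x, z, i, ctx) == pytest.approx(1.7 * d)
            assert effect_statistic(alter, x, z, i, ctx) == pytest.approx(1.7 * d)

    def test_similarity_centering_constant_from_panel(self, toy_panel):
        ctx = EffectContext.from_panel(toy_panel)
        sims = []
        for beh in toy_panel.behaviors:
            z = beh.values
            for i in range(len(z)):
                for j in range(len(z)):
                    if i != j:
                        sims.append(1 - abs(z[i] - z[j]) / 3)
        assert ctx.similarity_mean == pytest.approx(np.mean(sims))
        z_all = np.concatenate([b.values for b in toy_panel.behaviors])
        assert ctx.behavior_mean == pytest.approx(z_all.mean())
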