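"""Loop-based reference implementations used for validation.

Every effect statistic and descriptive index has a second, deliberately
naive implementation here — explicit Python loops transcribing the
defining sums, with no shared code or vectorization tricks.  The test
suite and the acceptance checks compare the production (vectorized)
implementations against these on enumerated and random states.
"""

from __future__ import annotations

import numpy as np

from .effects import BEHAVIOR_RANGE, EffectContext, EffectSpec
from .panel import DirectedNetwork

__all__ = [
    "naive_effect_statistic",
    "naive_behavior_statistic",
    "naive_reciprocity",
    "naive_transitivity",
    "naive_jaccard",
]


def naive_reciprocity(net: DirectedNetwork) -> float:
    x = net.ties
    n = net.n_actors
    ties = recip = 0
    for i in range(n):
        for j in range(n):
            if x[i, j]:
                ties += 1
                if x[j, i]:
                    recip += 1
    if ties == 0:
        raise ZeroDivisionError
    return recip / ties


def naive_transitivity(net: DirectedNetwork) -> float:
    x = net.ties
    n = net.n_actors
    paths = closed = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i == j or j == k or i == k:
                    continue
                if x[i, j] and x[j, k]:
                    paths += 1
                    if x[i, k]:
                        closed += 1
    if paths == 0:
        raise ZeroDivisionError
    return closed / paths


def naive_jaccard(net_a: DirectedNetwork, net_b: DirectedNetwork) -> float:
    a = {tuple(e) for e in net_a.edge_list().tolist()}
    b = {tuple(e) for e in net_b.edge_list().tolist()}
    if not a | b:
        raise ZeroDivisionError
    return len(a & b) / len(a | b)


def naive_effect_statistic(
    effect: EffectSpec,
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    ctx: EffectContext,
    period: int = 0,
) -> float:
    """Defining sum of one network-equation statistic, written as loops."""
    n = x.shape[0]
    name = effect.name
    others = [j for j in range(n) if j != i]

    def indeg(a: int) -> int:
        return sum(int(x[k, a]) for k in range(n))

    def outdeg(a: int) -> int:
        return sum(int(x[a, k]) for k in range(n))

    if name == "outdegree":
        return float(sum(int(x[i, j]) for j in others))
    if name == "reciprocity":
        return float(sum(x[i, j] * x[j, i] for j in others))
    if name == "transitive_triplets":
        total = 0
        for j in others:
            for k in others:
                total += x[i, j] * x[i, k] * x[k, j]
        return float(total)
    if name == "three_cycles":
        total = 0
        for j in others:
            for k in others:
                total += x[i, j] * x[j, k] * x[k, i]
        return float(total)
    if name == "betweenness":
        total = 0
        for j in others:
            for k in others:
                if j == k:
                    continue
                total += x[j, i] * x[i, k] * (1 - x[j, k])
        return float(total)
    if name == "indegree_popularity":
        return float(sum(x[i, j] * indeg(j) for j in others))
    if name == "out_in_sqrt_assortativity":
        return float(
            sum(x[i, j] * np.sqrt(outdeg(i)) * np.sqrt(indeg(j)) for j in others)
        )
    if name == "indegree_activity":
        return float(indeg(i) * outdeg(i))
    if name == "indegree_squared_activity":
        return float(indeg(i) ** 2 * outdeg(i))
    if name == "behavior_similarity":
        total = 0.0
        for j in others:
            sim = 1.0 - abs(float(z[i]) - float(z[j])) / BEHAVIOR_RANGE
            total += x[i, j] * (sim - ctx.similarity_mean)
        return total
    if name == "same_covariate":
        v = ctx.raw_value(effect.covariate, z, period)
        return float(sum(x[i, j] * (1 if v[i] == v[j] else 0) for j in others))
    if name == "covariate_alter":
        v = ctx.actor_value(effect.covariate, z, period)
        return float(sum(x[i, j] * v[j] for j in others))
    if name == "covariate_ego":
        v = ctx.actor_value(effect.covariate, z, period)
        return float(v[i] * outdeg(i))
    raise ValueError(name)


def naive_behavior_statistic(
    effect: EffectSpec,
    x: np.ndarray,
    z: np.ndarray,
    i: int,
    ctx: EffectContext,
    period: int = 0,
    candidate: int | None = None,
) -> float:
    """Defining sum of one behavior-equation statistic, written as loops."""
    n = x.shape[0]
    zi = float(z[i] if candidate is None else candidate)
    zc = zi - ctx.behavior_mean
    name = effect.name
    if name == "linear_shape":
        return zc
    if name == "quadratic_shape":
        return zc**2
    if name == "indegree":
        return zc * sum(int(x[j, i]) for j in range(n))
    if name == "average_incoming_similarity":
        supporters = [j for j in range(n) if x[j, i]]
        if not supporters:
            return 0.0
        total = 0.0
        for j in supporters:
            sim = 1.0 - abs(zi - float(z[j])) / BEHAVIOR_RANGE
            total += sim - ctx.similarity_mean
        return total / len(supporters)
    if name == "covariate_main":
        v = ctx.actor_value(effect.covariate, z, period)
        return zc * float(v[i])
    raise ValueError(name)
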