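"""Compiled inner loop for period simulation.

The micro-step loop is the computational bottleneck of estimation (tens of
millions of steps per fit).  This module provides a numba translation of
the loop in :mod:`coevnet.simulate` for models whose effects are all in the
closed catalog (which all shipped effects are).  It consumes the exact same
pre-drawn randomness blocks in the same order as the pure-numpy loop, so a
run is reproducible across the two paths up to floating-point summation
order.  When numba is unavailable the simulator transparently falls back
to the numpy loop.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


# network effect opcodes (order-free; one row of `net_vecs` per effect)
NET_OUTDEGREE = 0
NET_RECIPROCITY = 1
NET_TRANSITIVE_TRIPLETS = 2
NET_THREE_CYCLES = 3
NET_BETWEENNESS = 4
NET_INDEGREE_POPULARITY = 5
NET_OUT_IN_SQRT_ASSORTATIVITY = 6
NET_INDEGREE_ACTIVITY = 7
NET_INDEGREE_SQUARED_ACTIVITY = 8
NET_BEHAVIOR_SIMILARITY = 9
NET_SAME_COVARIATE = 10
NET_COVARIATE_ALTER = 11
NET_COVARIATE_EGO = 12
NET_BEHAVIOR_ALTER = 13
NET_BEHAVIOR_EGO = 14

BEH_LINEAR = 0
BEH_QUADRATIC = 1
BEH_INDEGREE = 2
BEH_AVG_INCOMING_SIMILARITY = 3
BEH_COVARIATE_MAIN = 4

_NET_CODE_BY_NAME = {
    "outdegree": NET_OUTDEGREE,
    "reciprocity": NET_RECIPROCITY,
    "transitive_triplets": NET_TRANSITIVE_TRIPLETS,
    "three_cycles": NET_THREE_CYCLES,
    "betweenness": NET_BETWEENNESS,
    "indegree_popularity": NET_INDEGREE_POPULARITY,
    "out_in_sqrt_assortativity": NET_OUT_IN_SQRT_ASSORTATIVITY,
    "indegree_activity": NET_INDEGREE_ACTIVITY,
    "indegree_squared_activity": NET_INDEGREE_SQUARED_ACTIVITY,
    "behavior_similarity": NET_BEHAVIOR_SIMILARITY,
}


def build_network_plan(effects, ctx, z_placeholder_n, period):
    """Pack the network effect list into kernel opcode/value arrays.

    Returns (codes, vecs) where ``vecs[k]`` holds the per-actor covariate
    values an effect needs (zeros when unused).  Effects on the co-evolving
    behavior get dedicated opcodes since their values change mid-period.
    """
    n = z_placeholder_n
    codes = np.empty(len(effects), dtype=np.int64)
    vecs = np.zeros((max(len(effects), 1), n), dtype=np.float64)
    for k, eff in enumerate(effects):
        if eff.name in _NET_CODE_BY_NAME:
            codes[k] = _NET_CODE_BY_NAME[eff.name]
        elif eff.name == "same_covariate":
            if eff.covariate == "behavior":
                raise ValueError("same_covariate on behavior not compiled")
            codes[k] = NET_SAME_COVARIATE
            vecs[k] = ctx.raw_value(eff.covariate, None, period)
        elif eff.name == "covariate_alter":
            if eff.covariate == "behavior":
                codes[k] = NET_BEHAVIOR_ALTER
            else:
                codes[k] = NET_COVARIATE_ALTER
                vecs[k] = ctx.actor_value(eff.covariate, None, period)
        elif eff.name == "covariate_ego":
            if eff.covariate == "behavior":
                codes[k] = NET_BEHAVIOR_EGO
            else:
                codes[k] = NET_COVARIATE_EGO
                vecs[k] = ctx.actor_value(eff.covariate, None, period)
        else:  # pragma: no cover - catalog is closed
            raise ValueError(eff.name)
    return codes, vecs


def build_behavior_plan(effects, ctx, n, period):
    codes = np.empty(len(effects), dtype=np.int64)
    vecs = np.zeros((max(len(effects), 1), n), dtype=np.float64)
    names = {
        "linear_shape": BEH_LINEAR,
        "quadratic_shape": BEH_QUADRATIC,
        "indegree": BEH_INDEGREE,
        "average_incoming_similarity": BEH_AVG_INCOMING_SIMILARITY,
    }
    for k, eff in enumerate(effects):
        if eff.name in names:
            codes[k] = names[eff.name]
        elif eff.name == "covariate_main":
            codes[k] = BEH_COVARIATE_MAIN
            vecs[k] = ctx.actor_value(eff.covariate, None, period)
        else:  # pragma: no cover
            raise ValueError(eff.name)
    return codes, vecs


@njit(cache=False, fastmath=False)
def _network_utilities(x, z, i, codes, betas, vecs, sim_mean, z_mean, u,
                       xr, rx, xc, cx, indeg):
    n = x.shape[0]
    need_xr = need_rx = need_xc = need_cx = need_indeg = False
    for k in range(codes.shape[0]):
        if betas[k] == 0.0:
            continue
        c = codes[k]
        if c == NET_TRANSITIVE_TRIPLETS:
            need_xr = True
            need_rx = True
        elif c == NET_THREE_CYCLES:
            need_xc = True
        elif c == NET_BETWEENNESS:
            need_cx = True
        elif c == NET_INDEGREE_POPULARITY or c == NET_OUT_IN_SQRT_ASSORTATIVITY:
            need_indeg = True

    outdeg_i = 0.0
    indeg_i = 0.0
    for j in range(n):
        outdeg_i += x[i, j]
        indeg_i += x[j, i]

    if need_xr or need_rx or need_xc or need_cx:
        for h in range(n):
            s_xr = 0.0
            s_rx = 0.0
            s_xc = 0.0
            s_cx = 0.0
            for j in range(n):
                if need_xr:
                    s_xr += x[h, j] * x[i, j]
                if need_rx:
                    s_rx += x[i, j] * x[j, h]
                if need_xc:
                    s_xc += x[h, j] * x[j, i]
                if need_cx:
                    s_cx += x[j, i] * x[j, h]
            xr[h] = s_xr
            rx[h] = s_rx
            xc[h] = s_xc
            cx[h] = s_cx
    if need_indeg:
        for h in range(n):
            s = 0.0
            for j in range(n):
                s += x[j, h]
            indeg[h] = s

    for h in range(n):
        u[h] = 0.0
    for k in range(codes.shape[0]):
        b = betas[k]
        if b == 0.0:
            continue
        c = codes[k]
        if c == NET_OUTDEGREE:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h])
        elif c == NET_RECIPROCITY:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * x[h, i]
        elif c == NET_TRANSITIVE_TRIPLETS:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * (xr[h] + rx[h])
        elif c == NET_THREE_CYCLES:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * xc[h]
        elif c == NET_BETWEENNESS:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * (indeg_i - x[h, i] - cx[h])
        elif c == NET_INDEGREE_POPULARITY:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * (indeg[h] - x[i, h] + 1.0)
        elif c == NET_OUT_IN_SQRT_ASSORTATIVITY:
            t = 0.0
            for j in range(n):
                t += x[i, j] * np.sqrt(indeg[j])
            base = np.sqrt(outdeg_i) * t
            for h in range(n):
                if x[i, h] == 0.0:
                    val = np.sqrt(outdeg_i + 1.0) * (t + np.sqrt(indeg[h] + 1.0))
                else:
                    if outdeg_i >= 1.0:
                        val = np.sqrt(outdeg_i - 1.0) * (t - np.sqrt(indeg[h]))
                    else:
                        val = 0.0
                u[h] += b * (val - base)
        elif c == NET_INDEGREE_ACTIVITY:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * indeg_i
        elif c == NET_INDEGREE_SQUARED_ACTIVITY:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * indeg_i * indeg_i
        elif c == NET_BEHAVIOR_SIMILARITY:
            for h in range(n):
                sim = 1.0 - abs(z[i] - z[h]) / 3.0
                u[h] += b * (1.0 - 2.0 * x[i, h]) * (sim - sim_mean)
        elif c == NET_SAME_COVARIATE:
            for h in range(n):
                same = 1.0 if vecs[k, h] == vecs[k, i] else 0.0
                u[h] += b * (1.0 - 2.0 * x[i, h]) * same
        elif c == NET_COVARIATE_ALTER:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * vecs[k, h]
        elif c == NET_COVARIATE_EGO:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * vecs[k, i]
        elif c == NET_BEHAVIOR_ALTER:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * (z[h] - z_mean)
        elif c == NET_BEHAVIOR_EGO:
            for h in range(n):
                u[h] += b * (1.0 - 2.0 * x[i, h]) * (z[i] - z_mean)
    u[i] = 0.0


@njit(cache=False, fastmath=False)
def _behavior_utilities(x, z, i, codes, betas, vecs, sim_mean, z_mean,
                        candidates, n_cand, u):
    n = x.shape[0]
    indeg_i = 0.0
    for j in range(n):
        indeg_i += x[j, i]
    for a in range(n_cand):
        u[a] = 0.0
    for k in range(codes.shape[0]):
        b = betas[k]
        if b == 0.0:
            continue
        c = codes[k]
        for a in range(n_cand):
            zc = candidates[a] - z_mean
            if c == BEH_LINEAR:
                u[a] += b * zc
            elif c == BEH_QUADRATIC:
                u[a] += b * zc * zc
            elif c == BEH_INDEGREE:
                u[a] += b * zc * indeg_i
            elif c == BEH_AVG_INCOMING_SIMILARITY:
                if indeg_i > 0.0:
                    s = 0.0
                    cnt = 0.0
                    for j in range(n):
                        if x[j, i] > 0.0:
                            s += (1.0 - abs(candidates[a] - z[j]) / 3.0) - sim_mean
                            cnt += 1.0
                    u[a] += b * s / cnt
            elif c == BEH_COVARIATE_MAIN:
                u[a] += b * zc * vecs[k, i]


@njit(cache=False, fastmath=False)
def _pick(u, n_opts, unit_draw):
    """Inverse-CDF draw on exp(u), mirroring the numpy _logit_choice."""
    m = u[0]
    for h in range(1, n_opts):
        if u[h] > m:
            m = u[h]
    total = 0.0
    for h in range(n_opts):
        total += np.exp(u[h] - m)
    target = unit_draw * total
    acc = 0.0
    for h in range(n_opts):
        acc += np.exp(u[h] - m)
        if acc > target:
            return h
    return n_opts - 1


@njit(cache=False, fastmath=False)
def run_block(
    x, z, clock,
    total_rate, p_net,
    net_codes, net_betas, net_vecs,
    beh_codes, beh_betas, beh_vecs,
    sim_mean, z_mean,
    waits, actors, procs, choices,
):
    """Consume one randomness block; returns (clock, done) and mutates x, z.

    ``done`` is True when the period clock passed 1 inside this block;
    False means the block was exhausted and the caller must refill.
    """
    n = x.shape[0]
    u = np.empty(n, dtype=np.float64)
    xr = np.empty(n, dtype=np.float64)
    rx = np.empty(n, dtype=np.float64)
    xc = np.empty(n, dtype=np.float64)
    cx = np.empty(n, dtype=np.float64)
    indeg = np.empty(n, dtype=np.float64)
    ub = np.empty(3, dtype=np.float64)
    cand = np.empty(3, dtype=np.float64)
    for idx in range(waits.shape[0]):
        clock += waits[idx]
        if clock > 1.0:
            return clock, True
        i = int(actors[idx])
        if procs[idx] < p_net:
            _network_utilities(x, z, i, net_codes, net_betas, net_vecs,
                               sim_mean, z_mean, u, xr, rx, xc, cx, indeg)
            h = _pick(u, n, choices[idx])
            if h != i:
                x[i, h] = 1.0 - x[i, h]
        else:
            zi = z[i]
            n_cand = 0
            for v in (zi - 1, zi, zi + 1):
                if 0 <= v <= 3:
                    cand[n_cand] = v
                    n_cand += 1
            _behavior_utilities(x, z, i, beh_codes, beh_betas, beh_vecs,
                                sim_mean, z_mean, cand, n_cand, ub)
            a = _pick(ub, n_cand, choices[idx])
            z[i] = int(cand[a])
    return clock, False
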