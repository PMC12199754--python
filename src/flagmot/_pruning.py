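"""Numba kernels for Felsenstein pruning on flattened trees.

Entry points:

* :func:`prune_kernel` — generic pass over precomputed per-edge transition
  matrices (plain likelihood API, small-tree oracles, ancestral passes);
* :func:`loglik_2state` — 2-state pass with closed-form edge kernels, the
  per-edge exponential ``exp(-(q01+q10) t_e)`` supplied precomputed;
* :func:`loglik_slots` — k-state pass over a *real* block-diagonal
  eigensystem Q = V B V⁻¹ (complex-conjugate eigenpairs become 2x2 rotation
  blocks), so each edge message is O(k²) real arithmetic without
  materializing P(t).

Partial likelihoods only shrink tip-to-root (transition rows sum to 1), so
rescaling is applied lazily when a node's maximum drops below 1e-140, with
the log scalers accumulated. Kernels return NaN for impossible data.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_RESCALE_FLOOR = 1e-140


@njit(cache=True)
def prune_kernel(order, parent, P, partials, root):
    """Postorder pass over precomputed edge matrices; returns the log scaler.

    ``partials`` is modified in place and must be seeded with tip indicators
    (ones for missing tips and internal nodes).
    """
    k = partials.shape[1]
    tmp = np.empty(k)
    log_scale = 0.0
    for ii in range(order.shape[0]):
        node = order[ii]
        m = 0.0
        for s in range(k):
            if partials[node, s] > m:
                m = partials[node, s]
        if m <= 0.0:
            return np.nan
        if m < _RESCALE_FLOOR:
            for s in range(k):
                partials[node, s] /= m
            log_scale += np.log(m)
        if node != root:
            par = parent[node]
            for s in range(k):
                acc = 0.0
                for s2 in range(k):
                    acc += P[node, s, s2] * partials[node, s2]
                tmp[s] = acc
            for s in range(k):
                partials[par, s] *= tmp[s]
    return log_scale


@njit(cache=True)
def loglik_2state(order, parent, e, base, partials, root, q01, q10):
    """2-state pruning with closed-form edge kernels; returns the log scaler.

    ``e[node]`` is exp(-(q01+q10)·t_node) for the edge above each node;
    ``base`` holds tip indicators; ``partials`` is a workspace overwritten on
    every call, with the (scaled) root partial left for the caller.
    """
    n = base.shape[0]
    for i in range(n):
        partials[i, 0] = base[i, 0]
        partials[i, 1] = base[i, 1]
    s = q01 + q10
    pi1 = q01 / s if s > 0.0 else 0.5
    pi0 = 1.0 - pi1
    log_scale = 0.0
    for ii in range(order.shape[0]):
        node = order[ii]
        p0 = partials[node, 0]
        p1 = partials[node, 1]
        m = p0 if p0 > p1 else p1
        if m <= 0.0:
            return np.nan
        if m < _RESCALE_FLOOR:
            p0 /= m
            p1 /= m
            partials[node, 0] = p0
            partials[node, 1] = p1
            log_scale += np.log(m)
        if node != root:
            par = parent[node]
            if s > 0.0:
                en = e[node]
                m0 = (pi0 + pi1 * en) * p0 + pi1 * (1.0 - en) * p1
                m1 = pi0 * (1.0 - en) * p0 + (pi1 + pi0 * en) * p1
            else:
                m0 = p0
                m1 = p1
            partials[par, 0] *= m0
            partials[par, 1] *= m1
    return log_scale


@njit(cache=True, fastmath=True)
def loglik_slots4(order, parent, base, partials, root, expcos, expsin,
                  pair_first, V, Vinv):
    """Unrolled 4-state version of :func:`loglik_slots` (the sampler hot path)."""
    n = base.shape[0]
    for i in range(n):
        partials[i, 0] = base[i, 0]
        partials[i, 1] = base[i, 1]
        partials[i, 2] = base[i, 2]
        partials[i, 3] = base[i, 3]
    log_scale = 0.0
    for ii in range(order.shape[0]):
        node = order[ii]
        p0 = partials[node, 0]
        p1 = partials[node, 1]
        p2 = partials[node, 2]
        p3 = partials[node, 3]
        m = p0
        if p1 > m:
            m = p1
        if p2 > m:
            m = p2
        if p3 > m:
            m = p3
        if m <= 0.0:
            return np.nan
        if m < _RESCALE_FLOOR:
            p0 /= m
            p1 /= m
            p2 /= m
            p3 /= m
            partials[node, 0] = p0
            partials[node, 1] = p1
            partials[node, 2] = p2
            partials[node, 3] = p3
            log_scale += np.log(m)
        if node != root:
            par = parent[node]
            y0 = Vinv[0, 0] * p0 + Vinv[0, 1] * p1 + Vinv[0, 2] * p2 + Vinv[0, 3] * p3
            y1 = Vinv[1, 0] * p0 + Vinv[1, 1] * p1 + Vinv[1, 2] * p2 + Vinv[1, 3] * p3
            y2 = Vinv[2, 0] * p0 + Vinv[2, 1] * p1 + Vinv[2, 2] * p2 + Vinv[2, 3] * p3
            y3 = Vinv[3, 0] * p0 + Vinv[3, 1] * p1 + Vinv[3, 2] * p2 + Vinv[3, 3] * p3
            if pair_first[0]:
                c = expcos[node, 0]
                sn = expsin[node, 0]
                z0 = c * y0 + sn * y1
                z1 = -sn * y0 + c * y1
            else:
                z0 = expcos[node, 0] * y0
                z1 = expcos[node, 1] * y1
            if pair_first[1]:
                c = expcos[node, 1]
                sn = expsin[node, 1]
                z1 = c * y1 + sn * y2
                z2 = -sn * y1 + c * y2
                z3 = expcos[node, 3] * y3
            elif pair_first[2]:
                c = expcos[node, 2]
                sn = expsin[node, 2]
                z2 = c * y2 + sn * y3
                z3 = -sn * y2 + c * y3
            else:
                z2 = expcos[node, 2] * y2
                z3 = expcos[node, 3] * y3
            m0 = V[0, 0] * z0 + V[0, 1] * z1 + V[0, 2] * z2 + V[0, 3] * z3
            m1 = V[1, 0] * z0 + V[1, 1] * z1 + V[1, 2] * z2 + V[1, 3] * z3
            m2 = V[2, 0] * z0 + V[2, 1] * z1 + V[2, 2] * z2 + V[2, 3] * z3
            m3 = V[3, 0] * z0 + V[3, 1] * z1 + V[3, 2] * z2 + V[3, 3] * z3
            if m0 < 0.0:
                m0 = 0.0
            if m1 < 0.0:
                m1 = 0.0
            if m2 < 0.0:
                m2 = 0.0
            if m3 < 0.0:
                m3 = 0.0
            partials[par, 0] *= m0
            partials[par, 1] *= m1
            partials[par, 2] *= m2
            partials[par, 3] *= m3
    return log_scale


@njit(cache=True)
def loglik_slots(order, parent, base, partials, root, expcos, expsin,
                 pair_first, V, Vinv):
    """k-state pruning in eigen-coordinates with real 2x2 rotation blocks.

    ``expcos``/``expsin`` hold, per node and eigen-slot, e^{a t}cos(b t) and
    e^{a t}sin(b t) (b = 0 for real eigenvalues, so expsin is zero there);
    ``pair_first[j]`` marks slot j as the first of a conjugate pair handled
    jointly with slot j+1. ``V``/``Vinv`` are the real modal matrices.
    """
    n, k = base.shape
    for i in range(n):
        for s in range(k):
            partials[i, s] = base[i, s]
    y = np.empty(k)
    z = np.empty(k)
    log_scale = 0.0
    for ii in range(order.shape[0]):
        node = order[ii]
        m = 0.0
        for s in range(k):
            if partials[node, s] > m:
                m = partials[node, s]
        if m <= 0.0:
            return np.nan
        if m < _RESCALE_FLOOR:
            for s in range(k):
                partials[node, s] /= m
            log_scale += np.log(m)
        if node != root:
            par = parent[node]
            for j in range(k):
                acc = 0.0
                for s2 in range(k):
                    acc += Vinv[j, s2] * partials[node, s2]
                y[j] = acc
            j = 0
            while j < k:
                if pair_first[j]:
                    c = expcos[node, j]
                    sn = expsin[node, j]
                    z[j] = c * y[j] + sn * y[j + 1]
                    z[j + 1] = -sn * y[j] + c * y[j + 1]
                    j += 2
                else:
                    z[j] = expcos[node, j] * y[j]
                    j += 1
            for s in range(k):
                acc = 0.0
                for j2 in range(k):
                    acc += V[s, j2] * z[j2]
                if acc < 0.0:
                    acc = 0.0
                partials[par, s] *= acc
    return log_scale
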