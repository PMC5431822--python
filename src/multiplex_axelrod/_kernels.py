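"""Numba kernels for the epoch loop and absorption scan.

The kernels share numba's per-thread global RNG; :func:`seed_rng` must be
called once before a run to make it reproducible.  All stochastic choices
(schedule permutation, neighbour, acceptance, feature, drift) draw from
that single stream in a fixed order.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def run_epochs(adj, indptr, indices, traits, q, layered, allow_noop, r, n_epochs):
    """Run ``n_epochs`` epochs in place; return the number of trait changes.

    One epoch visits every agent once in a fresh random order.  The focal
    agent ``i`` picks a uniform aggregate neighbour ``j``; with probability
    equal to the (layered or full-profile) cultural overlap, ``j`` copies
    one of ``i``'s traits.  In layered mode the copied feature is drawn
    among layers where the pair is linked (restricted to differing features
    unless ``allow_noop``); in classical mode among all differing features.
    After every focal-agent visit a drift event fires with probability
    ``r``: a uniform agent resets a uniform feature to a uniform trait.
    """
    F = adj.shape[0]
    N = traits.shape[0]
    feat_buf = np.empty(F, np.int64)
    changed = 0
    for _ in range(n_epochs):
        order = np.random.permutation(N)
        for t in range(N):
            i = order[t]
            deg = indptr[i + 1] - indptr[i]
            if deg > 0:
                j = indices[indptr[i] + np.random.randint(deg)]
                n_eq = 0
                n_cand = 0
                if layered:
                    for f in range(F):
                        if adj[f, i, j] == 1:
                            if traits[i, f] == traits[j, f]:
                                n_eq += 1
                                if allow_noop:
                                    feat_buf[n_cand] = f
                                    n_cand += 1
                            else:
                                feat_buf[n_cand] = f
                                n_cand += 1
                else:
                    for f in range(F):
                        if traits[i, f] == traits[j, f]:
                            n_eq += 1
                        else:
                            feat_buf[n_cand] = f
                            n_cand += 1
                if n_eq > 0 and n_cand > 0 and np.random.random() < n_eq / F:
                    f = feat_buf[np.random.randint(n_cand)]
                    if traits[j, f] != traits[i, f]:
                        traits[j, f] = traits[i, f]
                        changed += 1
            if r > 0.0 and np.random.random() < r:
                a = np.random.randint(N)
                f = np.random.randint(F)
                traits[a, f] = 1 + np.random.randint(q)
    return changed


@njit(cache=True)
def absorbed_scan(adj, indptr, indices, traits, layered):
    """True iff no aggregate-connected pair has an active bond.

    Layered: a bond is active when the pair agrees on some linked layer
    and disagrees on another (``0 < omega_ij < o_ij``).  Classical: active
    when the full profiles are neither equal nor fully different.
    """
    F = adj.shape[0]
    N = traits.shape[0]
    for i in range(N):
        for idx in range(indptr[i], indptr[i + 1]):
            j = indices[idx]
            if j <= i:
                continue
            n_eq = 0
            n_diff = 0
            if layered:
                for f in range(F):
                    if adj[f, i, j] == 1:
                        if traits[i, f] == traits[j, f]:
                            n_eq += 1
                        else:
                            n_diff += 1
            else:
                for f in range(F):
                    if traits[i, f] == traits[j, f]:
                        n_eq += 1
                    else:
                        n_diff += 1
            if n_eq > 0 and n_diff > 0:
                return False
    return True
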