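"""Synthetic multiplex ensembles with tunable structural overlap.

Two families are provided:

* *Rewired identical-ER multiplexes* — ``F`` copies of one Erdos-Renyi
  graph ``G(N, K)`` (structural overlap exactly 1), each edge then rewired
  independently with probability ``p``.  Larger ``p`` means lower overlap,
  from ``o = 1`` at ``p = 0`` down to ``o = 1/F`` at ``p = 1``; the
  closed-form (collisionless) prediction ``o(p, F)`` is in
  :func:`expected_overlap`.
* *Two-density multiplexes* — ``F_high`` identical dense layers plus
  ``F_low`` identical sparse layers whose edge set shares a fraction
  ``beta`` of its edges with the dense set.  ``beta`` interpolates linearly
  between minimal overlap (disjoint sets; the system decouples into two
  independent identical-layer blocks) and maximal overlap (sparse edges all
  contained in the dense set).

Because the analytic prediction neglects rewiring collisions, callers
should always report the overlap *measured* on the generated instance
(``net.structural_overlap()``), not the nominal ``p`` or ``beta``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .multiplex import MultiplexNetwork

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100_000


@dataclass
class OverlapPrediction:
    """Collisionless analytic prediction for a rewired identical-ER ensemble.

    ``o_pred`` is the predicted structural overlap; ``K_pred`` the predicted
    aggregate edge count (``None`` when the per-layer edge count is unknown).
    """

    o_pred: float
    K_pred: float | None = None


def _edge_count(N: int, k_mean: float) -> int:
    if not 0 < k_mean <= N - 1:
        raise ValueError(f"mean degree {k_mean} infeasible for N={N}")
    K = round(N * k_mean / 2)
    if K < 1:
        raise ValueError(f"mean degree {k_mean} gives an empty layer at N={N}")
    return K


def identical_er_multiplex(
    N: int,
    F: int,
    k_mean: float,
    seed: int | None = None,
    layer_names: list[str] | None = None,
) -> MultiplexNetwork:
    """``F`` copies of one ER graph ``G(N, K)`` with ``K = round(N k_mean / 2)``.

    The structural overlap of the result is exactly 1.
    """
    K = _edge_count(N, k_mean)
    g = nx.gnm_random_graph(N, K, seed=_int_seed(seed))
    edges = list(g.edges())
    return MultiplexNetwork(range(N), [edges] * F, layer_names)


def _int_seed(seed) -> int:
    """Collapse any seed spec into a 31-bit int for networkx."""
    return int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)


def rewire_layers(net: MultiplexNetwork, p: float, seed: int | None = None) -> MultiplexNetwork:
    """Independently rewire each edge of each layer with probability ``p``.

    A rewired edge is replaced by a uniformly random node pair not already
    linked on that layer (no self-loops, no duplicate edges), so each
    layer's edge count is conserved exactly.  The expected structural
    overlap of the result is approximately ``expected_overlap(p, F)``.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"rewiring probability must be in [0, 1], got {p}")
    first = net._layers[0]
    if any(layer != first for layer in net._layers[1:]):
        logger.warning("rewire_layers: input layers are not identical")
    N = net.N
    max_pairs = N * (N - 1) // 2
    rng = np.random.default_rng(seed)
    new_layers: list[list[tuple[int, int]]] = []
    for f in range(net.F):
        edges = sorted(net._layers[f])
        if p > 0 and len(edges) >= max_pairs:
            raise ValueError(f"layer {f} is complete; cannot rewire")
        current = set(edges)
        mask = rng.random(len(edges)) < p
        for edge, hit in zip(edges, mask):
            if not hit:
                continue
            current.remove(edge)
            for _ in range(_MAX_REDRAWS):
                u = int(rng.integers(N))
                v = int(rng.integers(N))
                if u == v:
                    continue
                pair = (u, v) if u < v else (v, u)
                if pair not in current:
                    current.add(pair)
                    break
            else:  # pragma: no cover - requires a pathologically dense layer
                raise RuntimeError(f"layer {f} too dense to rewire")
        new_layers.append([(net.nodes[a], net.nodes[b]) for a, b in sorted(current)])
    return MultiplexNetwork(net.nodes, new_layers, net.layer_names)


def expected_overlap(p: float, F: int, layer_edges: int | None = None) -> OverlapPrediction:
    """Closed-form structural overlap of a rewired identical-ER multiplex.

    Under independent per-edge rewiring and neglecting collisions (two
    edges rewired onto the same node pair), an original edge position
    survives with layer-multiplicity ``m ~ Binomial(F, 1-p)`` and each of
    the ``F - m`` rewired copies lands on a fresh position, giving the
    aggregate edge count

        ``K = K^[f] * sum_m C(F,m) (1-p)^m p^(F-m) (1 - delta_{0,m} + F - m)``

    and ``o = sum_f K^[f] / (F K) = 1 / (K / K^[f])``.  Exact at the
    endpoints: ``o(0) = 1`` and ``o(1) = 1/F``; in between the collision
    neglect biases the prediction low by ``O(1/N)``.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"rewiring probability must be in [0, 1], got {p}")
    if F < 1:
        raise ValueError("F must be >= 1")
    denom = 0.0
    for m in range(F + 1):
        weight = math.comb(F, m) * (1 - p) ** m * p ** (F - m)
        denom += weight * ((0 if m == 0 else 1) + (F - m))
    o_pred = 1.0 / denom
    K_pred = None if layer_edges is None else layer_edges * denom
    return OverlapPrediction(o_pred=o_pred, K_pred=K_pred)


def rewire_collision_bias_bound(p: float, F: int, layer_edges: int, N: int) -> float:
    """A-priori upper bound on the collision bias of :func:`expected_overlap`.

    The closed form assumes every rewired edge lands on a fresh node pair.
    In reality two edges can coincide, shrinking the aggregate and raising
    the measured overlap above the prediction.  The expected number of
    coincidence pairs involving at least one rewired edge is at most
    ``p (F K)^2 / P`` with ``P = N(N-1)/2`` candidate pairs, which
    propagates to an overlap excess of at most ``o_pred * p (F K)^2 / (P K_pred)``
    — an ``O(1/N)`` correction at fixed mean degree.
    """
    pred = expected_overlap(p, F, layer_edges=layer_edges)
    pairs = N * (N - 1) / 2
    deficit = p * (F * layer_edges) ** 2 / pairs
    return pred.o_pred * deficit / pred.K_pred


def rewiring_probability_for_overlap(o_target: float, F: int) -> float:
    """Invert :func:`expected_overlap`: the ``p`` whose predicted overlap is ``o_target``."""
    lo, hi = 1.0 / F, 1.0
    if not lo <= o_target <= hi:
        raise ValueError(f"target overlap {o_target} outside [{lo}, 1]")
    if o_target == 1.0:
        return 0.0
    if o_target == lo:
        return 1.0
    return float(brentq(lambda p: expected_overlap(p, F).o_pred - o_target, 0.0, 1.0, xtol=1e-12))


@dataclass
class TwoDensitySpec:
    """Two sets of identical layers with different densities.

    ``beta`` is the fraction of sparse-set edges drawn from the dense-set
    edge pool: ``beta = 0`` keeps the two edge sets disjoint (minimal
    overlap), ``beta = 1`` nests the sparse set inside the dense one
    (maximal overlap).
    """

    N: int
    F_low: int = 5
    F_high: int = 5
    k_low: float = 4.0
    k_high: float = 8.0
    beta: float = 0.0
    seed: int | None = None


def two_density_multiplex(spec: TwoDensitySpec) -> MultiplexNetwork:
    """Build the two-density multiplex described by ``spec``.

    With ``F_high`` dense layers of ``K_h`` edges and ``F_low`` sparse
    layers of ``K_l`` edges, the measured structural overlap runs from
    ``(F_h K_h + F_l K_l) / ((F_h + F_l)(K_h + K_l))`` at ``beta = 0`` up to
    ``(F_h K_h + F_l K_l) / ((F_h + F_l) K_h)`` at ``beta = 1``.
    """
    if not 0 <= spec.beta <= 1:
        raise ValueError(f"beta must be in [0, 1], got {spec.beta}")
    if spec.k_low > spec.k_high:
        raise ValueError("k_low must not exceed k_high (sparse set nests in dense set at beta=1)")
    N = spec.N
    K_h = _edge_count(N, spec.k_high)
    K_l = _edge_count(N, spec.k_low)
    max_pairs = N * (N - 1) // 2
    rng = np.random.default_rng(spec.seed)

    dense = nx.gnm_random_graph(N, K_h, seed=_int_seed(spec.seed))
    dense_edges = sorted(tuple(sorted(e)) for e in dense.edges())
    n_in = math.floor(spec.beta * K_l)
    n_out = K_l - n_in
    if K_h + n_out > max_pairs:
        raise ValueError("not enough node pairs outside the dense set")

    chosen = rng.choice(len(dense_edges), size=n_in, replace=False)
    sparse_edges = [dense_edges[i] for i in sorted(chosen)]
    dense_set = set(dense_edges)
    taken = set(sparse_edges)
    while n_out > 0:
        u = int(rng.integers(N))
        v = int(rng.integers(N))
        if u == v:
            continue
        pair = (u, v) if u < v else (v, u)
        if pair in dense_set or pair in taken:
            continue
        sparse_edges.append(pair)
        taken.add(pair)
        n_out -= 1

    names = [f"dense{i + 1}" for i in range(spec.F_high)] + [f"sparse{i + 1}" for i in range(spec.F_low)]
    layers = [dense_edges] * spec.F_high + [sorted(sparse_edges)] * spec.F_low
    return MultiplexNetwork(range(N), layers, names)
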