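"""Order parameters: global and topical cultural components, threshold location.

The global order parameter ``S`` is the size (normalised by ``N``) of the
largest *cultural component*: a maximal set of agents sharing all ``F``
traits and mutually reachable through aggregate edges whose endpoints also
share the full profile (the standard cultural-domain convention; a
permissive variant allowing paths through unlike agents is available via
``permissive=True``).  ``S ~ 1`` is globalisation, ``S ~ 1/N`` complete
fragmentation.

The *topical* component ``S^[f]`` applies the same construction to a
single layer and a single feature: agents connected on layer ``f`` through
same-trait-``f`` paths.  The spread of ``S^[f]`` across layers flags
feature-level consensus — its population standard deviation sits near 0 in
both the globalised and fragmented phases and near 0.5 in the mixed phase
where only part of the layers reach consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass
class ConsensusProfile:
    """Global ``S``, per-layer ``S_f`` and their mean / population sd."""

    S: float
    S_f: np.ndarray
    mean_Sf: float
    sd_Sf: float


@dataclass
class ThresholdEstimate:
    """Location of the first level-crossing of a response curve.

    ``x_c`` is ``None`` when the curve never crosses the level; ``bracket``
    holds the two curve points between which the crossing was interpolated.
    """

    x_c: float | None
    bracket: tuple[tuple[float, float], tuple[float, float]] | None
    level: float


def _largest_component_fraction(edges: np.ndarray, keep: np.ndarray, N: int) -> float:
    """Largest connected component of the subgraph of ``edges[keep]``, / N."""
    sub = edges[keep] if len(edges) else edges
    if len(sub) == 0:
        return 1.0 / N
    m = sp.coo_matrix(
        (np.ones(len(sub), dtype=np.int8), (sub[:, 0], sub[:, 1])), shape=(N, N)
    )
    _, labels = connected_components(m, directed=False)
    return int(np.bincount(labels).max()) / N


def largest_cultural_component(net, state, permissive: bool = False) -> float:
    """Normalised size ``S`` of the largest cultural component.

    ``permissive=True`` allows the connecting path to pass through agents
    with a different profile (component = most frequent profile within each
    aggregate connected component).
    """
    N = net.N
    edges = net.aggregate_edge_indices()
    t = state.traits
    if not permissive:
        keep = (
            np.all(t[edges[:, 0]] == t[edges[:, 1]], axis=1)
            if len(edges)
            else np.zeros(0, dtype=bool)
        )
        return _largest_component_fraction(edges, keep, N)
    if len(edges) == 0:
        return 1.0 / N
    m = sp.coo_matrix((np.ones(len(edges), dtype=np.int8), (edges[:, 0], edges[:, 1])), shape=(N, N))
    _, comp = connected_components(m, directed=False)
    _, pid = np.unique(t, axis=0, return_inverse=True)
    _, counts = np.unique(np.stack([comp, pid.ravel()], axis=1), axis=0, return_counts=True)
    return int(counts.max()) / N


def topical_component(net, state, layer: int) -> float:
    """Normalised largest topical component ``S^[f]`` of layer ``layer`` (0-based)."""
    if not 0 <= layer < net.F:
        raise ValueError(f"layer index {layer} out of range 0..{net.F - 1}")
    edges = net.layer_edge_indices(layer)
    t = state.traits[:, layer]
    keep = t[edges[:, 0]] == t[edges[:, 1]] if len(edges) else np.zeros(0, dtype=bool)
    return _largest_component_fraction(edges, keep, net.N)


def consensus_profile(net, state, permissive: bool = False) -> ConsensusProfile:
    """Assemble ``S``, all ``S^[f]``, their mean and population standard deviation."""
    S_f = np.array([topical_component(net, state, f) for f in range(net.F)])
    return ConsensusProfile(
        S=largest_cultural_component(net, state, permissive=permissive),
        S_f=S_f,
        mean_Sf=float(S_f.mean()),
        sd_Sf=float(S_f.std()),  # population sd: layers are the whole population
    )


def estimate_threshold(curve, level: float = 0.5) -> ThresholdEstimate:
    """Linearly interpolate the first crossing of ``mean_S`` through ``level``.

    ``curve`` is a sequence of ``(x, mean_S)`` pairs; it is sorted by ``x``
    before scanning.  Returns a no-threshold result (``x_c=None``) when the
    curve never reaches the level.
    """
    pts = sorted((float(x), float(y)) for x, y in curve)
    if len(pts) < 2:
        raise ValueError("need at least 2 curve points")
    for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
        if y1 == level:
            return ThresholdEstimate(x_c=x1, bracket=((x1, y1), (x2, y2)), level=level)
        if (y1 - level) * (y2 - level) < 0:
            x_c = x1 + (level - y1) * (x2 - x1) / (y2 - y1)
            return ThresholdEstimate(x_c=x_c, bracket=((x1, y1), (x2, y2)), level=level)
    if pts[-1][1] == level:
        x1, y1 = pts[-2]
        return ThresholdEstimate(x_c=pts[-1][0], bracket=((x1, y1), pts[-1]), level=level)
    return ThresholdEstimate(x_c=None, bracket=None, level=level)
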