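"""Multiplex network container, overlap algebra, aggregation and plain-text I/O.

A multiplex social network is a set of ``F`` unweighted, undirected simple
graphs (*layers*) sharing one node set of ``N`` agents.  Layer ``f`` carries
the interactions relevant to cultural feature ``f`` (e.g. sport, religion,
politics).  Two structural quantities drive everything downstream:

* the *edge overlap* of a pair ``(i, j)`` — the fraction of layers on which
  the pair is linked, ``o_ij = (1/F) sum_f a_ij^[f]``;
* the *structural overlap* ``o`` of the whole multiplex — the average edge
  overlap over connected pairs, which lives in ``[1/F, 1]`` and acts as the
  control parameter of the globalisation/multiculturality transition.

Node labels are arbitrary hashable values (opaque IDs in empirical edge
lists); internally they are mapped to dense indices ``0..N-1`` and all
public outputs report the original labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Supported multiplex edge-list column orders.
DIALECTS = ("layer-u-v", "u-v-layer")


@dataclass
class ActivityTable:
    """Per-node, per-layer degree and activity flags.

    ``b.loc[i, f]`` is True iff node ``i`` has at least one link on layer
    ``f`` (``k.loc[i, f] > 0``); inactive agents cannot be reached through
    that layer and never update the corresponding feature via it.
    """

    b: pd.DataFrame
    k: pd.DataFrame


class MultiplexNetwork:
    """``F`` simple graphs over a shared node set.

    Parameters
    ----------
    nodes
        Distinct node labels; their order is preserved and defines the
        internal index ``0..N-1``.
    layer_edges
        One iterable of ``(u, v)`` label pairs per layer.  Duplicate edges
        collapse; self-loops are rejected.
    layer_names
        Optional distinct layer labels (default ``"layer0"..``).
    """

    def __init__(
        self,
        nodes: Sequence[Hashable],
        layer_edges: Sequence[Iterable[tuple[Hashable, Hashable]]],
        layer_names: Sequence[str] | None = None,
    ) -> None:
        self.nodes: list[Hashable] = list(nodes)
        if len(self.nodes) < 2:
            raise ValueError("a multiplex needs at least 2 nodes")
        self._index: dict[Hashable, int] = {u: i for i, u in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("node labels must be distinct")

        if len(layer_edges) < 1:
            raise ValueError("a multiplex needs at least 1 layer")
        if layer_names is None:
            layer_names = [f"layer{f}" for f in range(len(layer_edges))]
        self.layer_names: list[str] = [str(n) for n in layer_names]
        if len(self.layer_names) != len(layer_edges):
            raise ValueError("layer_names must match the number of layers")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be distinct")

        self._layers: list[set[tuple[int, int]]] = []
        for edges in layer_edges:
            layer: set[tuple[int, int]] = set()
            for u, v in edges:
                try:
                    a, b = self._index[u], self._index[v]
                except KeyError as exc:
                    raise ValueError(f"edge references unknown node {exc.args[0]!r}") from None
                if a == b:
                    raise ValueError(f"self-loop on node {u!r} is not allowed")
                layer.add((a, b) if a < b else (b, a))
            self._layers.append(layer)

        self._arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # ------------------------------------------------------------------ basics

    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def F(self) -> int:
        return len(self._layers)

    def layer_edge_counts(self) -> np.ndarray:
        """Number of edges ``K^[f]`` on each layer."""
        return np.array([len(layer) for layer in self._layers])

    def layer_edges(self, f: int) -> list[tuple[Hashable, Hashable]]:
        """Edges of layer ``f`` as original-label pairs (deterministic order)."""
        return [(self.nodes[a], self.nodes[b]) for a, b in sorted(self._layers[f])]

    def layer_edge_indices(self, f: int) -> np.ndarray:
        """Edges of layer ``f`` as an ``(K, 2)`` array of internal indices."""
        if not 0 <= f < self.F:
            raise ValueError(f"layer index {f} out of range 0..{self.F - 1}")
        if not self._layers[f]:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self._layers[f]), dtype=np.int64)

    def layer_graph(self, f: int) -> nx.Graph:
        """Layer ``f`` as a networkx graph over the full node set."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.layer_edges(f))
        return g

    def index_of(self, u: Hashable) -> int:
        try:
            return self._index[u]
        except KeyError:
            raise ValueError(f"unknown node label {u!r}") from None

    # ----------------------------------------------------------------- overlap

    def edge_overlap(self, u: Hashable, v: Hashable) -> float:
        """Fraction of layers on which ``u`` and ``v`` are linked (``o_ij``)."""
        a, b = self.index_of(u), self.index_of(v)
        if a == b:
            raise ValueError("edge overlap is undefined for a node with itself")
        pair = (a, b) if a < b else (b, a)
        return sum(pair in layer for layer in self._layers) / self.F

    def structural_overlap(self) -> float:
        """Average edge overlap over connected pairs (``1/F <= o <= 1``).

        Since every connected pair contributes ``multiplicity / F`` to the
        numerator and 1 to the denominator, the average reduces to
        ``sum_f K^[f] / (F * K_aggregate)``.
        """
        total = int(self.layer_edge_counts().sum())
        if total == 0:
            raise ValueError("structural overlap is undefined for an edgeless multiplex")
        k_agg = len(set().union(*self._layers))
        return total / (self.F * k_agg)

    # --------------------------------------------------------------- aggregate

    def aggregate(self) -> nx.Graph:
        """Single-layer union of all layers (``a_ij = 1`` iff linked somewhere)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for f in range(self.F):
            g.add_edges_from(self.layer_edges(f))
        return g

    def aggregate_edge_indices(self) -> np.ndarray:
        """Aggregate edges as an ``(E, 2)`` array of internal indices."""
        union = set().union(*self._layers)
        if not union:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(union), dtype=np.int64)

    def node_activity(self) -> ActivityTable:
        """Per-node, per-layer degrees ``k_i^[f]`` and activity flags ``b_i^[f]``."""
        k = np.zeros((self.N, self.F), dtype=np.int64)
        for f, layer in enumerate(self._layers):
            for a, b in layer:
                k[a, f] += 1
                k[b, f] += 1
        kdf = pd.DataFrame(k, index=self.nodes, columns=self.layer_names)
        return ActivityTable(b=kdf > 0, k=kdf)

    def restrict_to_giant_component(self) -> "MultiplexNetwork":
        """Induced sub-multiplex on the largest aggregate connected component.

        Ties between equal-size components are broken by the component
        containing the lexicographically smallest label (via ``str``).
        """
        comps = list(nx.connected_components(self.aggregate()))
        best = max(comps, key=lambda c: (len(c), ))
        tied = [c for c in comps if len(c) == len(best)]
        if len(tied) > 1:
            best = min(tied, key=lambda c: min(str(u) for u in c))
        keep = [u for u in self.nodes if u in best]
        keep_idx = {self._index[u] for u in keep}
        layer_edges = [
            [(self.nodes[a], self.nodes[b]) for a, b in layer if a in keep_idx and b in keep_idx]
            for layer in self._layers
        ]
        logger.info("giant component: retained %d of %d nodes", len(keep), self.N)
        return MultiplexNetwork(keep, layer_edges, self.layer_names)

    # ----------------------------------------------------------------- kernels

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense per-layer adjacency + aggregate CSR, cached for the dynamics.

        Returns ``(adj, indptr, indices)`` where ``adj`` is a
        ``(F, N, N)`` uint8 tensor and ``indptr``/``indices`` encode the
        aggregate neighbour lists in CSR form.  The network must not be
        mutated after the first call (instances are treated as immutable).
        """
        if self._arrays is None:
            adj = np.zeros((self.F, self.N, self.N), dtype=np.uint8)
            for f, layer in enumerate(self._layers):
                for a, b in layer:
                    adj[f, a, b] = 1
                    adj[f, b, a] = 1
            agg = sp.csr_matrix(adj.max(axis=0))
            self._arrays = (
                adj,
                agg.indptr.astype(np.int64),
                agg.indices.astype(np.int64),
            )
        return self._arrays

    # -------------------------------------------------------------------- misc

    def __repr__(self) -> str:  # pragma: no cover
        return f"MultiplexNetwork(N={self.N}, F={self.F}, K={self.layer_edge_counts().tolist()})"


# ---------------------------------------------------------------------- I/O


def read_multiplex_edgelist(path, dialect: str = "layer-u-v") -> MultiplexNetwork:
    """Read a plain-text multiplex edge list.

    Rows are whitespace- or comma-separated with three columns in the order
    given by ``dialect`` (``"layer-u-v"`` or ``"u-v-layer"``); an optional
    fourth weight column is binarised (positive weight -> edge) with a logged
    warning.  Lines starting with ``#`` are skipped.  Duplicate rows collapse
    to one edge; self-loop rows raise.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    layers: dict[str, list[tuple[str, str]]] = {}
    nodes: dict[str, None] = {}
    warned_weights = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: malformed row {line!r} (expected 3 or 4 columns)")
            if len(parts) == 4:
                if not warned_weights:
                    logger.warning("%s: weight column present; binarising (weight > 0 -> edge)", path)
                    warned_weights = True
                try:
                    weight = float(parts[3])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric weight {parts[3]!r}") from None
                if weight <= 0:
                    continue
            if dialect == "layer-u-v":
                layer, u, v = parts[:3]
            else:
                u, v, layer = parts[:3]
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on node {u!r}")
            layers.setdefault(layer, []).append((u, v))
            nodes.setdefault(u)
            nodes.setdefault(v)
    if not layers:
        raise ValueError(f"{path}: no edges found")
    names = sorted(layers)
    return MultiplexNetwork(list(nodes), [layers[n] for n in names], names)


def write_multiplex_edgelist(net: MultiplexNetwork, path, dialect: str = "layer-u-v") -> None:
    """Write ``net`` as a plain-text edge list readable by :func:`read_multiplex_edgelist`."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w") as fh:
        fh.write("# multiplex edge list, columns: " + dialect.replace("-", " ") + "\n")
        for f, name in enumerate(net.layer_names):
            for u, v in net.layer_edges(f):
                if dialect == "layer-u-v":
                    fh.write(f"{name} {u} {v}\n")
                else:
                    fh.write(f"{u} {v} {name}\n")
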