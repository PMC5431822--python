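"""Independent brute-force reference implementations for property checks.

These deliberately avoid the package's vectorised/kernel code paths:
overlaps are per-pair python loops, components are hand-rolled BFS.
"""

from collections import deque

import numpy as np


def structural_overlap_brute(net) -> float:
    num = den = 0.0
    for a in range(net.N):
        for b in range(a + 1, net.N):
            u, v = net.nodes[a], net.nodes[b]
            o_ij = net.edge_overlap(u, v)
            if o_ij > 0:
                num += o_ij
                den += 1
    if den == 0:
        raise ValueError("no connected pairs")
    return num / den


def cultural_overlap_brute(net, state, u, v) -> float:
    a, b = net.index_of(u), net.index_of(v)
    total = 0
    for f in range(net.F):
        pair = (min(a, b), max(a, b))
        linked = pair in net._layers[f]
        if linked and state.traits[a, f] == state.traits[b, f]:
            total += 1
    return total / net.F


def is_absorbed_brute(net, state, mode) -> bool:
    t = state.traits
    for a, b in sorted(set().union(*net._layers)):
        if mode == "layered":
            eq = diff = 0
            for f in range(net.F):
                if (a, b) in net._layers[f]:
                    if t[a, f] == t[b, f]:
                        eq += 1
                    else:
                        diff += 1
            if eq > 0 and diff > 0:
                return False
        else:
            n_eq = int(np.sum(t[a] == t[b]))
            if 0 < n_eq < net.F:
                return False
    return True


def _bfs_largest(N, neighbours) -> int:
    seen = [False] * N
    best = 0
    for start in range(N):
        if seen[start]:
            continue
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            u = queue.popleft()
            size += 1
            for v in neighbours[u]:
                if not seen[v]:
                    seen[v] = True
                    queue.append(v)
        best = max(best, size)
    return best


def largest_cultural_component_brute(net, state) -> float:
    t = state.traits
    neighbours = [[] for _ in range(net.N)]
    for a, b in set().union(*net._layers):
        if np.array_equal(t[a], t[b]):
            neighbours[a].append(b)
            neighbours[b].append(a)
    return _bfs_largest(net.N, neighbours) / net.N


def topical_component_brute(net, state, f) -> float:
    t = state.traits[:, f]
    neighbours = [[] for _ in range(net.N)]
    for a, b in net._layers[f]:
        if t[a] == t[b]:
            neighbours[a].append(b)
            neighbours[b].append(a)
    return _bfs_largest(net.N, neighbours) / net.N
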