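"""Independent brute-force oracles and random-instance generators.

These deliberately avoid the package's own algorithms: minima are computed
by exhaustive enumeration so the fast implementations can be checked
against ground truth on small instances.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from cnsteiner.core import PatternSet, l1_distance
from cnsteiner.parsimony import Topology


def random_patterns(rng: np.random.Generator, n: int, d: int, max_count: int):
    """n distinct random patterns with entries in [0, max_count]."""
    if n > (max_count + 1) ** d:
        raise ValueError(f"cannot draw {n} distinct patterns with d={d}")
    pats = set()
    while len(pats) < n:
        pats.add(tuple(int(x) for x in rng.integers(0, max_count + 1, d)))
    return sorted(pats)


def random_pattern_set(rng, n, d, max_count) -> PatternSet:
    return PatternSet.from_patterns(random_patterns(rng, n, d, max_count))


def random_topology(rng: np.random.Generator, labels) -> Topology:
    """Uniform-ish random unrooted binary topology by random edge attachment."""
    top = Topology([tuple(p) for p in labels])
    n = top.n_leaves
    if n == 1:
        return top
    if n == 2:
        top.connect(0, 1)
        return top
    hub = top.new_internal()
    for leaf in range(3):
        top.connect(leaf, hub)
    for leaf in range(3, n):
        edges = top.edges()
        u, v = edges[rng.integers(len(edges))]
        w = top.new_internal()
        top.disconnect(u, v)
        top.connect(u, w)
        top.connect(v, w)
        top.connect(leaf, w)
    return top


def brute_force_wagner(top: Topology) -> int:
    """Minimum tree weight over all integer labelings of internal nodes.

    Per probe independently (the metric separates): enumerate every value
    assignment of the internal nodes within the leaf value range.
    """
    n = top.n_leaves
    if n <= 2:
        return 0 if n < 2 else l1_distance(top.leaf_labels[0], top.leaf_labels[1])
    internals = sorted(top.internal_nodes())
    edges = top.edges()
    d = len(top.leaf_labels[0])
    total = 0
    for j in range(d):
        leaf_vals = [p[j] for p in top.leaf_labels]
        lo, hi = min(leaf_vals), max(leaf_vals)
        best = None
        for assign in itertools.product(range(lo, hi + 1), repeat=len(internals)):
            val = dict(zip(internals, assign))
            for i, p in enumerate(top.leaf_labels):
                val[i] = p[j]
            cost = sum(abs(val[u] - val[v]) for u, v in edges)
            if best is None or cost < best:
                best = cost
        total += best
    return total


def brute_force_rsmt(patterns) -> int:
    """Exact RSMT weight by enumerating Steiner point subsets of the
    integer bounding box (at most n - 2 Steiner points are ever needed)
    and taking the MST of terminals plus the subset.  Tiny instances only."""
    patterns = [tuple(p) for p in patterns]
    n = len(patterns)
    if n == 1:
        return 0
    d = len(patterns[0])
    box = [
        range(min(p[j] for p in patterns), max(p[j] for p in patterns) + 1)
        for j in range(d)
    ]
    candidates = [p for p in itertools.product(*box) if p not in set(patterns)]

    def mst_weight(points):
        g = nx.Graph()
        pts = list(dict.fromkeys(points))
        for i in range(len(pts)):
            for k in range(i + 1, len(pts)):
                g.add_edge(i, k, weight=l1_distance(pts[i], pts[k]))
        if len(pts) == 1:
            return 0
        return sum(
            d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)
        )

    best = mst_weight(patterns)
    for r in range(1, n - 1):
        for extra in itertools.combinations(candidates, r):
            w = mst_weight(patterns + list(extra))
            if w < best:
                best = w
    return best
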