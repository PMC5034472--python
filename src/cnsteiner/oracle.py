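"""Exact rectilinear Steiner minimum trees on small instances.

Ground truth for testing the heuristics.  Steiner points may be restricted
to the Hanan grid (the Cartesian product of the terminals' per-probe
coordinate values) without loss of optimality; on that grid the classic
Dreyfus-Wagner dynamic program over terminal subsets finds the optimum.
Intended for a handful of terminals only — the limits abort rather than
silently approximate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    OBSERVED,
    STEINER,
    CountPattern,
    PatternSet,
    PhyloTree,
    l1_distance,
    tree_weight,
)


class OracleLimitError(ValueError):
    """Instance too large for the exact solver."""


@dataclass(frozen=True)
class OracleLimits:
    max_terminals: int = 8
    max_vertices: int = 5000


@dataclass(frozen=True)
class HananGrid:
    """Per-probe sorted coordinate values; vertices are their product."""

    coords: tuple[tuple[int, ...], ...]

    @classmethod
    def of(cls, terminals: tuple[CountPattern, ...]) -> "HananGrid":
        d = len(terminals[0])
        return cls(tuple(tuple(sorted({t[j] for t in terminals})) for j in range(d)))

    @property
    def n_vertices(self) -> int:
        out = 1
        for c in self.coords:
            out *= len(c)
        return out

    def vertices(self) -> list[CountPattern]:
        return [tuple(v) for v in itertools.product(*self.coords)]


def exact_rsmt(
    inputs: PatternSet, limits: OracleLimits = OracleLimits()
) -> tuple[int, PhyloTree]:
    """Optimal Steiner tree weight (and one optimal tree) on the Hanan grid.

    Dreyfus-Wagner subset DP: ``dp[S][v]`` is the optimal weight of a tree
    spanning terminal subset S plus grid vertex v.  Shortest grid paths
    under L1 are the L1 distances themselves, so the "walk" relaxation is a
    single min-plus product with the distance matrix.
    """
    terminals = inputs.patterns
    t = len(terminals)
    if t > limits.max_terminals:
        raise OracleLimitError(
            f"{t} terminals exceed the exact-solver limit of "
            f"{limits.max_terminals}; use a heuristic instead"
        )
    grid = HananGrid.of(terminals)
    if grid.n_vertices > limits.max_vertices:
        raise OracleLimitError(
            f"Hanan grid has {grid.n_vertices} vertices, limit is "
            f"{limits.max_vertices}"
        )
    if t == 1:
        tree = PhyloTree()
        tree.add_node(terminals[0], kind=OBSERVED)
        return 0, tree

    verts = grid.vertices()
    V = len(verts)
    coords = np.asarray(verts, dtype=np.int64)
    D = np.abs(coords[:, None, :] - coords[None, :, :]).sum(axis=2)
    tidx = [verts.index(p) for p in terminals]

    INF = np.int64(1 << 40)
    full = (1 << t) - 1
    dp = np.full((full + 1, V), INF, dtype=np.int64)
    pred = np.zeros((full + 1, V), dtype=np.int64)  # walk predecessor
    split = np.zeros((full + 1, V), dtype=np.int64)  # merge split choice
    for k in range(t):
        dp[1 << k] = D[tidx[k]]
        pred[1 << k] = tidx[k]

    subsets = sorted(range(1, full + 1), key=lambda s: (bin(s).count("1"), s))
    for S in subsets:
        if bin(S).count("1") < 2:
            continue
        low = S & (-S)
        merge = np.full(V, INF, dtype=np.int64)
        msplit = np.zeros(V, dtype=np.int64)
        sub = (S - 1) & S
        while sub:
            if sub & low:  # enumerate each split once
                cand = dp[sub] + dp[S ^ sub]
                better = cand < merge
                merge[better] = cand[better]
                msplit[better] = sub
            sub = (sub - 1) & S
        total = merge[:, None] + D
        u = np.argmin(total, axis=0)
        dp[S] = total[u, np.arange(V)]
        pred[S] = u
        split[S] = msplit[u]

    root = tidx[0]
    weight = int(dp[full][root])

    g = nx.Graph()
    for p in terminals:
        g.add_node(p)

    def build(S: int, v: int) -> None:
        if bin(S).count("1") == 1:
            k = S.bit_length() - 1
            if tidx[k] != v:
                g.add_edge(terminals[k], verts[v])
            return
        u = int(pred[S][v])
        if u != v:
            g.add_edge(verts[u], verts[v])
        S1 = int(split[S][u])
        build(S1, u)
        build(S ^ S1, u)

    build(full, root)

    # The reconstruction graph spans all terminals at total weight equal to
    # the optimum; reduce to a tree and splice redundant Steiner vertices.
    for a, b in g.edges:
        g.edges[a, b]["weight"] = l1_distance(a, b)
    mst = nx.minimum_spanning_tree(g)
    tree = _to_phylotree(mst, set(terminals))
    _prune_steiner(tree)
    w = tree_weight(tree)
    assert w == weight, f"reconstructed weight {w} != DP optimum {weight}"
    return weight, tree


def _to_phylotree(g: nx.Graph, observed: set[CountPattern]) -> PhyloTree:
    tree = PhyloTree()
    ids = {}
    for p in sorted(g.nodes):
        ids[p] = tree.add_node(p, kind=OBSERVED if p in observed else STEINER)
    for a, b in g.edges:
        tree.add_edge(ids[a], ids[b])
    return tree


def _prune_steiner(tree: PhyloTree) -> None:
    """Remove Steiner leaves and splice degree-2 Steiner vertices (on the
    grid every such vertex lies on a shortest path between its neighbors)."""
    g = tree.graph
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if tree.kind(v) != STEINER:
                continue
            deg = g.degree[v]
            if deg <= 1:
                g.remove_node(v)
                changed = True
            elif deg == 2:
                p, q = g.neighbors(v)
                if l1_distance(tree.label(p), tree.label(q)) == tree.edge_length(
                    p, v
                ) + tree.edge_length(v, q):
                    g.remove_node(v)
                    g.add_edge(p, q)
                    changed = True


def exhaustive_median(
    a: CountPattern, b: CountPattern, c: CountPattern
) -> CountPattern:
    """Brute-force three-pattern median over the integer bounding box.

    Independent validation target for the O(d) coordinatewise median; ties
    broken lexicographically.
    """
    ranges = [range(min(t), max(t) + 1) for t in zip(a, b, c)]
    best = None
    for m in itertools.product(*ranges):
        cost = l1_distance(m, a) + l1_distance(m, b) + l1_distance(m, c)
        if best is None or (cost, m) < best:
            best = (cost, m)
    return best[1]
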