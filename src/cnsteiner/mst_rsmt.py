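"""MST-based RSMT heuristic: iterative median Steiner-node insertion.

Starting from the L1 minimum spanning tree of the observed patterns, the
heuristic repeatedly solves three-pattern median instances — one per
(center, neighbor-pair) triplet of the current tree — and inserts the
median that (a) strictly lowers the tree weight and (b) has the smallest
*inference score*.  The inference score of a candidate is the sum of the
*Steiner counts* of its three nodes, where the Steiner count of a node is
the number of scored triplets containing it whose median differs from all
three members.  Inserting low-score medians first matters because the
insertion order affects the final local optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import (
    STEINER,
    OBSERVED,
    CountPattern,
    PatternSet,
    PhyloTree,
    is_steiner_required,
    l1_distance,
    median3,
)


@dataclass(frozen=True)
class MedianInstance:
    """One candidate median insertion: a center node and two of its neighbors."""

    center: int
    left: int
    right: int
    median: CountPattern
    gain: int  # weight of the two center-incident edges minus the 3-star weight

    @property
    def nodes(self) -> tuple[int, int, int]:
        return (self.center, self.left, self.right)


def build_mst(inputs: PatternSet) -> PhyloTree:
    """L1 minimum spanning tree over the distinct observed patterns.

    Kruskal on the complete graph with edges sorted by
    (length, lexicographic endpoint patterns) so ties resolve
    deterministically.
    """
    if inputs.n == 0:
        raise ValueError("empty input")
    pats = inputs.patterns
    t = PhyloTree()
    ids = {}
    for p in pats:
        ids[p] = t.add_node(p, kind=OBSERVED, multiplicity=inputs.multiplicity.get(p, 1))
    edges = []
    for i in range(len(pats)):
        for j in range(i + 1, len(pats)):
            a, b = sorted((pats[i], pats[j]))
            edges.append((l1_distance(a, b), a, b))
    edges.sort()
    parent = {p: p for p in pats}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            t.add_edge(ids[a], ids[b])
    return t


def enumerate_triples(t: PhyloTree) -> list[MedianInstance]:
    """All (center, unordered neighbor pair) median instances of the tree."""
    t.require_labeled()
    out = []
    for v in sorted(t.nodes()):
        nbrs = sorted(t.neighbors(v))
        lv = t.label(v)
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                u, w = nbrs[i], nbrs[j]
                lu, lw = t.label(u), t.label(w)
                m = median3(lu, lv, lw)
                current = l1_distance(lu, lv) + l1_distance(lv, lw)
                star = (
                    l1_distance(m, lu) + l1_distance(m, lv) + l1_distance(m, lw)
                )
                out.append(MedianInstance(v, u, w, m, current - star))
    return out


def steiner_counts(t: PhyloTree, triples: Optional[list[MedianInstance]] = None) -> dict[int, int]:
    """Per node: number of triplets containing it that require a Steiner node."""
    if triples is None:
        triples = enumerate_triples(t)
    counts = {v: 0 for v in t.nodes()}
    for inst in triples:
        labels = [t.label(x) for x in inst.nodes]
        if is_steiner_required(*labels):
            for x in inst.nodes:
                counts[x] += 1
    return counts


def inference_score(inst: MedianInstance, counts: dict[int, int]) -> int:
    return sum(counts[x] for x in inst.nodes)


def iterate_insert(t: PhyloTree, history: Optional[list[int]] = None) -> PhyloTree:
    """Median-insertion local search (the MSTtree inner loop).

    Each round inserts, among candidates with positive local gain, the
    median with minimum inference score (ties: larger gain, then
    lexicographically smallest median pattern).  The two center-incident
    edges are replaced by the 3-star at the median; afterwards Steiner
    nodes of degree <= 2 that lie on a shortest path between their
    neighbors are spliced out.  Stops at a local optimum.  The tree weight
    strictly decreases with every insertion, so the loop terminates.
    """
    t.require_labeled()
    t = t.copy()
    from .core import tree_weight

    if history is not None:
        history.append(tree_weight(t))
    while True:
        triples = enumerate_triples(t)
        counts = steiner_counts(t, triples)
        candidates = [inst for inst in triples if inst.gain > 0]
        if not candidates:
            break
        best = min(
            candidates,
            key=lambda c: (
                inference_score(c, counts),
                -c.gain,
                c.median,
                t.label(c.center),
                tuple(sorted((t.label(c.left), t.label(c.right)))),
            ),
        )
        _insert_median(t, best)
        _cleanup_steiner(t)
        if history is not None:
            history.append(tree_weight(t))
    return t


def _insert_median(t: PhyloTree, inst: MedianInstance) -> None:
    v, u, w = inst.center, inst.left, inst.right
    g = t.graph
    g.remove_edge(u, v)
    g.remove_edge(v, w)
    # If the median coincides with one of the triplet's own labels the new
    # node would sit at zero distance from it; merge instead of inserting.
    for x in (u, v, w):
        if t.label(x) == inst.median:
            for y in (u, v, w):
                if y != x and not g.has_edge(x, y):
                    t.add_edge(x, y)
            return
    m = t.add_node(inst.median, kind=STEINER)
    for x in (u, v, w):
        t.add_edge(m, x)


def _cleanup_steiner(t: PhyloTree) -> None:
    """Splice out redundant low-degree Steiner nodes (weight-neutral)."""
    g = t.graph
    changed = True
    while changed:
        changed = False
        for s in sorted(t.nodes()):
            if t.kind(s) != STEINER:
                continue
            deg = t.degree(s)
            if deg == 0:
                g.remove_node(s)
                changed = True
            elif deg == 1:
                g.remove_node(s)
                changed = True
            elif deg == 2:
                p, q = t.neighbors(s)
                if l1_distance(t.label(p), t.label(q)) == t.edge_length(
                    p, s
                ) + t.edge_length(s, q):
                    g.remove_node(s)
                    if not g.has_edge(p, q):
                        g.add_edge(p, q)
                    changed = True


def msttree(inputs: PatternSet, history: Optional[list[int]] = None) -> PhyloTree:
    """The full MST-based RSMT heuristic: MST, then iterative insertion."""
    return iterate_insert(build_mst(inputs), history=history)
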