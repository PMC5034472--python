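"""Deriving an RSMT from a maximum-parsimony topology.

A scored MPT fixes only the leaf labels; any weight-optimal assignment of
internal labels followed by contraction of trivial (zero-length) edges
yields a rectilinear Steiner tree of the same weight.  Among those, we want
few Steiner nodes.  The procedure: test every leaf for *lifting* (can its
pattern label its parent at no weight cost?); each liftable leaf roots a
candidate — bottom-up Farris ranges over the remaining tree, the leaf's
pattern forced onto the root, top-down assignment by clamping, trivial-edge
contraction — plus one unrooted fallback candidate.  The candidate with the
fewest Steiner nodes (weight is identical by construction) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import (
    OBSERVED,
    STEINER,
    CountPattern,
    PatternSet,
    PhyloTree,
    contract_trivial_edges,
    count_steiner_nodes,
    l1_distance,
    tree_weight,
)
from .parsimony import (
    Message,
    SearchConfig,
    Topology,
    combine_many,
    leaf_message,
    mpt_search,
    point_value,
    wagner_score,
)

Interval = tuple[tuple[int, ...], tuple[int, ...]]  # per-probe (lo, hi)


@dataclass
class CandidateTree:
    """One labeled-and-contracted RSMT candidate derived from an MPT."""

    tree: PhyloTree
    weight: int
    steiner_node_count: int
    provenance: str


def _rooted_order(adj: dict[int, list[int]], root: int, skip: Optional[int] = None):
    """Pre-order node list and parent map of the tree rooted at ``root``,
    ignoring the ``skip`` node (a removed leaf)."""
    parent: dict[int, Optional[int]] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w == skip or w == parent[u]:
                continue
            parent[w] = u
            order.append(w)
            stack.append(w)
    return order, parent


def bottom_up_ranges(
    top: Topology, root: int, skip: Optional[int] = None
) -> tuple[dict[int, Interval], dict[int, Message]]:
    """Bottom-up phase: Farris interval per node of the rooted topology.

    Returns the interval map and the raw subtree messages (interval plus
    accumulated cost), which the lifting test and assignment phase reuse.
    ``skip`` removes one leaf (the lifted one) from the traversal.
    """
    order, parent = _rooted_order(top.adj, root, skip)
    msgs: dict[int, Message] = {}
    for u in reversed(order):
        children = [w for w in top.adj[u] if w != parent[u] and w != skip]
        if not children:
            if not top.is_leaf(u):
                raise ValueError(f"internal node {u} has no children")
            msgs[u] = leaf_message(top.leaf_labels[u])
        else:
            msgs[u] = combine_many([msgs[c] for c in children])
    ranges = {u: (m[0], m[1]) for u, m in msgs.items()}
    return ranges, msgs


def top_down_assign(
    top: Topology,
    root: int,
    ranges: dict[int, Interval],
    root_value: CountPattern,
    skip: Optional[int] = None,
    inputs: Optional[PatternSet] = None,
    strict: bool = False,
) -> PhyloTree:
    """Top-down phase: assign each internal node, per probe, the value in
    its interval closest to its parent's value (clamping); leaves keep
    their observed patterns.  With ``strict`` the root value must lie
    inside the root interval (the forced-root variant used when lifting a
    leaf deliberately violates this)."""
    if strict:
        lo, hi = ranges[root]
        for a, b, x in zip(lo, hi, root_value):
            if not (a <= x <= b):
                raise ValueError(f"root value {root_value} outside interval {ranges[root]}")
    order, parent = _rooted_order(top.adj, root, skip)
    mult = inputs.multiplicity if inputs is not None else {}
    assigned: dict[int, CountPattern] = {root: tuple(root_value)}
    t = PhyloTree()
    for u in order:
        if u == root:
            lab = assigned[root]
        elif top.is_leaf(u):
            lab = top.leaf_labels[u]
        else:
            pv = assigned[parent[u]]
            lo, hi = ranges[u]
            lab = tuple(min(max(x, a), b) for a, b, x in zip(lo, hi, pv))
        assigned[u] = lab
        observed = top.is_leaf(u) or (u == root and skip is not None)
        t.add_node(
            lab,
            kind=OBSERVED if observed else STEINER,
            multiplicity=mult.get(lab, 1) if observed else 1,
            node_id=u,
        )
    for u in order:
        if parent[u] is not None:
            t.add_edge(parent[u], u)
    t.root = root
    return t


def can_lift(top: Topology, leaf: int, mpt_weight: Optional[int] = None) -> bool:
    """True iff the leaf's pattern can label its parent at no weight cost.

    Tested by removing the leaf, rooting at its former parent, forcing the
    root label to the leaf's pattern and rescoring: the forced weight (the
    leaf's now-trivial edge costs nothing) must equal the MPT weight.
    """
    if leaf not in top.adj or not top.is_leaf(leaf):
        raise KeyError(f"unknown leaf id {leaf}")
    if top.n_leaves <= 2:
        return True
    if mpt_weight is None:
        mpt_weight = wagner_score(top)
    parent = top.adj[leaf][0]
    x = top.leaf_labels[leaf]
    forced = 0
    for c in top.adj[parent]:
        if c == leaf:
            continue
        forced += _subtree_forced_cost(top, c, parent, x)
    return forced == mpt_weight


def _subtree_forced_cost(top: Topology, child: int, parent: int, x: CountPattern) -> int:
    """Cost of the subtree hanging at ``child`` (seen from ``parent``) when
    the parent is labeled ``x``: subtree message evaluated at x."""
    order, par = _rooted_order(top.adj, child, skip=parent)
    msgs: dict[int, Message] = {}
    for u in reversed(order):
        children = [w for w in top.adj[u] if w != par[u] and w != parent]
        if not children:
            msgs[u] = leaf_message(top.leaf_labels[u])
        else:
            msgs[u] = combine_many([msgs[c] for c in children])
    return point_value(msgs[child], x)


def derive_rsmt(top: Topology, inputs: PatternSet) -> CandidateTree:
    """Full MPT-to-RSMT conversion: lifted candidates, fallback, selection.

    The returned tree has exactly the MPT's parsimony weight; among all
    generated candidates it has the fewest Steiner nodes (ties broken by
    provenance for reproducibility).
    """
    n = top.n_leaves
    if n == 1:
        t = PhyloTree()
        t.add_node(top.leaf_labels[0], kind=OBSERVED,
                   multiplicity=inputs.multiplicity.get(top.leaf_labels[0], 1))
        t.root = 0
        return CandidateTree(t, 0, 0, "trivial")
    if n == 2:
        t = PhyloTree()
        a = t.add_node(top.leaf_labels[0], kind=OBSERVED,
                       multiplicity=inputs.multiplicity.get(top.leaf_labels[0], 1))
        b = t.add_node(top.leaf_labels[1], kind=OBSERVED,
                       multiplicity=inputs.multiplicity.get(top.leaf_labels[1], 1))
        t.add_edge(a, b)
        t.root = a
        return CandidateTree(t, tree_weight(t), 0, "trivial")

    mpt_weight = wagner_score(top)
    candidates: list[tuple[tuple, CandidateTree]] = []

    for leaf in range(n):
        if not can_lift(top, leaf, mpt_weight):
            continue
        root = top.adj[leaf][0]
        ranges, _ = bottom_up_ranges(top, root, skip=leaf)
        labeled = top_down_assign(
            top, root, ranges, top.leaf_labels[leaf], skip=leaf, inputs=inputs
        )
        cand = _finalize(labeled, inputs, f"lifted leaf {leaf}")
        candidates.append(((cand.steiner_node_count, cand.weight, 0, leaf), cand))

    # Unrooted fallback: root at an internal node; any interval point is
    # weight-optimal, so bias the root label toward the healthy diploid
    # ancestor (2, ..., 2).
    root = top.adj[0][0]
    ranges, _ = bottom_up_ranges(top, root)
    lo, hi = ranges[root]
    root_value = tuple(min(max(2, a), b) for a, b in zip(lo, hi))
    labeled = top_down_assign(top, root, ranges, root_value, inputs=inputs)
    cand = _finalize(labeled, inputs, "unrooted fallback")
    candidates.append(((cand.steiner_node_count, cand.weight, 1, 0), cand))

    candidates.sort(key=lambda kv: kv[0])
    best = candidates[0][1]
    assert best.weight == mpt_weight, (
        f"labeling changed the weight: {best.weight} != {mpt_weight}"
    )
    return best


def _finalize(labeled: PhyloTree, inputs: PatternSet, provenance: str) -> CandidateTree:
    contracted = contract_trivial_edges(labeled)
    # A Steiner-flagged node may carry an observed pattern without being
    # adjacent to its observed twin; Steiner accounting is by label.
    observed = set(inputs.patterns)
    for v in contracted.nodes():
        lab = contracted.label(v)
        if lab in observed and contracted.kind(v) != OBSERVED:
            contracted.set_label(v, lab, kind=OBSERVED)
            contracted.graph.nodes[v]["multiplicity"] = inputs.multiplicity.get(lab, 1)
    return CandidateTree(
        contracted,
        tree_weight(contracted),
        count_steiner_nodes(contracted, inputs),
        provenance,
    )


def mpttree(
    inputs: PatternSet,
    cfg: Optional[SearchConfig] = None,
) -> PhyloTree:
    """The full MPT-based RSMT heuristic: parsimony search, then labeling."""
    top, _ = mpt_search(inputs, cfg)
    return derive_rsmt(top, inputs).tree
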