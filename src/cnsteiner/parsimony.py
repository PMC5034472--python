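"""Maximum-parsimony tree search under the rectilinear metric.

Copy numbers are ordered (additive / Wagner) characters: the cost of an
edge is the sum over probes of the absolute difference of the endpoint
values.  Because the metric separates over probes, exact scoring of a fixed
topology reduces to an independent interval dynamic program per probe
(Farris intervals): a leaf carries the degenerate interval [x, x]; an
internal node takes the intersection of its children's intervals when it is
non-empty (no cost) and otherwise the gap between them, paying the gap
length.  The total over probes equals the minimum tree weight over all
integer labelings of the internal nodes.

The search itself is classic: greedy stepwise addition from a (shuffled)
leaf order, refined by NNI — or optionally SPR — hill climbing, repeated
over random-addition restarts.  Directional interval messages make each
candidate rearrangement scorable in O(d).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import CountPattern, PatternSet, l1_distance

# A message is (lo, hi, w): per-probe interval bounds plus accumulated cost.
# It encodes the exact cost function  w + sum_j dist(y_j, [lo_j, hi_j])  of a
# subtree as a function of the pattern y at its attachment point (slopes are
# +-1 outside the interval because the connecting edge is included).
Message = tuple[tuple[int, ...], tuple[int, ...], int]


def leaf_message(x: CountPattern) -> Message:
    return (x, x, 0)


def combine2(m1: Message, m2: Message) -> Message:
    """Merge two child messages at a node (per-probe Farris rule)."""
    lo1, hi1, w1 = m1
    lo2, hi2, w2 = m2
    lo, hi = [], []
    extra = 0
    for a1, b1, a2, b2 in zip(lo1, hi1, lo2, hi2):
        a = a1 if a1 > a2 else a2  # max of lows
        b = b1 if b1 < b2 else b2  # min of highs
        if a > b:
            extra += a - b
            a, b = b, a
        lo.append(a)
        hi.append(b)
    return (tuple(lo), tuple(hi), w1 + w2 + extra)


def combine_value(m1: Message, m2: Message) -> int:
    """Minimum total cost of joining two subtree messages at one node."""
    lo1, hi1, w1 = m1
    lo2, hi2, w2 = m2
    extra = 0
    for a1, b1, a2, b2 in zip(lo1, hi1, lo2, hi2):
        a = a1 if a1 > a2 else a2
        b = b1 if b1 < b2 else b2
        if a > b:
            extra += a - b
    return w1 + w2 + extra


def combine_many(msgs: Sequence[Message]) -> Message:
    """Merge k >= 1 child messages exactly.

    For k > 2 the summed cost function has slopes steeper than one, so the
    pairwise rule is insufficient; per probe we minimize the sum of interval
    distances over the candidate breakpoints (the interval bounds), which is
    exact because the sum is convex piecewise-linear with breakpoints there.
    """
    if len(msgs) == 1:
        return msgs[0]
    if len(msgs) == 2:
        return combine2(msgs[0], msgs[1])
    d = len(msgs[0][0])
    lo, hi = [], []
    extra = 0
    for j in range(d):
        bounds = sorted({m[0][j] for m in msgs} | {m[1][j] for m in msgs})
        best = None
        for y in bounds:
            c = 0
            for mlo, mhi, _ in msgs:
                if y < mlo[j]:
                    c += mlo[j] - y
                elif y > mhi[j]:
                    c += y - mhi[j]
            if best is None or c < best:
                best = c
        arg = [y for y in bounds if _sum_dist(msgs, j, y) == best]
        lo.append(min(arg))
        hi.append(max(arg))
        extra += best
    return (tuple(lo), tuple(hi), sum(m[2] for m in msgs) + extra)


def _sum_dist(msgs: Sequence[Message], j: int, y: int) -> int:
    c = 0
    for mlo, mhi, _ in msgs:
        if y < mlo[j]:
            c += mlo[j] - y
        elif y > mhi[j]:
            c += y - mhi[j]
    return c


def point_value(m: Message, x: CountPattern) -> int:
    """Evaluate a message's cost function at a fixed pattern."""
    lo, hi, w = m
    c = w
    for a, b, y in zip(lo, hi, x):
        if y < a:
            c += a - y
        elif y > b:
            c += y - b
    return c


@dataclass
class Topology:
    """Unrooted binary topology; leaves 0..n-1 carry count patterns."""

    leaf_labels: list[CountPattern]
    adj: dict[int, list[int]] = field(default_factory=dict)
    _next_id: int = 0

    def __post_init__(self) -> None:
        if not self.adj:
            self.adj = {i: [] for i in range(len(self.leaf_labels))}
        self._next_id = max(self.adj, default=-1) + 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def is_leaf(self, v: int) -> bool:
        return v < len(self.leaf_labels)

    def new_internal(self) -> int:
        v = self._next_id
        self._next_id += 1
        self.adj[v] = []
        return v

    def connect(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def disconnect(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (u, v) for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_nodes(self) -> list[int]:
        return [v for v in self.adj if not self.is_leaf(v)]

    def copy(self) -> "Topology":
        t = Topology(list(self.leaf_labels), {v: list(ws) for v, ws in self.adj.items()})
        t._next_id = self._next_id
        return t

    def validate(self) -> None:
        n = self.n_leaves
        if n <= 1:
            return
        if n == 2:
            assert self.adj[0] == [1] and self.adj[1] == [0]
            return
        for v, ws in self.adj.items():
            deg = len(ws)
            if self.is_leaf(v):
                if deg != 1:
                    raise ValueError(f"leaf {v} has degree {deg}")
            elif deg != 3:
                raise ValueError(f"internal node {v} has degree {deg}")


@dataclass
class SearchConfig:
    """Knobs of the maximum-parsimony hill climb."""

    restarts: int = 10
    neighborhood: str = "nni"  # or "spr"
    seed: int = 0
    max_rounds: int = 200

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.neighborhood not in ("nni", "spr"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")


def directed_messages(top: Topology) -> dict[tuple[int, int], Message]:
    """Message for every directed edge (u, v): the cost function of the
    u-side subtree, including the (u, v) edge, as a function of v's label."""
    msgs: dict[tuple[int, int], Message] = {}
    n = top.n_leaves
    if n < 2:
        return msgs
    root = 0
    # Downward pass (towards root 0): post-order on the tree rooted at 0.
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for w in top.adj[u]:
            if w != parent[u]:
                parent[w] = u
                order.append(w)
                stack.append(w)
    for u in reversed(order):
        p = parent[u]
        if p is None:
            continue
        if top.is_leaf(u):
            msgs[(u, p)] = leaf_message(top.leaf_labels[u])
        else:
            children = [w for w in top.adj[u] if w != p]
            msgs[(u, p)] = combine2(msgs[(children[0], u)], msgs[(children[1], u)])
    # Upward pass: pre-order.
    for u in order:
        p = parent[u]
        for c in top.adj[u]:
            if c == p:
                continue
            others = [w for w in top.adj[u] if w != c]
            incoming = [msgs[(w, u)] if w != p else msgs[(p, u)] for w in others]
            if top.is_leaf(u):
                msgs[(u, c)] = leaf_message(top.leaf_labels[u])
            elif len(incoming) == 1:
                msgs[(u, c)] = incoming[0]
            else:
                msgs[(u, c)] = combine2(incoming[0], incoming[1])
    return msgs


def wagner_score(
    top: Topology, return_intervals: bool = False
):
    """Exact parsimony weight of a leaf-labeled binary topology.

    Returns the weight, or ``(weight, intervals)`` with the per-internal-node
    Farris intervals of the dynamic program rooted at leaf 0 when
    ``return_intervals`` is set.  The weight is invariant to the rooting.
    """
    top.validate()
    n = top.n_leaves
    if n == 0:
        raise ValueError("empty topology")
    if n == 1:
        return (0, {}) if return_intervals else 0
    if n == 2:
        w = l1_distance(top.leaf_labels[0], top.leaf_labels[1])
        return (w, {}) if return_intervals else w
    msgs = _down_messages(top, root=0)
    r = top.adj[0][0]
    weight = point_value(msgs[(r, 0)], top.leaf_labels[0])
    if not return_intervals:
        return weight
    intervals = {
        u: (m[0], m[1])
        for (u, p), m in msgs.items()
        if not top.is_leaf(u)
    }
    return weight, intervals


def _down_messages(top: Topology, root: int) -> dict[tuple[int, int], Message]:
    """Only the towards-root half of :func:`directed_messages`."""
    msgs: dict[tuple[int, int], Message] = {}
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for w in top.adj[u]:
            if w != parent[u]:
                parent[w] = u
                order.append(w)
                stack.append(w)
    for u in reversed(order):
        p = parent[u]
        if p is None:
            continue
        if top.is_leaf(u):
            msgs[(u, p)] = leaf_message(top.leaf_labels[u])
        else:
            cs = [w for w in top.adj[u] if w != p]
            msgs[(u, p)] = combine2(msgs[(cs[0], u)], msgs[(cs[1], u)])
    return msgs


def _attach_cost(m1: Message, m2: Message, x: CountPattern) -> int:
    """Min cost of joining two edge-side messages and a new leaf at one node."""
    lo1, hi1, w1 = m1
    lo2, hi2, w2 = m2
    total = w1 + w2
    for j, xj in enumerate(x):
        best = None
        for y in (lo1[j], hi1[j], lo2[j], hi2[j], xj):
            c = 0
            if y < lo1[j]:
                c += lo1[j] - y
            elif y > hi1[j]:
                c += y - hi1[j]
            if y < lo2[j]:
                c += lo2[j] - y
            elif y > hi2[j]:
                c += y - hi2[j]
            c += abs(y - xj)
            if best is None or c < best:
                best = c
        total += best
    return total


def stepwise_addition(
    inputs: PatternSet | Sequence[CountPattern],
    order: Optional[Sequence[int]] = None,
) -> Topology:
    """Greedy leaf insertion: each new leaf goes on the edge whose exact
    attachment cost (computed from directional interval messages) is
    smallest.  Deterministic given the insertion order."""
    labels = list(inputs.patterns) if isinstance(inputs, PatternSet) else [
        tuple(p) for p in inputs
    ]
    if not labels:
        raise ValueError("empty input")
    n = len(labels)
    order = list(order) if order is not None else list(range(n))
    top = Topology(labels)
    if n == 1:
        return top
    if n == 2:
        top.connect(0, 1)
        return top
    hub = top.new_internal()
    for leaf in order[:3]:
        top.connect(leaf, hub)
    for leaf in order[3:]:
        # later leaves are still isolated, so traverse from the hub
        msgs = directed_messages_from(top, hub)
        best = None
        for u, v in top.edges():
            cost = _attach_cost(msgs[(u, v)], msgs[(v, u)], labels[leaf])
            if best is None or cost < best[0]:
                best = (cost, u, v)
        _, u, v = best
        w = top.new_internal()
        top.disconnect(u, v)
        top.connect(u, w)
        top.connect(v, w)
        top.connect(leaf, w)
    return top


def _nni_step(top: Topology) -> Optional[int]:
    """Best NNI move (steepest descent); applies it and returns the new
    score, or None at a local optimum."""
    msgs = directed_messages(top)
    base = None
    best = None  # (new_score, u, v, swap) with swap in {0, 1}
    for u, v in top.edges():
        if top.is_leaf(u) or top.is_leaf(v):
            continue
        a, b = [w for w in top.adj[u] if w != v]
        c, d = [w for w in top.adj[v] if w != u]
        ma, mb = msgs[(a, u)], msgs[(b, u)]
        mc, md = msgs[(c, v)], msgs[(d, v)]
        if base is None:
            base = combine_value(combine2(ma, mb), combine2(mc, md))
        s1 = combine_value(combine2(ma, mc), combine2(mb, md))  # swap b<->c
        s2 = combine_value(combine2(ma, md), combine2(mb, mc))  # swap b<->d
        for swap, s in ((0, s1), (1, s2)):
            if s < base and (best is None or s < best[0]):
                best = (s, u, v, swap)
    if best is None:
        return None
    _, u, v, swap = best
    a, b = [w for w in top.adj[u] if w != v]
    c, d = [w for w in top.adj[v] if w != u]
    other = c if swap == 0 else d
    _swap_subtrees(top, u, b, v, other)
    return best[0]


def _swap_subtrees(top: Topology, u: int, b: int, v: int, c: int) -> None:
    """Exchange subtree b (hanging off u) with subtree c (hanging off v)."""
    top.adj[u][top.adj[u].index(b)] = c
    top.adj[v][top.adj[v].index(c)] = b
    top.adj[b][top.adj[b].index(u)] = v
    top.adj[c][top.adj[c].index(v)] = u


def _spr_step(top: Topology) -> Optional[int]:
    """Best SPR move; O(n^2 d) per sweep.  Returns new score or None."""
    base = wagner_score(top)
    best = None  # (score, prune_u, prune_p, regraft_edge)
    for u, p in [(u, p) for u in top.adj for p in top.adj[u]]:
        if top.is_leaf(p):
            continue  # pruning would leave a single-leaf remainder
        trial = top.copy()
        msgs_full = directed_messages(trial)
        sub_msg = msgs_full[(u, p)]
        # Detach u-side subtree and splice p out of the remainder.
        trial.disconnect(u, p)
        x, y = trial.adj[p]
        trial.disconnect(p, x)
        trial.disconnect(p, y)
        trial.connect(x, y)
        sub_nodes = _component(trial, u)
        if len([w for w in sub_nodes if trial.is_leaf(w)]) >= trial.n_leaves - 2:
            continue
        rem_msgs = directed_messages_from(trial, x)
        for e_u, e_v in trial.edges():
            if e_u in sub_nodes or e_v in sub_nodes:
                continue
            if (e_u, e_v) == tuple(sorted((x, y))):
                pass  # regrafting on the origin edge recreates the input
            s = _attach_cost3(rem_msgs[(e_u, e_v)], rem_msgs[(e_v, e_u)], sub_msg)
            if s < base and (best is None or s < best[0]):
                best = (s, u, p, (e_u, e_v))
    if best is None:
        return None
    s, u, p, (e_u, e_v) = best
    top.disconnect(u, p)
    x, y = [w for w in top.adj[p]]
    top.disconnect(p, x)
    top.disconnect(p, y)
    top.connect(x, y)
    top.disconnect(e_u, e_v)
    top.connect(e_u, p)
    top.connect(e_v, p)
    top.connect(u, p)
    return s


def _attach_cost3(m1: Message, m2: Message, m3: Message) -> int:
    return combine_value(combine2(m1, m2), m3)


def _component(top: Topology, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in top.adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def directed_messages_from(top: Topology, root: int) -> dict[tuple[int, int], Message]:
    """Directed messages of the connected component containing ``root``."""
    msgs: dict[tuple[int, int], Message] = {}
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for w in top.adj[u]:
            if w != parent[u]:
                parent[w] = u
                order.append(w)
                stack.append(w)
    for u in reversed(order):
        p = parent[u]
        if p is None:
            continue
        ms = [msgs[(w, u)] for w in top.adj[u] if w != p]
        msgs[(u, p)] = leaf_message(top.leaf_labels[u]) if not ms else combine_many(ms)
    for u in order:
        p = parent[u]
        for c in top.adj[u]:
            if c == p:
                continue
            incoming = [msgs[(w, u)] for w in top.adj[u] if w != c]
            msgs[(u, c)] = (
                leaf_message(top.leaf_labels[u]) if not incoming else combine_many(incoming)
            )
    return msgs


def hill_climb(top: Topology, neighborhood: str = "nni", max_rounds: int = 200) -> int:
    """Refine a topology in place until no neighbor improves the score."""
    step = _nni_step if neighborhood == "nni" else _spr_step
    score = wagner_score(top)
    for _ in range(max_rounds):
        s = step(top)
        if s is None:
            break
        assert s <= score
        score = s
    return wagner_score(top)


def topology_from_tree(tree, patterns: Sequence[CountPattern]) -> Topology:
    """Refine a labeled Steiner tree into a leaf-labeled binary topology.

    Every node of the input tree becomes a chain of binary internal nodes
    (plus the pattern's leaf when the node is observed), so the topology
    admits a labeling of exactly the input tree's weight — its Wagner score
    is therefore at most that weight.  Used to seed the parsimony search
    from the MST-based heuristic's result.
    """
    labels = [tuple(p) for p in patterns]
    top = Topology(labels)
    leaf_of = {p: i for i, p in enumerate(labels)}
    from .core import OBSERVED  # local import to avoid a cycle at module load

    root = min(v for v in tree.nodes() if tree.kind(v) == OBSERVED)

    def rep(v: int, parent: Optional[int]) -> Optional[int]:
        reps = []
        for c in tree.neighbors(v):
            if c == parent:
                continue
            r = rep(c, v)
            if r is not None:
                reps.append(r)
        if tree.kind(v) == OBSERVED:
            current = leaf_of[tree.label(v)]
            for r in reps:
                i = top.new_internal()
                top.connect(i, current)
                top.connect(i, r)
                current = i
            return current
        if not reps:
            return None
        if len(reps) == 1:
            return reps[0]
        current = top.new_internal()
        top.connect(current, reps[0])
        top.connect(current, reps[1])
        for r in reps[2:]:
            i = top.new_internal()
            top.connect(i, current)
            top.connect(i, r)
            current = i
        return current

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * tree.n_nodes + 100))
    try:
        f = rep(root, None)
    finally:
        sys.setrecursionlimit(old)
    if f is not None and not top.is_leaf(f) and len(top.adj[f]) == 2:
        x, y = top.adj[f]
        top.disconnect(f, x)
        top.disconnect(f, y)
        top.connect(x, y)
        del top.adj[f]
    top.validate()
    return top


def mpt_search(
    inputs: PatternSet | Sequence[CountPattern],
    cfg: Optional[SearchConfig] = None,
) -> tuple[Topology, int]:
    """Best topology over hill-climbed starts.

    Starts are ``cfg.restarts`` random-addition stepwise trees (the first
    uses the input order) plus one deterministic start refined from the
    MST-based heuristic's tree, which anchors the search at a weight no
    worse than that heuristic's.
    """
    cfg = cfg or SearchConfig()
    labels = list(inputs.patterns) if isinstance(inputs, PatternSet) else [
        tuple(p) for p in inputs
    ]
    n = len(labels)
    if n <= 3:
        top = stepwise_addition(labels)
        return top, wagner_score(top)
    rng = random.Random(cfg.seed)
    starts: list[Topology] = []
    for r in range(cfg.restarts):
        order = list(range(n))
        if r > 0:  # first restart uses the input order, for determinism
            rng.shuffle(order)
        starts.append(stepwise_addition(labels, order))
    from .core import PatternSet as _PS
    from .mst_rsmt import msttree

    starts.append(topology_from_tree(msttree(_PS.from_patterns(labels)), labels))
    best: Optional[tuple[int, int, Topology]] = None
    for r, top in enumerate(starts):
        score = hill_climb(top, cfg.neighborhood, cfg.max_rounds)
        if best is None or score < best[0]:
            best = (score, r, top)
    return best[2], best[0]
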