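import pytest

from cnsteiner.core import PatternSet, count_steiner_nodes, tree_weight
from cnsteiner.labeling import (
    bottom_up_ranges,
    can_lift,
    derive_rsmt,
    mpttree,
    top_down_assign,
)
from cnsteiner.oracle import exact_rsmt
from cnsteiner.parsimony import (
    SearchConfig,
    Topology,
    mpt_search,
    wagner_score,
)
from helpers import random_pattern_set


def lifted_quartet():
    """Five leaves; removing leaf 4 and rooting at its parent (node 6)
    leaves a root with two cherry children — the canonical lifting shape."""
    top = Topology([(0,), (2,), (8,), (10,), (5,)])
    a, r, b = top.new_internal(), top.new_internal(), top.new_internal()
    top.connect(0, a)
    top.connect(1, a)
    top.connect(2, b)
    top.connect(3, b)
    top.connect(a, r)
    top.connect(b, r)
    top.connect(4, r)
    return top, r


def test_bottom_up_ranges_quartet_cherries():
    top, root = lifted_quartet()
    ranges, _ = bottom_up_ranges(top, root, skip=4)
    cherries = sorted(
        (ranges[v][0][0], ranges[v][1][0]) for v in ranges if not top.is_leaf(v) and v != root
    )
    assert cherries == [(0, 2), (8, 10)]
    assert ranges[root] == ((2,), (8,))


def test_bottom_up_ranges_identical_leaves():
    top = Topology([(3, 3)] * 3)
    hub = top.new_internal()
    for leaf in range(3):
        top.connect(leaf, hub)
    ranges, _ = bottom_up_ranges(top, hub)
    assert ranges[hub] == ((3, 3), (3, 3))


def test_bottom_up_ranges_three_leaf_median():
    top = Topology([(0,), (4,), (2,)])
    hub = top.new_internal()
    for leaf in range(3):
        top.connect(leaf, hub)
    ranges, _ = bottom_up_ranges(top, hub)
    assert ranges[hub] == ((2,), (2,))


@pytest.mark.parametrize("root_value,expected_internal", [((2,), {2, 8}), ((5,), {2, 8})])
def test_top_down_assign_quartet_weight(root_value, expected_internal):
    """Any root value inside the root interval yields the optimal weight;
    the cherry intervals clamp the internal labels."""
    top, root = lifted_quartet()
    ranges, _ = bottom_up_ranges(top, root, skip=4)
    t = top_down_assign(top, root, ranges, root_value, skip=4)
    internal = {
        t.label(v)[0] for v in t.nodes() if v not in (0, 1, 2, 3, root)
    }
    assert internal == expected_internal
    assert tree_weight(t) == 10 + abs(root_value[0] - 2) + abs(root_value[0] - 8) - 6


def test_top_down_assign_strict_rejects_outside_interval():
    top, root = lifted_quartet()
    ranges, _ = bottom_up_ranges(top, root, skip=4)
    with pytest.raises(ValueError):
        top_down_assign(top, root, ranges, (9,), skip=4, strict=True)
    t = top_down_assign(top, root, ranges, (2,), skip=4, strict=True)
    assert tree_weight(t) == 10


def test_can_lift_quartet():
    labels = [(2, 2, 2), (3, 2, 2), (3, 3, 2), (3, 3, 3)]
    top = Topology(labels)
    a, b = top.new_internal(), top.new_internal()
    top.connect(0, a)
    top.connect(1, a)
    top.connect(2, b)
    top.connect(3, b)
    top.connect(a, b)
    assert wagner_score(top) == 3
    assert can_lift(top, 1)  # parent can take (3,2,2) at weight 3
    assert can_lift(top, 2)


def test_can_lift_rejects_steiner_center():
    top = Topology([(0, 0), (4, 2), (2, 6)])
    hub = top.new_internal()
    for leaf in range(3):
        top.connect(leaf, hub)
    for leaf in range(3):
        assert not can_lift(top, leaf)
    with pytest.raises(KeyError):
        can_lift(top, 99)


def test_can_lift_duplicate_pattern():
    # a leaf whose pattern equals its cherry twin always lifts
    top = Topology([(1, 1), (1, 1), (4, 1), (4, 4)])
    a, b = top.new_internal(), top.new_internal()
    top.connect(0, a)
    top.connect(1, a)
    top.connect(2, b)
    top.connect(3, b)
    top.connect(a, b)
    assert can_lift(top, 0)


def test_derive_rsmt_quartet_chain():
    ps = PatternSet.from_patterns([(2, 2, 2), (3, 2, 2), (3, 3, 2), (3, 3, 3)])
    top, score = mpt_search(ps, SearchConfig(restarts=2))
    cand = derive_rsmt(top, ps)
    assert cand.weight == score == 3
    assert cand.steiner_node_count == 0
    assert cand.tree.n_nodes == 4
    degs = sorted(cand.tree.degree(v) for v in cand.tree.nodes())
    assert degs == [1, 1, 2, 2]  # a chain of the four observed patterns


def test_derive_rsmt_median_star():
    ps = PatternSet.from_patterns([(0, 0), (4, 2), (2, 6)])
    top, _ = mpt_search(ps)
    cand = derive_rsmt(top, ps)
    assert cand.weight == 10
    assert cand.steiner_node_count == 1
    steiner = [v for v in cand.tree.nodes() if cand.tree.kind(v) == "steiner"]
    assert [cand.tree.label(v) for v in steiner] == [(2, 2)]


def test_derive_rsmt_single_pattern():
    ps = PatternSet.from_patterns([(2, 2)])
    top, _ = mpt_search(ps)
    cand = derive_rsmt(top, ps)
    assert cand.weight == 0 and cand.steiner_node_count == 0


def test_derive_preserves_weight_and_bounds_steiner(rng):
    for _ in range(25):
        d = int(rng.integers(1, 4))
        n = int(rng.integers(2, min(9, 7**d + 1)))
        ps = random_pattern_set(rng, n, d, 6)
        top, score = mpt_search(ps, SearchConfig(restarts=2, seed=1))
        cand = derive_rsmt(top, ps)
        assert cand.weight == score
        assert cand.steiner_node_count <= max(n - 2, 0)
        assert tree_weight(cand.tree) == cand.weight
        observed = {
            cand.tree.label(v)
            for v in cand.tree.nodes()
            if cand.tree.kind(v) == "observed"
        }
        assert observed == set(ps.patterns)


def test_derive_weight_never_below_exact(rng):
    for _ in range(15):
        ps = random_pattern_set(rng, 5, 2, 5)
        opt, _ = exact_rsmt(ps)
        top, _ = mpt_search(ps, SearchConfig(restarts=3, seed=2))
        cand = derive_rsmt(top, ps)
        assert cand.weight >= opt


def test_mpttree_pipeline_roundtrip():
    ps = PatternSet.from_patterns([(0, 0), (4, 2), (2, 6), (4, 6)])
    t = mpttree(ps, SearchConfig(restarts=2))
    assert tree_weight(t) >= exact_rsmt(ps)[0]
    assert count_steiner_nodes(t, ps) <= 2
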