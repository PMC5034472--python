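import pytest

from cnsteiner.core import PatternSet, l1_distance, tree_weight
from cnsteiner.mst_rsmt import msttree
from cnsteiner.parsimony import (
    SearchConfig,
    Topology,
    combine_value,
    directed_messages,
    hill_climb,
    mpt_search,
    stepwise_addition,
    topology_from_tree,
    wagner_score,
)
from helpers import brute_force_wagner, random_patterns, random_topology


def quartet(labels):
    top = Topology([tuple(p) for p in labels])
    a = top.new_internal()
    b = top.new_internal()
    top.connect(0, a)
    top.connect(1, a)
    top.connect(2, b)
    top.connect(3, b)
    top.connect(a, b)
    return top


def test_wagner_score_one_probe_quartet():
    assert wagner_score(quartet([(0,), (2,), (8,), (10,)])) == 10


def test_wagner_score_identical_leaves():
    assert wagner_score(quartet([(3, 1)] * 4)) == 0


def test_wagner_score_three_leaves():
    top = Topology([(0,), (4,), (2,)])
    hub = top.new_internal()
    for leaf in range(3):
        top.connect(leaf, hub)
    assert wagner_score(top) == 4  # internal node takes the median 2


def test_wagner_score_rejects_unlabeled_or_nonbinary():
    top = Topology([(0,), (1,), (2,), (3,)])
    hub = top.new_internal()
    for leaf in range(4):
        top.connect(leaf, hub)
    with pytest.raises(ValueError):
        wagner_score(top)


def test_wagner_matches_bruteforce(rng):
    for _ in range(40):
        n = int(rng.integers(2, 7))
        labels = random_patterns(rng, n, int(rng.integers(1, 4)), 6)
        top = random_topology(rng, labels)
        assert wagner_score(top) == brute_force_wagner(top)


def test_wagner_rooting_invariance(rng):
    """The DP total must be identical no matter which edge evaluates it."""
    labels = random_patterns(rng, 6, 2, 6)
    top = random_topology(rng, labels)
    score = wagner_score(top)
    from cnsteiner.parsimony import combine2, point_value

    msgs = directed_messages(top)
    for u, v in top.edges():
        other = [w for w in top.adj[v] if w != u]
        if not other:  # v is a leaf: evaluate the u-side message at its label
            assert point_value(msgs[(u, v)], top.leaf_labels[v]) == score
        else:
            side = msgs[(other[0], v)]
            for w in other[1:]:
                side = combine2(side, msgs[(w, v)])
            assert combine_value(msgs[(u, v)], side) == score


def test_stepwise_addition_quartet_is_optimal():
    labels = [(2, 2, 2), (3, 2, 2), (3, 3, 2), (3, 3, 3)]
    top = stepwise_addition(labels)
    # brute force over the 3 quartet topologies
    scores = set()
    for pairs in ([(0, 1), (2, 3)], [(0, 2), (1, 3)], [(0, 3), (1, 2)]):
        q = Topology([tuple(p) for p in labels])
        a, b = q.new_internal(), q.new_internal()
        for leaf in pairs[0]:
            q.connect(leaf, a)
        for leaf in pairs[1]:
            q.connect(leaf, b)
        q.connect(a, b)
        scores.add(wagner_score(q))
    assert min(scores) == 3
    assert wagner_score(top) == 3


def test_stepwise_addition_three_patterns_unique_topology():
    top = stepwise_addition([(0, 0), (4, 2), (2, 6)])
    top.validate()
    assert wagner_score(top) == 10  # sum over probes of (max - min)


@pytest.mark.parametrize("seed", [0, 1, 42])
def test_mpt_search_quartet_any_seed(seed):
    ps = PatternSet.from_patterns([(2, 2, 2), (3, 2, 2), (3, 3, 2), (3, 3, 3)])
    _, score = mpt_search(ps, SearchConfig(restarts=3, seed=seed))
    assert score == 3


def test_mpt_search_two_patterns():
    ps = PatternSet.from_patterns([(0, 0), (4, 2)])
    top, score = mpt_search(ps)
    assert score == l1_distance((0, 0), (4, 2)) == 6


def test_hill_climb_never_worse_than_stepwise(rng):
    for _ in range(10):
        labels = random_patterns(rng, 8, 2, 8)
        top = stepwise_addition(labels)
        start = wagner_score(top)
        final = hill_climb(top, "nni")
        assert final <= start
        assert final == wagner_score(top)


def test_spr_neighborhood_also_descends(rng):
    labels = random_patterns(rng, 7, 2, 8)
    top = stepwise_addition(labels)
    start = wagner_score(top)
    assert hill_climb(top, "spr") <= start


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(restarts=0)
    with pytest.raises(ValueError):
        SearchConfig(neighborhood="tbr")


def test_topology_from_tree_score_bounded_by_tree_weight(rng):
    for _ in range(10):
        labels = random_patterns(rng, int(rng.integers(4, 10)), 3, 6)
        ps = PatternSet.from_patterns(labels)
        t = msttree(ps)
        top = topology_from_tree(t, labels)
        top.validate()
        assert wagner_score(top) <= tree_weight(t)
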