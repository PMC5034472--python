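import pytest

from cnsteiner.core import (
    OBSERVED,
    STEINER,
    DimensionError,
    LabelingError,
    PatternSet,
    PhyloTree,
    ProbePanel,
    contract_trivial_edges,
    count_steiner_nodes,
    is_steiner_required,
    l1_distance,
    median3,
    tree_weight,
)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((2, 2, 2, 2), (2, 2, 2, 2), 0),
        ((2, 1, 4, 2), (2, 2, 2, 2), 3),
        ((0, 5), (3, 1), 7),
    ],
)
def test_l1_distance(a, b, expected):
    assert l1_distance(a, b) == expected
    assert l1_distance(b, a) == expected


def test_l1_distance_dimension_mismatch():
    with pytest.raises(DimensionError):
        l1_distance((1, 2), (1, 2, 3))


@pytest.mark.parametrize(
    "triple,expected,star",
    [
        (((2, 2), (2, 2), (2, 2)), (2, 2), 0),
        (((0, 0), (4, 2), (2, 6)), (2, 2), 10),  # new Steiner state needed
        (((1, 1), (3, 1), (1, 3)), (1, 1), 4),  # median coincides with an input
    ],
)
def test_median3(triple, expected, star):
    m = median3(*triple)
    assert m == expected
    assert sum(l1_distance(m, p) for p in triple) == star


@pytest.mark.parametrize(
    "triple,required",
    [
        (((0, 0), (4, 2), (2, 6)), True),
        (((1, 1), (3, 1), (1, 3)), False),
        (((5,), (5,), (7,)), False),  # median equals a duplicated input
    ],
)
def test_is_steiner_required(triple, required):
    assert is_steiner_required(*triple) is required


def _tree(labels, edges, observed=None):
    return PhyloTree.from_labeled_edges(labels, edges, observed)


def test_tree_weight_examples():
    assert tree_weight(_tree({0: (2, 2), 1: (3, 4)}, [(0, 1)])) == 3
    star = _tree(
        {0: (2, 2), 1: (0, 0), 2: (4, 2), 3: (2, 6)}, [(0, 1), (0, 2), (0, 3)]
    )
    assert tree_weight(star) == 10
    assert tree_weight(_tree({0: (0,), 1: (1,), 2: (2,)}, [(0, 1), (1, 2)])) == 2


def test_tree_weight_requires_labels():
    t = PhyloTree()
    a = t.add_node((1,), kind=OBSERVED)
    b = t.add_node()
    t.add_edge(a, b)
    with pytest.raises(LabelingError):
        tree_weight(t)


def test_contract_trivial_edges_chain():
    t = _tree(
        {0: (2, 2), 1: (2, 2), 2: (4, 2)}, [(0, 1), (1, 2)], observed=[0, 2]
    )
    out = contract_trivial_edges(t)
    assert out.n_nodes == 2
    assert tree_weight(out) == tree_weight(t) == 2
    assert 0 in out.nodes() and 1 not in out.nodes()
    assert out.kind(0) == OBSERVED


def test_contract_trivial_edges_identity():
    t = _tree({0: (0, 0), 1: (1, 0)}, [(0, 1)])
    out = contract_trivial_edges(t)
    assert sorted(out.nodes()) == [0, 1]
    assert out.edges() == [(0, 1)]


def test_contract_observed_survives_steiner():
    # Steiner node with the same pattern as an observed node merges into it
    t = _tree(
        {0: (1, 1), 1: (1, 1), 2: (3, 1)}, [(1, 0), (1, 2)], observed=[0, 2]
    )
    out = contract_trivial_edges(t)
    assert out.n_nodes == 2
    assert all(out.kind(v) == OBSERVED for v in out.nodes())
    assert tree_weight(out) == 2


def test_count_steiner_nodes():
    inputs = PatternSet.from_patterns([(0, 0), (4, 2), (2, 6)])
    star = _tree(
        {0: (2, 2), 1: (0, 0), 2: (4, 2), 3: (2, 6)},
        [(0, 1), (0, 2), (0, 3)],
        observed=[1, 2, 3],
    )
    assert count_steiner_nodes(star, inputs) == 1
    inputs2 = PatternSet.from_patterns([(1, 1), (3, 1), (1, 3)])
    star2 = _tree(
        {0: (1, 1), 1: (1, 1), 2: (3, 1), 3: (1, 3)},
        [(0, 1), (0, 2), (0, 3)],
        observed=[1, 2, 3],
    )
    assert count_steiner_nodes(star2, inputs2) == 0


def test_pattern_set_validation():
    with pytest.raises(ValueError):
        PatternSet.from_patterns([(1, 1), (1, 1)])
    with pytest.raises(ValueError):
        PatternSet.from_patterns([(1, -1)])
    ps = PatternSet.from_patterns([(1, 2)], multiplicity={(1, 2): 5})
    assert ps.multiplicity[(1, 2)] == 5
    with pytest.raises(ValueError):
        PatternSet.from_patterns([(1, 2)], multiplicity={(1, 2): 0})


def test_probe_panel_validation():
    with pytest.raises(ValueError):
        ProbePanel(("a", "a"))
    panel = ProbePanel.generic(4, ["c1", "c1", "c2", "c2"])
    assert panel.require_chromosomes()["p3"] == "c2"
    with pytest.raises(ValueError):
        ProbePanel.generic(2).require_chromosomes()
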