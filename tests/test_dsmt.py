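import pytest

from cnsteiner.core import (
    PatternSet,
    PhyloTree,
    ProbePanel,
    l1_distance,
    tree_weight,
)
from cnsteiner.dsmt import (
    EventModel,
    detect_duplication_branches,
    dsmttree,
    duplication_distance,
    edge_cost,
    generalized_tree_weight,
    split_rebuild_reassemble,
)
from cnsteiner.mst_rsmt import msttree
from cnsteiner.simulate import SimulationConfig, grow_tree
from helpers import random_patterns

PANEL4 = ProbePanel.generic(4, ["chr1", "chr1", "chr2", "chr2"])
MODEL = EventModel()


@pytest.mark.parametrize(
    "parent,child,cost,script",
    [
        ((2, 2, 2, 2), (4, 4, 4, 4), 1, ("WGD",)),
        ((2, 2, 2, 2), (4, 4, 2, 2), 1, ("dup:chr1",)),
        ((2, 2, 2, 2), (4, 4, 4, 5), 2, ("WGD",)),  # WGD + one gain
        ((2, 2, 2, 2), (2, 2, 2, 3), 1, ()),  # plain single gain
    ],
)
def test_duplication_distance_examples(parent, child, cost, script):
    c, s = duplication_distance(parent, child, MODEL, PANEL4)
    assert (c, s) == (cost, script)


def test_duplication_distance_simple_gain_two_probes():
    panel = ProbePanel.generic(2, ["c1", "c1"])
    assert duplication_distance((2, 2), (2, 3), MODEL, panel) == (1, ())


def test_duplication_distance_dominated_by_l1(rng):
    for _ in range(200):
        a = tuple(int(x) for x in rng.integers(0, 9, 4))
        b = tuple(int(x) for x in rng.integers(0, 9, 4))
        c, script = duplication_distance(a, b, MODEL, PANEL4)
        assert c <= l1_distance(a, b)
        if not script:
            assert c == l1_distance(a, b)


def test_duplication_requires_chromosome_map():
    panel = ProbePanel.generic(4)  # no chromosome assignment
    with pytest.raises(ValueError):
        duplication_distance((2,) * 4, (4,) * 4, MODEL, panel)
    # with chromosomal duplications disabled the map is not needed
    model = EventModel(chromosomal_dup=False)
    assert duplication_distance((2,) * 4, (4,) * 4, model, panel)[0] == 1


def test_duplication_is_directional():
    # halving is not an event: going back down costs full L1
    down, script = duplication_distance((4, 4, 4, 4), (2, 2, 2, 2), MODEL, PANEL4)
    assert down == 8 and script == ()
    assert edge_cost((4, 4, 4, 4), (2, 2, 2, 2), MODEL, PANEL4) == 1


def _chain(labels):
    t = PhyloTree()
    ids = [t.add_node(lab, kind="observed") for lab in labels]
    for a, b in zip(ids, ids[1:]):
        t.add_edge(a, b)
    return t


def test_detect_duplication_branches():
    t = _chain([(2, 2, 2, 2), (4, 4, 4, 5)])
    (branch,) = detect_duplication_branches(t, MODEL, PANEL4)
    assert branch.script == ("WGD",)
    assert branch.cost == 2 and branch.l1_cost == 9

    t2 = _chain([(2, 2), (3, 2)])
    panel2 = ProbePanel.generic(2, ["c1", "c2"])
    assert detect_duplication_branches(t2, MODEL, panel2) == []

    t3 = _chain([(2, 2, 2, 2), (2, 2, 2, 3), (2, 2, 3, 3)])
    assert detect_duplication_branches(t3, MODEL, PANEL4) == []


def test_split_rebuild_degenerate_without_duplications():
    pats = [(2, 2, 2, 2), (2, 2, 2, 3), (3, 2, 2, 3)]
    ps = PatternSet.from_patterns(pats, panel=PANEL4)
    t = msttree(ps)
    out = split_rebuild_reassemble(t, ps, "mst", MODEL, PANEL4)
    assert tree_weight(out) == tree_weight(t)


def test_split_rebuild_chain_with_wgd():
    ps = PatternSet.from_patterns(
        [(2, 2, 2, 2), (4, 4, 4, 4), (4, 4, 4, 5)], panel=PANEL4
    )
    t = _chain(list(ps.patterns))
    out = split_rebuild_reassemble(t, ps, "mst", MODEL, PANEL4)
    assert generalized_tree_weight(out, MODEL, PANEL4) == 2


@pytest.mark.parametrize("method", ["mst", "mpt"])
def test_dsmttree_examples(method):
    ps = PatternSet.from_patterns(
        [(2, 2, 2, 2), (4, 4, 4, 4), (4, 4, 4, 5)], panel=PANEL4
    )
    t = dsmttree(ps, MODEL, PANEL4, method=method)
    assert generalized_tree_weight(t, MODEL, PANEL4) == 2


def test_dsmttree_single_pattern():
    ps = PatternSet.from_patterns([(2, 2, 2, 2)], panel=PANEL4)
    t = dsmttree(ps, MODEL, PANEL4)
    assert t.n_nodes == 1


def test_dsmttree_matches_rsmt_without_duplications(rng):
    pats = random_patterns(rng, 6, 4, 4)
    ps = PatternSet.from_patterns(pats, panel=PANEL4)
    model = EventModel(chromosomal_dup=False, whole_genome_dup=False)
    t = dsmttree(ps, model, PANEL4)
    assert generalized_tree_weight(t, model, PANEL4) == tree_weight(msttree(ps))


def test_dsmttree_never_exceeds_rsmt_on_simulations():
    for seed in range(5):
        cfg = SimulationConfig(
            d=4,
            growth=0.4,
            target_range=(25, 40),
            p_gain=0.42,
            p_loss=0.42,
            p_chrom=0.10,
            p_wgd=0.06,
            seed=seed,
        )
        _, sample = grow_tree(cfg)
        model = EventModel()
        panel = cfg.panel()
        t = dsmttree(sample, model, panel)
        rsmt_w = tree_weight(msttree(sample))
        assert generalized_tree_weight(t, model, panel) <= rsmt_w


def test_reassembly_marks_removed_branch_events():
    ps = PatternSet.from_patterns(
        [(2, 2, 2, 2), (4, 4, 4, 4), (4, 4, 4, 5)], panel=PANEL4
    )
    t = dsmttree(ps, MODEL, PANEL4)
    scripts = [
        t.graph.edges[u, v].get("events")
        for u, v in t.edges()
        if t.graph.edges[u, v].get("events")
    ]
    assert ("WGD",) in scripts
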