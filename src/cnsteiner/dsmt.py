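"""RSMT extension for large-scale duplication events (DSMT).

Cancer genomes undergo chromosomal and whole-genome duplications that a
pure single-gene (L1) metric over-charges: one whole-genome doubling of a
diploid 4-probe pattern costs 8 single-gene gains under L1 but is a single
biological event.  The generalized edge metric here is defined by an
explicit event grammar: on a parent-to-child edge, first apply a set of
doubling events — at most one whole-genome duplication and at most one
duplication per chromosome, each of unit cost, each doubling the counts
current at the time it applies — then pay one unit per residual single-gene
gain or loss.  The grammar is minimized exhaustively (probe panels are
small), and doublings are irreversible, so the metric is directional;
unrooted edge weights take the cheaper orientation.

The DSMT heuristic mirrors the RSMT ones: seed a tree under the
generalized metric, locate branches where a duplication strictly beats L1,
remove them, rebuild each resulting component with an RSMT heuristic, and
re-insert the removed branches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .core import (
    OBSERVED,
    STEINER,
    CountPattern,
    PatternSet,
    PhyloTree,
    ProbePanel,
    l1_distance,
    tree_weight,
)
from .labeling import derive_rsmt
from .mst_rsmt import msttree
from .parsimony import SearchConfig, mpt_search


@dataclass(frozen=True)
class EventModel:
    """Admissible mutation events, all at unit cost."""

    single_gain: bool = True
    single_loss: bool = True
    chromosomal_dup: bool = True
    whole_genome_dup: bool = True

    def needs_chromosomes(self) -> bool:
        return self.chromosomal_dup


@dataclass(frozen=True)
class DuplicationBranch:
    """A tree edge better explained with doubling events than by L1 alone."""

    parent: int
    child: int
    script: tuple[str, ...]
    residual: int  # single-gene events after the duplications
    cost: int
    l1_cost: int


def _duplication_sets(model: EventModel, chromosomes: list[str]):
    wgd_opts = (False, True) if model.whole_genome_dup else (False,)
    chrom_opts = []
    if model.chromosomal_dup:
        for r in range(len(chromosomes) + 1):
            chrom_opts.extend(itertools.combinations(chromosomes, r))
    else:
        chrom_opts = [()]
    for wgd in wgd_opts:
        for chroms in chrom_opts:
            yield wgd, chroms


def _residual_cost(applied: CountPattern, child: CountPattern, model: EventModel) -> Optional[int]:
    cost = 0
    for a, c in zip(applied, child):
        if c > a:
            if not model.single_gain:
                return None
            cost += c - a
        elif c < a:
            if not model.single_loss:
                return None
            cost += a - c
    return cost


def duplication_distance(
    parent: CountPattern,
    child: CountPattern,
    model: EventModel,
    panel: ProbePanel,
) -> tuple[int, tuple[str, ...]]:
    """Cheapest event script turning ``parent`` into ``child``.

    Exhaustive over the duplication grammar (at most ``2^(c+1)`` doubling
    sets for c chromosomes); the no-duplication script is always a
    candidate, so the result never exceeds the L1 distance.  Ties prefer
    fewer duplications, so the empty script wins when doubling does not
    strictly help.
    """
    if len(parent) != len(child):
        raise ValueError("pattern length mismatch")
    chromosomes: list[str] = []
    chrom_of: dict[str, str] = {}
    if model.chromosomal_dup:
        chrom_of = dict(panel.require_chromosomes())
        chromosomes = sorted(set(chrom_of.values()))
    best: Optional[tuple[int, int, tuple[str, ...]]] = None
    for wgd, chroms in _duplication_sets(model, chromosomes):
        factors = []
        for name in panel.probe_names:
            f = 1
            if wgd:
                f *= 2
            if chrom_of.get(name) in chroms:
                f *= 2
            factors.append(f)
        applied = tuple(p * f for p, f in zip(parent, factors))
        residual = _residual_cost(applied, child, model)
        if residual is None:
            continue
        n_dups = int(wgd) + len(chroms)
        script = (("WGD",) if wgd else ()) + tuple(f"dup:{c}" for c in chroms)
        cand = (n_dups + residual, n_dups, script)
        if best is None or cand < best:
            best = cand
    if best is None:  # single-gene events disabled and no doubling fits
        raise ValueError(f"no admissible event script from {parent} to {child}")
    return best[0], best[2]


def edge_cost(
    a: CountPattern, b: CountPattern, model: EventModel, panel: ProbePanel
) -> int:
    """Unrooted generalized edge weight: cheaper of the two orientations."""
    return min(
        duplication_distance(a, b, model, panel)[0],
        duplication_distance(b, a, model, panel)[0],
    )


def generalized_tree_weight(
    t: PhyloTree, model: EventModel, panel: ProbePanel
) -> int:
    t.require_labeled()
    return sum(
        edge_cost(t.label(u), t.label(v), model, panel) for u, v in t.edges()
    )


def _choose_root(t: PhyloTree) -> int:
    """Diploid pattern if present, else the minimum-sum pattern (lex ties)."""
    best = None
    for v in t.nodes():
        lab = t.label(v)
        if lab == (2,) * len(lab):
            return v
        key = (sum(lab), lab, v)
        if best is None or key < best[0]:
            best = (key, v)
    return best[1]


def detect_duplication_branches(
    t: PhyloTree, model: EventModel, panel: ProbePanel
) -> list[DuplicationBranch]:
    """Edges whose generalized (parent-to-child) cost strictly beats L1.

    The tree is oriented away from the diploid root (or the minimum-sum
    pattern when no diploid is observed), since doublings are
    irreversible and must point forward in time.
    """
    t.require_labeled()
    root = _choose_root(t)
    out = []
    parent = {root: None}
    stack = [root]
    while stack:
        u = stack.pop()
        for w in t.neighbors(u):
            if w == parent[u]:
                continue
            parent[w] = u
            stack.append(w)
            cost, script = duplication_distance(t.label(u), t.label(w), model, panel)
            l1 = l1_distance(t.label(u), t.label(w))
            if cost < l1:
                n_dups = len(script)
                out.append(
                    DuplicationBranch(u, w, script, cost - n_dups, cost, l1)
                )
    return sorted(out, key=lambda b: (b.parent, b.child))


def _rebuild(
    patterns: list[CountPattern],
    inputs: PatternSet,
    method: str,
    cfg: Optional[SearchConfig],
) -> PhyloTree:
    mult = {p: inputs.multiplicity.get(p, 1) for p in patterns}
    sub = PatternSet.from_patterns(patterns, panel=inputs.panel, multiplicity=mult)
    if method == "mst":
        return msttree(sub)
    if method == "mpt":
        top, _ = mpt_search(sub, cfg)
        return derive_rsmt(top, sub).tree
    raise ValueError(f"unknown rebuild method {method!r}")


def split_rebuild_reassemble(
    t: PhyloTree,
    inputs: PatternSet,
    method: str,
    model: EventModel,
    panel: ProbePanel,
    cfg: Optional[SearchConfig] = None,
) -> PhyloTree:
    """Remove duplication branches, re-solve each component as an RSMT,
    re-insert the removed branches between the same endpoint patterns."""
    branches = detect_duplication_branches(t, model, panel)
    work = t.copy()
    for b in branches:
        work.graph.remove_edge(b.parent, b.child)
    observed = set(inputs.patterns)
    components = [sorted(c) for c in nx.connected_components(work.graph)]
    components.sort()
    comp_of = {v: i for i, c in enumerate(components) for v in c}

    out = PhyloTree()
    # node id in `out` carrying a given pattern, per component
    locator: list[dict[CountPattern, int]] = []
    for comp in components:
        terminals: list[CountPattern] = []
        for v in comp:
            lab = t.label(v)
            incident = any(
                b.parent == v or b.child == v for b in branches
            )
            if (lab in observed or incident) and lab not in terminals:
                terminals.append(lab)
        terminals.sort()
        ids: dict[CountPattern, int] = {}
        if not terminals:
            locator.append(ids)
            continue
        rebuilt = _rebuild(terminals, inputs, method, cfg)
        remap = {}
        for v in sorted(rebuilt.nodes()):
            lab = rebuilt.label(v)
            kind = OBSERVED if lab in observed else STEINER
            nid = out.add_node(
                lab, kind=kind, multiplicity=inputs.multiplicity.get(lab, 1)
            )
            remap[v] = nid
            if lab not in ids:
                ids[lab] = nid
        for u, v in rebuilt.edges():
            out.add_edge(remap[u], remap[v])
        locator.append(ids)
    for b in branches:
        pu = locator[comp_of[b.parent]][t.label(b.parent)]
        cv = locator[comp_of[b.child]][t.label(b.child)]
        out.add_edge(pu, cv)
        out.graph.edges[pu, cv]["events"] = b.script
    out.validate_tree()
    return out


def _generalized_mst(
    inputs: PatternSet, model: EventModel, panel: ProbePanel
) -> PhyloTree:
    """Spanning tree of the observed patterns under the generalized metric
    (the seed of the DSMT pipeline); deterministic Kruskal."""
    pats = inputs.patterns
    t = PhyloTree()
    ids = {p: t.add_node(p, kind=OBSERVED, multiplicity=inputs.multiplicity.get(p, 1))
           for p in pats}
    edges = []
    for i in range(len(pats)):
        for j in range(i + 1, len(pats)):
            a, b = sorted((pats[i], pats[j]))
            edges.append((edge_cost(a, b, model, panel), a, b))
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


def dsmttree(
    inputs: PatternSet,
    model: EventModel,
    panel: Optional[ProbePanel] = None,
    method: str = "mst",
    cfg: Optional[SearchConfig] = None,
    seed_tree: Optional[PhyloTree] = None,
) -> PhyloTree:
    """The full DSMT heuristic.

    Seeds from the generalized-metric spanning tree (or a user-supplied
    tree), splits at duplication branches, rebuilds each component with the
    chosen RSMT heuristic, reassembles, and keeps the better (by
    generalized weight) of the reassembled tree and the plain RSMT
    heuristic tree — so duplication handling can only help.
    """
    if inputs.n == 0:
        raise ValueError("empty input")
    panel = panel or inputs.panel
    if inputs.n == 1:
        t = PhyloTree()
        t.add_node(inputs.patterns[0], kind=OBSERVED)
        t.root = 0
        return t
    seed = seed_tree if seed_tree is not None else _generalized_mst(inputs, model, panel)
    assembled = split_rebuild_reassemble(seed, inputs, method, model, panel, cfg)
    plain = _rebuild(list(inputs.patterns), inputs, method, cfg)
    wa = generalized_tree_weight(assembled, model, panel)
    wp = generalized_tree_weight(plain, model, panel)
    best = assembled if wa <= wp else plain
    best.root = _choose_root(best)
    return best
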