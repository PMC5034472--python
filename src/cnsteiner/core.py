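"""Domain types and rectilinear-metric primitives.

A *cell count pattern* is the vector of integer copy numbers of ``d`` FISH
gene probes measured in a single cell.  Trees over such patterns use the
rectilinear (L1) metric: the distance between two patterns is the number of
single-gene duplication and loss events separating them.  These primitives —
the metric, the three-pattern median, tree weight, trivial-edge contraction
and Steiner-node accounting — are shared by every tree-building module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

#: A cell count pattern: copy number per probe, in panel order.
CountPattern = tuple[int, ...]

OBSERVED = "observed"
STEINER = "steiner"
UNLABELED = "unlabeled"


class DimensionError(ValueError):
    """Patterns of unequal length were combined."""


class LabelingError(ValueError):
    """An operation requiring fully labeled nodes met an unlabeled one."""


def as_pattern(values: Iterable[int]) -> CountPattern:
    """Validate and freeze a sequence of copy numbers into a pattern."""
    pat = tuple(int(v) for v in values)
    for v in pat:
        if v < 0:
            raise ValueError(f"copy numbers must be non-negative, got {pat}")
    return pat


def _check_dims(*patterns: CountPattern) -> None:
    d = len(patterns[0])
    for p in patterns[1:]:
        if len(p) != d:
            raise DimensionError(
                f"pattern length mismatch: {len(p)} != {d} ({patterns})"
            )


def l1_distance(a: CountPattern, b: CountPattern) -> int:
    """Rectilinear distance |a1-b1| + ... + |ad-bd|.

    Equals the minimum number of single-gene duplication and loss events
    turning one pattern into the other.
    """
    _check_dims(a, b)
    return sum(abs(x - y) for x, y in zip(a, b))


def median3(a: CountPattern, b: CountPattern, c: CountPattern) -> CountPattern:
    """Coordinatewise median of three patterns.

    The star joining the median to a, b, c has total length
    ``sum_j (max_j - min_j)``, which is the optimal Steiner tree on three
    terminals under the rectilinear metric (the copy number of each probe is
    optimized independently, and the integer median minimizes the sum of
    absolute deviations).
    """
    _check_dims(a, b, c)
    return tuple(sorted(t)[1] for t in zip(a, b, c))


def is_steiner_required(a: CountPattern, b: CountPattern, c: CountPattern) -> bool:
    """True iff the optimal median of a, b, c differs from all three inputs."""
    m = median3(a, b, c)
    return m != a and m != b and m != c


@dataclass(frozen=True)
class ProbePanel:
    """Identity and (optional) chromosome assignment of the gene probes."""

    probe_names: tuple[str, ...]
    chromosome_of: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if len(set(self.probe_names)) != len(self.probe_names):
            raise ValueError("probe names must be unique")

    @property
    def d(self) -> int:
        return len(self.probe_names)

    def require_chromosomes(self) -> Mapping[str, str]:
        if self.chromosome_of is None:
            raise ValueError("probe->chromosome map required but not provided")
        missing = [p for p in self.probe_names if p not in self.chromosome_of]
        if missing:
            raise ValueError(f"chromosome map missing probes: {missing}")
        return self.chromosome_of

    @classmethod
    def generic(cls, d: int, chromosomes: Optional[Sequence[str]] = None) -> "ProbePanel":
        names = tuple(f"p{i+1}" for i in range(d))
        chrom = None
        if chromosomes is not None:
            if len(chromosomes) != d:
                raise ValueError("one chromosome label per probe required")
            chrom = dict(zip(names, chromosomes))
        return cls(names, chrom)


@dataclass
class PatternSet:
    """The distinct cell count patterns of one sample, with multiplicities.

    Multiplicities (cells observed per pattern) are carried for reporting
    only; tree construction operates on the distinct patterns, following the
    formal problem definitions.
    """

    panel: ProbePanel
    patterns: tuple[CountPattern, ...]
    multiplicity: dict[CountPattern, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pats = tuple(as_pattern(p) for p in self.patterns)
        if len(set(pats)) != len(pats):
            raise ValueError("patterns must be pairwise distinct")
        for p in pats:
            if len(p) != self.panel.d:
                raise DimensionError(
                    f"pattern {p} has {len(p)} probes, panel has {self.panel.d}"
                )
        object.__setattr__(self, "patterns", pats)
        if not self.multiplicity:
            self.multiplicity = {p: 1 for p in pats}
        for p, m in self.multiplicity.items():
            if m < 1:
                raise ValueError(f"multiplicity of {p} must be >= 1, got {m}")

    @property
    def n(self) -> int:
        return len(self.patterns)

    @property
    def d(self) -> int:
        return self.panel.d

    def __iter__(self) -> Iterator[CountPattern]:
        return iter(self.patterns)

    @classmethod
    def from_patterns(
        cls,
        patterns: Iterable[Sequence[int]],
        panel: Optional[ProbePanel] = None,
        multiplicity: Optional[Mapping[CountPattern, int]] = None,
    ) -> "PatternSet":
        pats = tuple(as_pattern(p) for p in patterns)
        if not pats:
            raise ValueError("at least one pattern required")
        if panel is None:
            panel = ProbePanel.generic(len(pats[0]))
        return cls(panel, pats, dict(multiplicity) if multiplicity else {})


class PhyloTree:
    """A connected acyclic graph whose nodes carry optional count patterns.

    Thin wrapper over :class:`networkx.Graph`; node attributes are
    ``label`` (a :data:`CountPattern` or None), ``kind`` (observed /
    steiner / unlabeled) and ``multiplicity``.  Edge lengths are derived
    from the active metric, never stored.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.root: Optional[int] = None
        self._next_id = 0

    # -- construction -------------------------------------------------
    def add_node(
        self,
        label: Optional[Sequence[int]] = None,
        kind: str = UNLABELED,
        multiplicity: int = 1,
        node_id: Optional[int] = None,
    ) -> int:
        if node_id is None:
            node_id = self._next_id
        if node_id in self.graph:
            raise ValueError(f"node id {node_id} already present")
        self._next_id = max(self._next_id, node_id + 1)
        lab = as_pattern(label) if label is not None else None
        if lab is None and kind != UNLABELED:
            raise LabelingError(f"{kind} node requires a label")
        self.graph.add_node(node_id, label=lab, kind=kind, multiplicity=multiplicity)
        return node_id

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError("self-loops not allowed")
        self.graph.add_edge(u, v)

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.graph = self.graph.copy()
        t.root = self.root
        t._next_id = self._next_id
        return t

    # -- accessors ----------------------------------------------------
    def label(self, v: int) -> Optional[CountPattern]:
        return self.graph.nodes[v]["label"]

    def kind(self, v: int) -> str:
        return self.graph.nodes[v]["kind"]

    def multiplicity(self, v: int) -> int:
        return self.graph.nodes[v].get("multiplicity", 1)

    def set_label(self, v: int, label: Sequence[int], kind: Optional[str] = None) -> None:
        self.graph.nodes[v]["label"] = as_pattern(label)
        if kind is not None:
            self.graph.nodes[v]["kind"] = kind

    def nodes(self) -> list[int]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[int, int]]:
        return list(self.graph.edges)

    def neighbors(self, v: int) -> list[int]:
        return list(self.graph.neighbors(v))

    def degree(self, v: int) -> int:
        return self.graph.degree[v]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edge_length(self, u: int, v: int, metric=l1_distance) -> int:
        lu, lv = self.label(u), self.label(v)
        if lu is None or lv is None:
            raise LabelingError(f"edge ({u},{v}) has an unlabeled endpoint")
        return metric(lu, lv)

    def require_labeled(self) -> None:
        for v in self.graph.nodes:
            if self.label(v) is None:
                raise LabelingError(f"node {v} is unlabeled")

    def validate_tree(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise ValueError("empty tree")
        if not nx.is_tree(self.graph):
            raise ValueError("graph is not a tree (connected and acyclic)")

    @classmethod
    def from_labeled_edges(
        cls,
        node_labels: Mapping[int, Sequence[int]],
        edges: Iterable[tuple[int, int]],
        observed: Optional[Iterable[int]] = None,
    ) -> "PhyloTree":
        """Convenience builder used by tests and IO."""
        t = cls()
        obs = set(observed) if observed is not None else set(node_labels)
        for nid, lab in node_labels.items():
            t.add_node(lab, kind=OBSERVED if nid in obs else STEINER, node_id=nid)
        for u, v in edges:
            t.add_edge(u, v)
        return t


def tree_weight(t: PhyloTree, metric=l1_distance) -> int:
    """Sum of edge lengths under ``metric``; requires fully labeled nodes."""
    t.require_labeled()
    return sum(t.edge_length(u, v, metric) for u, v in t.graph.edges)


def contract_trivial_edges(t: PhyloTree, metric=l1_distance) -> PhyloTree:
    """Merge every zero-length ("trivial") edge; weight is preserved.

    A trivial edge joins two identically labeled nodes; the merged node is
    observed if either endpoint was.  Among observed endpoints the smallest
    node id survives, giving deterministic output.
    """
    t.require_labeled()
    out = t.copy()
    g = out.graph
    while True:
        trivial = None
        for u, v in g.edges:
            if metric(g.nodes[u]["label"], g.nodes[v]["label"]) == 0:
                trivial = (u, v)
                break
        if trivial is None:
            break
        u, v = trivial
        keep, drop = _merge_priority(g, u, v)
        if g.nodes[drop]["kind"] == OBSERVED and g.nodes[keep]["kind"] != OBSERVED:
            g.nodes[keep]["kind"] = OBSERVED  # observed identity survives a merge
            g.nodes[keep]["multiplicity"] = g.nodes[drop].get("multiplicity", 1)
        for w in list(g.neighbors(drop)):
            if w != keep:
                g.add_edge(keep, w)
        g.remove_node(drop)
        if out.root == drop:
            out.root = keep
    return out


def _merge_priority(g: nx.Graph, u: int, v: int) -> tuple[int, int]:
    """Which endpoint of a trivial edge survives: observed first, then min id."""
    ku = g.nodes[u]["kind"] == OBSERVED
    kv = g.nodes[v]["kind"] == OBSERVED
    if ku and not kv:
        return u, v
    if kv and not ku:
        return v, u
    return (u, v) if u < v else (v, u)


def count_steiner_nodes(t: PhyloTree, inputs: PatternSet) -> int:
    """Nodes labeled by a pattern not among the observed input patterns."""
    t.require_labeled()
    observed = set(inputs.patterns)
    return sum(1 for v in t.graph.nodes if t.label(v) not in observed)
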