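"""Readers and writers: FISH count tables, trees, run summaries.

Input samples are TSV files with a header row of probe names, one row of
non-negative integer copy numbers per cell pattern, and an optional
trailing ``count`` column of per-pattern cell multiplicities.  Trees go out
as Newick (node labels = copy numbers joined by ``.``, branch lengths =
metric edge lengths), a nodes TSV, an edges TSV and a JSON run summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import pandas as pd

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

log = logging.getLogger("cnsteiner")

MULTIPLICITY_COLUMN = "count"


class ParseError(ValueError):
    pass


def read_panel_tsv(path: str | Path) -> dict[str, str]:
    """Probe-to-chromosome map: TSV with columns ``probe`` and ``chromosome``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "probe" not in cols or "chromosome" not in cols:
        raise ParseError(
            f"{path}: chromosome map needs 'probe' and 'chromosome' columns, "
            f"got {list(df.columns)}"
        )
    df.columns = cols
    return dict(zip(df["probe"], df["chromosome"]))


def read_fish_tsv(
    path: str | Path, panel_path: Optional[str | Path] = None
) -> PatternSet:
    """Read a FISH sample; duplicate rows are merged with summed counts."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    cols = list(df.columns)
    has_mult = cols and cols[-1].lower() == MULTIPLICITY_COLUMN
    probe_names = cols[:-1] if has_mult else cols
    if not probe_names:
        raise ParseError(f"{path}: no probe columns")
    for ri, row in df.iterrows():
        for ci, col in enumerate(cols):
            v = row[col]
            if pd.isna(v) or float(v) != int(v) or int(v) < 0:
                raise ParseError(
                    f"{path}: row {ri + 1} column {ci + 1} ({col}): "
                    f"expected a non-negative integer, got {v!r}"
                )
    chrom = read_panel_tsv(panel_path) if panel_path else None
    panel = ProbePanel(tuple(probe_names), chrom)
    mult: dict[CountPattern, int] = {}
    order: list[CountPattern] = []
    for _, row in df.iterrows():
        pat = tuple(int(row[c]) for c in probe_names)
        m = int(row[cols[-1]]) if has_mult else 1
        if pat in mult:
            log.warning("duplicate pattern row %s merged (multiplicities summed)", pat)
            mult[pat] += m
        else:
            mult[pat] = m
            order.append(pat)
    return PatternSet(panel, tuple(order), mult)


def write_fish_tsv(pset: PatternSet, path: str | Path) -> None:
    rows = [
        list(p) + [pset.multiplicity.get(p, 1)] for p in pset.patterns
    ]
    df = pd.DataFrame(rows, columns=list(pset.panel.probe_names) + [MULTIPLICITY_COLUMN])
    df.to_csv(path, sep="\t", index=False)


@dataclass
class RunSummary:
    """What one tree-building run produced; serialized alongside the tree."""

    method: str
    tree_weight: int
    steiner_nodes: int
    n_nodes: int
    n_edges: int
    parameters: dict = field(default_factory=dict)
    seed: Optional[int] = None
    wall_time_s: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_tree(
        cls,
        tree: PhyloTree,
        inputs: PatternSet,
        method: str,
        parameters: Optional[dict] = None,
        seed: Optional[int] = None,
        wall_time_s: Optional[float] = None,
    ) -> "RunSummary":
        from .core import count_steiner_nodes

        return cls(
            method=method,
            tree_weight=tree_weight(tree),
            steiner_nodes=count_steiner_nodes(tree, inputs),
            n_nodes=tree.n_nodes,
            n_edges=tree.graph.number_of_edges(),
            parameters=parameters or {},
            seed=seed,
            wall_time_s=wall_time_s,
        )


def pattern_label(p: CountPattern) -> str:
    return ".".join(str(x) for x in p)


def parse_pattern_label(s: str) -> CountPattern:
    return tuple(int(x) for x in s.split("."))


def to_newick(tree: PhyloTree) -> str:
    """Newick with internal-node labels and integer branch lengths."""
    tree.require_labeled()
    root = tree.root if tree.root is not None else min(tree.nodes())
    if tree.n_nodes == 1:
        return f"({pattern_label(tree.label(root))});"

    def render(v: int, parent: Optional[int]) -> str:
        children = [w for w in tree.neighbors(v) if w != parent]
        lab = pattern_label(tree.label(v))
        if parent is None:
            inner = ",".join(render(c, v) for c in children)
            return f"({inner}){lab}"
        length = tree.edge_length(parent, v)
        if not children:
            return f"{lab}:{length}"
        inner = ",".join(render(c, v) for c in children)
        return f"({inner}){lab}:{length}"

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, tree.n_nodes * 4 + 100))
    try:
        return render(root, None) + ";"
    finally:
        sys.setrecursionlimit(old)


def write_tree(
    tree: PhyloTree,
    prefix: str | Path,
    inputs: PatternSet,
    method: str = "unknown",
    parameters: Optional[dict] = None,
    seed: Optional[int] = None,
    wall_time_s: Optional[float] = None,
) -> RunSummary:
    """Write Newick, nodes TSV, edges TSV and summary JSON under ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tree.require_labeled()
    Path(f"{prefix}.nwk").write_text(to_newick(tree) + "\n")
    node_rows = [
        {
            "id": v,
            "pattern": pattern_label(tree.label(v)),
            "kind": tree.kind(v),
            "multiplicity": tree.multiplicity(v),
        }
        for v in sorted(tree.nodes())
    ]
    pd.DataFrame(node_rows).to_csv(f"{prefix}.nodes.tsv", sep="\t", index=False)
    edge_rows = [
        {
            "parent": u,
            "child": v,
            "length": tree.edge_length(u, v),
            "events": ";".join(tree.graph.edges[u, v].get("events", ())),
        }
        for u, v in sorted(tree.edges())
    ]
    pd.DataFrame(edge_rows).to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
    summary = RunSummary.from_tree(
        tree, inputs, method, parameters, seed, wall_time_s
    )
    Path(f"{prefix}.summary.json").write_text(summary.to_json() + "\n")
    return summary


def read_tree(newick_path: str | Path, nodes_path: str | Path) -> PhyloTree:
    """Rebuild a tree from its Newick and nodes-TSV files."""
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"pattern": str})
    kind_of = dict(zip(nodes["pattern"], nodes["kind"]))
    mult_of = dict(zip(nodes["pattern"], nodes["multiplicity"]))
    dt = dendropy.Tree.get(
        path=str(newick_path), schema="newick", suppress_internal_node_taxa=True
    )
    out = PhyloTree()
    ids: dict[dendropy.Node, int] = {}
    seed = dt.seed_node
    skip = None
    seed_label = seed.taxon.label if seed.taxon else seed.label
    if seed_label is None and len(seed.child_nodes()) == 1:
        skip = seed  # the "(x);" form wraps a single-node tree
        seed = seed.child_nodes()[0]
    for node in dt.preorder_node_iter():
        if node is skip:
            continue
        label = node.taxon.label if node.taxon else node.label
        if label is None:
            raise ParseError(f"{newick_path}: unlabeled node in Newick")
        pat = parse_pattern_label(label)
        nid = out.add_node(
            pat,
            kind=kind_of.get(label, STEINER),
            multiplicity=int(mult_of.get(label, 1)),
        )
        ids[node] = nid
        if node.parent_node is not None and node.parent_node in ids:
            out.add_edge(ids[node.parent_node], nid)
    out.root = ids[seed]
    return out
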