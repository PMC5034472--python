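"""Synthetic tumor-progression samples with ground truth.

The generator emulates the simulation regime the tree heuristics are
benchmarked under: a clonal expansion starting from a healthy diploid cell
(copy number 2 for every probe), growing until the sample holds a target
number of distinct cell count patterns (by default 120-150, on panels of
4, 6 or 8 probes, growth factors 0.4 or 0.5).

Growth semantics: per round, every existing cell buds a daughter with
probability g (the *growth factor*); each new edge applies exactly one
mutation event drawn from the configured event distribution — single-gene
gain or loss, and optionally chromosomal or whole-genome doubling.  A probe
whose count has hit zero never re-amplifies when ``zero_absorbing`` is set
(homozygous loss is irreversible).  Each sample draws its own target
pattern count uniformly from the configured range and stops the moment the
target is reached, so counts vary across samples exactly over that range.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    OBSERVED,
    CountPattern,
    PatternSet,
    PhyloTree,
    ProbePanel,
    tree_weight,
)
from .dsmt import EventModel, dsmttree, generalized_tree_weight
from .labeling import derive_rsmt
from .mst_rsmt import build_mst, msttree
from .oracle import OracleLimitError, OracleLimits, exact_rsmt
from .parsimony import SearchConfig, mpt_search


@dataclass
class SimulationConfig:
    """Study conditions of one simulated sample family."""

    d: int = 4
    growth: float = 0.4
    target_range: tuple[int, int] = (120, 150)
    p_gain: float = 0.5
    p_loss: float = 0.5
    p_chrom: float = 0.0
    p_wgd: float = 0.0
    zero_absorbing: bool = True
    seed: int = 0
    chromosomes: Optional[Sequence[str]] = None
    max_nodes: int = 10**6

    def __post_init__(self) -> None:
        lo, hi = self.target_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid target range [{lo}, {hi}]")
        if not (0 < self.growth <= 1):
            raise ValueError("growth factor must be in (0, 1]")
        probs = (self.p_gain, self.p_loss, self.p_chrom, self.p_wgd)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"event probabilities must be >= 0 and sum to 1: {probs}")
        if self.p_chrom > 0 and self.chromosomes is None:
            # default panel layout: two probes per chromosome
            self.chromosomes = tuple(
                f"chr{i // 2 + 1}" for i in range(self.d)
            )
        if self.chromosomes is not None and len(self.chromosomes) != self.d:
            raise ValueError("one chromosome label per probe required")

    def panel(self) -> ProbePanel:
        return ProbePanel.generic(self.d, self.chromosomes)


_EVENTS = ("gain", "loss", "chrom", "wgd")


def _apply_event(
    pattern: CountPattern,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[CountPattern, Optional[str]]:
    """Draw one event and apply it; None event if nothing is applicable."""
    probs = np.array([cfg.p_gain, cfg.p_loss, cfg.p_chrom, cfg.p_wgd])
    for _ in range(20):
        kind = _EVENTS[rng.choice(4, p=probs)]
        if kind == "gain":
            eligible = [
                j for j, c in enumerate(pattern)
                if c > 0 or not cfg.zero_absorbing
            ]
            if not eligible:
                continue
            j = eligible[rng.integers(len(eligible))]
            out = list(pattern)
            out[j] += 1
            return tuple(out), f"gain:{j}"
        if kind == "loss":
            eligible = [j for j, c in enumerate(pattern) if c > 0]
            if not eligible:
                continue
            j = eligible[rng.integers(len(eligible))]
            out = list(pattern)
            out[j] -= 1
            return tuple(out), f"loss:{j}"
        if kind == "chrom":
            chroms = sorted(set(cfg.chromosomes))
            c = chroms[rng.integers(len(chroms))]
            out = tuple(
                v * 2 if cfg.chromosomes[j] == c else v
                for j, v in enumerate(pattern)
            )
            if out != pattern:
                return out, f"dup:{c}"
            continue
        if kind == "wgd":
            out = tuple(v * 2 for v in pattern)
            if out != pattern:
                return out, "WGD"
            continue
    return pattern, None  # fully degenerate state (e.g. all probes lost)


def grow_tree(cfg: SimulationConfig) -> tuple[PhyloTree, PatternSet]:
    """Simulate one sample; returns the true lineage tree and its patterns.

    The returned tree's graph attributes carry ``n_events`` (total mutation
    events on the lineage) and ``target`` (the drawn distinct-pattern
    target).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.target_range
    target = int(rng.integers(lo, hi + 1))
    root_pattern = (2,) * cfg.d

    tree = PhyloTree()
    root = tree.add_node(root_pattern, kind=OBSERVED)
    tree.root = root
    node_pattern = {root: root_pattern}
    distinct = {root_pattern}
    n_events = 0

    while len(distinct) < target:
        parents = list(node_pattern)
        order = rng.permutation(len(parents))
        budded = False
        for i in order:
            if len(node_pattern) >= cfg.max_nodes:
                raise RuntimeError("simulation exceeded the node budget")
            if rng.random() >= cfg.growth:
                continue
            budded = True
            p = parents[i]
            child_pat, event = _apply_event(node_pattern[p], cfg, rng)
            child = tree.add_node(child_pat, kind=OBSERVED)
            tree.add_edge(p, child)
            tree.graph.edges[p, child]["event"] = event
            node_pattern[child] = child_pat
            if event is not None:
                n_events += 1
            distinct.add(child_pat)
            if len(distinct) >= target:
                break
        if not budded and cfg.growth >= 1:
            break

    multiplicity: dict[CountPattern, int] = {}
    for pat in node_pattern.values():
        multiplicity[pat] = multiplicity.get(pat, 0) + 1
    patterns = tuple(sorted(distinct))
    pset = PatternSet(cfg.panel(), patterns, multiplicity)
    tree.graph.graph["n_events"] = n_events
    tree.graph.graph["target"] = target
    return tree, pset


def _method_weight(
    name: str,
    sample: PatternSet,
    cfg: SimulationConfig,
    search: Optional[SearchConfig],
    oracle_limits: OracleLimits,
) -> Optional[int]:
    model = EventModel(
        chromosomal_dup=cfg.p_chrom > 0, whole_genome_dup=cfg.p_wgd > 0
    )
    if name == "mst":
        return tree_weight(build_mst(sample))
    if name == "msttree":
        return tree_weight(msttree(sample))
    if name == "mpttree":
        top, _ = mpt_search(sample, search)
        return derive_rsmt(top, sample).weight
    if name == "dsmttree":
        t = dsmttree(sample, model, sample.panel)
        return generalized_tree_weight(t, model, sample.panel)
    if name == "exact":
        try:
            w, _ = exact_rsmt(sample, oracle_limits)
            return w
        except OracleLimitError as e:
            logging.getLogger("cnsteiner").warning("exact solver skipped: %s", e)
            return None
    raise ValueError(f"unknown method {name!r}")


def benchmark(
    methods: Sequence[str],
    cfgs: Sequence[SimulationConfig],
    replicates: int,
    search: Optional[SearchConfig] = None,
    oracle_limits: OracleLimits = OracleLimits(),
) -> pd.DataFrame:
    """Tree weight and best-score fraction per method across replicates.

    For each replicate the per-replicate minimum weight defines "best";
    every method attaining it (ties included) is counted.  The exact oracle
    is skipped (not failed) on instances beyond its limits.
    """
    rows = []
    for ci, cfg in enumerate(cfgs):
        for r in range(replicates):
            rep_cfg = SimulationConfig(
                **{
                    **cfg.__dict__,
                    "seed": cfg.seed + r,
                    "chromosomes": cfg.chromosomes,
                }
            )
            _, sample = grow_tree(rep_cfg)
            for m in methods:
                t0 = time.perf_counter()
                w = _method_weight(m, sample, rep_cfg, search, oracle_limits)
                dt = time.perf_counter() - t0
                rows.append(
                    {
                        "config": ci,
                        "replicate": r,
                        "method": m,
                        "weight": w,
                        "runtime_s": dt,
                        "n_patterns": sample.n,
                    }
                )
    raw = pd.DataFrame(rows)
    best = raw.dropna(subset=["weight"]).groupby(["config", "replicate"])["weight"].transform("min")
    raw["is_best"] = raw["weight"] == best
    summary = (
        raw.groupby(["config", "method"], sort=False)
        .agg(
            best_fraction=("is_best", "mean"),
            mean_weight=("weight", "mean"),
            mean_runtime_s=("runtime_s", "mean"),
            n=("replicate", "count"),
        )
        .reset_index()
    )
    summary.attrs["raw"] = raw
    return summary
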