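# cnsteiner

Steiner-tree heuristics for inferring tumor progression from FISH gene
copy-number patterns.

Fluorescence in situ hybridization (FISH) counts the copies of a handful of
gene probes in hundreds of single cells from one tumor.  Each cell yields a
*count pattern* `(x_1, …, x_d) ∈ N^d`; the sample reduces to its distinct
patterns with multiplicities.  Under the rectilinear (L1) metric
`Σ_j |x_j − y_j|` — the number of single-gene duplication and loss events
between two patterns — a minimum-weight tree spanning the observed patterns,
with unobserved *Steiner* patterns allowed as internal states, is a
most-parsimonious model of how the tumor progressed from a single (diploid)
ancestor.  That object is the rectilinear Steiner minimum tree **RSMT(n, d)**;
it is NP-complete, and this package implements two heuristics for it plus a
duplication-aware generalization:

- **`msttree`** — start from the L1 minimum spanning tree and iteratively
  insert three-pattern medians (each `RSMT(3, d)` is solved exactly by the
  coordinatewise median), ordered by an *inference score* that accounts for
  how insertions interact, until a local optimum.
- **`mpttree`** — search for a maximum-parsimony topology (`MPT(n, d)`,
  Wagner parsimony scored exactly by a per-probe interval DP), then label
  its internal nodes without increasing the weight, contract zero-length
  branches, and keep the candidate with fewest Steiner nodes.
- **`dsmttree`** — extend either heuristic with large-scale duplication
  events (chromosomal and whole-genome doublings at unit cost): locate
  branches better explained by a doubling script than by L1, split there,
  rebuild each part as an RSMT, and reassemble (**DSMT(n, d)**).
- **`exact_rsmt`** — an exact small-instance solver (Hanan grid +
  Dreyfus–Wagner DP) used as ground truth.
- **`grow_tree`** — a seeded simulator of tumor clonal expansion producing
  samples in the benchmark regime (4/6/8 probes, growth factors 0.4/0.5,
  120–150 distinct patterns) with ground-truth lineages.

See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

A toy cervical-panel sample (`toy.tsv`, tab-separated, one row per distinct
pattern; an optional trailing `count` column carries multiplicities):

```text
LAMP3	PROX1	PRKAA1	CCND1
2	2	2	2
2	1	4	2
3	1	4	2
4	2	2	4
4	2	6	4
2	2	2	4
```

```sh
cnsteiner rsmt --method mpt --input toy.tsv --out-prefix out --seed 7 --restarts 4
```

prints

```text
weight=12 steiner=0
```

meaning the best progression tree found explains the six observed patterns
with 12 single-gene duplication/loss events and needs no unobserved
intermediate state.  `out.nwk` holds the tree (node labels are copy numbers
joined by `.`, branch lengths are L1 distances):

```text
((3.1.4.2:1)2.1.4.2:3,((4.2.6.4:4)4.2.2.4:2)2.2.2.4:2)2.2.2.2;
```

rooted at the healthy diploid cell `2.2.2.2`, which doubles CCND1 toward
`2.2.2.4` on one lineage and loses a PROX1 copy while amplifying PRKAA1 on
the other.  `out.nodes.tsv`, `out.edges.tsv` and
`out.summary.json` carry the same tree in tabular and summary form, and

```sh
cnsteiner score out.nwk out.nodes.tsv toy.tsv
```

re-reads the files and reproduces `weight=12 steiner=0` exactly.

With a probe-to-chromosome map, whole-genome and chromosomal doublings
become single events.  For a sample containing `4.4.4.4` (a doubled
genome), `cnsteiner dsmt --input wgd.tsv --chromosomes map.tsv
--out-prefix d` reports `generalized_weight=3` where the plain L1 heuristic
(`cnsteiner rsmt --method mst …`) needs `weight=9` — the doubling is one
event, not eight single-gene gains.

Other subcommands: `exact` (refuses instances beyond its limits rather than
approximating), `simulate`, and `benchmark` (best-score fractions across
simulated replicates).

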