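# Methods notes

## Graph model and centrality conventions

The interaction network is a simple undirected graph over gene symbols.
Confidence scores are used once, as an edge-inclusion filter (default
0.7, the conventional "high confidence" STRING threshold); all path
computations are hop-count based. Scores above 1 trigger a whole-file
reinterpretation as the 0–999 integer scale — mixed scales in one file
are not meaningful, so detection is global, not per-row.

Betweenness is normalized by the undirected pair count (n−1)(n−2)/2,
with n the full node count of the loaded graph, disconnected nodes
included; node pairs without a connecting path contribute zero. This is
the convention of the standard network-analyzer tooling, and it keeps
BC in [0,1] regardless of connectivity. Graphs with fewer than three
nodes have no interior pairs; BC is defined as 0 there (with a warning)
rather than raising.

The scale-free summary is an ordinary least-squares line through
log(count) vs log(degree) on the raw degree histogram — no log-binning,
no cumulative transform — because the quantity of interest is the
single r² such tools print, not a rigorous tail exponent. Degree-0
nodes and empty histogram bins are skipped; fewer than three distinct
positive degrees is an error, since a two-point fit always has r² = 1.

## Hub selection and backbone

The dual cutoff is the union of two strict criteria (degree > 50 OR
BC > 0.05). Union rather than intersection is forced by the worked
example: one of the five published hubs has degree 49 and qualifies on
betweenness alone. Canonical ranking is BC desc, degree desc, symbol
asc; the symbol tie-break is this package's convention to make ranking
total and reproducible.

The backbone is the full node-induced subgraph on hubs ∪ neighbors;
edges between two non-hub neighbors are retained. Since the source
analysis never states whether such edges were kept, the package also
exposes `hub_edge_fraction` (hub-incident edges / backbone edges) so the
"fraction of connections due to hubs" is computable under either
reading. The fraction is computed over backbone edges, not main-network
edges.

## Leave-k-out validation

The deletion pool is the top-22 ranked nodes. Level 1 deletes each pool
member once (22 networks). Levels 2–4 construct, per hub and per
repeat (5 repeats), the hub plus k−1 companions sampled without
replacement from the remaining pool — 25 networks per level, 97 total.
Sampling uses a seeded generator, independent across (hub, repeat)
slots; duplicate sets across repeats are permitted. Test-network
re-ranking reuses the canonical ranking.

Per-level accuracy is Σ frequencies / (5 × networks); overall accuracy
is the unweighted mean of the level accuracies. The mean-of-levels
reading is the one consistent with the published worked example
(mean 0.77636 → 0.776; the pooled ratio 374/485 ≈ 0.771 is not what was
printed). Reported tables round to 3 decimals; computations keep full
precision.

A bookkeeping caveat in the published frequency table: at levels 3–4
one hub is recorded as retained in 23 of 25 networks, although the
stated design deletes each hub in 5 of the 25, capping retention at 20.
The package implements the design as stated; the accuracy arithmetic on
the printed rows is unaffected.

## Regulatory network

Binding-site counts for duplicate (TF, target) records are summed
before the evidence filter (sites are counted per promoter, so
additivity is the natural reading); pairs need ≥ 2 sites (strictly more
than one) to form an edge. TF family is carried as an annotation only —
ranking operates on individual TFs, since the core regulators of
interest are individual factors. Connectivity ties break
lexicographically. A symbol appearing as both TF and target is
disambiguated by prefixing the TF node (with a warning) to keep the
graph bipartite.

## Comparative-Ct analysis

Technical replicates collapse to their mean when the replicate SD is
≤ 0.5 cycles (a common duplicate-agreement rule); noisier wells are
excluded. ΔCt normalizes to the GUSB endogenous control; a sample whose
reference well fails QC cannot be normalized and is dropped (an error
is raised only when a sample never had the reference gene measured).
The calibrator is a designated sample ID when given, otherwise the
pooled mean control ΔCt per gene — under the fallback the *geometric*
mean control fold change is 1 by construction. Amplification efficiency
is fixed at 2 (the comparative-Ct assumption), so fold change is
2^−ΔΔCt and one fewer cycle doubles expression.

Persistent-outlier exclusion removes samples with |ΔCt − group mean| >
4 group-SD. The threshold is deliberately conservative: the rule exists
to remove gross technical failures (a failed well is several cycles —
many SDs — off), and a tighter 3-SD cut trims ~0.3% of legitimate
Gaussian samples per group, which measurably inflates the downstream
t-test's type-I error above its nominal 5% (≈5.3–5.5% in 4000-run null
calibrations). At 4 SD the exclusion is essentially inactive on clean
data and the test keeps nominal size.

Group comparison reports means ± SEM on the fold-change scale, matching
how relative expression is conventionally displayed, but computes the
equal-variance t statistic and p on log2 fold change (equivalently
−ΔΔCt): threshold cycles, not fold changes, are the normally
distributed measurement, and a t-test on raw 2^−ΔΔCt values is
anticonservative (≈6.7% type-I in null calibration). Pearson
correlations require ≥ 3 complete sample pairs; constant columns yield
missing values rather than errors.

## Synthetic generators

The generators encode the study conditions and exist so every stage has
an input with the right statistical structure.

- **PPI network** (`simulate_ppi`): preferential attachment to 145
  nodes (8 edges per arriving node), then the 5 highest-degree nodes
  are designated hubs and receive additional randomly-wired edges until
  each exceeds degree 55 and the total reaches 1234 edges (±2%
  feasibility band). Preferential attachment is used because only a
  scale-free architecture with dominant hubs needs emulating, not a
  specific evidence-channel mixture. Confidences are uniform on
  [0.7, 1.0], i.e. already above the filter. Planted hubs adopt the
  canonical hub-gene symbols. What this does *not* emulate: STRING's
  per-channel evidence structure, the true community structure of
  inflammatory pathways, or the published network's exact degree/BC
  values — so tests recover *planted* structure, and quantities such as
  the backbone size or the hub-incident edge share differ from the
  published ones by construction (the synthetic hubs' neighborhoods
  cover nearly the whole 145-node graph).
- **TF table** (`simulate_tf_table`): 3 core TFs bound to all 5 targets
  with ≥ 2 sites; 181 further TFs with 1–2 targets each, allocated by a
  capacity-greedy assignment so the per-target counts are exactly
  (69, 75, 74, 70, 37) and the union exactly 184. `decoy_fraction`
  (default 0.2) of the emitted rows are decoy TFs with a single binding
  site, which the evidence filter removes — a fraction of 1.0 emits
  decoys only, giving an empty filtered network.
- **Ct table** (`simulate_ct`): 64 cases / 64 controls, duplicate
  wells. Per-gene control mean ΔCt is −log2 of the published control
  mean expression, and cases are shifted by −log2(fold change), with
  fold changes taken as published case/control mean ratios (PTGS2
  6.12/1.63 ≈ 3.75, etc.). Biological noise is Normal(0, 0.6) on ΔCt;
  technical noise Normal(0, 0.15) per well; the reference gene sits at
  Ct ≈ 25. The 0.6/0.15 SDs are typical whole-blood qPCR magnitudes
  chosen once as defaults; biological variation is modeled symmetric on
  the ΔCt (log) scale, so simulated fold changes are lognormal.
- **Gene lists** (`simulate_gene_lists`): 78 text-mining genes with
  Z > 1 plus 15 sub-threshold decoys, 68 curated genes, 22 shared
  symbols → a filtered merge of 124.

All generators are deterministic under a fixed seed.

## Numerical and reporting choices

- Strictness: every published threshold (Z > 1, degree > 50, BC > 0.05,
  "more than one" binding site) is a strict inequality; edge-confidence
  inclusion is ≥.
- Accuracies and table entries are rounded to 3 decimals for reporting
  only.
- The pipeline summary is validated by a pydantic model whose JSON
  Schema ships next to the summary.
- Problem sizes in the test suite: betweenness is cross-checked against
  a brute-force all-shortest-paths oracle on random connected graphs of
  ≤ 8 nodes; hub recovery over 50 seeded networks; null calibration of
  the group comparison over 1000 simulated cohorts at n = 64/64.

## Limitations

- The hub cutoffs (50 / 0.05) are absolute, tuned to a ~145-node
  network; they do not transfer to networks of very different size or
  density without adjustment.
- The degree-histogram r² is a descriptive statistic, not a test of
  power-law behavior; proper tail fitting would use maximum likelihood
  with a KS-based cutoff.
- Equal-variance t-tests and nominal p-values follow the source
  analysis; there is no multiple-testing correction and no covariate
  adjustment.
- Symbol handling is canonicalization only (upper-case, trimmed); no
  alias/ortholog resolution is attempted.
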