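# tempat — function-aware discovery of temporal expression patterns

`tempat` analyzes treated-vs-control expression time courses (bulk
microarray or sequencing, one profile per gene) and answers three questions
at once: *which genes respond*, *what characteristic temporal shapes the
responses follow*, and *which functional gene groups each shape belongs
to*. It integrates selection, clustering and annotation in a single
framework instead of running them as independent post-hoc steps, which lets
each step inform the others — most visibly in the recovery rule, where
cluster structure rescues genes the multiplicity-corrected selection alone
would miss.

## The model

Each gene's differential (treated − control) log2 profile is
`X_i = <x_i(1), …, x_i(m)>` on `m` shared timepoints. A *cluster* is a set
of genes following one characteristic temporal pattern
`P = <p(1), …, p(m)>` up to gene-specific affine transforms:

    x_i(t) = k_i · p(t) + q_i + ε_i(t),      ε_i(t) ~ N(0, σ_i(t)²)

with signed scale `k_i` (anticorrelated members are allowed) and offset
`q_i`. The pipeline has four stages:

1. **Gene ranking.** Each gene gets an area statistic
   `A_i = |∫ x_i(t) dt| / (t_m − t_1)` — the magnitude of its average
   displacement from the no-effect baseline. A Monte-Carlo null (flat
   profiles plus measurement noise, with σ estimated from experimental
   replicates per intensity bin) gives an empirical p-value;
   Benjamini–Hochberg adjustment gives FDR p-values.
2. **Functional annotation.** Gene Ontology `is_a` DAG plus optional flat
   gene sets (GMT); annotations are propagated to ancestors under the
   true-path rule.
3. **Pattern search.** Within each functional node, iterative weighted
   least squares alternates between fitting `(k_i, q_i)` per gene and
   re-estimating `p(t)` from the current members, keeping genes whose fit
   passes a χ² goodness-of-fit test and beats a flat profile in a
   family-wise-corrected F test. Nodes are visited leaves-first; genes
   clustered at a node are removed from all its ancestors (never from
   siblings), so each cluster is reported at its most specific term.
   A cluster counts only if it holds ≥ 1 FDR-significant gene.
4. **Selection with recovery.** Final selection = FDR-significant genes
   plus genes with raw p < α that share a cluster (same pattern, same
   term) with an FDR-significant gene.

A built-in simulator reproduces the benchmark conditions used throughout:
1000 genes × 13 timepoints, 6 clusters of 20 DE genes from distinct
template shapes, noise sd 0.2, 880 flat null profiles; evaluation matches
inferred to true clusters by maximal intersection.

## Worked example

Run the synthetic benchmark end to end (simulate → select → discover →
recover → evaluate) and inspect the manifest:

```bash
tempat run --out demo --seed 42
```

```text
n_clusters: 11  n_pattern_groups: 11  n_selected: 112
precision: {1: 0.944, 2: 1.0, 3: 0.95, 4: 1.0, 5: 1.0, 6: 1.0}
recall:    {1: 0.85,  2: 0.95, 3: 0.95, 4: 0.7, 5: 0.65, 6: 0.75}
fn_rate: 0.1167  fn_threshold_only: 0.15  realized_fdr: 0.0536
```

Of 120 truly differentially expressed genes, the FDR threshold alone
missed 18 (15%); adding cluster-based recovery brought the misses down to
14 (11.7%) while the realized FDR stayed near the nominal 5%. Each of the
six simulated clusters was recovered with high purity (precision ≥ 0.94).
The run directory holds every artifact as TSV/JSON: the matrix, the
selection table (`area`, `p_raw`, `p_fdr`, `status`), per-cluster member
fits `(k, q, gof_p, flat_p)`, canonical patterns, the final selection with
provenance (`fdr_significant` / `recovered`), and the evaluation report.

The repeated-simulation study behind the headline numbers:

```bash
tempat validate --n-datasets 20 --seed 1
```

prints per-cluster mean/sd precision and recall, the FN rate with and
without recovery, the paired Wilcoxon p-value for the FN reduction, and
the realized FDR.

Real-format inputs work the same way: `tempat select --matrix X.tsv
--replicates R.tsv …` followed by `tempat discover --obo go.obo
--annotations genes.gaf …`; see `tempat --help`.

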