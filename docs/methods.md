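# Methods

This note documents the statistical model, the algorithmic and numerical
choices, and the scope of what the synthetic benchmark does and does not
demonstrate.

## Model and assumptions

A cluster is a set of genes whose differential profiles are affine
transforms of one temporal pattern:

    x_i(t) = k_i p(t) + q_i + ε_i(t),   ε_i(t) ~ N(0, σ_i(t)²), independent.

Assumptions: measurement noise is Gaussian, independent across timepoints
and genes, with a variance that may depend on expression intensity but is
estimated from replicates rather than fitted per gene; gene–pattern
relations are linear and instantaneous (no lags, no saturation); a gene may
follow different patterns in different functional contexts (sibling terms),
but within one cluster all members share a single `P`.

`P` is identifiable only up to an affine transform — replacing
`(P, k_i, q_i)` by `(aP + b, k_i/a, q_i − b·k_i/a)` changes nothing — so
discovered patterns are reported canonically: zero mean, unit Euclidean
norm, sign positively correlated with the seed gene's profile. Refitting a
canonical pattern reproduces it (asserted in tests).

## Gene ranking

The area statistic is the magnitude of the time-normalized net area,
`A = |∫ x(t) dt| / (t_m − t_1)`, integrated over the piecewise-linear
interpolant. It measures sustained displacement from baseline; a response
that rises and falls symmetrically around zero has small net area and a
large p-value. That blind spot is intentional division of labor: such
shape-only responders are precisely what the pattern search detects and the
recovery step rescues, which is how the pipeline lowers false negatives at
a held FDR. A constant profile `c` has `A = |c|`, and `A(c·x) = |c|·A(x)`.

The null ("true differential profile is flat zero") is materialized by
Monte Carlo: 10 000 flat profiles with per-timepoint Gaussian noise at the
replicate-estimated sd, shared by all genes in the same intensity bin
(the null depends only on the bin sd). Empirical p-values use the
add-one rule `p = (1 + #{A_null ≥ A}) / (n_mc + 1)`; Benjamini–Hochberg
gives the FDR p-values. The replicate error model pools within-gene
unbiased variances per equal-width intensity bin (single global bin for
homoscedastic data; sd floor 1e-6 guards degenerate replicates; nearest-bin
lookup extrapolates outside the grid).

## Pattern search

Per functional node, candidate seeds are the unassigned FDR-significant
genes, tried in increasing `p_fdr`. A cluster must contain at least one
significant gene, so this candidate set cannot miss a discoverable
cluster; it also keeps all-null nodes cheap (no candidates, no work).
From a seed's canonicalized profile the search alternates:

* gene step: closed-form WLS of every node gene on the two-column design
  `(p, 1)` with inverse-variance weights. Membership requires
  (a) goodness of fit not rejected — weighted RSS against
  `χ²(m−2)` at level 0.05 (two fitted parameters) — and (b) the pattern
  term significant against the constant-only fit — F(1, m−2), with the
  threshold Bonferroni-corrected by the number of genes tested in the node.
  The correction is essential: every gene in the node is tested against
  each candidate pattern, and an uncorrected 5% gate would admit ~5% of
  the node's null genes into every cluster, destroying precision. The
  Bonferroni choice trades some sensitivity for family-wise control; with
  the benchmark's 1000-gene node the per-gene level is 5e-5.
* pattern step: `p(t) = Σ w_i k_i (x_i(t) − q_i) / Σ w_i k_i²` over current
  members, then canonicalization.

Both steps are exact coordinate-descent minimizers of the total weighted
RSS, so the objective is non-increasing while membership is unchanged
(asserted in tests). Iteration stops at a membership fixpoint, on a
detected membership cycle (member sets are hashed; the lowest-RSS state
seen is returned and flagged non-converged), or at `max_iter` = 100.
A returned cluster needs ≥ 2 members (`min_cluster_size`; singletons would
defeat the recovery rule) and ≥ 1 member with `p_fdr < 0.05`.

The node search repeats on the residual gene set until no candidate seed
yields a cluster. The DAG traversal visits terms in reverse-topological
order (deeper first, lexicographic tie-break — a unique, deterministic
order), deleting each cluster's genes from all strict ancestors of the
discovering term. Flat gene sets and unannotated genes are attached as
depth-1 pseudo-terms under a virtual root so the same traversal covers
them. Node-level patterns are consolidated globally by single-linkage
merging at signed correlation ≥ 0.95; the correlation is signed so
anticorrelated patterns remain distinct clusters.

## Recovery and evaluation

Final selection = `{p_fdr < α}` ∪ `{p_raw < α and member of a cluster
containing an FDR-significant gene}`, α = 0.05 for both gates. Recovery
only adds genes. Realized FDR is reported for both the threshold-only and
the final selection, since the benchmark shows recovery adds almost no
false positives (cluster membership is family-wise gated).

Cluster scoring uses maximal-intersection matching: per true cluster,
TP = largest overlap with any inferred cluster; precision = TP / matched
cluster size, recall = TP / true cluster size. Genes discovered at several
sibling terms are first deduplicated into their best-fitting cluster
(smallest `flat_p`) so the matching sees a partition. With no inferred
clusters, precision and recall are reported as 0 with a flag.

## Synthetic benchmark

Defaults: 1000 genes × 13 uniformly spaced timepoints, 6 clusters × 20 DE
genes, noise sd 0.2, profiles clipped to [−6, 6], nulls flat zero plus
noise. Per cluster, 10 genes draw `|k| ~ U(0.5, 2)`, `q ~ U(−0.5, 0.5)`
and 10 draw `|k| ~ U(1, 3)`, `q ~ U(−3, 3)`; `k`'s sign is a fair coin
(the ± interval notation read as the union of the mirrored intervals).

The six template shapes are PCHIP interpolants of hand-chosen control
points, rescaled exactly to [−1, 1] (templates 1–3) or [0, 1] (4–6):
gradual decline, early transient peak with late repression, early dip with
late induction, rapid induction to plateau, mid-course transient pulse,
delayed induction. Because `k` is signed, a template and its negation
generate the same profile family, so the shapes were chosen with pairwise
canonical |correlation| ≤ ~0.88 in either orientation — the distinctness
that makes six clusters statistically resolvable at all. Replicate
measurements (default 2) share each gene's true baseline value plus
independent noise.

What the benchmark does not emulate: probe-level artifacts, normalization
residue, intensity-dependent (heteroscedastic) noise, correlated noise
across timepoints, lagged or nonlinear co-expression, and realistic
annotation sparsity (the validation study uses a single shared functional
node). Passing benchmarks therefore demonstrates correctness of the
machinery and its operating characteristics under the stated noise model,
not performance on any particular real platform.

Desk-scale study sizes: the validation study averages 20 simulated
datasets (the package's default; `--n-datasets` raises it), which puts
Monte-Carlo standard errors on per-cluster precision/recall around 1–3
percentage points.

## Numerical notes and edge cases

* Flat data under the flat-comparison F test (`RSS0 ≈ 0`) returns
  `flat_p = 1`; an exact fit (`RSS = 0`, `RSS0 > 0`) returns `flat_p = 0`.
* A constant pattern or an all-zero scale vector raises a degenerate-design
  error rather than producing NaNs.
* Weights are inverse measurement variances; the χ² goodness-of-fit
  calibration relies on that scaling.
* Intensity lookup for nulls and weights uses the gene's mean absolute
  differential expression; with a single-bin error model this reduces to
  one shared global sd.
* All randomness flows from one seed through `numpy` `SeedSequence`
  spawning, making every run (and every output file) bit-reproducible;
  derived seeds stay below 2³¹.
* Tables round-trip byte-identically (`float_precision="round_trip"` on
  read, shortest-repr floats on write).

## Known limitations

* The membership thresholds (χ² at 0.05, Bonferroni flat gate) are design
  choices of this implementation; other gating schemes (e.g. BH within
  node) trade precision against recall differently.
* The false-negative level of the threshold-only selection depends
  strongly on the templates' net time-averages; bipolar shapes with
  near-zero net area are the hardest selection targets by construction.
* Only `is_a` edges are traversed; evidence codes are ignored; annotation
  databases with `part_of`-heavy namespaces would need an extended loader.
* The area statistic ranks by sustained displacement only; a selection
  method tuned to oscillatory responses could replace it — the pipeline
  only needs a p-value per gene.
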