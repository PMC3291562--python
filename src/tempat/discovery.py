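"""Iterative weighted-least-squares discovery of temporal patterns.

Within a functional gene set, a cluster is the set of genes whose profiles
are affine transforms of one shared temporal pattern P:

    x_i(t) = k_i * p(t) + q_i + eps_i(t),  eps_i(t) ~ N(0, sigma_i(t)^2).

The search alternates two weighted-least-squares steps:

1. *gene step* — with P fixed, fit (k_i, q_i) per gene in closed form and
   keep the genes whose fit both survives a chi-square goodness-of-fit test
   (weighted RSS against chi-square with m-2 degrees of freedom) and is
   significantly better than a flat profile (F test of the pattern term);
2. *pattern step* — with the kept genes' (k_i, q_i) fixed, re-estimate
   p(t) per timepoint by WLS over genes.

Iteration stops at a membership fixpoint (or a detected cycle, or an
iteration cap).  A cluster is recorded only if it has at least
``min_cluster_size`` members and contains at least one gene whose
FDR-adjusted selection p-value is below the significance level.

The affine model makes P identifiable only up to an affine transform
(aP + b absorbed into k and q), so discovered patterns are reported in a
canonical form: zero mean, unit Euclidean norm, sign positively correlated
with the seed gene's profile.

Because every gene in the set is tested against each candidate pattern,
the flat-profile F test is Bonferroni-corrected for the number of genes
tested; without that control roughly ``flat_alpha`` of the null genes would
leak into every cluster, degrading precision far below what the gated
iteration otherwise achieves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, InvalidInputError
from .ontology import AnnotationMap, OntologyGraph, leaves_first_order, remove_from_ancestors
from .selection import ErrorModel

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """Constant pattern or all-zero scales: the WLS design is singular."""


@dataclass
class DiscoveryConfig:
    """Thresholds and caps of the pattern search."""

    gof_alpha: float = 0.05  # goodness-of-fit rejection level (keep if p > alpha)
    cluster_alpha: float = 0.05  # FDR level that makes a cluster significant
    flat_alpha: float = 0.05  # family-wise level of the flat-profile F test
    flat_correction: str = "bonferroni"  # "bonferroni" over tested genes, or "none"
    max_iter: int = 100
    min_cluster_size: int = 2
    merge_r: float = 0.95  # signed-correlation threshold for global pattern merging

    def validate(self) -> None:
        for p in (self.gof_alpha, self.cluster_alpha, self.flat_alpha):
            if not 0 < p < 1:
                raise InvalidInputError("alpha thresholds must lie in (0, 1)")
        if self.flat_correction not in ("bonferroni", "none"):
            raise InvalidInputError("flat_correction must be 'bonferroni' or 'none'")

    def flat_threshold(self, n_tested: int) -> float:
        if self.flat_correction == "bonferroni":
            return self.flat_alpha / max(n_tested, 1)
        return self.flat_alpha


@dataclass
class PatternProfile:
    """A canonical temporal pattern (zero mean, unit norm, non-constant)."""

    values: np.ndarray
    term: str | None = None


@dataclass
class GeneFit:
    """Per-gene affine fit to a pattern with its two test p-values."""

    gene_id: str
    k: float
    q: float
    gof_p: float
    flat_p: float


@dataclass
class ClusterModel:
    """A discovered pattern, its member fits, and the owning term."""

    pattern: PatternProfile
    members: list[GeneFit]
    term: str | None = None
    converged: bool = True
    n_iter: int = 0
    rss: float = 0.0
    rss_trace: list[float] = field(default_factory=list)
    membership_trace: list[frozenset] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [f.gene_id for f in self.members]


def canonicalize(values: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean, unit-norm form of a profile; sign aligned with ``ref``."""
    v = np.asarray(values, dtype=float)
    v = v - v.mean()
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise DegenerateDesignError("constant profile cannot be canonicalized")
    v = v / norm
    if ref is not None:
        r = np.asarray(ref, dtype=float)
        if float(np.dot(v, r - r.mean())) < 0:
            v = -v
    return v


def _prepare_weights(weights, n: int, m: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim == 0:
        w = np.full((n, m), float(w))
    elif w.ndim == 1:
        if w.shape[0] != m:
            raise InvalidInputError("per-timepoint weights must have length m")
        w = np.broadcast_to(w, (n, m)).copy()
    elif w.shape != (n, m):
        raise InvalidInputError("weights must broadcast to (n_genes, n_timepoints)")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise InvalidInputError("weights must be positive and finite")
    return w


def weights_from_sigma(sigma, m: int | None = None) -> np.ndarray:
    """Inverse-variance weights ``1 / sigma^2`` (scalar or per-timepoint)."""
    sig = np.asarray(sigma, dtype=float)
    w = 1.0 / sig**2
    if w.ndim == 0 and m is not None:
        w = np.full(m, float(w))
    return w


def _fit_many(X: np.ndarray, p: np.ndarray, W: np.ndarray):
    """Closed-form WLS of every row of X on the design (pattern, constant).

    Weights are inverse measurement variances, so the weighted RSS of a
    well-fitting gene is chi-square with m-2 degrees of freedom; the flat
    comparison is the F test of the pattern coefficient.
    """
    n, m = X.shape
    if np.ptp(p) == 0:
        raise DegenerateDesignError("constant pattern")
    sw = W.sum(axis=1)
    swp = W @ p
    swpp = W @ (p * p)
    swx = (W * X).sum(axis=1)
    swpx = (W * X) @ p
    det = sw * swpp - swp**2
    k = (sw * swpx - swp * swx) / det
    q = (swpp * swx - swp * swpx) / det
    resid = X - k[:, None] * p[None, :] - q[:, None]
    rss = (W * resid**2).sum(axis=1)
    q0 = swx / sw
    rss0 = (W * (X - q0[:, None]) ** 2).sum(axis=1)
    dof = m - 2
    gof_p = stats.chi2.sf(rss, dof)
    gain = np.maximum(rss0 - rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = gain / (rss / dof)
    flat_p = np.where(
        rss0 <= 1e-300,
        1.0,  # identically flat data: no evidence against the flat model
        np.where(rss <= 1e-300, 0.0, stats.f.sf(fstat, 1, dof)),
    )
    return k, q, rss, gof_p, flat_p


def fit_gene_to_pattern(
    series: np.ndarray, pattern: PatternProfile | np.ndarray, weights=1.0, gene_id: str = ""
) -> GeneFit:
    """WLS fit of one gene profile to a pattern (any profile, not only canonical)."""
    x = np.asarray(series, dtype=float)
    p = pattern.values if isinstance(pattern, PatternProfile) else np.asarray(pattern, float)
    if x.shape != p.shape:
        raise InvalidInputError("series and pattern must have equal length")
    W = _prepare_weights(weights, 1, len(x))
    k, q, _, gof_p, flat_p = _fit_many(x[None, :], p, W)
    return GeneFit(gene_id=gene_id, k=float(k[0]), q=float(q[0]),
                   gof_p=float(gof_p[0]), flat_p=float(flat_p[0]))


def estimate_pattern(
    members: list[tuple[np.ndarray, GeneFit]],
    weights: np.ndarray | None = None,
    ref: np.ndarray | None = None,
    term: str | None = None,
) -> PatternProfile:
    """Re-estimate P per timepoint by WLS over member genes.

    With (k_i, q_i) fixed, the WLS estimate at each timepoint is

        p(t) = sum_i w_i k_i (x_i(t) - q_i) / sum_i w_i k_i^2,

    then canonicalized.  ``weights`` is one scalar weight per member gene
    (uniform when omitted); ``ref`` fixes the sign of the canonical form.
    """
    if not members:
        raise InvalidInputError("need at least one member")
    X = np.stack([np.asarray(s, float) for s, _ in members])
    k = np.array([f.k for _, f in members])
    q = np.array([f.q for _, f in members])
    w = np.ones(len(members)) if weights is None else np.asarray(weights, float)
    den = float((w * k**2).sum())
    if den <= 0:
        raise DegenerateDesignError("all member scales are zero")
    p = (w * k) @ (X - q[:, None]) / den
    if ref is None:
        ref = X[0]
    return PatternProfile(values=canonicalize(p, ref=ref), term=term)


def discover_pattern(
    X: np.ndarray,
    p_fdr: np.ndarray,
    seed_idx: int,
    config: DiscoveryConfig,
    weights=1.0,
    gene_ids: np.ndarray | None = None,
    term: str | None = None,
) -> ClusterModel | None:
    """One round of the iterative pattern search, seeded at one gene.

    Returns the converged cluster, or ``None`` when the final member set is
    empty, too small, or contains no FDR-significant gene.
    """
    config.validate()
    n, m = X.shape
    if gene_ids is None:
        gene_ids = np.array([str(i) for i in range(n)])
    if not 0 <= seed_idx < n:
        raise InvalidInputError("seed gene index out of range")
    W = _prepare_weights(weights, n, m)
    ref = X[seed_idx]
    try:
        P = canonicalize(ref)
    except DegenerateDesignError:
        return None
    flat_thr = config.flat_threshold(n)
    seen: dict[frozenset, tuple[np.ndarray, float]] = {}
    prev_members: frozenset | None = None
    converged = False
    rss_trace: list[float] = []
    membership_trace: list[frozenset] = []
    idx = np.array([], dtype=int)
    k = q = gof_p = flat_p = None
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        k, q, rss, gof_p, flat_p = _fit_many(X, P, W)
        keep = (gof_p > config.gof_alpha) & (flat_p < flat_thr)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            return None
        members = frozenset(idx.tolist())
        total_rss = float(rss[idx].sum())
        rss_trace.append(total_rss)
        membership_trace.append(members)
        if members == prev_members:
            converged = True
            break
        if members in seen:
            # membership cycle: fall back to the best (lowest-RSS) state seen
            best_P, _ = min(seen.values(), key=lambda s: s[1])
            k, q, rss, gof_p, flat_p = _fit_many(X, best_P, W)
            keep = (gof_p > config.gof_alpha) & (flat_p < flat_thr)
            idx = np.flatnonzero(keep)
            P = best_P
            logger.info("membership cycle detected; returning lowest-RSS state")
            break
        seen[members] = (P, total_rss)
        prev_members = members
        gene_w = W[idx].mean(axis=1)
        fits = [GeneFit(str(gene_ids[i]), float(k[i]), float(q[i]),
                        float(gof_p[i]), float(flat_p[i])) for i in idx]
        P = estimate_pattern(
            [(X[i], f) for i, f in zip(idx, fits)], weights=gene_w, ref=ref
        ).values
    else:
        logger.info("pattern search hit max_iter=%d without converging", config.max_iter)
    if idx.size < config.min_cluster_size:
        return None
    if not np.any(p_fdr[idx] < config.cluster_alpha):
        return None
    members_fits = [GeneFit(str(gene_ids[i]), float(k[i]), float(q[i]),
                            float(gof_p[i]), float(flat_p[i])) for i in idx]
    return ClusterModel(
        pattern=PatternProfile(values=P, term=term),
        members=members_fits,
        term=term,
        converged=converged,
        n_iter=n_iter,
        rss=float(rss_trace[-1]),
        rss_trace=rss_trace,
        membership_trace=membership_trace,
    )


def discover_patterns_in_node(
    X: np.ndarray,
    gene_ids: np.ndarray,
    p_fdr: np.ndarray,
    config: DiscoveryConfig,
    weights=1.0,
    term: str | None = None,
) -> list[ClusterModel]:
    """All patterns of one functional gene set.

    Each round re-applies the search to the residual (unclustered) genes,
    seeding at unassigned FDR-significant genes in order of increasing
    adjusted p-value until one seed yields a significant cluster.  Only
    significant genes can seed: a cluster must contain at least one, so
    every discoverable cluster offers such an anchor, while a noisy seed
    profile cannot silently terminate the whole node.  The search stops
    when the residual is exhausted or no candidate seed succeeds.
    """
    n, m = X.shape
    gene_ids = np.asarray(gene_ids)
    W = _prepare_weights(weights, n, m)
    remaining = np.arange(n)
    clusters: list[ClusterModel] = []
    while remaining.size >= config.min_cluster_size:
        sub_p = p_fdr[remaining]
        candidates = np.flatnonzero(sub_p < config.cluster_alpha)
        candidates = candidates[np.argsort(sub_p[candidates], kind="stable")]
        model = None
        for seed_local in candidates:
            model = discover_pattern(
                X[remaining],
                sub_p,
                int(seed_local),
                config,
                weights=W[remaining],
                gene_ids=gene_ids[remaining],
                term=term,
            )
            if model is not None:
                break
        if model is None:
            break
        clusters.append(model)
        member_set = set(model.member_ids)
        keep_mask = np.array([str(gene_ids[i]) not in member_set for i in remaining])
        remaining = remaining[keep_mask]
    return clusters


def traverse_and_discover(
    ontology: OntologyGraph,
    annotations: AnnotationMap,
    matrix: ExpressionMatrix,
    selection: pd.DataFrame,
    config: DiscoveryConfig,
    error_model: ErrorModel | None = None,
) -> list[ClusterModel]:
    """Leaves-first pattern discovery over the whole annotation DAG.

    Terms are visited from most to least specific; after each term's search,
    clustered genes are deleted from all ancestors of the term (never from
    siblings), so every cluster is reported at the most specific term that
    supports it.  Per-gene fit weights come from the error model evaluated
    at the gene's mean absolute intensity (uniform unit-variance-scaled
    weights when no model is given).
    """
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    p_fdr_all = selection["p_fdr"].reindex(matrix.gene_ids).to_numpy()
    if error_model is not None:
        sds = error_model.sd_for(np.abs(matrix.values).mean(axis=1))
    else:
        sds = np.ones(matrix.n_genes)
    gene_weights = 1.0 / sds**2
    working = annotations.working_copy()
    clusters: list[ClusterModel] = []
    for node in leaves_first_order(ontology):
        genes = sorted(working.get(node, set()) & gene_index.keys())
        if len(genes) < config.min_cluster_size:
            continue
        idx = np.array([gene_index[g] for g in genes])
        W = np.repeat(gene_weights[idx][:, None], matrix.n_timepoints, axis=1)
        found = discover_patterns_in_node(
            matrix.values[idx], np.array(genes), p_fdr_all[idx], config,
            weights=W, term=node,
        )
        for model in found:
            remove_from_ancestors(working, ontology, set(model.member_ids), node, inplace=True)
        if found:
            logger.info("node %s: %d cluster(s)", node, len(found))
        clusters.extend(found)
    return clusters


@dataclass
class PatternGroup:
    """A consolidated global pattern and the node-level clusters behind it."""

    profile: np.ndarray
    clusters: list[ClusterModel]

    @property
    def n_genes(self) -> int:
        return sum(len(c.members) for c in self.clusters)


def merge_patterns(clusters: list[ClusterModel], merge_r: float = 0.95) -> list[PatternGroup]:
    """Single-linkage grouping of node-level patterns by signed correlation.

    Patterns are merged when their canonical profiles correlate at or above
    ``merge_r``; the correlation is signed, so anticorrelated patterns stay
    distinct.  Each group's profile is the member-count-weighted mean of its
    patterns, re-canonicalized with the largest cluster's pattern as sign
    reference.
    """
    if not clusters:
        return []
    profiles = np.stack([c.pattern.values for c in clusters])
    corr = profiles @ profiles.T  # canonical profiles: dot product = Pearson r
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if corr[i, j] >= merge_r:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    by_root: dict[int, list[int]] = {}
    for i in range(n):
        by_root.setdefault(find(i), []).append(i)
    groups = []
    for members in by_root.values():
        sizes = np.array([len(clusters[i].members) for i in members], dtype=float)
        biggest = members[int(np.argmax(sizes))]
        mean_profile = (sizes @ profiles[members]) / sizes.sum()
        profile = canonicalize(mean_profile, ref=profiles[biggest])
        groups.append(PatternGroup(profile=profile, clusters=[clusters[i] for i in members]))
    groups.sort(key=lambda g: -g.n_genes)
    return groups
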