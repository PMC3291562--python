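"""Synthetic time-course benchmark generator.

Emulates a treated-vs-control microarray time course: a small number of
differentially expressed (DE) gene clusters, each sharing a characteristic
temporal pattern, embedded in a large background of flat noisy profiles.

Each DE profile is an affine transform of its cluster template,

    x_i(t) = k_i * p(t) + q_i + eps_i(t),   eps ~ N(0, noise_sd^2),

with gene-specific scale ``k_i`` (sign included, so anticorrelated members
are possible) and offset ``q_i``.  Defaults reproduce the benchmark
conditions used throughout the package: 1000 genes on 13 timepoints, 6
clusters of 20 DE genes each (120 DE genes, 880 nulls), Gaussian noise with
standard deviation 0.2, and per-cluster half/half sampling of (k, q) from
two uniform regimes: |k| in (0.5, 2) with q in (-0.5, 0.5), and |k| in
(1, 3) with q in (-3, 3).  All profiles are clipped to [-6, 6].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .matrix import ExpressionMatrix


class InvalidConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# Reference template shapes, one per cluster, as (time, value) control points
# on the unit time interval; monotone cubic (PCHIP) interpolation followed by
# an exact affine rescale to the target range.  Three bipolar shapes span
# [-1, 1]; three unipolar shapes span [0, 1].  The families are qualitative:
# a gradual decline, an early transient peak followed by repression, an
# early dip with late induction, a rapid induction to a plateau, a mid-course
# transient pulse, and a delayed induction.  Because member genes carry a
# signed scale k, a template and its negation generate the same profile
# family; the shapes are therefore chosen so that no two canonical
# (centered, normalized) templates exceed |r| ~ 0.9 in either orientation,
# keeping the six cluster families statistically distinguishable.
_TEMPLATE_CONTROL_POINTS: dict[int, list[tuple[float, float]]] = {
    1: [(0.0, 1.0), (0.2, 0.85), (0.5, 0.0), (0.8, -0.85), (1.0, -1.0)],
    2: [(0.0, 0.0), (0.1, 0.8), (0.18, 1.0), (0.35, 0.3), (0.55, -0.8),
        (0.7, -1.0), (0.85, -0.55), (1.0, -0.25)],
    3: [(0.0, -0.15), (0.15, -0.55), (0.35, -1.0), (0.55, -0.35),
        (0.7, 0.55), (0.82, 1.0), (1.0, 0.75)],
    4: [(0.0, 0.0), (0.12, 0.1), (0.28, 0.75), (0.4, 1.0), (1.0, 1.0)],
    5: [(0.0, 0.0), (0.25, 0.1), (0.4, 0.9), (0.5, 1.0), (0.6, 0.9),
        (0.75, 0.1), (1.0, 0.0)],
    6: [(0.0, 0.0), (0.55, 0.0), (0.7, 0.3), (0.85, 0.85), (1.0, 1.0)],
}

BIPOLAR_IDS = (1, 2, 3)  # range [-1, 1]
UNIPOLAR_IDS = (4, 5, 6)  # range [0, 1]


@dataclass(frozen=True)
class TemplatePattern:
    """A cluster template: ``id`` 1..6, sampled values, and polarity."""

    id: int
    values: np.ndarray
    polarity: str  # "bipolar" ([-1, 1]) or "unipolar" ([0, 1])


def make_template_patterns(n_timepoints: int) -> list[TemplatePattern]:
    """Sample the six reference template shapes on a uniform time grid.

    Bipolar templates (ids 1-3) have min exactly -1 and max exactly 1;
    unipolar templates (ids 4-6) have min 0 and max 1.
    """
    if n_timepoints < 4:
        raise InvalidConfigurationError("need at least 4 timepoints for templates")
    s = np.linspace(0.0, 1.0, n_timepoints)
    templates = []
    for tid in sorted(_TEMPLATE_CONTROL_POINTS):
        pts = _TEMPLATE_CONTROL_POINTS[tid]
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        raw = PchipInterpolator(xs, ys)(s)
        lo, hi = (-1.0, 1.0) if tid in BIPOLAR_IDS else (0.0, 1.0)
        span = raw.max() - raw.min()
        values = lo + (hi - lo) * (raw - raw.min()) / span
        polarity = "bipolar" if tid in BIPOLAR_IDS else "unipolar"
        templates.append(TemplatePattern(id=tid, values=values, polarity=polarity))
    return templates


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark (defaults documented above)."""

    n_genes: int = 1000
    n_timepoints: int = 13
    n_clusters: int = 6
    genes_per_cluster: int = 20
    noise_sd: float = 0.2
    # two (|k|, q) sampling regimes; each cluster draws half its genes from each
    k_ranges: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 2.0), (1.0, 3.0))
    q_ranges: tuple[tuple[float, float], tuple[float, float]] = ((-0.5, 0.5), (-3.0, 3.0))
    clip: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters * self.genes_per_cluster > self.n_genes:
            raise InvalidConfigurationError("more DE genes than total genes")
        if self.genes_per_cluster > 0 and not 1 <= self.n_clusters <= 6:
            raise InvalidConfigurationError("between 1 and 6 template clusters supported")
        if self.noise_sd < 0:
            raise InvalidConfigurationError("noise_sd must be non-negative")
        for lo, hi in (*self.k_ranges, *self.q_ranges):
            if hi <= lo:
                raise InvalidConfigurationError("empty sampling interval")
        if self.n_timepoints < 4:
            raise InvalidConfigurationError("need at least 4 timepoints")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    de_gene_ids: set[str]
    cluster_of: dict[str, int]
    true_k: dict[str, float]
    true_q: dict[str, float]


def simulate_gene(
    template: TemplatePattern,
    k: float,
    q: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one profile ``k * template + q`` plus i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise InvalidConfigurationError("noise_sd must be non-negative")
    m = len(template.values)
    return k * template.values + q + rng.normal(0.0, noise_sd, size=m)


def _draw_signed_k(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Uniform over (-hi, -lo) U (lo, hi), equal mass on each side."""
    mag = rng.uniform(lo, hi)
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    return sign * mag


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate one benchmark dataset with ground truth.

    DE genes come first (cluster by cluster), followed by pure-noise null
    profiles (true flat zero plus noise).  Within a cluster the first half
    of the genes uses the first (k, q) regime, the second half the second.
    A fixed ``config.seed`` yields a bit-identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates = make_template_patterns(config.n_timepoints)
    m = config.n_timepoints
    values = np.empty((config.n_genes, m))
    de_ids: set[str] = set()
    cluster_of: dict[str, int] = {}
    true_k: dict[str, float] = {}
    true_q: dict[str, float] = {}
    row = 0
    if config.genes_per_cluster > 0:
        for c in range(config.n_clusters):
            template = templates[c]
            n_first = config.genes_per_cluster // 2 + config.genes_per_cluster % 2
            for j in range(config.genes_per_cluster):
                regime = 0 if j < n_first else 1
                k = _draw_signed_k(rng, *config.k_ranges[regime])
                q = rng.uniform(*config.q_ranges[regime])
                gid = f"g{row:04d}"
                values[row] = simulate_gene(template, k, q, config.noise_sd, rng)
                de_ids.add(gid)
                cluster_of[gid] = template.id
                true_k[gid] = k
                true_q[gid] = q
                row += 1
    # null profiles: flat zero plus the same noise
    n_null = config.n_genes - row
    values[row:] = rng.normal(0.0, config.noise_sd, size=(n_null, m))
    np.clip(values, -config.clip, config.clip, out=values)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    matrix = ExpressionMatrix(gene_ids=gene_ids, times=np.arange(m, dtype=float), values=values)
    return matrix, SimulationTruth(de_ids, cluster_of, true_k, true_q)


def simulate_replicates(
    config: SimulationConfig,
    n_reps: int,
    truth: SimulationTruth | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Replicate measurements of the baseline timepoint, one row per gene.

    Each gene's replicates share a common true value (its noiseless profile
    at the first timepoint; zero when no truth is supplied) perturbed by
    independent Gaussian(0, noise_sd^2) measurement error.  Feeds the
    replicate-based error model of the selection step.
    """
    config.validate()
    if n_reps < 2:
        raise InvalidConfigurationError("need at least 2 replicates")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    base = np.zeros(config.n_genes)
    if truth is not None:
        templates = {t.id: t for t in make_template_patterns(config.n_timepoints)}
        gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
        for i, gid in enumerate(gene_ids):
            if gid in truth.de_gene_ids:
                t0 = templates[truth.cluster_of[gid]].values[0]
                base[i] = truth.true_k[gid] * t0 + truth.true_q[gid]
    reps = base[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_reps))
    return reps
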