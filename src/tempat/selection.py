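"""Differential-expression ranking by the area statistic.

A gene's evidence for differential expression is the magnitude of the
time-normalized net area bounded by its treated-minus-control profile and
the zero line,

    A(x) = | integral x(t) dt | / (t_m - t_1),

with the integral taken over the piecewise-linear interpolant of the
profile.  The statistic measures the average signed displacement from the
no-effect baseline, so a sustained shift in either direction scores high
while a profile oscillating symmetrically around zero scores low — such
shape-only responders are exactly the false negatives the cluster-based
recovery step later rescues.  The null hypothesis ("the true differential
profile is flat zero") is materialized by Monte Carlo: flat profiles
perturbed by Gaussian measurement noise whose standard deviation comes
from an intensity-binned replicate error model.  Empirical p-values are
adjusted for multiplicity with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, InvalidInputError

#: lower bound applied to estimated measurement SDs, so degenerate
#: (all-identical) replicates still yield a proper, if razor-thin, null
SD_FLOOR = 1e-6

STATUS_SIGNIFICANT = "fdr_significant"
STATUS_RECOVERED = "recovered"
STATUS_NOT_SELECTED = "not_selected"


@dataclass
class ErrorModel:
    """Measurement SD as a step function of mean expression intensity."""

    intensity_grid: np.ndarray  # bin centers, increasing
    sd_at: np.ndarray  # estimated SD per bin, all > 0

    def __post_init__(self) -> None:
        self.intensity_grid = np.asarray(self.intensity_grid, dtype=float)
        self.sd_at = np.asarray(self.sd_at, dtype=float)
        if np.any(self.sd_at <= 0):
            raise InvalidInputError("error model SDs must be positive")

    def sd_for(self, intensity: float | np.ndarray) -> np.ndarray:
        """Nearest-bin lookup (constant extrapolation outside the grid)."""
        intensity = np.atleast_1d(np.asarray(intensity, dtype=float))
        idx = np.abs(intensity[:, None] - self.intensity_grid[None, :]).argmin(axis=1)
        return self.sd_at[idx]


def estimate_error_model(replicates: np.ndarray, n_bins: int = 1) -> ErrorModel:
    """Estimate an intensity-dependent error model from replicate measurements.

    Parameters
    ----------
    replicates:
        ``(n_genes, n_reps)`` array; each row holds repeated measurements of
        the same quantity for one gene.
    n_bins:
        number of equal-width intensity bins over the range of per-gene mean
        intensities.  Bins left empty are merged into their nearest occupied
        neighbor.  With homoscedastic data a single global bin suffices.

    The per-bin SD pools the within-gene unbiased variances of all genes in
    the bin, weighted by their degrees of freedom.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[1] < 2:
        raise InvalidInputError("need at least 2 replicates per gene")
    n_genes, n_reps = reps.shape
    mean_int = reps.mean(axis=1)
    var = reps.var(axis=1, ddof=1)
    dof = n_reps - 1
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    if n_bins == 1 or np.ptp(mean_int) == 0:
        centers = np.array([mean_int.mean()])
        sds = np.array([max(np.sqrt(var.mean()), SD_FLOOR)])
        return ErrorModel(centers, sds)
    edges = np.linspace(mean_int.min(), mean_int.max(), n_bins + 1)
    which = np.clip(np.digitize(mean_int, edges[1:-1]), 0, n_bins - 1)
    centers, sds = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue  # empty bin: implicitly merged by nearest-bin lookup
        pooled = (dof * var[mask]).sum() / (dof * mask.sum())
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        sds.append(max(np.sqrt(pooled), SD_FLOOR))
    return ErrorModel(np.array(centers), np.array(sds))


def area_statistic(profile: np.ndarray, times: np.ndarray) -> float:
    """Magnitude of the time-normalized net area of a differential profile."""
    profile = np.asarray(profile, dtype=float)
    times = np.asarray(times, dtype=float)
    if profile.shape != times.shape:
        raise InvalidInputError("profile and times must have equal length")
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    span = times[-1] - times[0]
    return float(np.abs(np.trapezoid(profile, times)) / span)


def _area_many(profiles: np.ndarray, times: np.ndarray) -> np.ndarray:
    span = times[-1] - times[0]
    return np.abs(np.trapezoid(profiles, times, axis=1)) / span


def null_area_distribution(
    sd: float,
    times: np.ndarray,
    n_mc: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sorted Monte-Carlo sample of the area statistic under the flat null.

    ``n_mc`` flat-truth profiles are drawn with independent per-timepoint
    Gaussian noise of standard deviation ``sd``.
    """
    if n_mc < 1000:
        raise InvalidInputError("n_mc must be at least 1000")
    times = np.asarray(times, dtype=float)
    draws = rng.normal(0.0, sd, size=(int(n_mc), len(times)))
    return np.sort(_area_many(draws, times))


def _empirical_pvalues(areas: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    n_mc = len(null_sorted)
    # number of null areas >= observed, via position in the sorted sample
    n_ge = n_mc - np.searchsorted(null_sorted, areas, side="left")
    return (1.0 + n_ge) / (n_mc + 1.0)


def gene_pvalues(
    matrix: ExpressionMatrix,
    error_model: ErrorModel,
    n_mc: int = 10000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Area statistic and raw empirical p-value for every gene.

    Genes in the same intensity bin share one Monte-Carlo null sample (the
    null depends only on the bin SD).  With a single-bin error model all
    genes share one null.  Intensity for the bin lookup is the gene's mean
    absolute differential expression.
    """
    if rng is None:
        rng = np.random.default_rng()
    areas = _area_many(matrix.values, matrix.times)
    intensity = np.abs(matrix.values).mean(axis=1)
    sds = error_model.sd_for(intensity)
    p_raw = np.empty(matrix.n_genes)
    for sd in np.unique(sds):
        null_sorted = null_area_distribution(sd, matrix.times, n_mc, rng)
        mask = sds == sd
        p_raw[mask] = _empirical_pvalues(areas[mask], null_sorted)
    return pd.DataFrame({"area": areas, "p_raw": p_raw}, index=pd.Index(matrix.gene_ids, name="gene_id"))


def fdr_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_genes(
    matrix: ExpressionMatrix,
    error_model: ErrorModel,
    alpha: float = 0.05,
    n_mc: int = 10000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full selection table: area, raw and FDR-adjusted p-values, status.

    ``status`` is ``fdr_significant`` iff the adjusted p-value is below
    ``alpha``; the ``recovered`` status is assigned later by the
    cluster-based rescue step.
    """
    result = gene_pvalues(matrix, error_model, n_mc=n_mc, rng=rng)
    result["p_fdr"] = fdr_adjust(result["p_raw"].to_numpy())
    result["status"] = np.where(
        result["p_fdr"] < alpha, STATUS_SIGNIFICANT, STATUS_NOT_SELECTED
    )
    return result
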