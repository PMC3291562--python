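"""Core container for differential expression time courses.

The central object of the package is a genes x timepoints matrix of
*differential* (treated minus control) log2 expression values.  Row ``i``
holds the time series profile ``x_i(1) ... x_i(m)`` of gene ``i`` sampled at
``m`` common timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Differential log2 expression profiles on a shared time grid.

    Parameters
    ----------
    gene_ids:
        ``n`` unique gene identifiers, one per row.
    times:
        ``m`` strictly increasing sampling times (minutes or any consistent
        unit; all statistics are normalized by the total span).
    values:
        ``(n, m)`` array of treated-minus-control log2 expression.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-D genes x timepoints array")
        if len(self.gene_ids) != n:
            raise InvalidInputError("gene_ids length does not match values rows")
        if len(set(self.gene_ids)) != n:
            raise InvalidInputError("gene_ids must be unique")
        if self.times.shape != (m,):
            raise InvalidInputError("times length does not match values columns")
        if n < 1 or m < 3:
            raise InvalidInputError("need at least 1 gene and 3 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("values contain missing or non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def index_of(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{i}" for i in range(self.n_timepoints)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, times: np.ndarray | None = None) -> "ExpressionMatrix":
        if "gene_id" not in df.columns:
            raise InvalidInputError("expected a 'gene_id' column")
        value_cols = [c for c in df.columns if c != "gene_id"]
        if times is None:
            # timepoint labels t0..t{m-1} map onto a unit-spaced grid
            times = np.arange(len(value_cols), dtype=float)
        return cls(
            gene_ids=list(df["gene_id"].astype(str)),
            times=np.asarray(times, dtype=float),
            values=df[value_cols].to_numpy(dtype=float),
        )
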