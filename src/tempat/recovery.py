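"""Final gene selection with cluster-based rescue of false negatives.

The FDR threshold alone is conservative: with many genes and few
replicates, true responders with modest effect sizes miss the adjusted
cutoff.  A gene that (a) has a raw p-value below the significance level and
(b) belongs to a discovered cluster — genes sharing one temporal pattern
and one functional annotation — containing at least one FDR-significant
gene is very likely a false negative of the threshold, and is rescued into
the final selection.  Recovery only ever adds genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .discovery import ClusterModel
from .selection import STATUS_NOT_SELECTED, STATUS_RECOVERED, STATUS_SIGNIFICANT


@dataclass
class FinalSelection:
    """Selected genes with their provenance and cluster memberships."""

    selected: set[str]
    provenance: dict[str, str]  # gene -> fdr_significant | recovered
    cluster_of: dict[str, list[int]] = field(default_factory=dict)

    def annotate(self, selection: pd.DataFrame) -> pd.DataFrame:
        """Selection table with the final post-recovery status column."""
        out = selection.copy()
        out["status"] = [
            self.provenance.get(g, STATUS_NOT_SELECTED) for g in out.index
        ]
        out["cluster_ids"] = [
            ",".join(map(str, self.cluster_of.get(g, []))) for g in out.index
        ]
        return out


def recover_genes(
    selection: pd.DataFrame,
    clusters: list[ClusterModel],
    alpha: float = 0.05,
    raw_alpha: float | None = None,
) -> FinalSelection:
    """Combine FDR thresholding with cluster-based false-negative recovery.

    selected = {p_fdr < alpha}  union
               {p_raw < raw_alpha, member of a cluster holding >= 1
                FDR-significant gene}

    ``raw_alpha`` defaults to ``alpha``.  Cluster membership already implies
    a shared temporal pattern and a shared functional term, so only the raw
    p-value and the presence of a significant cluster-mate are checked here.
    """
    if raw_alpha is None:
        raw_alpha = alpha
    p_fdr = selection["p_fdr"]
    p_raw = selection["p_raw"]
    fdr_sig = set(selection.index[p_fdr < alpha])
    cluster_of: dict[str, list[int]] = {}
    for ci, cl in enumerate(clusters):
        for gid in cl.member_ids:
            cluster_of.setdefault(gid, []).append(ci)
    recovered: set[str] = set()
    for ci, cl in enumerate(clusters):
        member_ids = set(cl.member_ids)
        if not member_ids & fdr_sig:
            continue
        for gid in member_ids - fdr_sig:
            if gid in selection.index and p_raw[gid] < raw_alpha:
                recovered.add(gid)
    provenance = {g: STATUS_SIGNIFICANT for g in fdr_sig}
    provenance.update({g: STATUS_RECOVERED for g in recovered})
    return FinalSelection(
        selected=fdr_sig | recovered,
        provenance=provenance,
        cluster_of=cluster_of,
    )
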