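"""Scoring inferred clusters and selections against simulation truth.

Cluster quality uses maximal-intersection matching: for every true
(simulated) cluster, the true-positive count is its largest overlap with
any inferred cluster, the arg-max inferred cluster is its match, precision
is TP divided by the matched cluster's size and recall is TP divided by
the true cluster's size.  An inferred cluster may match several true
clusters; counts are always per true cluster.

Selection quality is the false-negative rate (missed true DE genes over
true DE genes) and the realized false discovery rate (false positives over
selected genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .discovery import ClusterModel
from .recovery import FinalSelection
from .simulate import SimulationTruth


@dataclass
class EvaluationReport:
    """Per-true-cluster matching results plus optional selection metrics."""

    intersection: pd.DataFrame  # true clusters x inferred clusters, overlap counts
    tp: dict[int, int]
    matched: dict[int, int | None]  # true cluster -> matched inferred index
    precision: dict[int, float]
    recall: dict[int, float]
    no_inferred: bool = False
    fn_rate: float | None = None
    realized_fdr: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "matched": self.matched,
            "precision": self.precision,
            "recall": self.recall,
            "no_inferred": self.no_inferred,
            "fn_rate": self.fn_rate,
            "realized_fdr": self.realized_fdr,
        }


def deduplicate_memberships(clusters: list[ClusterModel]) -> list[set[str]]:
    """Assign each gene to its single best-fitting cluster.

    Genes clustered at several terms (sibling-node duplicates) are kept only
    in the cluster where their flat-profile test is strongest (smallest
    flat_p; first cluster on ties), so the matching sees a partition.
    """
    best: dict[str, tuple[float, int]] = {}
    for ci, cl in enumerate(clusters):
        for fit in cl.members:
            cur = best.get(fit.gene_id)
            if cur is None or fit.flat_p < cur[0]:
                best[fit.gene_id] = (fit.flat_p, ci)
    memberships: list[set[str]] = [set() for _ in clusters]
    for gid, (_, ci) in best.items():
        memberships[ci].add(gid)
    return memberships


def match_clusters(
    truth: SimulationTruth, inferred: list[ClusterModel]
) -> EvaluationReport:
    """Maximal-intersection matching of inferred to simulated clusters."""
    true_ids = sorted(set(truth.cluster_of.values()))
    true_members = {
        c: {g for g, cl in truth.cluster_of.items() if cl == c} for c in true_ids
    }
    memberships = deduplicate_memberships(inferred)
    counts = pd.DataFrame(
        [
            [len(true_members[c] & mem) for mem in memberships]
            for c in true_ids
        ],
        index=pd.Index(true_ids, name="true_cluster"),
        columns=pd.Index(range(len(memberships)), name="inferred_cluster"),
    )
    tp: dict[int, int] = {}
    matched: dict[int, int | None] = {}
    precision: dict[int, float] = {}
    recall: dict[int, float] = {}
    no_inferred = len(memberships) == 0
    for c in true_ids:
        if no_inferred:
            tp[c], matched[c] = 0, None
            precision[c], recall[c] = 0.0, 0.0
            continue
        row = counts.loc[c]
        j = int(row.idxmax())
        tp[c] = int(row.max())
        matched[c] = j
        size = len(memberships[j])
        precision[c] = tp[c] / size if size else 0.0
        recall[c] = tp[c] / len(true_members[c])
    return EvaluationReport(
        intersection=counts,
        tp=tp,
        matched=matched,
        precision=precision,
        recall=recall,
        no_inferred=no_inferred,
    )


def selection_metrics(
    truth: SimulationTruth, final: FinalSelection | set[str]
) -> tuple[float, float]:
    """(false-negative rate, realized FDR) of a gene selection against truth."""
    selected = final.selected if isinstance(final, FinalSelection) else set(final)
    de = truth.de_gene_ids
    fn_rate = len(de - selected) / len(de) if de else 0.0
    realized_fdr = len(selected - de) / len(selected) if selected else 0.0
    return fn_rate, realized_fdr
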