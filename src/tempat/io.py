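"""Shared TSV/JSON/YAML readers and writers.

All tables are tab-separated with optional ``#``-prefixed ``key=value``
metadata lines before the header.  Writing a table read by the matching
reader reproduces it byte for byte (the round-trip contract used by the
pipeline's determinism checks).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discovery import ClusterModel, GeneFit, PatternProfile
from .matrix import ExpressionMatrix
from .simulate import SimulationConfig, SimulationTruth


def _write_tsv(df: pd.DataFrame, path, metadata: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, index_col=None) -> tuple[pd.DataFrame, dict]:
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            metadata[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=index_col, float_precision="round_trip")
    return df, metadata


def write_matrix(matrix: ExpressionMatrix, path, metadata: dict | None = None) -> None:
    meta = {"times": ",".join(repr(float(t)) for t in matrix.times), **(metadata or {})}
    _write_tsv(matrix.to_frame(), path, metadata=meta)


def read_matrix(path) -> ExpressionMatrix:
    df, meta = _read_tsv(path)
    times = None
    if "times" in meta:
        times = np.array([float(v) for v in meta["times"].split(",")])
    return ExpressionMatrix.from_frame(df, times=times)


def read_matrix_pair(treated_path, control_path) -> ExpressionMatrix:
    """Load treated and control matrices and difference them on load."""
    treated = read_matrix(treated_path)
    control = read_matrix(control_path)
    if treated.gene_ids != control.gene_ids or not np.array_equal(treated.times, control.times):
        raise ValueError("treated and control matrices are not aligned")
    return ExpressionMatrix(
        gene_ids=treated.gene_ids,
        times=treated.times,
        values=treated.values - control.values,
    )


def write_truth(truth: SimulationTruth, path, metadata: dict | None = None) -> None:
    rows = sorted(truth.cluster_of)
    df = pd.DataFrame(
        {
            "gene_id": rows,
            "cluster_id": [truth.cluster_of[g] for g in rows],
            "k": [truth.true_k[g] for g in rows],
            "q": [truth.true_q[g] for g in rows],
        }
    )
    _write_tsv(df, path, metadata=metadata)


def read_truth(path) -> SimulationTruth:
    df, _ = _read_tsv(path)
    df["gene_id"] = df["gene_id"].astype(str)
    return SimulationTruth(
        de_gene_ids=set(df["gene_id"]),
        cluster_of=dict(zip(df["gene_id"], df["cluster_id"].astype(int))),
        true_k=dict(zip(df["gene_id"], df["k"].astype(float))),
        true_q=dict(zip(df["gene_id"], df["q"].astype(float))),
    )


def write_replicates(replicates: np.ndarray, gene_ids, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame(replicates, columns=[f"rep{i}" for i in range(replicates.shape[1])])
    df.insert(0, "gene_id", list(gene_ids))
    _write_tsv(df, path, metadata=metadata)


def read_replicates(path) -> tuple[np.ndarray, list[str]]:
    df, _ = _read_tsv(path)
    gene_ids = list(df["gene_id"].astype(str))
    reps = df[[c for c in df.columns if c != "gene_id"]].to_numpy(dtype=float)
    return reps, gene_ids


def write_selection(selection: pd.DataFrame, path, metadata: dict | None = None) -> None:
    _write_tsv(selection.reset_index(), path, metadata=metadata)


def read_selection(path) -> pd.DataFrame:
    df, _ = _read_tsv(path)
    df["gene_id"] = df["gene_id"].astype(str)
    return df.set_index("gene_id")


def write_clusters(clusters: list[ClusterModel], out_dir, metadata: dict | None = None) -> None:
    """Write member fits (clusters.tsv) and canonical patterns (patterns.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    member_rows = []
    pattern_rows = []
    for ci, cl in enumerate(clusters):
        for fit in cl.members:
            member_rows.append(
                {
                    "cluster_id": ci,
                    "term_id": cl.term if cl.term is not None else "",
                    "gene_id": fit.gene_id,
                    "k": fit.k,
                    "q": fit.q,
                    "gof_p": fit.gof_p,
                    "flat_p": fit.flat_p,
                }
            )
        pattern_rows.append(
            {"cluster_id": ci, **{f"t{i}": v for i, v in enumerate(cl.pattern.values)}}
        )
    cols = ["cluster_id", "term_id", "gene_id", "k", "q", "gof_p", "flat_p"]
    _write_tsv(pd.DataFrame(member_rows, columns=cols), out_dir / "clusters.tsv", metadata=metadata)
    _write_tsv(pd.DataFrame(pattern_rows), out_dir / "patterns.tsv", metadata=metadata)


def read_clusters(out_dir) -> list[ClusterModel]:
    out_dir = Path(out_dir)
    members, _ = _read_tsv(out_dir / "clusters.tsv")
    patterns, _ = _read_tsv(out_dir / "patterns.tsv", index_col="cluster_id")
    clusters: list[ClusterModel] = []
    for ci in patterns.index:
        values = patterns.loc[ci].to_numpy(dtype=float)
        sub = members[members["cluster_id"] == ci]
        term = None
        if not sub.empty:
            raw_term = sub["term_id"].iloc[0]
            term = None if pd.isna(raw_term) or raw_term == "" else str(raw_term)
        fits = [
            GeneFit(str(r.gene_id), float(r.k), float(r.q), float(r.gof_p), float(r.flat_p))
            for r in sub.itertuples()
        ]
        clusters.append(
            ClusterModel(pattern=PatternProfile(values=values, term=term), members=fits, term=term)
        )
    return clusters


def write_simulation_config(config: SimulationConfig, path) -> None:
    data = {
        "n_genes": config.n_genes,
        "n_timepoints": config.n_timepoints,
        "n_clusters": config.n_clusters,
        "genes_per_cluster": config.genes_per_cluster,
        "noise_sd": config.noise_sd,
        "k_ranges": [list(r) for r in config.k_ranges],
        "q_ranges": [list(r) for r in config.q_ranges],
        "clip": config.clip,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "k_ranges" in data:
        data["k_ranges"] = tuple(tuple(r) for r in data["k_ranges"])
    if "q_ranges" in data:
        data["q_ranges"] = tuple(tuple(r) for r in data["q_ranges"])
    return SimulationConfig(**data)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
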