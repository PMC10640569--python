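"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: covariates and matrices as TSV, metadata as
JSON sidecars, time series as ``.npy`` arrays with a JSON sidecar naming
the sampling rate and node coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attack import AttackResult
from .types import Connectome, NodeTimeseries, SubjectRecord

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_covariates",
    "write_attack_results",
    "read_timeseries",
    "write_timeseries",
]


def write_cohort(
    cohort: list[tuple[SubjectRecord, Connectome]], outdir: str | Path
) -> None:
    """Write covariates TSV, one adjacency TSV per subject, and coordinates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, conn in cohort:
        rows.append(
            {
                "id": rec.id,
                "age_years": rec.age_years,
                "sex": rec.sex,
                "handedness": rec.handedness,
                "mean_node_distance": rec.mean_node_distance,
            }
        )
        np.savetxt(outdir / f"{rec.id}_adjacency.tsv", conn.W, delimiter="\t")
        if conn.node_coords is not None:
            coords = pd.DataFrame(conn.node_coords, columns=["x", "y", "z"])
            coords.insert(0, "node", np.arange(len(coords)))
            coords.to_csv(outdir / f"{rec.id}_coords.tsv", sep="\t", index=False)
    pd.DataFrame(rows).to_csv(outdir / "covariates.tsv", sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_cohort(indir: str | Path) -> list[tuple[SubjectRecord, Connectome]]:
    indir = Path(indir)
    cov = read_covariates(indir / "covariates.tsv")
    out = []
    for _, row in cov.iterrows():
        w = np.loadtxt(indir / f"{row['id']}_adjacency.tsv", delimiter="\t")
        coords_path = indir / f"{row['id']}_coords.tsv"
        coords = None
        if coords_path.exists():
            coords = pd.read_csv(coords_path, sep="\t")[["x", "y", "z"]].to_numpy()
        rec = SubjectRecord(
            id=str(row["id"]),
            age_years=float(row["age_years"]),
            sex=str(row["sex"]),
            handedness=str(row["handedness"]),
            mean_node_distance=float(row["mean_node_distance"]),
        )
        out.append(
            (
                rec,
                Connectome(
                    W=w,
                    node_coords=coords,
                    mean_distance=rec.mean_node_distance,
                    subject_id=rec.id,
                ),
            )
        )
    return out


def write_attack_results(results: list[AttackResult], path: str | Path) -> None:
    """Long-format TSV: subject_id, strategy, density, mean_percolation_point."""
    rows = []
    for r in results:
        for d, p in zip(r.densities, r.mean_percolation):
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "strategy": r.strategy,
                    "density": d,
                    "mean_percolation_point": p,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_timeseries(ts: NodeTimeseries, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / f"{ts.subject_id}_timeseries.npy", ts.data)
    sidecar = {
        "subject_id": ts.subject_id,
        "fs": ts.fs,
        "node_coords": ts.node_coords.tolist(),
    }
    (outdir / f"{ts.subject_id}_timeseries.json").write_text(json.dumps(sidecar))


def read_timeseries(outdir: str | Path, subject_id: str) -> NodeTimeseries:
    outdir = Path(outdir)
    data = np.load(outdir / f"{subject_id}_timeseries.npy")
    sidecar = json.loads((outdir / f"{subject_id}_timeseries.json").read_text())
    return NodeTimeseries(
        subject_id=subject_id,
        data=data,
        fs=float(sidecar["fs"]),
        node_coords=np.asarray(sidecar["node_coords"], dtype=float),
    )
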