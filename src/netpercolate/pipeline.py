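"""End-to-end orchestration: cohort -> connectivity -> attacks -> FDA -> FoSR.

The pipeline runs each configured attack strategy over every subject's
connectome (optionally restricted to a node subset such as a language
network), assembles the per-density mean percolation points into a
functional sample, applies the QC chain, fits the function-on-scalar
regression with bootstrap bands, and writes every intermediate table plus
a run manifest.  Deterministic given the master seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as npio
from .attack import AttackSimulator, removal_frequency_map
from .connectivity import MultitaperWPLI, mean_node_distance
from .fda import FunctionalQC
from .fosr import FunctionOnScalarRegression, build_design_matrix
from .synthetic import SyntheticCohortSpec, generate_cohort
from .types import ConfigurationError, Connectome, FunctionalSample

__all__ = ["PipelineConfig", "run_pipeline", "subset_network", "age_quartiles"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Configuration for one full run; exactly one input mode applies."""

    mode: str = "synthetic"  # synthetic | adjacency | timeseries
    output_dir: str = "netpercolate_out"
    seed: int = 0
    # synthetic mode
    cohort: dict = field(default_factory=dict)  # SyntheticCohortSpec overrides
    # adjacency / timeseries modes
    input_dir: str | None = None
    subject_ids: list[str] | None = None  # timeseries mode
    # optional induced-subgraph analysis (e.g. a language-network node list)
    node_subset: list[int] | None = None
    # attack settings (desk-scale default grid: 1%..30% in 1% steps)
    strategies: list[str] = field(default_factory=lambda: ["random", "betweenness"])
    densities: list[float] = field(default_factory=lambda: (np.arange(1, 31) / 100).tolist())
    n_iter: int = 100
    map_density: float = 0.05
    # FDA / FoSR settings
    spike_z: float = 2.0
    ssr_z: float = 2.0
    trim_tol: float = 1e-6
    n_basis: int = 5
    n_boot: int = 1000
    alpha: float = 0.001
    # connectivity settings (timeseries mode)
    fmin: float = 0.5
    fmax: float = 100.0
    fstep: float = 0.5
    half_bandwidth: float = 2.0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "adjacency", "timeseries"):
            raise ConfigurationError(f"unknown input mode {self.mode!r}")
        if self.mode != "synthetic":
            if self.input_dir is None or not Path(self.input_dir).exists():
                raise ConfigurationError(
                    f"{self.mode} mode requires an existing input_dir"
                )
        d = np.asarray(self.densities, dtype=float)
        if np.any(d <= 0) or np.any(d > 1) or np.any(np.diff(d) <= 0):
            raise ConfigurationError("densities must be strictly increasing in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def subset_network(conn: Connectome, node_list: list[int]) -> Connectome:
    """Induced sub-connectome on ``node_list``; mean distance recomputed."""
    n = conn.n_nodes
    nodes = list(node_list)
    for v in nodes:
        if not 0 <= v < n:
            raise ConfigurationError(f"unknown node id {v}")
    if len(set(nodes)) != len(nodes):
        raise ConfigurationError("node_list contains duplicates")
    idx = np.asarray(nodes, dtype=int)
    coords = conn.node_coords[idx] if conn.node_coords is not None else None
    dist = mean_node_distance(coords) if coords is not None else float("nan")
    return Connectome(
        W=conn.W[np.ix_(idx, idx)],
        node_coords=coords,
        mean_distance=dist,
        n_bins_aggregated=conn.n_bins_aggregated,
        subject_id=conn.subject_id,
    )


def age_quartiles(ages: np.ndarray) -> np.ndarray:
    """Quartile label (1-4) per subject by sample quartiles, ties to lower."""
    ages = np.asarray(ages, dtype=float)
    qs = np.quantile(ages, [0.25, 0.5, 0.75])
    return 1 + np.searchsorted(qs, ages, side="left").astype(int)


def _load_inputs(cfg: PipelineConfig):
    if cfg.mode == "synthetic":
        spec = SyntheticCohortSpec(master_seed=cfg.seed, **cfg.cohort)
        return generate_cohort(spec)
    if cfg.mode == "adjacency":
        return npio.read_cohort(cfg.input_dir)
    # timeseries mode: covariates table + per-subject arrays
    cov = npio.read_covariates(Path(cfg.input_dir) / "covariates.tsv")
    est = MultitaperWPLI(
        fmin=cfg.fmin, fmax=cfg.fmax, fstep=cfg.fstep, half_bandwidth=cfg.half_bandwidth
    )
    out = []
    for _, row in cov.iterrows():
        ts = npio.read_timeseries(cfg.input_dir, str(row["id"]))
        conn = est.transform(ts)
        from .types import SubjectRecord

        rec = SubjectRecord(
            id=str(row["id"]),
            age_years=float(row["age_years"]),
            sex=str(row["sex"]),
            handedness=str(row["handedness"]),
            mean_node_distance=conn.mean_distance,
        )
        out.append((rec, conn))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _load_inputs(cfg)
    records = [rec for rec, _ in cohort]
    connectomes = [conn for _, conn in cohort]
    if cfg.node_subset is not None:
        connectomes = [subset_network(c, cfg.node_subset) for c in connectomes]
        for rec, conn in zip(records, connectomes):
            rec.mean_node_distance = (
                conn.mean_distance if np.isfinite(conn.mean_distance)
                else rec.mean_node_distance
            )
    if cfg.mode == "synthetic":
        npio.write_cohort(list(zip(records, connectomes)), outdir / "cohort")

    cov = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "handedness": [r.handedness for r in records],
            "mean_node_distance": [r.mean_node_distance for r in records],
        }
    )
    cov["age_quartile"] = age_quartiles(cov["age_years"].to_numpy())
    cov.to_csv(outdir / "covariates.tsv", sep="\t", index=False)

    densities = np.asarray(cfg.densities, dtype=float)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n_subjects_input": len(records),
        "strategies": {},
    }

    for si, strategy in enumerate(cfg.strategies):
        logger.info("attack stage: strategy=%s", strategy)
        sim = AttackSimulator(
            strategy=strategy,
            densities=densities,
            n_iter=cfg.n_iter,
            seed=int(
                np.random.SeedSequence([cfg.seed, si]).generate_state(1)[0] % (2**31)
            ),
        )
        try:
            results = sim.transform(connectomes)
        except Exception as exc:  # noqa: BLE001 - stage failures must name the stage
            raise RuntimeError(f"attack stage failed for strategy {strategy}: {exc}") from exc
        npio.write_attack_results(results, outdir / f"percolation_{strategy}.tsv")

        # removal-frequency maps per age quartile at the map density
        maps = {}
        for q in (1, 2, 3, 4):
            ids = cov.loc[cov["age_quartile"] == q, "id"].tolist()
            if not ids:
                continue
            m = removal_frequency_map(results, cfg.map_density, subject_ids=ids)
            maps[q] = m.frequencies
        map_df = pd.DataFrame(
            {"node": np.arange(connectomes[0].n_nodes)}
            | {f"q{q}_fraction": v for q, v in maps.items()}
        )
        map_df.to_csv(outdir / f"removal_map_{strategy}.tsv", sep="\t", index=False)

        # functional sample (drop densities that are missing for any subject)
        values = np.stack([r.mean_percolation for r in results])
        ok = np.all(np.isfinite(values), axis=0)
        fs = FunctionalSample(
            densities=densities[ok],
            values=values[:, ok],
            subject_ids=[r.subject_id for r in results],
        )
        qc = FunctionalQC(
            spike_z=cfg.spike_z, ssr_z=cfg.ssr_z, trim_tol=cfg.trim_tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cleaned = qc.fit_transform(fs)
        rep = qc.report_
        pd.DataFrame(
            {
                "subject_id": [
                    s for s, m in zip(fs.subject_ids, rep.spike_mask) if m
                ],
                "lambda": rep.lambdas,
                "gcv": rep.gcvs,
                "ssr": rep.ssrs,
                "retained": rep.ssr_mask,
            }
        ).to_csv(outdir / f"qc_{strategy}.tsv", sep="\t", index=False)

        keep_ids = set(cleaned.subject_ids)
        x = build_design_matrix(cov[cov["id"].isin(keep_ids)])
        model = FunctionOnScalarRegression(
            densities=cleaned.densities, n_basis=cfg.n_basis, alpha=cfg.alpha
        )
        try:
            model.fit(x, cleaned)
            model.bootstrap_ci(
                n_boot=cfg.n_boot,
                seed=int(
                    np.random.SeedSequence([cfg.seed, si, 1]).generate_state(1)[0]
                    % (2**31)
                ),
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"model stage failed for strategy {strategy}: {exc}") from exc
        summary = model.significance_summary()

        beta_rows = []
        for j, name in enumerate(model.coef_names_):
            for k, d in enumerate(model.densities_):
                beta_rows.append(
                    {
                        "covariate": name,
                        "density": d,
                        "beta": model.coef_[j, k],
                        "ci_lo": model.ci_lower_[name][k],
                        "ci_hi": model.ci_upper_[name][k],
                    }
                )
        pd.DataFrame(beta_rows).to_csv(
            outdir / f"betas_{strategy}.tsv", sep="\t", index=False
        )

        strat_summary = {
            "f_overall": model.f_overall_,
            "p_overall": model.p_overall_,
            "r2_adjusted": model.r2_adjusted_,
            "functional_r2": model.functional_r2_,
            "functional_r2_covariates": model.functional_r2_covariates_,
            "f_covariates": model.f_covariates_,
            "p_covariates": model.p_covariates_,
            "semipartial": model.semipartial_,
            "significant": {
                row["covariate"]: {
                    "significant": bool(row["significant"]),
                    "direction": row["direction"],
                    "ranges": row["ranges"],
                }
                for _, row in summary.iterrows()
            },
            "trimmed_domain": list(rep.trimmed_domain),
            "n_dropped_spike": rep.n_dropped_spike,
            "n_dropped_ssr": rep.n_dropped_ssr,
            "n_retained": cleaned.n_subjects,
        }
        # subject-count conservation across QC stages
        assert (
            len(records)
            == strat_summary["n_retained"]
            + strat_summary["n_dropped_spike"]
            + strat_summary["n_dropped_ssr"]
        )
        (outdir / f"model_{strategy}.json").write_text(
            json.dumps(strat_summary, indent=2, default=float)
        )
        manifest["strategies"][strategy] = strat_summary

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
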