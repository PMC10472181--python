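"""End-to-end pipeline: simulate -> preprocess -> smooth -> FPCA -> fit -> cluster.

One seeded, configured run that persists every intermediate artifact so each
stage can also be re-run standalone from the previous stage's files.  Module
seeds are derived from the master seed by a counter-based scheme (stage index
as spawn key), so adding a stage never shifts earlier stages' random streams.
Identical config + master seed gives byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .clustering import kmeans_fit
from .fpca import FPCAModel, fit_fpca
from .outcome import NetConfig, StabilityFit, assemble_design, stability_selection
from .panel import AdherencePanel
from .preprocessing import preprocess
from .smoothing import SmoothingConfig, evaluate_curves, smooth_mission
from .synthetic import SimConfig, generate_cohort

logger = logging.getLogger("trajphen")

#: stage indices for counter-based seed derivation
_STAGE_SIM, _STAGE_NET, _STAGE_CLUSTER = 0, 3, 4


def derive_seed(master_seed: int, stage: int) -> int:
    """Deterministic per-stage seed (< 2**31) from the master seed."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(stage,)).generate_state(1)[0]) % (
        2**31
    )


@dataclass
class RunConfig:
    seed: int = 0
    sim: SimConfig | None = field(default_factory=SimConfig)
    adherence_path: str | None = None  # used instead of simulation when set
    covariates_path: str | None = None
    outcome_path: str | None = None
    threshold: float = 0.20
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    cutoff: float = 0.70
    max_k: int | None = 2
    eval_grid_size: int = 101
    net: NetConfig = field(default_factory=NetConfig)
    cluster_mission: str = "M5"
    cluster_k: int = 4
    cluster_n_init: int = 50

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["sim"] is not None:
            d["sim"]["obs_weeks"] = [float(w) for w in d["sim"]["obs_weeks"]]
            d["sim"]["outcome_betas"] = [float(b) for b in d["sim"]["outcome_betas"]]
        d["smoothing"]["lambda_grid"] = [float(g) for g in d["smoothing"]["lambda_grid"]]
        if isinstance(d["smoothing"]["lambda_smooth"], (int, float)):
            d["smoothing"]["lambda_smooth"] = float(d["smoothing"]["lambda_smooth"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            if sim.get("obs_weeks") is not None:
                sim["obs_weeks"] = tuple(sim["obs_weeks"])
            if sim.get("outcome_betas") is not None:
                sim["outcome_betas"] = np.asarray(sim["outcome_betas"], dtype=float)
            d["sim"] = SimConfig(**sim)
        if isinstance(d.get("smoothing"), dict):
            d["smoothing"] = SmoothingConfig(**d["smoothing"])
        if isinstance(d.get("net"), dict):
            d["net"] = NetConfig(**d["net"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config: RunConfig
    n_kept: int
    n_excluded: int
    lambda_smooth: dict[str, float]
    spectra: dict[str, dict]
    stability: StabilityFit
    cluster_sizes: dict[int, int]
    cluster_centroids: list[list[float]]
    fpca_models: dict[str, FPCAModel]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "n_kept": self.n_kept,
            "n_excluded": self.n_excluded,
            "lambda_smooth": self.lambda_smooth,
            "spectra": self.spectra,
            "log_lambda_median": self.stability.log_lambda_median,
            "selected_predictors": self.stability.table.index[
                self.stability.table["selected"]
            ].tolist(),
            "cluster_sizes": {str(k): v for k, v in self.cluster_sizes.items()},
            "cluster_centroids": self.cluster_centroids,
        }


def _load_inputs(config: RunConfig, out: Path):
    if config.adherence_path is not None:
        panel = tio.read_adherence(config.adherence_path)
        covariates = tio.read_covariates(config.covariates_path)
        outcome = tio.read_outcome(config.outcome_path)
        truth = None
    else:
        sim = dataclasses.replace(config.sim, seed=derive_seed(config.seed, _STAGE_SIM))
        panel, covariates, outcome, truth = generate_cohort(sim)
        tio.write_adherence(panel, out / "adherence.csv")
        tio.write_covariates(covariates, out / "covariates.csv")
        tio.write_outcome(outcome, out / "outcome.csv")
        tio.write_truth(truth, out / "truth.json")
    return panel, covariates, outcome, truth


def run_all(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute all stages in order, persisting artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate/load"
    try:
        panel, covariates, outcome, truth = _load_inputs(config, out)
        logger.info("stage=%s n=%d missions=%d elapsed=%.1fs", stage,
                    panel.n_participants, panel.n_missions, time.time() - t0)

        stage = "preprocess"
        clean, report = preprocess(panel, threshold=config.threshold)
        covariates = covariates.loc[clean.participant_ids]
        outcome = outcome.loc[clean.participant_ids]
        tio.write_adherence(clean, out / "adherence_clean.csv")
        tio.write_json(report.to_dict(), out / "filter_report.json")
        logger.info("stage=%s kept=%d excluded=%d", stage, len(report.kept_ids),
                    len(report.excluded_ids))

        stage = "smooth"
        grid = np.linspace(clean.obs_weeks[0], clean.obs_weeks[-1], config.eval_grid_size)
        curve_sets = {}
        for mission in clean.mission_ids:
            values, _ = clean.mission_matrix(mission)
            curves = smooth_mission(values, clean.obs_weeks, config.smoothing,
                                    mission=mission, participant_ids=clean.participant_ids)
            curve_sets[mission] = curves
            tio.write_curves(curves, out / f"curves_{mission}.json")
        lambdas = {m: c.lambda_smooth for m, c in curve_sets.items()}
        logger.info("stage=%s lambda=%s", stage, lambdas)

        stage = "fpca"
        models: dict[str, FPCAModel] = {}
        score_frames: dict[str, pd.DataFrame] = {}
        spectra: dict[str, dict] = {}
        for mission, curves in curve_sets.items():
            values = evaluate_curves(curves, grid)
            model = fit_fpca(values, grid, cutoff=config.cutoff, max_k=config.max_k,
                             mission=mission, participant_ids=clean.participant_ids)
            models[mission] = model
            kept = model.scores[:, : model.n_retained]
            score_frames[mission] = pd.DataFrame(
                kept,
                index=pd.Index(clean.participant_ids, name="participant_id"),
                columns=[f"pc{j + 1}" for j in range(model.n_retained)],
            )
            spectra[mission] = {
                "eigenvalues": model.eigenvalues[:5].tolist(),
                "variance_proportions": model.variance_proportions[:5].tolist(),
                "n_retained": model.n_retained,
            }
            eig = pd.DataFrame({"week": grid, "mean": model.mean_curve})
            for j in range(model.n_retained):
                eig[f"phi{j + 1}"] = model.eigenfunctions[j]
            eig.to_csv(out / f"eigenfunctions_{mission}.csv", index=False,
                       lineterminator="\n")
        scores_out = pd.concat(
            {m: df for m, df in score_frames.items()}, axis=1
        )
        scores_out.columns = [f"{m}_{c}" for m, c in scores_out.columns]
        scores_out.to_csv(out / "fpca_scores.csv", lineterminator="\n")
        tio.write_json(spectra, out / "spectrum.json")
        logger.info("stage=%s n_retained=%s", stage,
                    {m: s["n_retained"] for m, s in spectra.items()})

        stage = "fit"
        design = assemble_design(score_frames, covariates)
        net = dataclasses.replace(config.net, seed=derive_seed(config.seed, _STAGE_NET))
        fit = stability_selection(design, outcome, net)
        fit.table.to_csv(out / "stability.csv", lineterminator="\n")
        logger.info("stage=%s selected=%d log_lambda=%.4f", stage,
                    int(fit.table["selected"].sum()), fit.log_lambda_median)

        stage = "cluster"
        cl_scores = score_frames[config.cluster_mission]
        cluster = kmeans_fit(cl_scores, k=config.cluster_k, n_init=config.cluster_n_init,
                             seed=derive_seed(config.seed, _STAGE_CLUSTER))
        cluster.labels.to_frame().to_csv(out / "clusters.csv", lineterminator="\n")
        pd.DataFrame(
            cluster.centroids,
            index=pd.Index(range(1, cluster.k + 1), name="cluster"),
            columns=list(cl_scores.columns),
        ).to_csv(out / "centroids.csv", lineterminator="\n")
        logger.info("stage=%s sizes=%s wcss=%.3f", stage,
                    cluster.sizes().to_dict(), cluster.wcss)

        report_obj = RunReport(
            config=config,
            n_kept=len(report.kept_ids),
            n_excluded=len(report.excluded_ids),
            lambda_smooth=lambdas,
            spectra=spectra,
            stability=fit,
            cluster_sizes={int(k): int(v) for k, v in cluster.sizes().items()},
            cluster_centroids=cluster.centroids.tolist(),
            fpca_models=models,
        )
        tio.write_json(report_obj.to_dict(), out / "run_report.json")
        logger.info("done elapsed=%.1fs", time.time() - t0)
        return report_obj
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def demo_config(seed: int = 7, n_participants: int = 120) -> RunConfig:
    """Small demonstration configuration used by the analysis scripts.

    Stability-selection repetition counts are scaled to 200 repetitions and
    100 bootstraps, which keeps the demo quick while leaving the survival
    fractions and bootstrap quantiles well resolved.
    """
    return RunConfig(
        seed=seed,
        sim=SimConfig(n_participants=n_participants),
        net=NetConfig(n_reps=200, n_boot=100),
    )
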