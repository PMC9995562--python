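"""End-to-end orchestration: generate/load -> similarity -> fits -> factorial
-> epochs -> behavior, with tidy CSV outputs and a reproducibility manifest.

Every stage is a pure function of the loaded data plus the configuration;
rerunning with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import (
    behavior_correlation,
    compare_correlations_fisher,
    dprime,
    reinstatement_table,
)
from .design import EventDesign, build_all_model_matrices
from .epochs import EpochBins, epoch_tests, grand_mean, subject_epoch_means
from .event_types import condition_table, factorial_anova
from .fitting import compare_model_fits
from .similarity import encoding_similarity_matrix, recall_similarity_matrix
from .synth import GeneratorConfig, SyntheticDataset, generate_dataset, read_dataset

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "Diagnostics"]

STAGES = ("similarity", "fit", "factorial", "epochs", "behavior")


@dataclass
class PipelineConfig:
    """Run configuration; either a synthetic generator config or an input
    directory written in the package's CSV layout."""

    output_dir: str = "eventrsa_out"
    data_dir: str | None = None  # load instead of generate when set
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    rois: Sequence[str] | None = None  # default: all ROIs present
    stages: Sequence[str] = STAGES
    seed: int = 0
    alpha: float = 0.05
    schema_includes_same_context: bool = True
    include_diagonal: bool = True
    z_before_averaging: bool = True
    grand_mean_matched_only: bool = False
    behavior_alternative: str = "two-sided"
    behavior_roi: str = "HPC"
    epoch_bins: EpochBins = field(default_factory=EpochBins)
    include_series: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        if isinstance(self.epoch_bins, dict):
            self.epoch_bins = EpochBins(**self.epoch_bins)
        self.generator.seed = self.seed
        if self.rois is not None and len(self.rois) == 0:
            raise ValueError("ROI list is empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Diagnostics:
    passed: bool
    issues: list[str]
    warnings: list[str]


def validate_inputs(directory: str | Path) -> Diagnostics:
    """Check a data directory for completeness and degenerate patterns.

    Returns diagnostics rather than raising: missing files or shape
    mismatches are issues (fail); constant voxel patterns are warnings.
    """
    directory = Path(directory)
    issues: list[str] = []
    warnings: list[str] = []
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        return Diagnostics(False, [f"missing manifest: {manifest_path}"], [])
    manifest = json.loads(manifest_path.read_text())
    try:
        design = EventDesign.from_json(directory / "design.json")
    except FileNotFoundError:
        return Diagnostics(False, ["missing design.json"], [])
    E = design.n_events
    for roi in manifest["rois"]:
        for s in range(manifest["n_subjects"]):
            names = [
                f"patterns/sub-{s:02d}_roi-{roi}_run-{r + 1}.csv"
                for r in range(manifest["n_runs"])
            ] + [f"patterns/sub-{s:02d}_roi-{roi}_recall.csv"]
            for rel in names:
                path = directory / rel
                if not path.exists():
                    issues.append(f"missing pattern file: {rel}")
                    continue
                arr = pd.read_csv(path).to_numpy()
                if arr.shape[1] != E:
                    issues.append(f"{rel}: {arr.shape[1]} events, expected {E}")
                elif not np.isfinite(arr).all():
                    warnings.append(f"{rel}: non-finite voxel values")
                else:
                    const = np.ptp(arr, axis=0) == 0
                    for eid in np.flatnonzero(const):
                        warnings.append(
                            f"constant pattern: subject {s}, roi {roi}, "
                            f"file {rel}, event {eid}"
                        )
    if not (directory / "behavior.csv").exists():
        issues.append("missing behavior.csv")
    return Diagnostics(passed=not issues, issues=issues, warnings=warnings)


def _load_or_generate(config: PipelineConfig) -> SyntheticDataset:
    if config.data_dir is not None:
        diag = validate_inputs(config.data_dir)
        if not diag.passed:
            raise ValueError("input validation failed: " + "; ".join(diag.issues))
        return read_dataset(config.data_dir)
    return generate_dataset(config.generator, include_series=config.include_series)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write all outputs under
    ``config.output_dir``; returns the in-memory result bundle."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage_done(name):
        log.append({"stage": name, "elapsed_s": round(time.time() - t0, 3)})

    dataset = _load_or_generate(config)
    rois = list(config.rois) if config.rois is not None else list(dataset.rois)
    missing = set(rois) - set(dataset.rois)
    if missing:
        raise ValueError(f"ROIs not present in data: {sorted(missing)}")
    design = dataset.design
    models = build_all_model_matrices(
        design, schema_includes_same_context=config.schema_includes_same_context
    )
    stage_done("load")

    results: dict = {"design": design, "rois": rois}
    enc_sims: dict[str, list] = {}
    rec_sims: dict[str, list] = {}
    if "similarity" in config.stages:
        for roi in rois:
            enc_sims[roi] = [
                encoding_similarity_matrix(
                    dataset.encoding[roi][s],
                    z_before_averaging=config.z_before_averaging,
                    subject_id=s,
                    roi_name=roi,
                )
                for s in range(dataset.n_subjects)
            ]
            rec_sims[roi] = [
                recall_similarity_matrix(
                    dataset.encoding[roi][s],
                    dataset.recall[roi][s],
                    z_before_averaging=config.z_before_averaging,
                    subject_id=s,
                    roi_name=roi,
                )
                for s in range(dataset.n_subjects)
            ]
            simdir = out / "similarity" / roi
            simdir.mkdir(parents=True, exist_ok=True)
            for s in range(dataset.n_subjects):
                enc_sims[roi][s].to_csv(
                    simdir / f"sub-{s:02d}_encoding.csv", labels=design.labels
                )
                rec_sims[roi][s].to_csv(
                    simdir / f"sub-{s:02d}_recall.csv", labels=design.labels
                )
        results["encoding_similarity"] = enc_sims
        results["recall_similarity"] = rec_sims
        stage_done("similarity")

    if "fit" in config.stages:
        fit_rows, anova_rows, tukey_rows = [], [], []
        fits = {}
        for roi in rois:
            for source, sims in (("encoding", enc_sims[roi]), ("recall", rec_sims[roi])):
                res = compare_model_fits(
                    sims, models,
                    include_diagonal=config.include_diagonal, roi_name=roi,
                )
                fits[(roi, source)] = res
                for _, row in res.group_fits.iterrows():
                    fit_rows.append(
                        {"roi": roi, "source": source, "level": "group", **row}
                    )
                for model in res.subject_table.columns:
                    for s, z in res.subject_table[model].items():
                        fit_rows.append(
                            {"roi": roi, "source": source, "level": "subject",
                             "model": model, "subject": s, "z": z}
                        )
                anova_rows.append(
                    {"roi": roi, "source": source, "F": res.anova.F,
                     "df_num": res.anova.df_num, "df_den": res.anova.df_den,
                     "p": res.anova.p}
                )
                for _, row in res.pairwise.iterrows():
                    tukey_rows.append({"roi": roi, "source": source, **row})
        results["model_fits"] = fits
        pd.DataFrame(fit_rows).to_csv(out / "model_fits.csv", index=False)
        pd.DataFrame(anova_rows).to_csv(out / "model_fit_anova.csv", index=False)
        pd.DataFrame(tukey_rows).to_csv(out / "model_fit_tukey.csv", index=False)
        stage_done("fit")

    if "factorial" in config.stages:
        fact = {}
        cond_frames, eff_rows = [], []
        for roi in rois:
            table = condition_table(
                enc_sims[roi], design, include_diagonal=config.include_diagonal
            )
            res = factorial_anova(table)
            fact[roi] = res
            table.insert(0, "roi", roi)
            cond_frames.append(table)
            for _, row in res.effects.iterrows():
                eff_rows.append({"roi": roi, **row})
        results["factorial"] = fact
        pd.concat(cond_frames).to_csv(out / "condition_means.csv", index=False)
        pd.DataFrame(eff_rows).to_csv(out / "factorial_anova.csv", index=False)
        stage_done("factorial")

    if "epochs" in config.stages and dataset.series is not None:
        epoch_results = {}
        for roi in rois:
            em = pd.DataFrame(
                [
                    subject_epoch_means(dataset.series[roi][s], config.epoch_bins)
                    for s in range(dataset.n_subjects)
                ]
            )
            gm = pd.Series(
                [
                    grand_mean(
                        dataset.series[roi][s],
                        config.epoch_bins,
                        matched_only=config.grand_mean_matched_only,
                    )
                    for s in range(dataset.n_subjects)
                ]
            )
            epoch_results[roi] = epoch_tests(em, gm)
        results["epochs"] = epoch_results
        rows = []
        for roi, res in epoch_results.items():
            for _, r in res.t_tests.iterrows():
                rows.append({"roi": roi, **r})
        pd.DataFrame(rows).to_csv(out / "epoch_tests.csv", index=False)
        stage_done("epochs")

    if "behavior" in config.stages:
        roi = config.behavior_roi
        if roi not in rec_sims:
            raise ValueError(f"behavior ROI {roi!r} not among analyzed ROIs")
        summaries = reinstatement_table(rec_sims[roi])
        n = len(summaries)
        r_m, p_m = behavior_correlation(
            summaries, dataset.behavior, "matched",
            alternative=config.behavior_alternative,
        )
        r_mm, p_mm = behavior_correlation(
            summaries, dataset.behavior, "mismatched",
            alternative=config.behavior_alternative,
        )
        z, p_z = compare_correlations_fisher(r_m, n, r_mm, n)
        dprimes = dataset.behavior.apply(
            lambda b: dprime(b.hits, b.false_alarms, b.n_targets, b.n_lures), axis=1
        )
        behavior_stats = pd.DataFrame(
            [
                {"measure": "matched_r", "value": r_m, "p": p_m},
                {"measure": "mismatched_r", "value": r_mm, "p": p_mm},
                {"measure": "fisher_z_diff", "value": z, "p": p_z},
                {"measure": "mean_dprime", "value": float(dprimes.mean()), "p": np.nan},
            ]
        )
        results["behavior"] = behavior_stats
        summaries.to_csv(out / "reinstatement_summaries.csv", index=False)
        behavior_stats.to_csv(out / "behavior_stats.csv", index=False)
        stage_done("behavior")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": log,
        "rois": rois,
        "n_subjects": dataset.n_subjects,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
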