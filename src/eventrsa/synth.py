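"""Synthetic multivoxel pattern generator with planted representational structure.

Emulates per-subject, per-ROI voxel-by-event beta patterns for a
person-x-context event design: three encoding runs and one (weaker, noisier)
recall run, an optional TR-resolved beta series per event, and a behavioral
table (verifiable-detail totals and recognition hits/false alarms).

Generative model, per subject s and ROI:

    signal(event) = w_person * v_person + w_context * v_context
                  + w_schema * v_type + w_episodic * v_event
                  + w_global * v_subject
    encoding(run, event) = signal(event) + eps_run,   eps ~ N(0, noise_sd^2)
    recall(event) = recall_attenuation * signal(event) + eps_rec,
                    sd(eps_rec) = recall_noise_sd / f_s
    series(run, event, tr) = gain[tr] * signal(event) + eps_tr

where the component vectors v are independent unit-variance Gaussian voxel
vectors drawn fresh per subject and ROI (all analyses are within-subject, so
no cross-subject alignment is simulated), and f_s ~ LogNormal(0, 0.25) is a
subject-level recall-fidelity latent. The same latent drives behavior:

    details_s = round(behavior_base + behavior_coupling * f_s + N(0, 1)),

floored at zero, so the planted correlation between hippocampal
encoding-recall reinstatement and recalled detail counts is positive and
grows with ``behavior_coupling``.

Default ROI profiles plant the four representational signatures of the
cortico-hippocampal networks under study: posterior-medial (PM) -> context,
anterior-temporal (AT) -> person, medial prefrontal (mPFC) -> schema,
hippocampus (HPC) -> episodic. HPC additionally gets a boundary-weighted
TR gain profile (high at event onset/offset, low mid-event).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import EventDesign, build_default_design

__all__ = [
    "ROIProfile",
    "GeneratorConfig",
    "SyntheticDataset",
    "DEFAULT_ROI_PROFILES",
    "boundary_gain_profile",
    "flat_gain_profile",
    "generate_dataset",
    "generate_beta_series",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class ROIProfile:
    """Non-negative mixing weights for one ROI's planted components."""

    w_person: float = 0.0
    w_context: float = 0.0
    w_schema: float = 0.0
    w_episodic: float = 0.0
    w_global: float = 0.0

    def __post_init__(self) -> None:
        for name, w in self.as_dict().items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"{name} must be finite and non-negative")

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}


DEFAULT_ROI_PROFILES: dict[str, ROIProfile] = {
    "PM": ROIProfile(w_context=1.0, w_schema=0.4, w_episodic=0.4, w_global=0.2),
    "AT": ROIProfile(w_person=1.0, w_episodic=0.4, w_global=0.2),
    "mPFC": ROIProfile(w_schema=1.0, w_context=0.3, w_episodic=0.3, w_global=0.2),
    "HPC": ROIProfile(w_episodic=1.0, w_context=0.4, w_global=0.2),
}


def flat_gain_profile(n_tr: int = 33, gain: float = 1.0) -> np.ndarray:
    return np.full(n_tr, gain)


def boundary_gain_profile(
    n_tr: int = 33,
    title_trs: int = 4,
    boundary_len: int = 7,
    boundary_gain: float = 1.0,
    mid_gain: float = 0.2,
    title_gain: float = 0.2,
) -> np.ndarray:
    """High signal gain at event onset/offset TRs, low mid-event.

    With defaults this puts full gain on TRs 5-11 and 27-33 (1-based) and
    attenuated gain in between, emulating boundary-weighted hippocampal
    encoding.
    """
    g = np.full(n_tr, mid_gain)
    g[:title_trs] = title_gain
    g[title_trs : title_trs + boundary_len] = boundary_gain
    g[n_tr - boundary_len :] = boundary_gain
    return g


def _default_epoch_gain(rois, n_tr: int, title_trs: int) -> dict[str, np.ndarray]:
    return {
        roi: boundary_gain_profile(n_tr, title_trs)
        if roi == "HPC"
        else flat_gain_profile(n_tr)
        for roi in rois
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the design being emulated: 20 subjects, 8 events
    (2 persons x 4 contexts), 3 encoding runs plus 1 recall run, ~33 TRs per
    40-s event (TR = 1.22 s) of which the first 4 cover the title screen.
    Effect sizes (mixing weights, noise) are not published for the original
    data; the defaults give signal-to-noise at which the planted structure is
    comfortably recoverable with 20 subjects.
    """

    n_subjects: int = 20
    n_voxels: int = 500
    n_runs: int = 3
    roi_profiles: Mapping[str, ROIProfile] = field(
        default_factory=lambda: dict(DEFAULT_ROI_PROFILES)
    )
    noise_sd: float = 1.0
    recall_attenuation: float = 0.7
    recall_noise_sd: float = 1.4
    n_tr_per_event: int = 33
    title_trs: int = 4
    epoch_gain: Mapping[str, np.ndarray] | None = None
    series_noise_sd: float = 1.0
    fidelity_sigma: float = 0.25
    behavior_base: float = 90.0
    behavior_coupling: float = 20.0
    n_recognition_targets: int = 24
    n_recognition_lures: int = 24
    dprime_scale: float = 1.5
    seed: int = 0
    design: EventDesign = field(default_factory=build_default_design)

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_voxels", "n_runs", "n_tr_per_event"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.roi_profiles:
            raise ValueError("at least one ROI profile is required")
        self.roi_profiles = {
            k: (v if isinstance(v, ROIProfile) else ROIProfile(**v))
            for k, v in self.roi_profiles.items()
        }
        if not 0 <= self.recall_attenuation <= 1:
            raise ValueError("recall_attenuation must be in [0, 1]")
        if self.noise_sd < 0 or self.recall_noise_sd < 0 or self.series_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.epoch_gain is not None:
            for roi, g in self.epoch_gain.items():
                if len(np.asarray(g)) != self.n_tr_per_event:
                    raise ValueError(
                        f"epoch_gain[{roi!r}] length != n_tr_per_event"
                    )

    def resolved_epoch_gain(self) -> dict[str, np.ndarray]:
        if self.epoch_gain is not None:
            return {k: np.asarray(v, dtype=float) for k, v in self.epoch_gain.items()}
        return _default_epoch_gain(
            self.roi_profiles, self.n_tr_per_event, self.title_trs
        )


@dataclass
class SyntheticDataset:
    """Generated patterns plus ground truth.

    encoding[roi] : (n_subjects, n_runs, n_events, n_voxels)
    recall[roi]   : (n_subjects, n_events, n_voxels)
    series[roi]   : (n_subjects, n_runs, n_events, n_tr, n_voxels) or absent
    behavior      : per-subject detail totals and recognition counts
    truth         : config echo plus per-subject fidelity latents
    """

    design: EventDesign
    encoding: dict[str, np.ndarray]
    recall: dict[str, np.ndarray]
    behavior: pd.DataFrame
    truth: dict
    series: dict[str, np.ndarray] | None = None

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.encoding)

    @property
    def n_subjects(self) -> int:
        return next(iter(self.encoding.values())).shape[0]


def _subject_signals(
    rng: np.random.Generator, config: GeneratorConfig
) -> dict[str, np.ndarray]:
    """Noise-free event signal patterns (n_events, n_voxels) per ROI."""
    design = config.design
    V = config.n_voxels
    persons = {p: rng.standard_normal(V) for p in design.persons}
    contexts = {c: rng.standard_normal(V) for c in design.contexts}
    ctypes = {t: rng.standard_normal(V) for t in design.context_types}
    events = {e.event_id: rng.standard_normal(V) for e in design.events}
    out = {}
    for roi, prof in config.roi_profiles.items():
        v_subject = rng.standard_normal(V)
        sig = np.empty((design.n_events, V))
        for e in design.events:
            sig[e.event_id] = (
                prof.w_person * persons[e.person]
                + prof.w_context * contexts[e.context]
                + prof.w_schema * ctypes[e.context_type]
                + prof.w_episodic * events[e.event_id]
                + prof.w_global * v_subject
            )
        out[roi] = sig
    return out


def generate_dataset(
    config: GeneratorConfig, *, include_series: bool = False
) -> SyntheticDataset:
    """Generate a full multi-subject dataset.

    Bit-reproducible for a fixed seed. The seed stream is forked per subject
    (one child stream each), so increasing ``n_subjects`` leaves earlier
    subjects' data untouched.
    """
    design = config.design
    E, V, R = design.n_events, config.n_voxels, config.n_runs
    rois = list(config.roi_profiles)
    gains = config.resolved_epoch_gain() if include_series else None

    encoding = {roi: np.empty((config.n_subjects, R, E, V)) for roi in rois}
    recall = {roi: np.empty((config.n_subjects, E, V)) for roi in rois}
    series = (
        {roi: np.empty((config.n_subjects, R, E, config.n_tr_per_event, V)) for roi in rois}
        if include_series
        else None
    )

    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    behavior_rng = np.random.default_rng(root.spawn(1)[0])

    fidelity = np.empty(config.n_subjects)
    for s, seq in enumerate(subject_seeds):
        rng = np.random.default_rng(seq)
        fidelity[s] = np.exp(rng.normal(0.0, config.fidelity_sigma))
        signals = _subject_signals(rng, config)
        for roi in rois:
            sig = signals[roi]
            encoding[roi][s] = sig[None, :, :] + rng.normal(
                0.0, config.noise_sd, size=(R, E, V)
            )
            recall_sd = config.recall_noise_sd / fidelity[s]
            recall[roi][s] = config.recall_attenuation * sig + rng.normal(
                0.0, recall_sd, size=(E, V)
            )
            if include_series:
                g = gains[roi]  # (n_tr,)
                series[roi][s] = g[None, None, :, None] * sig[None, :, None, :] + (
                    rng.normal(
                        0.0,
                        config.series_noise_sd,
                        size=(R, E, config.n_tr_per_event, V),
                    )
                )

    behavior = _generate_behavior(behavior_rng, config, fidelity)
    truth = {
        "seed": config.seed,
        "fidelity": fidelity.tolist(),
        "roi_profiles": {k: v.as_dict() for k, v in config.roi_profiles.items()},
        "noise_sd": config.noise_sd,
        "recall_attenuation": config.recall_attenuation,
        "recall_noise_sd": config.recall_noise_sd,
        "behavior_base": config.behavior_base,
        "behavior_coupling": config.behavior_coupling,
    }
    return SyntheticDataset(
        design=design,
        encoding=encoding,
        recall=recall,
        behavior=behavior,
        truth=truth,
        series=series,
    )


def _generate_behavior(
    rng: np.random.Generator, config: GeneratorConfig, fidelity: np.ndarray
) -> pd.DataFrame:
    n = len(fidelity)
    details = np.maximum(
        0,
        np.rint(
            config.behavior_base
            + config.behavior_coupling * fidelity
            + rng.normal(0.0, 1.0, size=n)
        ),
    ).astype(int)
    # recognition: discriminability scales with the same fidelity latent
    dprime = config.dprime_scale * fidelity
    from scipy.stats import norm

    hit_p = norm.cdf(dprime / 2)
    fa_p = norm.cdf(-dprime / 2)
    hits = rng.binomial(config.n_recognition_targets, hit_p)
    fas = rng.binomial(config.n_recognition_lures, fa_p)
    return pd.DataFrame(
        {
            "subject": np.arange(n),
            "details_total": details,
            "hits": hits,
            "false_alarms": fas,
            "n_targets": config.n_recognition_targets,
            "n_lures": config.n_recognition_lures,
        }
    )


def generate_beta_series(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """TR-resolved beta series only (the ``series`` component)."""
    return generate_dataset(config, include_series=True).series


# ---------------------------------------------------------------------------
# on-disk layout: one CSV matrix (voxels x events) per subject/roi/run, plus
# recall patterns, behavior table, truth and a manifest

def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write a dataset as a tree of plain-text files; returns the manifest path.

    Layout::

        <dir>/design.json
        <dir>/patterns/sub-<s>_roi-<roi>_run-<r>.csv    (voxels x events)
        <dir>/patterns/sub-<s>_roi-<roi>_recall.csv
        <dir>/behavior.csv
        <dir>/truth.json
        <dir>/manifest.json
    """
    directory = Path(directory)
    (directory / "patterns").mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    dataset.design.to_json(directory / "design.json")
    files.append("design.json")

    cols = [f"event{eid}" for eid in range(dataset.design.n_events)]
    for roi, arr in dataset.encoding.items():
        n_subjects, n_runs = arr.shape[:2]
        for s in range(n_subjects):
            for r in range(n_runs):
                rel = f"patterns/sub-{s:02d}_roi-{roi}_run-{r + 1}.csv"
                pd.DataFrame(arr[s, r].T, columns=cols).to_csv(
                    directory / rel, index=False
                )
                files.append(rel)
            rel = f"patterns/sub-{s:02d}_roi-{roi}_recall.csv"
            pd.DataFrame(dataset.recall[roi][s].T, columns=cols).to_csv(
                directory / rel, index=False
            )
            files.append(rel)

    dataset.behavior.to_csv(directory / "behavior.csv", index=False)
    files.append("behavior.csv")
    (directory / "truth.json").write_text(json.dumps(dataset.truth, indent=2))
    files.append("truth.json")

    manifest = {
        "rois": list(dataset.rois),
        "n_subjects": dataset.n_subjects,
        "n_runs": int(next(iter(dataset.encoding.values())).shape[1]),
        "n_events": dataset.design.n_events,
        "files": sorted(files),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read back a tree written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    design = EventDesign.from_json(directory / "design.json")
    E = design.n_events
    n_subjects, n_runs = manifest["n_subjects"], manifest["n_runs"]

    encoding: dict[str, np.ndarray] = {}
    recall: dict[str, np.ndarray] = {}
    for roi in manifest["rois"]:
        enc_runs = []
        rec_subjects = []
        for s in range(n_subjects):
            runs = []
            for r in range(n_runs):
                df = pd.read_csv(
                    directory / f"patterns/sub-{s:02d}_roi-{roi}_run-{r + 1}.csv"
                )
                runs.append(df.to_numpy().T)  # -> (events, voxels)
            enc_runs.append(runs)
            rec = pd.read_csv(directory / f"patterns/sub-{s:02d}_roi-{roi}_recall.csv")
            rec_subjects.append(rec.to_numpy().T)
        encoding[roi] = np.asarray(enc_runs)
        recall[roi] = np.asarray(rec_subjects)
        if encoding[roi].shape[2] != E:
            raise ValueError(f"ROI {roi}: event count mismatch with design")

    behavior = pd.read_csv(directory / "behavior.csv")
    truth = json.loads((directory / "truth.json").read_text())
    return SyntheticDataset(
        design=design,
        encoding=encoding,
        recall=recall,
        behavior=behavior,
        truth=truth,
    )
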