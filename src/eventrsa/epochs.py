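"""TR-resolved same-event similarity and temporal-epoch statistics.

A beta series models one beta pattern per TR of each event rather than one
per event. Each TR's pattern in one encoding run is correlated with the
pattern at the same TR of the same event in the other runs, giving a per-TR
Fisher-z similarity trace. After dropping the leading title-screen TRs
(default 4 of 33), the trace is binned into event Onset (first 7 TRs),
Mid-event (middle 15) and Offset (last 7). Epoch means are tested per
subject against that subject's grand mean — the TR-wise cross-run similarity
pooled over all event pairs and runs — followed by a one-way
repeated-measures ANOVA over the three epochs with Tukey HSD.

TR slicing is stated 1-based and inclusive in all documentation: with the
defaults, onset = TRs 5-11, mid = 12-26, offset = 27-33.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import RMAnovaResult, rm_anova_fits, tukey_hsd
from .similarity import fisher_z, _rowwise_corr

__all__ = [
    "EpochBins",
    "trwise_same_event_similarity",
    "subject_epoch_means",
    "bin_epochs",
    "grand_mean",
    "EpochTestResult",
    "epoch_tests",
]

EPOCH_NAMES = ("onset", "mid", "offset")


@dataclass(frozen=True)
class EpochBins:
    """Epoch lengths in TRs; title TRs are discarded before binning."""

    title: int = 4
    onset: int = 7
    mid: int = 15
    offset: int = 7

    def __post_init__(self) -> None:
        if min(self.onset, self.mid, self.offset) < 1 or self.title < 0:
            raise ValueError("bin lengths must be >= 1 (title >= 0)")

    @property
    def n_tr(self) -> int:
        return self.title + self.onset + self.mid + self.offset

    def slices(self) -> dict[str, slice]:
        o0 = self.title
        m0 = o0 + self.onset
        f0 = m0 + self.mid
        return {
            "onset": slice(o0, m0),
            "mid": slice(m0, f0),
            "offset": slice(f0, f0 + self.offset),
        }


def trwise_same_event_similarity(series: np.ndarray) -> np.ndarray:
    """Per-TR cross-run same-event similarity trace for one event.

    ``series`` is (n_runs, n_tr, n_voxels) for one subject/ROI/event. For
    each TR, the patterns at that TR are correlated across every unordered
    run pair and the Fisher-z values averaged; returns a length-n_tr trace.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 3:
        raise ValueError("expected series shaped (runs, trs, voxels)")
    n_runs, n_tr, _ = series.shape
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    pairs = list(combinations(range(n_runs), 2))
    trace = np.zeros(n_tr)
    for a, b in pairs:
        for t in range(n_tr):
            r = _rowwise_corr(series[a, t : t + 1], series[b, t : t + 1])[0, 0]
            trace[t] += fisher_z(r)
    return trace / len(pairs)


def _trwise_corr_all_events(series_a, series_b) -> np.ndarray:
    """(E, E, n_tr) TR-matched Fisher-z correlations between two runs."""
    n_events, n_tr, _ = series_a.shape
    out = np.empty((n_events, n_events, n_tr))
    for t in range(n_tr):
        out[:, :, t] = fisher_z(_rowwise_corr(series_a[:, t], series_b[:, t]))
    return out


def subject_epoch_means(
    series: np.ndarray, bins: EpochBins = EpochBins()
) -> dict[str, float]:
    """Epoch means of the same-event trace averaged over events.

    ``series`` is (n_runs, n_events, n_tr, n_voxels) for one subject/ROI.
    """
    series = np.asarray(series, dtype=float)
    n_runs, n_events, n_tr, _ = series.shape
    if n_tr != bins.n_tr:
        raise ValueError(f"series has {n_tr} TRs but bins describe {bins.n_tr}")
    traces = np.stack(
        [trwise_same_event_similarity(series[:, e]) for e in range(n_events)]
    )
    mean_trace = traces.mean(axis=0)
    return dict(zip(EPOCH_NAMES, bin_epochs(mean_trace, bins)))


def bin_epochs(
    trace: np.ndarray, bins: EpochBins = EpochBins()
) -> tuple[float, float, float]:
    """(onset_mean, mid_mean, offset_mean) of a per-TR trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape != (bins.n_tr,):
        raise ValueError(
            f"trace length {trace.size} does not match bins ({bins.n_tr} TRs)"
        )
    s = bins.slices()
    return (
        float(trace[s["onset"]].mean()),
        float(trace[s["mid"]].mean()),
        float(trace[s["offset"]].mean()),
    )


def grand_mean(
    series: np.ndarray,
    bins: EpochBins = EpochBins(),
    *,
    matched_only: bool = False,
) -> float:
    """Baseline TR-wise cross-run similarity for one subject/ROI.

    Pools the TR-matched Fisher-z correlations over all run pairs, all
    non-title TRs and — by default — all event pairs, matched and mismatched
    ("across all events"). ``matched_only`` restricts to same-event pairs.
    """
    series = np.asarray(series, dtype=float)
    n_runs, n_events, n_tr, _ = series.shape
    keep = np.zeros(n_tr, dtype=bool)
    keep[bins.title :] = True
    total, count = 0.0, 0
    for a, b in combinations(range(n_runs), 2):
        z = _trwise_corr_all_events(series[a], series[b])[:, :, keep]
        if matched_only:
            idx = np.arange(n_events)
            z = z[idx, idx]
        total += z.sum()
        count += z.size
    return total / count


@dataclass
class EpochTestResult:
    epoch_means: pd.DataFrame  # subject x epoch
    grand_means: pd.Series  # per subject
    t_tests: pd.DataFrame  # epoch, t, df, p (vs. subject grand means)
    anova: RMAnovaResult
    pairwise: pd.DataFrame


def epoch_tests(
    epoch_means: pd.DataFrame, grand_means: pd.Series
) -> EpochTestResult:
    """Per-epoch one-sample t-tests against subject grand means, plus a
    repeated-measures ANOVA over epochs with Tukey HSD.

    ``epoch_means`` is a subject x {onset, mid, offset} table;
    ``grand_means`` one baseline value per subject (paired difference, since
    the baseline varies by subject). t df = n - 1; ANOVA df = (2, 2(n - 1)).
    """
    epoch_means = epoch_means[list(EPOCH_NAMES)]
    if len(epoch_means) != len(grand_means):
        raise ValueError("epoch table and grand means differ in subject count")
    n = len(epoch_means)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    gm = np.asarray(grand_means, dtype=float)
    for epoch in EPOCH_NAMES:
        diff = epoch_means[epoch].to_numpy(dtype=float) - gm
        if np.ptp(diff) == 0:  # zero-variance difference: t = 0 or +-inf
            t = 0.0 if diff[0] == 0 else np.sign(diff[0]) * np.inf
            p = 1.0 if diff[0] == 0 else 0.0
        else:
            t, p = stats.ttest_1samp(diff, 0.0)
        rows.append({"epoch": epoch, "t": float(t), "df": n - 1, "p": float(p)})
    anova = rm_anova_fits(epoch_means)
    pairwise = tukey_hsd(epoch_means.mean(axis=0), anova.ms_error, anova.df_den, n)
    return EpochTestResult(
        epoch_means=epoch_means,
        grand_means=pd.Series(gm, index=epoch_means.index),
        t_tests=pd.DataFrame(rows),
        anova=anova,
        pairwise=pairwise,
    )
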