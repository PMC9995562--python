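"""Encoding-recall reinstatement vs. recall behavior, and recognition d'.

Per subject, matched reinstatement is the mean Fisher-z similarity of the
diagonal of the encoding-recall matrix (each event at encoding vs. the same
event at recall) and mismatched reinstatement the mean of the off-diagonal
cells. Subject-level reinstatement is correlated with the total number of
verifiable details recalled; matched and mismatched correlations are
compared with the Fisher r-to-z test. Recognition performance is summarized
as d' = z(hit rate) - z(false-alarm rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import SimilarityMatrix

__all__ = [
    "ReinstatementSummary",
    "reinstatement_summary",
    "reinstatement_table",
    "behavior_correlation",
    "compare_correlations_fisher",
    "compare_correlations_dependent",
    "dprime",
]


@dataclass(frozen=True)
class ReinstatementSummary:
    matched_mean: float
    mismatched_mean: float


def reinstatement_summary(sim) -> ReinstatementSummary:
    """Matched (diagonal) and mismatched (off-diagonal) mean reinstatement
    from an E x E encoding-recall similarity matrix."""
    values = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square encoding-recall matrix")
    E = values.shape[0]
    diag = np.diagonal(values)
    off = values[~np.eye(E, dtype=bool)]
    return ReinstatementSummary(
        matched_mean=float(diag.mean()), mismatched_mean=float(off.mean())
    )


def reinstatement_table(sims_per_subject) -> pd.DataFrame:
    rows = []
    for s, sim in enumerate(sims_per_subject):
        summ = reinstatement_summary(sim)
        sid = getattr(sim, "subject_id", None)
        rows.append(
            {
                "subject": sid if sid is not None else s,
                "matched_mean": summ.matched_mean,
                "mismatched_mean": summ.mismatched_mean,
            }
        )
    return pd.DataFrame(rows)


def behavior_correlation(
    summaries: pd.DataFrame,
    behavior: pd.DataFrame,
    which: str = "matched",
    *,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Pearson correlation between per-subject reinstatement and detail
    totals; two-tailed t-based p by default (``alternative`` passes through
    to a one-tailed test if requested)."""
    if which not in ("matched", "mismatched"):
        raise ValueError("which must be 'matched' or 'mismatched'")
    merged = summaries.merge(behavior, on="subject")
    if len(merged) < 4:
        raise ValueError("need at least 4 subjects")
    x = merged[f"{which}_mean"].to_numpy(dtype=float)
    y = merged["details_total"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("detail counts have zero variance")
    r, p = stats.pearsonr(x, y, alternative=alternative)
    return float(r), float(p)


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed
    normal p. Antisymmetric in (r1, r2).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_correlations_dependent(
    r1: float, r2: float, r12: float, n: int
) -> tuple[float, float]:
    """Steiger's test for two correlations sharing one variable in one
    sample (the matched and mismatched correlations come from the same
    subjects); ``r12`` is the correlation between the two predictors.
    Non-default alternative to :func:`compare_correlations_fisher`."""
    if n <= 3:
        raise ValueError("need n > 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rm2 = (r1**2 + r2**2) / 2
    f = min((1 - r12) / (2 * (1 - rm2)), 1.0)
    h = (1 - f * rm2) / (1 - rm2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2 * (1 - r12) * h))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def dprime(
    hits: int, false_alarms: int, n_targets: int, n_lures: int
) -> float:
    """Recognition d' = z(hit rate) - z(false-alarm rate).

    Extreme rates (0 or 1) are replaced by 1/(2N) and 1 - 1/(2N) so the
    normal quantiles stay finite.
    """
    if n_targets < 1 or n_lures < 1:
        raise ValueError("n_targets and n_lures must be >= 1")
    if not (0 <= hits <= n_targets and 0 <= false_alarms <= n_lures):
        raise ValueError("counts out of range")
    hr = hits / n_targets
    far = false_alarms / n_lures
    hr = min(max(hr, 1 / (2 * n_targets)), 1 - 1 / (2 * n_targets))
    far = min(max(far, 1 / (2 * n_lures)), 1 - 1 / (2 * n_lures))
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))
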