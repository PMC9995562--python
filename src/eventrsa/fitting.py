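"""Model-matrix fits and their statistical comparison.

A similarity matrix's fit to a binary hypothesis matrix is the point-biserial
correlation (a Pearson correlation against a 0/1 vector) over the lower half
of the matrix including the diagonal. Fits are computed at the group level
(element-wise mean matrix across subjects, then one correlation) and per
subject (Fisher-z-transformed fits aggregated across subjects), with a
one-way repeated-measures ANOVA over models and Tukey HSD pairwise contrasts
using the repeated-measures error term.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelMatrix, lower_half_vector
from .similarity import SimilarityMatrix, fisher_z

__all__ = [
    "PointBiserialFit",
    "RMAnovaResult",
    "ModelFitResult",
    "point_biserial_fit",
    "group_fit",
    "subject_fit_table",
    "rm_anova_fits",
    "tukey_hsd",
    "compare_model_fits",
]


def _sim_values(sim) -> np.ndarray:
    return sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)


@dataclass(frozen=True)
class PointBiserialFit:
    r: float
    p: float
    n_cells: int


def point_biserial_fit(
    sim, model: ModelMatrix, *, include_diagonal: bool = True
) -> PointBiserialFit:
    """Point-biserial correlation between a similarity matrix and a model.

    Both matrices are vectorized over the lower half (row-major, i >= j);
    the two-tailed p comes from the t distribution with n_cells - 2 df,
    treating matrix cells as observations (descriptive, since cells from one
    subject are not strictly independent).
    """
    values = _sim_values(sim)
    if values.shape != model.values.shape:
        raise ValueError("similarity and model matrices differ in size")
    y = lower_half_vector(values, include_diagonal=include_diagonal)
    x = lower_half_vector(model.values, include_diagonal=include_diagonal).astype(float)
    if np.all(x == x[0]):
        raise ValueError(
            f"model {model.kind!r} vectorizes to a constant; "
            "a point-biserial fit needs both classes present"
        )
    if np.ptp(y) == 0:
        # constant similarity vector: zero covariance with any model
        return PointBiserialFit(r=0.0, p=1.0, n_cells=len(x))
    r, p = stats.pearsonr(x, y)
    return PointBiserialFit(r=float(r), p=float(p), n_cells=len(x))


def group_fit(
    sims: Sequence, model: ModelMatrix, *, include_diagonal: bool = True
) -> PointBiserialFit:
    """Fit on the element-wise mean similarity matrix across subjects."""
    if len(sims) < 1:
        raise ValueError("need at least one similarity matrix")
    arrs = [_sim_values(s) for s in sims]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("similarity matrices differ in shape across subjects")
    return point_biserial_fit(
        np.mean(arrs, axis=0), model, include_diagonal=include_diagonal
    )


def subject_fit_table(
    sims_per_subject: Sequence,
    models: Mapping[str, ModelMatrix],
    *,
    include_diagonal: bool = True,
) -> pd.DataFrame:
    """Per-subject Fisher-z-transformed point-biserial fits.

    Returns a (n_subjects x n_models) DataFrame of atanh(r) values; column
    order follows the ``models`` mapping.
    """
    rows = []
    for sim in sims_per_subject:
        rows.append(
            {
                name: fisher_z(
                    point_biserial_fit(sim, m, include_diagonal=include_diagonal).r
                )
                for name, m in models.items()
            }
        )
    table = pd.DataFrame(rows)
    table.index.name = "subject"
    return table


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ms_error: float
    n_subjects: int
    means: pd.Series


def rm_anova_fits(table: pd.DataFrame) -> RMAnovaResult:
    """One-way repeated-measures ANOVA over the columns of a subject x
    condition table.

    Subjects are the repeated factor: the subject sum of squares is removed
    and the error term is the subject-by-condition interaction with
    (m - 1)(n - 1) degrees of freedom.
    """
    if table.isna().any().any():
        raise ValueError("missing cells in repeated-measures table")
    data = table.to_numpy(dtype=float)
    n, m = data.shape
    if n < 2 or m < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = m * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_num, df_den = m - 1, (m - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    tol = 1e-12 * max(ss_total, 1.0)  # round-off floor for degenerate tables
    if ms_err > tol:
        F = ms_cond / ms_err
        p = float(stats.f.sf(F, df_num, df_den))
    elif ms_cond <= tol:  # fully degenerate table (identical columns)
        F, p = 0.0, 1.0
    else:
        F, p = np.inf, 0.0
    return RMAnovaResult(
        F=float(F),
        df_num=df_num,
        df_den=df_den,
        p=p,
        ms_error=float(ms_err),
        n_subjects=n,
        means=table.mean(axis=0),
    )


def tukey_hsd(
    means: Mapping[str, float] | pd.Series,
    ms_error: float,
    df_error: int,
    n_per_group: int,
) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts from cell means and an ANOVA error term.

    The studentized-range statistic for groups i, j is
    q = |mean_i - mean_j| / sqrt(ms_error / n_per_group) and the adjusted p
    is the survival function of the studentized range distribution with k
    groups and ``df_error`` degrees of freedom. Pass the repeated-measures
    error term to match a repeated-measures ANOVA.
    """
    means = pd.Series(means)
    k = len(means)
    if k < 3:
        raise ValueError("Tukey HSD needs at least 3 groups")
    se = np.sqrt(ms_error / n_per_group)
    rows = []
    for a, b in combinations(means.index, 2):
        diff = means[a] - means[b]
        q = np.abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_error)) if se > 0 else 0.0
        rows.append(
            {"group_a": a, "group_b": b, "mean_diff": float(diff), "q": float(q),
             "p_adj": min(p, 1.0)}
        )
    return pd.DataFrame(rows)


@dataclass
class ModelFitResult:
    """Bundle of group fits, per-subject fits, and their comparison."""

    group_fits: pd.DataFrame  # model, r, p, n_cells
    subject_table: pd.DataFrame  # subject x model (Fisher z)
    anova: RMAnovaResult
    pairwise: pd.DataFrame  # Tukey HSD over models
    roi_name: str | None = None

    @property
    def winning_model(self) -> str:
        return str(self.group_fits.set_index("model")["r"].idxmax())


def compare_model_fits(
    sims: Sequence,
    models: Mapping[str, ModelMatrix],
    *,
    include_diagonal: bool = True,
    roi_name: str | None = None,
) -> ModelFitResult:
    """Full model-comparison pipeline for one ROI across subjects."""
    grows = []
    for name, m in models.items():
        fit = group_fit(sims, m, include_diagonal=include_diagonal)
        grows.append({"model": name, "r": fit.r, "p": fit.p, "n_cells": fit.n_cells})
    table = subject_fit_table(sims, models, include_diagonal=include_diagonal)
    anova = rm_anova_fits(table)
    pairwise = tukey_hsd(
        table.mean(axis=0), anova.ms_error, anova.df_den, len(table)
    )
    return ModelFitResult(
        group_fits=pd.DataFrame(grows),
        subject_table=table,
        anova=anova,
        pairwise=pairwise,
        roi_name=roi_name,
    )
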