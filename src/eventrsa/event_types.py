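"""Factorial event-type analysis of pattern similarity.

Every event pair is classified by whether the two events share their central
person (same vs. different) and how their contexts relate (same context,
similar = different contexts of the same type, or different types). Lower-half
similarity cells (including the diagonal, whose cross-run same-event cells
form the (same person, same context) condition) are averaged per condition
and subject, and the subject-condition means enter a two-way
person x context ANOVA with Tukey HSD contrasts on the context factor.

For the default 8-event design the 36 lower-half cells partition into the
2 x 3 = 6 conditions as 8 + 4 + 8 + 4 + 4 + 8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import EventDesign, lower_half_vector
from .fitting import tukey_hsd
from .similarity import SimilarityMatrix

__all__ = [
    "PERSON_LEVELS",
    "CONTEXT_LEVELS",
    "classify_pair",
    "condition_means",
    "condition_table",
    "FactorialAnovaResult",
    "factorial_anova",
]

PERSON_LEVELS = ("same", "different")
CONTEXT_LEVELS = ("same", "similar", "different")


def classify_pair(design: EventDesign, i: int, j: int) -> tuple[str, str]:
    """(person_factor, context_factor) for an event pair; i == j allowed
    (the cross-run same-event cell classifies as (same, same))."""
    a, b = design.events[i], design.events[j]
    person = "same" if a.person == b.person else "different"
    if a.context == b.context:
        context = "same"
    elif a.context_type == b.context_type:
        context = "similar"
    else:
        context = "different"
    return person, context


def condition_means(
    sim, design: EventDesign, *, include_diagonal: bool = True
) -> pd.DataFrame:
    """Mean lower-half similarity per (person, context) condition for one
    subject. Returns 6 rows with columns person_factor, context_factor,
    mean_z, n_cells."""
    values = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    E = design.n_events
    if values.shape != (E, E):
        raise ValueError("similarity matrix does not match the design size")
    k = 0 if include_diagonal else -1
    rows_i, cols_j = np.tril_indices(E, k=k)
    cells = values[rows_i, cols_j]
    labels = [classify_pair(design, int(i), int(j)) for i, j in zip(rows_i, cols_j)]
    df = pd.DataFrame(
        {
            "person_factor": [l[0] for l in labels],
            "context_factor": [l[1] for l in labels],
            "z": cells,
        }
    )
    out = []
    for p in PERSON_LEVELS:
        for c in CONTEXT_LEVELS:
            sub = df[(df.person_factor == p) & (df.context_factor == c)]
            if sub.empty:
                raise ValueError(
                    f"condition (person={p}, context={c}) has no cells in this design"
                )
            out.append(
                {
                    "person_factor": p,
                    "context_factor": c,
                    "mean_z": float(sub.z.mean()),
                    "n_cells": int(len(sub)),
                }
            )
    return pd.DataFrame(out)


def condition_table(
    sims_per_subject, design: EventDesign, *, include_diagonal: bool = True
) -> pd.DataFrame:
    """Tidy subject x condition table (6 rows per subject)."""
    frames = []
    for s, sim in enumerate(sims_per_subject):
        cm = condition_means(sim, design, include_diagonal=include_diagonal)
        sid = getattr(sim, "subject_id", None)
        cm.insert(0, "subject", sid if sid is not None else s)
        frames.append(cm)
    return pd.concat(frames, ignore_index=True)


@dataclass
class FactorialAnovaResult:
    effects: pd.DataFrame  # effect, F, df_num, df_den, p
    cell_means: pd.DataFrame
    context_pairwise: pd.DataFrame
    ms_error: float
    df_error: int

    def effect(self, name: str) -> pd.Series:
        return self.effects.set_index("effect").loc[name]


def factorial_anova(table: pd.DataFrame) -> FactorialAnovaResult:
    """Two-way fixed-effects ANOVA on the subject-condition means.

    The table must be the balanced 2 x 3 layout from :func:`condition_table`
    (one mean per subject and condition). Each subject-condition mean is
    treated as one observation, so the error df is 6n - 6; this matches the
    conventional analysis of condition-collapsed similarity scores. Tukey HSD
    contrasts on the context factor use the same error term with 2n
    observations per context level.
    """
    required = {"subject", "person_factor", "context_factor", "mean_z"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby(["person_factor", "context_factor"]).size()
    n_subjects = table["subject"].nunique()
    if len(counts) != 6 or counts.nunique() != 1 or counts.iloc[0] != n_subjects:
        raise ValueError("unbalanced table: need all 6 conditions per subject")

    y = table["mean_z"].to_numpy(dtype=float)
    grand = y.mean()
    N = len(y)

    def level_means(col):
        return table.groupby(col)["mean_z"].mean()

    pm = level_means("person_factor")
    cm = level_means("context_factor")
    cellm = table.groupby(["person_factor", "context_factor"])["mean_z"].mean()

    n_per_person = N / len(pm)
    n_per_context = N / len(cm)
    n_per_cell = N / len(cellm)

    ss_person = float(n_per_person * ((pm - grand) ** 2).sum())
    ss_context = float(n_per_context * ((cm - grand) ** 2).sum())
    ss_cells = float(n_per_cell * ((cellm - grand) ** 2).sum())
    ss_inter = ss_cells - ss_person - ss_context
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = max(ss_total - ss_cells, 0.0)

    df_person = len(pm) - 1
    df_context = len(cm) - 1
    df_inter = df_person * df_context
    df_error = N - len(cellm)
    ms_error = ss_error / df_error

    tol = 1e-12 * max(ss_total, 1.0)  # round-off floor for degenerate tables

    def frow(name, ss, df):
        ms = max(ss, 0.0) / df
        if ms_error > tol:
            F = ms / ms_error
            p = float(stats.f.sf(F, df, df_error))
        elif ms <= tol:  # fully degenerate (all means equal)
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
        return {"effect": name, "F": float(F), "df_num": df, "df_den": df_error, "p": p}

    effects = pd.DataFrame(
        [
            frow("person", ss_person, df_person),
            frow("context", ss_context, df_context),
            frow("interaction", ss_inter, df_inter),
        ]
    )
    context_pairwise = tukey_hsd(
        cm.to_dict(), ms_error, df_error, int(n_per_context)
    )
    return FactorialAnovaResult(
        effects=effects,
        cell_means=cellm.reset_index().rename(columns={"mean_z": "mean"}),
        context_pairwise=context_pairwise,
        ms_error=float(ms_error),
        df_error=int(df_error),
    )
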