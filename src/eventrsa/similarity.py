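"""Event-by-event pattern similarity with cross-run averaging.

Encoding-encoding similarity compares each event's multivoxel beta pattern
across pairs of encoding runs: with 3 runs a same-event cell averages the 3
across-run correlations (run1-run2, run1-run3, run2-run3) and a
different-event cell averages all 6 ordered cross-run pairings (twice the
same-event count), which makes the matrix symmetric by construction.
Encoding-recall similarity compares each encoding-run pattern against the
single recall-run pattern and averages across the three encoding runs.

Correlations are Pearson r, passed through the Fisher r-to-z
variance-stabilizing transform (atanh) before averaging by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "fisher_z",
    "correlate_patterns",
    "encoding_similarity_matrix",
    "recall_similarity_matrix",
    "cross_run_term_counts",
]

# atanh diverges at |r|=1; perfect correlations (noise-free synthetic data)
# are clamped just inside the open interval.
_R_CLAMP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r), with |r|=1 clamped to finite z."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    return float(out) if out.ndim == 0 else out


def correlate_patterns(v1: np.ndarray, v2: np.ndarray) -> float:
    """Pearson correlation between two voxel patterns."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("patterns must be 1-D vectors of equal length")
    if v1.size < 3:
        raise ValueError("need at least 3 voxels")
    d1 = v1 - v1.mean()
    d2 = v2 - v2.mean()
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-variance pattern (degenerate ROI extraction)")
    return float(np.clip(d1 @ d2 / (n1 * n2), -1.0, 1.0))


@dataclass
class SimilarityMatrix:
    """Event-by-event similarity, Fisher-z by default.

    ``source`` is ``encoding_encoding`` (symmetric) or ``encoding_recall``
    (row = encoding event, column = recall event; not required symmetric).
    """

    values: np.ndarray
    scale: str = "fisher_z"
    source: str = "encoding_encoding"
    subject_id: str | int | None = None
    roi_name: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("similarity values must be finite")
        if self.scale == "r" and np.abs(v).max() > 1:
            raise ValueError("|r| > 1 on r scale")
        self.values = v

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path, labels=None) -> None:
        labels = labels if labels is not None else list(range(self.n_events))
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


def _as_run_array(patterns) -> np.ndarray:
    """Normalize run->event->voxel-vector input to an (R, E, V) array."""
    if isinstance(patterns, Mapping):
        runs = []
        event_keys = None
        for run_key in sorted(patterns):
            events = patterns[run_key]
            keys = sorted(events)
            if event_keys is None:
                event_keys = keys
            elif keys != event_keys:
                raise ValueError(f"run {run_key!r} is missing events")
            runs.append(np.asarray([events[k] for k in keys], dtype=float))
        arr = np.asarray(runs)
    else:
        arr = np.asarray(patterns, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected patterns shaped (runs, events, voxels)")
    return arr


def _drop_null_voxels(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    """Listwise-exclude voxels that are non-finite in any run/event."""
    stacked = np.concatenate([a.reshape(-1, a.shape[-1]) for a in arrays])
    keep = np.isfinite(stacked).all(axis=0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable voxels after null exclusion")
    if keep.all():
        return arrays
    return tuple(a[..., keep] for a in arrays)


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlations between rows of a (ExV) and b (ExV)."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1)
    bn = np.linalg.norm(bz, axis=1)
    if (an == 0).any() or (bn == 0).any():
        raise ValueError("zero-variance pattern (degenerate ROI extraction)")
    return np.clip((az / an[:, None]) @ (bz / bn[:, None]).T, -1.0, 1.0)


def cross_run_term_counts(n_runs: int) -> tuple[int, int]:
    """(same-event, different-event) correlation counts averaged per cell.

    Same-event cells average one correlation per unordered run pair;
    different-event cells additionally average both event orderings.
    """
    n_pairs = len(list(combinations(range(n_runs), 2)))
    return n_pairs, 2 * n_pairs


def encoding_similarity_matrix(
    patterns,
    *,
    z_before_averaging: bool = True,
    subject_id=None,
    roi_name: str | None = None,
    return_counts: bool = False,
):
    """Cross-run event-by-event similarity for one subject and ROI.

    Parameters
    ----------
    patterns
        Array shaped (n_runs, n_events, n_voxels), or a mapping
        run -> event -> voxel vector. At least 2 runs.
    z_before_averaging
        Apply atanh to each correlation before averaging across run pairs
        (default); if False, average raw r then transform once.
    return_counts
        Also return the E x E integer matrix counting how many correlations
        each cell averaged.
    """
    arr = _as_run_array(patterns)
    n_runs, n_events, _ = arr.shape
    if n_runs < 2:
        raise ValueError("need at least 2 runs for cross-run similarity")
    (arr,) = _drop_null_voxels(arr)

    acc = np.zeros((n_events, n_events))
    counts = np.zeros((n_events, n_events), dtype=int)
    for a, b in combinations(range(n_runs), 2):
        c = _rowwise_corr(arr[a], arr[b])  # c[i,j] = r(run a event i, run b event j)
        t = fisher_z(c) if z_before_averaging else c
        # diagonal: one term per unordered run pair; off-diagonal: both
        # orderings (event i in run a vs j in run b, and vice versa).
        eye = np.eye(n_events, dtype=bool)
        acc += np.where(eye, t, t + t.T)
        counts += np.where(eye, 1, 2)
    values = acc / counts
    if not z_before_averaging:
        values = fisher_z(values)
    sim = SimilarityMatrix(
        values=values,
        scale="fisher_z",
        source="encoding_encoding",
        subject_id=subject_id,
        roi_name=roi_name,
    )
    return (sim, counts) if return_counts else sim


def recall_similarity_matrix(
    encoding,
    recall,
    *,
    z_before_averaging: bool = True,
    subject_id=None,
    roi_name: str | None = None,
):
    """Encoding-recall similarity: cell (i, j) compares event i at encoding
    (averaged over encoding runs) with event j at recall.

    ``encoding`` is (n_runs, n_events, n_voxels) or a mapping; ``recall`` is
    (n_events, n_voxels) or a mapping event -> voxel vector.
    """
    enc = _as_run_array(encoding)
    if isinstance(recall, Mapping):
        rec = np.asarray([recall[k] for k in sorted(recall)], dtype=float)
    else:
        rec = np.asarray(recall, dtype=float)
    if rec.ndim != 2:
        raise ValueError("recall patterns must be shaped (events, voxels)")
    if rec.shape[0] != enc.shape[1]:
        raise ValueError("missing recall event patterns")
    enc, rec = _drop_null_voxels(enc, rec)

    n_runs, n_events, _ = enc.shape
    terms = np.zeros((n_events, n_events))
    for a in range(n_runs):
        c = _rowwise_corr(enc[a], rec)
        terms += fisher_z(c) if z_before_averaging else c
    values = terms / n_runs
    if not z_before_averaging:
        values = fisher_z(values)
    return SimilarityMatrix(
        values=values,
        scale="fisher_z",
        source="encoding_recall",
        subject_id=subject_id,
        roi_name=roi_name,
    )
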