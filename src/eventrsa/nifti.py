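"""Optional volumetric adapter: extract voxel-by-event patterns from NIfTI
beta images using a binary ROI mask.

Voxel indexing is 0-based; a voxel enters the pattern when the mask is
nonzero at that voxel, in a fixed C-order scan of the volume so patterns are
reproducible across images sharing a grid. Requires nibabel (an optional
dependency); everything else in the package works from delimited text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["extract_patterns", "write_pattern_image"]


def _nib():
    try:
        import nibabel
    except ImportError as exc:  # pragma: no cover - exercised only sans nibabel
        raise ImportError("the NIfTI adapter requires nibabel") from exc
    return nibabel


def extract_patterns(beta_path: str | Path, mask_path: str | Path) -> np.ndarray:
    """Extract an (n_events, n_voxels) matrix from a 4D beta image.

    ``beta_path`` is a 4D NIfTI whose last axis indexes events (or TRs);
    ``mask_path`` a 3D image on the same grid whose nonzero voxels define
    the ROI.
    """
    nib = _nib()
    beta = np.asanyarray(nib.load(str(beta_path)).dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj)
    if beta.ndim != 4:
        raise ValueError("beta image must be 4D (x, y, z, event)")
    if mask.shape != beta.shape[:3]:
        raise ValueError("mask grid does not match beta image grid")
    keep = mask.reshape(-1) != 0
    if keep.sum() == 0:
        raise ValueError("empty ROI mask")
    flat = beta.reshape(-1, beta.shape[3])
    return flat[keep].T.copy()  # (events, voxels)


def write_pattern_image(
    patterns: np.ndarray,
    mask: np.ndarray,
    beta_path: str | Path,
    mask_path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Inverse of :func:`extract_patterns` for round-trip testing: scatter
    (n_events, n_voxels) patterns into the nonzero voxels of ``mask`` and
    write both images."""
    nib = _nib()
    mask = np.asarray(mask)
    keep = mask.reshape(-1) != 0
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[1] != keep.sum():
        raise ValueError("pattern voxel count does not match mask voxels")
    affine = affine if affine is not None else np.eye(4)
    vol = np.zeros((mask.size, patterns.shape[0]))
    vol[keep] = patterns.T
    nib.save(
        nib.Nifti1Image(vol.reshape(*mask.shape, patterns.shape[0]), affine),
        str(beta_path),
    )
    nib.save(nib.Nifti1Image(mask.astype(np.int16), affine), str(mask_path))
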