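"""Deterministic derived measures computed before any model fitting.

Four transformations precede the latent-variable analyses:

* the white-matter-lesion load expressed as a percentage of total
  intracranial volume (``wml_ratio``),
* the Fisher z transform of ROI-to-ROI correlation coefficients
  (``fisher_z``),
* sign inversion of speed-based executive scores so that higher always
  means better (``invert_speed_scores``),
* voxelwise lesion frequency maps across a set of binary lesion masks on
  a common reference grid (``lesion_frequency_map`` / :class:`LesionMaskSet`).
"""

from __future__ import annotations

import glob as _glob
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "wml_ratio",
    "fisher_z",
    "invert_speed_scores",
    "LesionMaskSet",
    "lesion_frequency_map",
]


def wml_ratio(wml_volume, tiv):
    """Lesion load as a percentage of total intracranial volume.

    Parameters
    ----------
    wml_volume : float or array-like
        Total white-matter-lesion volume in mm^3 (>= 0).
    tiv : float or array-like
        Total intracranial volume in mm^3 (> 0).

    Returns
    -------
    float or ndarray
        ``100 * wml_volume / tiv``, the percent-of-TIV lesion load. On
        this scale a typical mixed ageing cohort has mean ~0.1-0.3 with a
        long right tail.
    """
    wml = np.asarray(wml_volume, dtype=float)
    t = np.asarray(tiv, dtype=float)
    if np.any(t <= 0):
        raise ValueError("TIV must be strictly positive")
    if np.any(wml < 0):
        raise ValueError("WML volume must be non-negative")
    if np.any(wml > t):
        warnings.warn("WML volume exceeds TIV; ratio above 100%", stacklevel=2)
    out = 100.0 * wml / t
    return float(out) if out.ndim == 0 else out


def fisher_z(r):
    """Fisher z transform arctanh(r) of a correlation coefficient.

    Accepts scalars or arrays with ``|r| < 1``; NaN entries propagate.
    """
    arr = np.asarray(r, dtype=float)
    finite = np.isfinite(arr)
    if np.any(np.abs(arr[finite]) >= 1):
        raise ValueError("correlation must satisfy |r| < 1")
    out = np.arctanh(arr)
    return float(out) if out.ndim == 0 else out


def invert_speed_scores(table, variables):
    """Negate speed-based scores so higher values mean better performance.

    Timed executive tests (trail making, Stroop interference) are scored
    as completion time or error cost, where larger raw values mean worse
    performance; negation aligns their direction with the rest of the
    battery while preserving linearity of the factor model.

    Parameters
    ----------
    table : pandas.DataFrame
        Subject-by-variable data; missing entries stay missing.
    variables : sequence of str
        Column names to negate.

    Returns
    -------
    pandas.DataFrame
        A copy with the listed columns multiplied by -1.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"unknown variables: {missing}")
    out = table.copy()
    for v in variables:
        out[v] = -out[v]
    return out


@dataclass
class LesionMaskSet:
    """Binary lesion masks from several subjects on a shared voxel grid.

    Attributes
    ----------
    masks : ndarray, shape (n_subjects, i, j, k)
        Stacked binary masks (values 0/1).
    voxel_volume : float
        Volume of one voxel in mm^3.
    space_tag : str
        Label of the common reference space (e.g. ``"MNI152"``).
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine shared by all masks.
    """

    masks: np.ndarray
    voxel_volume: float = 1.0
    space_tag: str = "unspecified"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 4:
            raise ValueError("masks must be a (n_subjects, i, j, k) array")
        vals = np.unique(self.masks)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask values must be binary (0/1)")

    def __len__(self):
        return self.masks.shape[0]

    @classmethod
    def from_nifti(cls, paths, space_tag="unspecified"):
        """Load binary masks from NIfTI files; grids and affines must match."""
        import nibabel as nib

        if isinstance(paths, str):
            paths = sorted(_glob.glob(paths))
        if not paths:
            raise ValueError("no mask files given")
        imgs = [nib.load(p) for p in paths]
        shape, affine = imgs[0].shape, imgs[0].affine
        for p, im in zip(paths, imgs):
            if im.shape != shape:
                raise ValueError(f"mask grid mismatch for {p}")
            if not np.allclose(im.affine, affine, atol=1e-4):
                raise ValueError(f"mask affine mismatch for {p}")
        data = np.stack([np.asarray(im.get_fdata() > 0.5, dtype=np.uint8) for im in imgs])
        voxvol = float(abs(np.linalg.det(affine[:3, :3])))
        return cls(masks=data, voxel_volume=voxvol, space_tag=space_tag, affine=affine)

    def lesion_volumes(self):
        """Per-subject total lesion volume in mm^3."""
        return self.masks.reshape(len(self), -1).sum(axis=1) * self.voxel_volume


def lesion_frequency_map(masks):
    """Voxelwise lesion frequency across subjects.

    Each voxel of the output is the proportion of subjects whose binary
    mask is 1 at that voxel, i.e. the across-subject mean of the masks.

    Parameters
    ----------
    masks : LesionMaskSet or ndarray (n_subjects, i, j, k)

    Returns
    -------
    ndarray (i, j, k) with values in [0, 1].
    """
    arr = masks.masks if isinstance(masks, LesionMaskSet) else np.asarray(masks)
    if arr.ndim != 4 or arr.shape[0] < 1:
        raise ValueError("need at least one mask on a 3-D grid")
    return arr.mean(axis=0)


def write_frequency_map(freq, affine, path):
    """Write a frequency map as a float NIfTI-1 image."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(freq, dtype=np.float32), np.asarray(affine))
    nib.save(img, path)
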