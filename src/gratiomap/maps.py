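"""NIfTI voxel-map front end: fuse co-registered maps into a g-ratio map.

Reads co-registered NIfTI-1 volumes (myelin biomarker, diffusion signal
fractions, white-matter tissue-probability maps), converts signal fractions
to AWF, applies an effective calibration, computes the aggregate g-ratio
per voxel, and masks the result by the overlap of two tissue-probability
maps.  Missing values are NaN inside NIfTI; a companion validity mask is
written alongside so consumers need not rely on NaN conventions.

No resampling or reorientation is ever performed — misaligned inputs are
rejected, because residual misalignment corrupts the fused g-ratio.
Registration is an upstream responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np

from gratiomap.calibration import (
    CalibrationError,
    EffectiveCalibration,
    calibrated_mvf,
    calibrate_none,
    spc_gratio,
    spc_mvf,
)
from gratiomap.core import avf_from_awf, awf_from_noddi, g_from_volume_fractions

__all__ = [
    "AFFINE_TOL",
    "AlignmentError",
    "VoxelMap",
    "TissueMask",
    "load_map",
    "save_map",
    "overlap_mask",
    "gratio_map",
    "roi_calibrate_map",
]

logger = logging.getLogger(__name__)

#: Absolute per-element tolerance on affine agreement between co-processed
#: maps; balances header rounding against true misalignment.
AFFINE_TOL = 1e-4


class AlignmentError(ValueError):
    """Raised when co-processed maps do not share grid shape and affine."""


@dataclass(frozen=True)
class VoxelMap:
    """A 3-D voxel grid with its spatial affine; missing values are NaN."""

    data: np.ndarray
    affine: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape


@dataclass(frozen=True)
class TissueMask:
    """Boolean voxel mask with provenance (threshold and source kinds)."""

    mask: np.ndarray
    affine: np.ndarray
    threshold: Optional[float] = None
    sources: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def load_map(path, kind: str = "") -> VoxelMap:
    """Load a NIfTI volume as a float VoxelMap (squeezed to 3-D)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return VoxelMap(data=data, affine=np.asarray(img.affine), kind=kind or str(path))


def save_map(vmap: VoxelMap, path) -> None:
    """Write a VoxelMap to NIfTI-1, preserving the affine untouched."""
    nib.Nifti1Image(np.asarray(vmap.data, dtype=np.float64), vmap.affine).to_filename(
        str(path)
    )


def check_aligned(*maps: VoxelMap, tol: float = AFFINE_TOL) -> None:
    """Verify all maps share grid shape and affine (elementwise tolerance)."""
    ref = maps[0]
    for other in maps[1:]:
        if other.shape != ref.shape:
            raise AlignmentError(
                f"grid shape mismatch: {ref.kind or 'map'} {ref.shape} vs "
                f"{other.kind or 'map'} {other.shape}"
            )
        if not np.allclose(other.affine, ref.affine, rtol=0.0, atol=tol):
            raise AlignmentError(
                f"affine mismatch between {ref.kind or 'map'} and "
                f"{other.kind or 'map'}:\n{ref.affine}\nvs\n{other.affine}"
            )


def overlap_mask(tpm_a: VoxelMap, tpm_b: VoxelMap, threshold: float = 0.5) -> TissueMask:
    """Voxels where BOTH tissue probabilities strictly exceed the threshold.

    The comparison is strict (>): a probability exactly at the threshold is
    excluded.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    check_aligned(tpm_a, tpm_b)
    for name, tpm in (("tpm_a", tpm_a), ("tpm_b", tpm_b)):
        vals = tpm.data[np.isfinite(tpm.data)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError(f"{name} has values outside [0, 1]")
    with np.errstate(invalid="ignore"):
        mask = (tpm_a.data > threshold) & (tpm_b.data > threshold)
    return TissueMask(
        mask=mask,
        affine=tpm_a.affine,
        threshold=threshold,
        sources=(tpm_a.kind, tpm_b.kind),
    )


def gratio_map(
    myelin_map: VoxelMap,
    nu_map: VoxelMap,
    calib: EffectiveCalibration,
    mask: TissueMask,
    nu0_map: Optional[VoxelMap] = None,
) -> Tuple[VoxelMap, Dict[str, int]]:
    """Fuse calibrated myelin and diffusion maps into an aggregate g-ratio map.

    Per voxel inside the mask: ``MVF = clip(α_eff·M, 0, 1)``,
    ``AWF = ν·(1−ν0)`` (ν0 = 0 if absent), ``AVF = (1−MVF)·AWF``, then the
    closed-form g.  Voxels outside the mask, or with any missing input, are
    NaN.  Returns the map and a QC dict with clipped/missing counts.
    """
    maps = [myelin_map, nu_map] + ([nu0_map] if nu0_map is not None else [])
    check_aligned(*maps)
    if mask.mask.shape != myelin_map.shape:
        raise AlignmentError(
            f"mask shape {mask.mask.shape} != map shape {myelin_map.shape}"
        )
    m = myelin_map.data
    nu = nu_map.data
    nu0 = nu0_map.data if nu0_map is not None else np.zeros_like(nu)

    inputs_ok = np.isfinite(m) & np.isfinite(nu) & np.isfinite(nu0)
    active = mask.mask & inputs_ok
    if not active.any():
        logger.warning("gratio_map: output is entirely masked/missing")

    raw_mvf = calib.alpha_eff * m
    mvf = np.clip(raw_mvf, 0.0, 1.0)
    n_clipped = int(np.sum(active & np.isfinite(raw_mvf) & (raw_mvf != mvf)))
    if n_clipped:
        logger.info("gratio_map: clipped %d voxel(s) to [0, 1]", n_clipped)

    awf = awf_from_noddi(np.where(active, nu, np.nan), np.where(active, nu0, np.nan))
    avf = avf_from_awf(awf, np.where(active, mvf, np.nan))
    g = g_from_volume_fractions(np.where(active, mvf, np.nan), avf)
    qc = {
        "n_voxels": int(g.size),
        "n_in_mask": mask.n_voxels,
        "n_valid": int(np.isfinite(g).sum()),
        "n_missing_inputs": int(np.sum(mask.mask & ~inputs_ok)),
        "n_clipped": n_clipped,
    }
    return VoxelMap(data=g, affine=myelin_map.affine, kind="g_ratio"), qc


def roi_calibrate_map(
    myelin_map: VoxelMap,
    nu_map: VoxelMap,
    roi_mask: TissueMask,
    reference_kind: str,
    reference_value: float,
    nu0_map: Optional[VoxelMap] = None,
    overlap: Optional[TissueMask] = None,
) -> EffectiveCalibration:
    """Single-point calibration of a voxel map from a reference ROI.

    ROI means of the biomarker and of AWF = ν·(1−ν0) are computed over the
    ROI voxels (intersected with the tissue overlap mask when given) and
    passed to the scalar calibration procedures.

    ``reference_kind``: ``"g"``, ``"mvf"`` or ``"none"`` (the latter
    ignores ``reference_value``).
    """
    maps = [myelin_map, nu_map] + ([nu0_map] if nu0_map is not None else [])
    check_aligned(*maps)
    if roi_mask.mask.shape != myelin_map.shape:
        raise AlignmentError("ROI mask grid does not match the maps")
    roi = roi_mask.mask.copy()
    if overlap is not None:
        if overlap.mask.shape != roi.shape:
            raise AlignmentError("overlap mask grid does not match the ROI")
        roi &= overlap.mask
    if not roi.any():
        raise CalibrationError("ROI is empty after masking")
    m_roi = myelin_map.data[roi]
    nu_roi = nu_map.data[roi]
    nu0_roi = nu0_map.data[roi] if nu0_map is not None else np.zeros_like(nu_roi)
    awf_roi = awf_from_noddi(nu_roi, nu0_roi)
    if reference_kind == "g":
        return spc_gratio(m_roi, awf_roi, reference_value)
    if reference_kind == "mvf":
        return spc_mvf(m_roi, reference_value)
    if reference_kind == "none":
        return calibrate_none(m_roi)
    raise ValueError(f"unknown reference_kind {reference_kind!r}")
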