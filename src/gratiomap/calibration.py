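"""Linear biomarker-to-MVF law and single-point calibration (SPC).

A myelin biomarker M relates to the myelin volume fraction linearly,
``MVF = α·M + β``, with coefficients that depend on scanner, sequence and
biomarker model.  Single-point calibration collapses the two unknowns into
one effective proportionality constant α_eff estimated from a reference
region of interest (ROI), either against a reference MVF or against a
reference g-ratio.

The g-referenced variant is solved in closed form: the reference condition

    g_ref = sqrt(1 - MVF* / (MVF* + (1 - MVF*)·A)),  A = <AWF>_ROI

inverts to ``MVF* = A·(1 - g_ref²) / (g_ref² + A·(1 - g_ref²))`` and then
``α_eff = MVF* / <M>_ROI``.  A numeric minimiser is deliberately not used
here (it exists only as an independent oracle in the test-suite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Union

import numpy as np

from gratiomap.core import avf_from_awf, g_from_volume_fractions

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "EffectiveCalibration",
    "ROIReference",
    "apply_linear_model",
    "calibrated_mvf",
    "calibrate_none",
    "mvf_star_from_g",
    "spc_gratio",
    "spc_mvf",
]

logger = logging.getLogger(__name__)

ArrayLike = Union[float, np.ndarray]


class CalibrationError(ValueError):
    """Raised when a calibration cannot be performed on the given inputs."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear law linking a biomarker value M to MVF: ``MVF = α·M + β``."""

    alpha: float
    beta: float = 0.0
    biomarker_kind: str = "generic"

    def __post_init__(self) -> None:
        if self.alpha == 0:
            raise ValueError("alpha must be non-zero")


@dataclass(frozen=True)
class EffectiveCalibration:
    """Single effective proportionality constant from a reference ROI.

    ``calibrated MVF = clip(alpha_eff · M, 0, 1)`` — no offset term, by
    construction of the single-point procedures.
    """

    alpha_eff: float
    roi_summary: float
    reference_kind: str  # one of {"mvf_ref", "g_ref", "none"}
    reference_value: Optional[float] = None
    n_roi: int = 0

    def __post_init__(self) -> None:
        if self.reference_kind not in ("mvf_ref", "g_ref", "none"):
            raise ValueError(f"unknown reference_kind {self.reference_kind!r}")
        if not np.isfinite(self.alpha_eff):
            raise ValueError("alpha_eff must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_dict(cls, d: dict) -> "EffectiveCalibration":
        return cls(
            alpha_eff=d["alpha_eff"],
            roi_summary=d["roi_summary"],
            reference_kind=d["reference_kind"],
            reference_value=d.get("reference_value"),
            n_roi=int(d.get("n_roi", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "EffectiveCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ROIReference:
    """Reference ROI: sample/voxel indices and exactly one reference value."""

    roi_mask: Sequence[int]
    g_ref: Optional[float] = None
    mvf_ref: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.roi_mask) == 0:
            raise ValueError("ROI must be non-empty")
        if (self.g_ref is None) == (self.mvf_ref is None):
            raise ValueError("exactly one of g_ref / mvf_ref must be set")


def apply_linear_model(m: ArrayLike, model: CalibrationModel) -> ArrayLike:
    """Map biomarker values to MVF estimates via ``α·M + β``, clipped to [0, 1].

    The number of clipped samples is logged at INFO level.
    """
    m_arr = np.asarray(m, dtype=float)
    raw = model.alpha * m_arr + model.beta
    clipped = np.clip(raw, 0.0, 1.0)
    n_clipped = int(np.sum(np.isfinite(raw) & (raw != clipped)))
    if n_clipped:
        logger.info("apply_linear_model: clipped %d sample(s) to [0, 1]", n_clipped)
    if m_arr.ndim == 0:
        return float(clipped)
    return clipped


def calibrated_mvf(calib: EffectiveCalibration, m: ArrayLike) -> ArrayLike:
    """Calibrated MVF map: ``clip(α_eff · M, 0, 1)`` with clip logging."""
    return apply_linear_model(m, CalibrationModel(alpha=calib.alpha_eff, beta=0.0))


def _roi_mean(values: ArrayLike, name: str) -> tuple[float, int]:
    arr = np.asarray(values, dtype=float).ravel()
    valid = arr[np.isfinite(arr)]
    n_dropped = arr.size - valid.size
    if n_dropped:
        logger.info("%s: dropped %d missing ROI sample(s)", name, n_dropped)
    if valid.size < 1:
        raise CalibrationError(f"ROI has no valid {name} samples")
    return float(valid.mean()), int(valid.size)


def spc_mvf(m_values: ArrayLike, mvf_ref: float) -> EffectiveCalibration:
    """MVF-referenced single-point calibration.

    Sets the calibrated ROI mean equal to the reference:
    ``α_eff = MVF_ref / <M>_ROI``.
    """
    if not 0 < mvf_ref < 1:
        raise CalibrationError(f"mvf_ref must be in (0, 1), got {mvf_ref}")
    m_mean, n = _roi_mean(m_values, "biomarker")
    if m_mean <= 0:
        raise CalibrationError(f"ROI mean biomarker must be > 0, got {m_mean}")
    return EffectiveCalibration(
        alpha_eff=mvf_ref / m_mean,
        roi_summary=m_mean,
        reference_kind="mvf_ref",
        reference_value=float(mvf_ref),
        n_roi=n,
    )


def mvf_star_from_g(g_ref: float, awf_roi: float) -> float:
    """ROI-level MVF implied by a reference g-ratio and ROI-mean AWF.

    Closed-form inversion of ``g² = 1 − MVF/(MVF + (1−MVF)·A)``:
    ``MVF* = A·(1−g²) / (g² + A·(1−g²))``.
    """
    if not 0 < g_ref < 1:
        raise CalibrationError(f"g_ref must be in (0, 1), got {g_ref}")
    if not 0 < awf_roi <= 1:
        raise CalibrationError(f"ROI AWF must be in (0, 1], got {awf_roi}")
    q = 1.0 - g_ref**2
    return awf_roi * q / (g_ref**2 + awf_roi * q)


def spc_gratio(
    m_values: ArrayLike, awf_values: ArrayLike, g_ref: float
) -> EffectiveCalibration:
    """g-ratio-referenced single-point calibration (closed form).

    Finds α_eff such that the aggregate g-ratio recomputed from the ROI-mean
    calibrated MVF and the ROI-mean AWF equals ``g_ref`` exactly.
    """
    m_mean, n_m = _roi_mean(m_values, "biomarker")
    awf_mean, _ = _roi_mean(awf_values, "AWF")
    if m_mean <= 0:
        raise CalibrationError(f"ROI mean biomarker must be > 0, got {m_mean}")
    mvf_star = mvf_star_from_g(g_ref, awf_mean)
    alpha_eff = mvf_star / m_mean
    # Fixed-point sanity check: the defining equation must be satisfied.
    g_check = g_from_volume_fractions(mvf_star, avf_from_awf(awf_mean, mvf_star))
    if abs(g_check - g_ref) > 1e-10:
        raise CalibrationError(
            f"internal inconsistency: recomputed ROI g {g_check} != g_ref {g_ref}"
        )
    return EffectiveCalibration(
        alpha_eff=alpha_eff,
        roi_summary=m_mean,
        reference_kind="g_ref",
        reference_value=float(g_ref),
        n_roi=n_m,
    )


def calibrate_none(m_values: ArrayLike) -> EffectiveCalibration:
    """Identity calibration: use the biomarker directly as an MVF proxy.

    Only valid when the biomarker is already volume-fraction scaled; values
    outside [0, 1] raise (e.g. uncalibrated MTsat exceeds 1 in white matter,
    so its g-ratio is undefined without calibration).
    """
    arr = np.asarray(m_values, dtype=float).ravel()
    valid = arr[np.isfinite(arr)]
    if valid.size < 1:
        raise CalibrationError("no valid biomarker samples")
    if np.any(valid < 0) or np.any(valid > 1):
        raise CalibrationError(
            "biomarker values outside [0, 1]: not a volume-fraction-scaled "
            "proxy; calibration is required"
        )
    return EffectiveCalibration(
        alpha_eff=1.0,
        roi_summary=float(valid.mean()),
        reference_kind="none",
        reference_value=None,
        n_roi=int(valid.size),
    )
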