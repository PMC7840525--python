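"""White-matter volume-fraction model and closed-form aggregate g-ratio.

The voxel is modelled as three non-overlapping compartments — axonal,
myelin, and extracellular — whose volume fractions (AVF, MVF, EVF) sum to
one.  The aggregate g-ratio of a voxel is

    g = sqrt(1 - MVF / (MVF + AVF)) = sqrt(AVF / (AVF + MVF))

which for a single fibre with circular cross-section reduces to the
microscopic definition g = RI / RO (inner over outer radius), and for a
population of fibres equals the fibre-area-weighted mean of the
microscopic g-ratios when all fibres share the same g.

All quantities are dimensionless fractions except radii, which carry
micrometres.  This module is purely computational: no file I/O, no
randomness.  Undefined values (e.g. g of an empty voxel with
MVF + AVF = 0) are represented as NaN and must be propagated, never
silently replaced by 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "SUM_TOL",
    "AxonGeometry",
    "AxonPopulation",
    "WMVolumeFractions",
    "VoxelComposition",
    "DiffusionFractions",
    "g_from_volume_fractions",
    "avf_from_awf",
    "awf_from_noddi",
    "aggregate_from_population",
    "biomarkers_from_composition",
]

#: Tolerance on volume-fraction sum identities.  Violations raise, they are
#: never silently renormalised.
SUM_TOL = 1e-9

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class AxonGeometry:
    """A single fibre: inner (axon) and outer (axon + myelin) radius in μm."""

    inner_radius: float
    outer_radius: float

    def __post_init__(self) -> None:
        if not self.inner_radius > 0:
            raise ValueError(f"inner_radius must be > 0, got {self.inner_radius}")
        if self.outer_radius < self.inner_radius:
            raise ValueError(
                f"outer_radius ({self.outer_radius}) must be >= "
                f"inner_radius ({self.inner_radius})"
            )

    @property
    def g(self) -> float:
        """Microscopic g-ratio RI/RO, in (0, 1]."""
        return self.inner_radius / self.outer_radius


@dataclass(frozen=True)
class AxonPopulation:
    """Ordered collection of fibres plus the sample's fibre packing fraction.

    ``packing_fraction`` is the fibre volume fraction (FVF = MVF + AVF) the
    population occupies within its sample; the remainder is extracellular.
    """

    axons: Tuple[AxonGeometry, ...]
    packing_fraction: float

    def __init__(self, axons: Sequence[AxonGeometry], packing_fraction: float):
        axons = tuple(axons)
        if not axons:
            raise ValueError("AxonPopulation must contain at least one axon")
        if not 0 < packing_fraction <= 1:
            raise ValueError(
                f"packing_fraction must be in (0, 1], got {packing_fraction}"
            )
        object.__setattr__(self, "axons", axons)
        object.__setattr__(self, "packing_fraction", packing_fraction)

    def __len__(self) -> int:
        return len(self.axons)

    def inner_radii(self) -> np.ndarray:
        return np.array([a.inner_radius for a in self.axons])

    def outer_radii(self) -> np.ndarray:
        return np.array([a.outer_radius for a in self.axons])


@dataclass(frozen=True)
class WMVolumeFractions:
    """Myelin / axonal / extracellular volume fractions; sum to one."""

    mvf: float
    avf: float
    evf: float

    def __post_init__(self) -> None:
        for name, v in (("mvf", self.mvf), ("avf", self.avf), ("evf", self.evf)):
            if not (-SUM_TOL <= v <= 1 + SUM_TOL):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = self.mvf + self.avf + self.evf
        if abs(total - 1.0) > SUM_TOL:
            raise ValueError(f"MVF + AVF + EVF must equal 1, got {total!r}")

    @property
    def fvf(self) -> float:
        """Fibre volume fraction MVF + AVF."""
        return self.mvf + self.avf

    @property
    def awf(self) -> float:
        """Axon water fraction AVF / (AVF + EVF) of the non-myelin space."""
        denom = self.avf + self.evf
        if denom == 0:
            return float("nan")
        return self.avf / denom


@dataclass(frozen=True)
class VoxelComposition:
    """Four-pool proton bookkeeping of a voxel.

    Aqueous sub-fractions: myelin water ``f_mw``, axonal water ``f_aw``,
    extracellular water ``f_ew``, CSF ``f_csf``.  Bound (macromolecular)
    sub-fractions: myelin ``f_bm`` and non-myelin ``f_bnm``.  Water plus
    bound pools account for the whole voxel: fW + fB = 1.
    """

    f_mw: float
    f_aw: float
    f_ew: float
    f_csf: float
    f_bm: float
    f_bnm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_mw", "f_aw", "f_ew", "f_csf", "f_bm", "f_bnm"):
            v = getattr(self, name)
            if v < -SUM_TOL:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if abs(self.f_water + self.f_bound - 1.0) > SUM_TOL:
            raise ValueError(
                f"fW + fB must equal 1, got {self.f_water + self.f_bound!r}"
            )

    @property
    def f_water(self) -> float:
        return self.f_mw + self.f_aw + self.f_ew + self.f_csf

    @property
    def f_bound(self) -> float:
        return self.f_bm + self.f_bnm


@dataclass(frozen=True)
class DiffusionFractions:
    """NODDI-style signal fractions: stick fraction ν, isotropic fraction ν0.

    ``nu0`` defaults to 0, which reduces to the two-compartment case.
    """

    nu: float
    nu0: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.nu <= 1:
            raise ValueError(f"nu must be in [0, 1], got {self.nu}")
        if not 0 <= self.nu0 <= 1:
            raise ValueError(f"nu0 must be in [0, 1], got {self.nu0}")


def _asarray(x: ArrayLike) -> Tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def g_from_volume_fractions(mvf: ArrayLike, avf: ArrayLike) -> ArrayLike:
    """Aggregate g-ratio from myelin and axonal volume fractions.

    ``g = sqrt(1 - MVF/(MVF+AVF)) = sqrt(AVF/(AVF+MVF))``.

    Accepts scalars or broadcastable arrays.  NaN inputs propagate to NaN.
    Voxels with ``MVF + AVF = 0`` are undefined and yield NaN (the g-ratio
    of an empty voxel carries no information).  Negative inputs or
    ``MVF + AVF > 1`` raise :class:`ValueError`.
    """
    mvf_a, mvf_scalar = _asarray(mvf)
    avf_a, avf_scalar = _asarray(avf)
    mvf_a, avf_a = np.broadcast_arrays(mvf_a, avf_a)
    finite = np.isfinite(mvf_a) & np.isfinite(avf_a)
    if np.any(mvf_a[finite] < 0) or np.any(avf_a[finite] < 0):
        raise ValueError("volume fractions must be non-negative")
    total = mvf_a + avf_a
    if np.any(total[finite] > 1 + SUM_TOL):
        raise ValueError("MVF + AVF must not exceed 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(total > 0, avf_a / np.where(total > 0, total, 1.0), np.nan))
    out = np.where(finite & (total > 0), out, np.nan)
    if mvf_scalar and avf_scalar:
        return float(out)
    return out


def avf_from_awf(awf: ArrayLike, mvf: ArrayLike) -> ArrayLike:
    """Axonal volume fraction from axon water fraction: AVF = (1 − MVF)·AWF.

    Rescales the water-signal fraction by the MR-invisible myelin volume.
    """
    awf_a, s1 = _asarray(awf)
    mvf_a, s2 = _asarray(mvf)
    for name, arr in (("awf", awf_a), ("mvf", mvf_a)):
        finite = np.isfinite(arr)
        if np.any(arr[finite] < 0) or np.any(arr[finite] > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = (1.0 - mvf_a) * awf_a
    if s1 and s2:
        return float(out)
    return out


def awf_from_noddi(fracs: Union[DiffusionFractions, ArrayLike], nu0: ArrayLike | None = None) -> ArrayLike:
    """Axon water fraction from NODDI signal fractions: AWF = ν·(1 − ν0).

    Accepts a :class:`DiffusionFractions` instance, or ``(nu, nu0)`` as
    scalars/arrays (``nu0`` defaults to 0 for two-compartment models).
    """
    if isinstance(fracs, DiffusionFractions):
        return fracs.nu * (1.0 - fracs.nu0)
    nu_a, s1 = _asarray(fracs)
    nu0_a, s2 = _asarray(0.0 if nu0 is None else nu0)
    for name, arr in (("nu", nu_a), ("nu0", nu0_a)):
        finite = np.isfinite(arr)
        if np.any(arr[finite] < 0) or np.any(arr[finite] > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = nu_a * (1.0 - nu0_a)
    if s1 and s2:
        return float(out)
    return out


def aggregate_from_population(
    pop: AxonPopulation,
) -> Tuple[WMVolumeFractions, float, float]:
    """Collapse an axon population into voxel-level fractions and g-ratios.

    Cross-sectional areas are proportional to r² (π cancels).  With
    ``S_I = Σ RI²`` and ``S_O = Σ RO²`` and packing fraction FVF:

    - ``MVF = FVF · (S_O − S_I) / S_O``
    - ``AVF = FVF · S_I / S_O``
    - ``EVF = 1 − FVF``

    Returns ``(fractions, g_aggregate, g_area_weighted)`` where
    ``g_aggregate`` applies :func:`g_from_volume_fractions` and
    ``g_area_weighted = Σ(RO²·g_i)/S_O`` is the fibre-area-weighted mean of
    microscopic g-ratios; the two coincide for uniform-g populations.
    """
    ri = pop.inner_radii()
    ro = pop.outer_radii()
    s_i = float(np.sum(ri**2))
    s_o = float(np.sum(ro**2))
    fvf = pop.packing_fraction
    mvf = fvf * (s_o - s_i) / s_o
    avf = fvf * s_i / s_o
    evf = 1.0 - fvf
    fractions = WMVolumeFractions(mvf=mvf, avf=avf, evf=evf)
    g_aggregate = g_from_volume_fractions(mvf, avf)
    g_area_weighted = float(np.sum(ro**2 * (ri / ro)) / s_o)
    return fractions, g_aggregate, g_area_weighted


def biomarkers_from_composition(comp: VoxelComposition) -> Dict[str, float]:
    """Compartment-based myelin biomarkers of a voxel composition.

    Returns ``{"MWF", "BPF", "PSR", "MTV", "PD"}`` where MWF = fMW/fW,
    BPF = fB/(fW+fB) = fB, PSR = fB/fW, PD = fW and MTV = 1 − PD = fB.
    A voxel without water (fW = 0) has undefined MWF and PSR (NaN).
    """
    f_w = comp.f_water
    f_b = comp.f_bound
    if f_w == 0:
        mwf = float("nan")
        psr = float("nan")
    else:
        mwf = comp.f_mw / f_w
        psr = f_b / f_w
    return {
        "MWF": mwf,
        "BPF": f_b / (f_w + f_b),
        "PSR": psr,
        "MTV": 1.0 - f_w,
        "PD": f_w,
    }
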