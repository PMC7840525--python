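"""Synthetic white-matter cohorts with known ground truth.

Generates per-sample axon populations spanning hypo- to hyper-myelination
(via demyelination arms), collapses them to voxel-level volume fractions,
and produces myelin biomarkers under the linear law ``MVF = α·M + β``
(inverted, optionally with additive Gaussian noise; the default is
noise-free).  Every draw is governed by a single mandatory seed so cohorts
are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from gratiomap.core import (
    AxonGeometry,
    AxonPopulation,
    VoxelComposition,
    WMVolumeFractions,
    aggregate_from_population,
    avf_from_awf,
    g_from_volume_fractions,
)

__all__ = [
    "DistributionSpec",
    "BiomarkerSpec",
    "CohortConfig",
    "GroundTruthSample",
    "generate_population",
    "apply_demyelination",
    "generate_biomarkers",
    "build_cohort",
    "cohort_frame",
    "write_cohort",
]

#: Columns of the tidy cohort table that are not biomarker columns.
BASE_COLUMNS = ("sample_id", "arm", "MVF", "AVF", "EVF", "AWF", "g_true")


@dataclass(frozen=True)
class DistributionSpec:
    """Small declarative distribution: name plus keyword parameters.

    Supported names:

    - ``"gamma"``: params ``shape``, ``scale``
    - ``"beta"``: params ``a``, ``b``, ``low``, ``high`` (affinely rescaled)
    - ``"uniform"``: params ``low``, ``high``
    - ``"constant"``: param ``value`` (degenerate, for tests)
    """

    name: str
    params: Dict[str, float] = field(default_factory=dict)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.name == "gamma":
            return rng.gamma(shape=p["shape"], scale=p["scale"], size=size)
        if self.name == "beta":
            low, high = p.get("low", 0.0), p.get("high", 1.0)
            return low + (high - low) * rng.beta(p["a"], p["b"], size=size)
        if self.name == "uniform":
            return rng.uniform(p["low"], p["high"], size=size)
        if self.name == "constant":
            return np.full(size, float(p["value"]))
        raise ValueError(f"unknown distribution {self.name!r}")

    @property
    def mean(self) -> float:
        """Analytic mean, used by Monte-Carlo sanity tests."""
        p = self.params
        if self.name == "gamma":
            return p["shape"] * p["scale"]
        if self.name == "beta":
            low, high = p.get("low", 0.0), p.get("high", 1.0)
            return low + (high - low) * p["a"] / (p["a"] + p["b"])
        if self.name == "uniform":
            return 0.5 * (p["low"] + p["high"])
        if self.name == "constant":
            return float(p["value"])
        raise ValueError(f"unknown distribution {self.name!r}")


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generating law of one biomarker: MVF = α·M + β plus optional noise."""

    kind: str
    alpha: float
    beta: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha == 0:
            raise ValueError("alpha must be non-zero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_inner_radius_law() -> DistributionSpec:
    return DistributionSpec("gamma", {"shape": 5.0, "scale": 0.1})


def _default_g_micro_law() -> DistributionSpec:
    return DistributionSpec("beta", {"a": 5.0, "b": 5.0, "low": 0.5, "high": 0.95})


def _default_biomarkers() -> Tuple[BiomarkerSpec, ...]:
    return (BiomarkerSpec("generic", alpha=1.0, beta=0.0),)


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic cohort; the seed is mandatory.

    ``demyelination_factors`` lists myelin-thickness factors d in [0, 1]
    (1 = intact, 0 = fully demyelinated); samples are assigned to arms
    round-robin.  ``unmyelinated_axon_fraction`` optionally mixes in axons
    with no myelin sheath (g = 1); the default excludes them.
    """

    seed: int
    n_samples: int = 200
    axons_per_sample: int = 500
    inner_radius_law: DistributionSpec = field(default_factory=_default_inner_radius_law)
    g_micro_law: DistributionSpec = field(default_factory=_default_g_micro_law)
    fvf_range: Tuple[float, float] = (0.55, 0.85)
    demyelination_factors: Tuple[float, ...] = (1.0, 0.85, 0.7, 0.55, 0.4)
    biomarker_specs: Tuple[BiomarkerSpec, ...] = field(default_factory=_default_biomarkers)
    unmyelinated_axon_fraction: float = 0.0
    # Optional compartment-split realism layer (see VoxelComposition).
    rho_myelin_water: float = 0.5
    f_bnm: float = 0.0
    f_csf: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.axons_per_sample < 1:
            raise ValueError("n_samples and axons_per_sample must be >= 1")
        lo, hi = self.fvf_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"fvf_range must lie within (0, 1], got {self.fvf_range}")
        for d in self.demyelination_factors:
            if not 0 <= d <= 1:
                raise ValueError(f"demyelination factor must be in [0, 1], got {d}")
        if not self.demyelination_factors:
            raise ValueError("demyelination_factors must be non-empty")
        if not 0 <= self.unmyelinated_axon_fraction <= 1:
            raise ValueError("unmyelinated_axon_fraction must be in [0, 1]")
        if not 0 <= self.rho_myelin_water <= 1:
            raise ValueError("rho_myelin_water must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruthSample:
    """One simulated sample: known fractions, g-ratio, AWF and biomarkers."""

    sample_id: int
    arm: float
    fractions: WMVolumeFractions
    g_true: float
    awf_true: float
    biomarkers: Dict[str, float]
    composition: Optional[VoxelComposition] = None


def generate_population(config: CohortConfig, rng: np.random.Generator) -> AxonPopulation:
    """Draw one axon population from the configured radius and g laws.

    Per axon, the inner radius RI and microscopic g are drawn independently
    and the outer radius follows as ``RO = RI / g``.  The packing fraction
    is drawn uniformly within ``fvf_range``.
    """
    n = config.axons_per_sample
    ri = config.inner_radius_law.draw(rng, n)
    if np.any(ri <= 0):
        raise ValueError("inner_radius_law produced non-positive radii")
    g = config.g_micro_law.draw(rng, n)
    if np.any(g <= 0) or np.any(g > 1):
        raise ValueError("g_micro_law produced values outside (0, 1]")
    if config.unmyelinated_axon_fraction > 0:
        bare = rng.random(n) < config.unmyelinated_axon_fraction
        g = np.where(bare, 1.0, g)
    ro = ri / g
    fvf = rng.uniform(*config.fvf_range)
    axons = [AxonGeometry(float(a), float(b)) for a, b in zip(ri, ro)]
    return AxonPopulation(axons, packing_fraction=float(fvf))


def apply_demyelination(pop: AxonPopulation, d: float) -> AxonPopulation:
    """Thin every myelin sheath by factor d: ``RO' = RI + d·(RO − RI)``.

    ``d = 1`` is the identity; ``d = 0`` removes all myelin (g = 1 for
    every axon).  Inner radii and packing are unchanged.
    """
    if not 0 <= d <= 1:
        raise ValueError(f"demyelination factor must be in [0, 1], got {d}")
    axons = [
        AxonGeometry(a.inner_radius, a.inner_radius + d * (a.outer_radius - a.inner_radius))
        for a in pop.axons
    ]
    return AxonPopulation(axons, packing_fraction=pop.packing_fraction)


def generate_biomarkers(
    mvf: float,
    specs: Sequence[BiomarkerSpec],
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Invert the linear law per spec: ``M = (MVF − β)/α (+ noise)``.

    With ``noise_sd = 0`` the forward model recovers MVF exactly.  A
    zero-noise biomarker that comes out negative indicates an offset too
    large for the cohort's MVF range and raises.
    """
    out: Dict[str, float] = {}
    for spec in specs:
        m = (mvf - spec.beta) / spec.alpha
        if spec.noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            m += rng.normal(0.0, spec.noise_sd)
        elif m < 0:
            raise ValueError(
                f"biomarker {spec.kind!r}: offset beta={spec.beta} too large "
                f"for MVF={mvf} (negative zero-noise biomarker)"
            )
        out[spec.kind] = float(m)
    return out


def _composition_from_fractions(
    fr: WMVolumeFractions, config: CohortConfig
) -> VoxelComposition:
    # fMW + fBM = MVF, fAW = AVF, fEW absorbs the remainder so pools sum to 1.
    f_mw = config.rho_myelin_water * fr.mvf
    f_bm = (1.0 - config.rho_myelin_water) * fr.mvf
    f_ew = fr.evf - config.f_bnm - config.f_csf
    if f_ew < 0:
        raise ValueError("f_bnm + f_csf exceed the extracellular fraction")
    return VoxelComposition(
        f_mw=f_mw, f_aw=fr.avf, f_ew=f_ew, f_csf=config.f_csf,
        f_bm=f_bm, f_bnm=config.f_bnm,
    )


def build_cohort(config: CohortConfig) -> List[GroundTruthSample]:
    """Generate the full cohort of ground-truth samples.

    Pipeline per sample: draw population → apply the sample's demyelination
    arm → aggregate to volume fractions, g and AWF → generate biomarkers.
    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    arms = config.demyelination_factors
    samples: List[GroundTruthSample] = []
    for i in range(config.n_samples):
        d = arms[i % len(arms)]
        pop = generate_population(config, rng)
        if d != 1.0:
            pop = apply_demyelination(pop, d)
        fractions, _, _ = aggregate_from_population(pop)
        awf_true = fractions.awf
        # Ground-truth g through the same AWF->AVF route the MR pipeline
        # uses, so a perfect biomarker proxy reproduces g_true bit-exactly.
        g_true = g_from_volume_fractions(
            fractions.mvf, avf_from_awf(awf_true, fractions.mvf)
        )
        biomarkers = generate_biomarkers(fractions.mvf, config.biomarker_specs, rng)
        composition = _composition_from_fractions(fractions, config)
        samples.append(
            GroundTruthSample(
                sample_id=i,
                arm=float(d),
                fractions=fractions,
                g_true=g_true,
                awf_true=awf_true,
                biomarkers=biomarkers,
                composition=composition,
            )
        )
    return samples


def cohort_frame(samples: Sequence[GroundTruthSample]) -> pd.DataFrame:
    """Tidy per-sample table: base columns plus one column per biomarker."""
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "arm": s.arm,
            "MVF": s.fractions.mvf,
            "AVF": s.fractions.avf,
            "EVF": s.fractions.evf,
            "AWF": s.awf_true,
            "g_true": s.g_true,
        }
        row.update(s.biomarkers)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(samples: Sequence[GroundTruthSample], path, config: Optional[CohortConfig] = None) -> None:
    """Write the cohort CSV; if a config is given, echo it to ``<path>.config.json``."""
    frame = cohort_frame(samples)
    frame.to_csv(path, index=False)
    if config is not None:
        with open(f"{path}.config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)
            fh.write("\n")
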