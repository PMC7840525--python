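import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gratiomap.core import (
    AxonGeometry,
    AxonPopulation,
    DiffusionFractions,
    VoxelComposition,
    WMVolumeFractions,
    aggregate_from_population,
    avf_from_awf,
    awf_from_noddi,
    biomarkers_from_composition,
    g_from_volume_fractions,
)


class TestAxonGeometry:
    def test_g_ratio(self):
        assert AxonGeometry(0.6, 1.0).g == pytest.approx(0.6, abs=1e-15)

    def test_unmyelinated_axon_allowed(self):
        assert AxonGeometry(0.5, 0.5).g == 1.0

    @pytest.mark.parametrize("ri, ro", [(0.0, 1.0), (-0.1, 1.0), (0.6, 0.5)])
    def test_invalid_radii_raise(self, ri, ro):
        with pytest.raises(ValueError):
            AxonGeometry(ri, ro)


class TestWMVolumeFractions:
    def test_sum_identity_enforced(self):
        with pytest.raises(ValueError, match="sum|equal 1"):
            WMVolumeFractions(mvf=0.3, avf=0.3, evf=0.3)

    def test_no_silent_renormalisation(self):
        fr = WMVolumeFractions(mvf=0.3, avf=0.3, evf=0.4)
        assert fr.mvf == 0.3 and fr.fvf == pytest.approx(0.6)

    def test_awf(self):
        fr = WMVolumeFractions(mvf=0.3, avf=0.35, evf=0.35)
        assert fr.awf == pytest.approx(0.5)


class TestVoxelComposition:
    def test_pool_sum_enforced(self):
        with pytest.raises(ValueError):
            VoxelComposition(f_mw=0.5, f_aw=0.4, f_ew=0.3, f_csf=0.0, f_bm=0.2)

    def test_negative_subfraction_rejected(self):
        with pytest.raises(ValueError):
            VoxelComposition(f_mw=-0.1, f_aw=0.6, f_ew=0.3, f_csf=0.0, f_bm=0.2)


class TestGFromVolumeFractions:
    def test_unmyelinated_limit(self):
        assert g_from_volume_fractions(0.0, 0.5) == 1.0

    def test_symmetric_case(self):
        assert g_from_volume_fractions(0.5, 0.5) == pytest.approx(
            math.sqrt(0.5), abs=1e-15
        )

    def test_single_fibre_consistency(self):
        # cross-sectional areas of a fibre RI=0.6, RO=1.0 (pi cancels)
        avf, mvf = 0.36, 0.64
        assert g_from_volume_fractions(mvf, avf) == pytest.approx(0.6, abs=1e-12)

    def test_empty_voxel_is_nan_not_zero(self):
        assert math.isnan(g_from_volume_fractions(0.0, 0.0))

    def test_nan_propagates(self):
        out = g_from_volume_fractions(np.array([0.3, np.nan]), np.array([0.3, 0.3]))
        assert math.isnan(out[1]) and np.isfinite(out[0])

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            g_from_volume_fractions(-0.1, 0.5)

    def test_sum_above_one_raises(self):
        with pytest.raises(ValueError):
            g_from_volume_fractions(0.6, 0.6)

    def test_vectorised(self):
        g = g_from_volume_fractions(np.array([0.0, 0.5]), np.array([0.5, 0.5]))
        assert g == pytest.approx([1.0, math.sqrt(0.5)])

    @given(
        mvf=st.floats(1e-6, 0.5),
        avf=st.floats(1e-6, 0.5),
        c=st.floats(0.01, 1.0),
    )
    def test_scale_invariance(self, mvf, avf, c):
        # g is independent of the fibre volume fraction
        assert g_from_volume_fractions(c * mvf, c * avf) == pytest.approx(
            g_from_volume_fractions(mvf, avf), rel=1e-12
        )

    def test_monotonicity_in_mvf(self):
        mvfs = np.linspace(0.01, 0.5, 50)
        g = g_from_volume_fractions(mvfs, np.full_like(mvfs, 0.4))
        assert np.all(np.diff(g) < 0)

    def test_monotonicity_in_avf(self):
        avfs = np.linspace(0.01, 0.5, 50)
        g = g_from_volume_fractions(np.full_like(avfs, 0.4), avfs)
        assert np.all(np.diff(g) > 0)


class TestAvfFromAwf:
    @pytest.mark.parametrize(
        "awf, mvf, expected",
        [(0.5, 0.0, 0.5), (1.0, 0.3, 0.7), (0.5, 0.3, 0.35)],
    )
    def test_examples(self, awf, mvf, expected):
        assert avf_from_awf(awf, mvf) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            avf_from_awf(1.2, 0.3)
        with pytest.raises(ValueError):
            avf_from_awf(0.5, -0.1)

    @given(awf=st.floats(0, 1), mvf=st.floats(0, 1))
    def test_avf_plus_mvf_bounded(self, awf, mvf):
        assert avf_from_awf(awf, mvf) + mvf <= 1 + 1e-12


class TestAwfFromNoddi:
    @pytest.mark.parametrize(
        "nu, nu0, expected",
        [(0.6, 0.0, 0.6), (0.6, 0.1, 0.54), (0.0, 0.7, 0.0)],
    )
    def test_examples(self, nu, nu0, expected):
        assert awf_from_noddi(nu, nu0) == pytest.approx(expected, abs=1e-15)

    def test_dataclass_input(self):
        assert awf_from_noddi(DiffusionFractions(nu=0.6, nu0=0.1)) == pytest.approx(0.54)

    def test_default_nu0_zero(self):
        assert awf_from_noddi(0.6) == 0.6

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            awf_from_noddi(1.5, 0.0)
        with pytest.raises(ValueError):
            DiffusionFractions(nu=0.5, nu0=-0.2)


def _brute_force_aggregate(ri, ro, fvf):
    """Independent oracle: direct summation over fibre cross-sections."""
    s_i = sum(r**2 for r in ri)
    s_o = sum(r**2 for r in ro)
    mvf = fvf * (s_o - s_i) / s_o
    avf = fvf * s_i / s_o
    g_agg = math.sqrt(avf / (avf + mvf))
    g_aw = sum(o**2 * (i / o) for i, o in zip(ri, ro)) / s_o
    return mvf, avf, g_agg, g_aw


class TestAggregateFromPopulation:
    def test_uniform_g_population(self):
        axons = [AxonGeometry(r, r / 0.7) for r in (0.3, 0.5, 0.8, 1.1)]
        pop = AxonPopulation(axons, packing_fraction=0.8)
        fr, g_agg, g_aw = aggregate_from_population(pop)
        assert g_agg == pytest.approx(0.7, abs=1e-12)
        assert g_aw == pytest.approx(0.7, abs=1e-12)
        assert fr.evf == pytest.approx(0.2, abs=1e-12)

    def test_two_axon_derived_example(self):
        # frozen from the brute-force oracle: both axons have g = 0.6
        pop = AxonPopulation(
            [AxonGeometry(0.6, 1.0), AxonGeometry(0.3, 0.5)], packing_fraction=1.0
        )
        fr, g_agg, g_aw = aggregate_from_population(pop)
        assert g_agg == pytest.approx(math.sqrt((0.36 + 0.09) / 1.25), abs=1e-12)
        assert g_agg == pytest.approx(0.6, abs=1e-12)
        assert g_aw == pytest.approx(0.6, abs=1e-12)

    def test_heterogeneous_population_matches_oracle(self, rng):
        ri = rng.gamma(5.0, 0.1, size=300)
        g = rng.uniform(0.55, 0.85, size=300)
        ro = ri / g
        pop = AxonPopulation(
            [AxonGeometry(float(a), float(b)) for a, b in zip(ri, ro)],
            packing_fraction=0.7,
        )
        fr, g_agg, g_aw = aggregate_from_population(pop)
        mvf_o, avf_o, g_agg_o, g_aw_o = _brute_force_aggregate(ri, ro, 0.7)
        assert fr.mvf == pytest.approx(mvf_o, abs=1e-12)
        assert fr.avf == pytest.approx(avf_o, abs=1e-12)
        assert g_agg == pytest.approx(g_agg_o, abs=1e-12)
        assert g_aw == pytest.approx(g_aw_o, abs=1e-12)
        # moderate dispersion: aggregate stays close to area-weighted mean
        assert abs(g_agg - g_aw) / g_aw < 0.02

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            AxonPopulation([], packing_fraction=0.5)


class TestBiomarkersFromComposition:
    def test_reference_example(self):
        comp = VoxelComposition(
            f_mw=0.1, f_aw=0.4, f_ew=0.3, f_csf=0.0, f_bm=0.15, f_bnm=0.05
        )
        bm = biomarkers_from_composition(comp)
        assert bm["MWF"] == pytest.approx(0.125)
        assert bm["BPF"] == pytest.approx(0.2)
        assert bm["PSR"] == pytest.approx(0.25)
        assert bm["MTV"] == pytest.approx(0.2)
        assert bm["PD"] == pytest.approx(0.8)

    def test_all_water_voxel(self):
        comp = VoxelComposition(f_mw=0.2, f_aw=0.5, f_ew=0.2, f_csf=0.1, f_bm=0.0)
        bm = biomarkers_from_composition(comp)
        assert bm["BPF"] == 0.0 and bm["MTV"] == pytest.approx(0.0)
        assert bm["MWF"] == pytest.approx(0.2)

    def test_equal_pools(self):
        comp = VoxelComposition(f_mw=0.1, f_aw=0.2, f_ew=0.2, f_csf=0.0, f_bm=0.5)
        bm = biomarkers_from_composition(comp)
        assert bm["PSR"] == pytest.approx(1.0)
        assert bm["BPF"] == pytest.approx(0.5)

    def test_identities(self, rng):
        # BPF = MTV and PSR = BPF/(1-BPF), exactly
        for _ in range(20):
            w = rng.dirichlet(np.ones(5))
            comp = VoxelComposition(
                f_mw=w[0], f_aw=w[1], f_ew=w[2], f_csf=0.0, f_bm=w[3], f_bnm=w[4]
            )
            bm = biomarkers_from_composition(comp)
            assert bm["BPF"] == pytest.approx(bm["MTV"], abs=1e-12)
            assert bm["PSR"] == pytest.approx(bm["BPF"] / (1 - bm["BPF"]), abs=1e-12)
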