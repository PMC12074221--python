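"""Forward-model unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colefit import (
    ColeParams,
    FrequencyGrid,
    Z1Params,
    Z2Params,
    derived_ri,
    impedance_z0,
    impedance_z1,
    impedance_z2,
    impedance_zc,
    spectrum,
)

from oracle import z0_brute, z1_brute, z2_brute


class TestDerivedRi:
    @pytest.mark.parametrize(
        "r0,rinf,expected", [(100.0, 50.0, 100.0), (100.0, 99.0, 9900.0)]
    )
    def test_plug_in(self, r0, rinf, expected):
        assert derived_ri(r0, rinf) == pytest.approx(expected)

    @pytest.mark.parametrize("r0,rinf", [(100.0, 100.0), (50.0, 100.0), (1.0, 0.0)])
    def test_requires_r0_above_rinf(self, r0, rinf):
        with pytest.raises(ValueError):
            derived_ri(r0, rinf)


class TestColeModel:
    def test_zero_frequency_is_r0(self, cole_params):
        assert impedance_zc(cole_params, 0.0) == pytest.approx(100.0 + 0j)

    def test_characteristic_frequency_point(self):
        # at omega*tau = 1 and alpha = 1: ZC = Rinf + (R0-Rinf)(1-j)/2
        p = ColeParams(r0=100.0, rinf=50.0, cm=100e-9, alpha=1.0)
        tau = (p.r0 + p.ri) * p.cm
        f = 1.0 / (2 * np.pi * tau)
        assert impedance_zc(p, f) == pytest.approx(75.0 - 25.0j, rel=1e-12)

    def test_high_frequency_limit_is_rinf(self, cole_params):
        z = impedance_zc(cole_params, 1e12)
        assert abs(z - cole_params.rinf) < 1e-3 * cole_params.rinf

    def test_negative_frequency_rejected(self, cole_params):
        with pytest.raises(ValueError):
            impedance_zc(cole_params, -1.0)

    def test_td_rotation(self):
        p = ColeParams(r0=100.0, rinf=50.0, cm=100e-9, alpha=1.0, td=1e-6)
        tau = (p.r0 + p.ri) * p.cm
        f = 1.0 / (2 * np.pi * tau)
        expected = (75.0 - 25.0j) * np.exp(-2j * np.pi * f * p.td)
        assert impedance_z0(p, f) == pytest.approx(expected, rel=1e-12)

    def test_td_zero_equals_zc(self, cole_params, default_grid):
        f = default_grid.frequencies
        np.testing.assert_allclose(
            impedance_z0(cole_params, f), impedance_zc(cole_params, f), rtol=1e-15
        )

    def test_rotation_at_dc_is_identity(self):
        p = ColeParams(r0=100.0, rinf=50.0, cm=100e-9, alpha=0.7, td=1.5e-6)
        assert impedance_z0(p, 0.0) == pytest.approx(100.0 + 0j)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(r0=50.0, rinf=50.0, cm=1e-7, alpha=0.8),
            dict(r0=100.0, rinf=50.0, cm=-1e-7, alpha=0.8),
            dict(r0=100.0, rinf=50.0, cm=1e-7, alpha=0.0),
            dict(r0=100.0, rinf=50.0, cm=1e-7, alpha=1.2),
            dict(r0=100.0, rinf=50.0, cm=1e-7, alpha=0.8, td=-1e-9),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ColeParams(**bad)


class TestShuntModel:
    def test_cp_zero_degenerates_to_z0(self, cole_params, default_grid):
        f = default_grid.frequencies
        z1 = impedance_z1(Z1Params(cole=cole_params, cp=0.0), f)
        np.testing.assert_allclose(z1, impedance_z0(cole_params, f), rtol=1e-12)

    def test_dc_is_r0_for_any_shunt(self, cole_params):
        z = impedance_z1(Z1Params(cole=cole_params, cp=1e-9), 0.0)
        assert z == pytest.approx(cole_params.r0 + 0j)

    def test_shunt_reduces_modulus(self, cole_params, default_grid):
        f = default_grid.frequencies
        z1 = impedance_z1(Z1Params(cole=cole_params, cp=1e-9), f)
        zc = impedance_zc(cole_params, f)
        assert np.all(np.abs(z1) <= np.abs(zc) + 1e-12)

    def test_parallel_combination_value(self):
        p = Z1Params(
            cole=ColeParams(r0=100.0, rinf=50.0, cm=100e-9, alpha=1.0), cp=1e-9
        )
        got = impedance_z1(p, 1e6)
        want = z1_brute(100.0, 50.0, 100e-9, 1.0, 0.0, 1e-9, 1e6)
        assert got == pytest.approx(want, rel=1e-12)


class TestFrequencyDependentCapacitance:
    def test_a_zero_degenerates_to_z0(self, cole_params, default_grid):
        p2 = Z2Params(r0=100.0, rinf=50.0, cm_lf=100e-9, a=0.0, alpha=0.85)
        f = default_grid.frequencies
        np.testing.assert_allclose(
            impedance_z2(p2, f), impedance_z0(cole_params, f), rtol=1e-12
        )

    def test_dc_is_r0(self, z2_params):
        assert impedance_z2(z2_params, 0.0) == pytest.approx(100.0 + 0j)

    def test_value_against_direct_formula(self):
        p = Z2Params(r0=100.0, rinf=50.0, cm_lf=100e-9, a=2e-14, alpha=0.8)
        got = impedance_z2(p, 5e5)
        want = z2_brute(100.0, 50.0, 100e-9, 2e-14, 0.8, 0.0, 5e5)
        assert got == pytest.approx(want, rel=1e-12)

    def test_nonpositive_effective_capacitance_rejected(self):
        p = Z2Params(r0=100.0, rinf=50.0, cm_lf=1e-10, a=-9e-17, alpha=0.8)
        with pytest.raises(ValueError):
            impedance_z2(p, 2e6)  # cm_eff = 1e-10 - 1.8e-10 < 0


class TestFrequencyGrid:
    def test_default_grid_endpoints_and_size(self, default_grid):
        f = default_grid.frequencies
        assert len(default_grid) == 22
        assert f[0] == 5000.0
        assert f[-1] == 1_000_000.0
        # log-spaced: constant ratio between neighbours
        ratios = f[1:] / f[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    @pytest.mark.parametrize(
        "bad", [[", "], [], [0.0, 1.0], [2.0, 1.0], [1.0, 1.0], [np.nan, 1.0]]
    )
    def test_invalid_grids_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            FrequencyGrid(bad)


class TestSpectrum:
    def test_length_and_order(self, cole_params, default_grid):
        sp = spectrum(cole_params, default_grid)
        assert len(sp) == 22
        np.testing.assert_array_equal(sp.frequencies, default_grid.frequencies)

    def test_single_frequency_matches_scalar(self, cole_params):
        grid = FrequencyGrid([1e4])
        sp = spectrum(cole_params, grid)
        assert sp.z[0] == impedance_z0(cole_params, 1e4)

    def test_z2_a_zero_spectrum_identical_to_z0(self, cole_params, default_grid):
        p2 = Z2Params(r0=100.0, rinf=50.0, cm_lf=100e-9, a=0.0, alpha=0.85)
        np.testing.assert_allclose(
            spectrum(p2, default_grid).z, spectrum(cole_params, default_grid).z,
            rtol=1e-13,
        )


params_strategy = st.builds(
    ColeParams,
    r0=st.floats(min_value=20.0, max_value=1000.0),
    rinf=st.floats(min_value=1.0, max_value=19.0),
    cm=st.floats(min_value=1e-10, max_value=1e-6),
    alpha=st.floats(min_value=0.3, max_value=1.0),
    td=st.floats(min_value=0.0, max_value=2e-6),
)


class TestArcProperties:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=params_strategy, f=st.floats(min_value=0.0, max_value=1e9))
    def test_arc_between_limits_with_capacitive_phase(self, p, f):
        z = impedance_zc(p, f)
        assert p.rinf - 1e-9 <= z.real <= p.r0 + 1e-9
        assert z.imag <= 1e-9

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=params_strategy, f=st.floats(min_value=0.0, max_value=1e9))
    def test_td_rotation_preserves_modulus(self, p, f):
        assert abs(impedance_z0(p, f)) == pytest.approx(
            abs(impedance_zc(p, f)), rel=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(p=params_strategy)
    def test_zero_frequency_exactly_r0(self, p):
        assert impedance_z0(p, 0.0) == p.r0 + 0j


class TestOracleEquivalence:
    """Vectorized models agree with scalar brute-force evaluation."""

    def test_random_draws_all_models(self, default_grid):
        rng = np.random.default_rng(42)
        f = default_grid.frequencies
        for _ in range(100):
            rinf = rng.uniform(1.0, 500.0)
            r0 = rinf + rng.uniform(1.0, 1000.0)
            cm = 10 ** rng.uniform(-10, -6)
            alpha = rng.uniform(0.3, 1.0)
            td = rng.uniform(0.0, 2e-6)
            cp = 10 ** rng.uniform(-13, -8)
            a = rng.uniform(0.0, 1e-13)
            p0 = ColeParams(r0=r0, rinf=rinf, cm=cm, alpha=alpha, td=td)
            p1 = Z1Params(cole=p0, cp=cp)
            p2 = Z2Params(r0=r0, rinf=rinf, cm_lf=cm, a=a, alpha=alpha, td=td)
            want0 = np.array([z0_brute(r0, rinf, cm, alpha, td, fi) for fi in f])
            want1 = np.array([z1_brute(r0, rinf, cm, alpha, td, cp, fi) for fi in f])
            want2 = np.array([z2_brute(r0, rinf, cm, a, alpha, td, fi) for fi in f])
            np.testing.assert_allclose(impedance_z0(p0, f), want0, rtol=1e-12)
            np.testing.assert_allclose(impedance_z1(p1, f), want1, rtol=1e-12)
            np.testing.assert_allclose(impedance_z2(p2, f), want2, rtol=1e-12)
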