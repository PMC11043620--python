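import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpflow.solution_biophysics import (CDConstants, CrowderSpec, Instrument,
                                         apparent_mass, cd_helicity, cumulant_fit,
                                         extrapolate_zero_concentration,
                                         regularized_inversion,
                                         relative_mass_series,
                                         stokes_einstein_diffusion,
                                         stokes_einstein_radius, volume_fraction)
from idpflow.synthetic_data import (DLSTruth, SLSTruth, make_dls_correlogram,
                                    make_sls_series)
from idpflow.solution_biophysics.sls import forward_intensity_ratio


def test_stokes_einstein_round_trip():
    rs = 3.7e-9
    d = stokes_einstein_diffusion(rs, 296.15, 0.9e-3)
    assert np.isclose(stokes_einstein_radius(d, 296.15, 0.9e-3), rs, rtol=1e-14)


class TestCumulant:
    def test_noise_free_monodisperse(self):
        corr = make_dls_correlogram(DLSTruth(components=((2.0, 1.0),)))
        res = cumulant_fit(corr, order=1)
        assert abs(res.hydro.R_S_nm - 2.0) / 2.0 < 0.005

    def test_viscosity_consistency(self):
        # regenerate the fixture at doubled viscosity: D halves, R_S invariant
        for visc in (0.9e-3, 1.8e-3):
            inst = Instrument(viscosity_Pa_s=visc)
            corr = make_dls_correlogram(
                DLSTruth(components=((2.0, 1.0),), instrument=inst))
            res = cumulant_fit(corr)
            assert abs(res.hydro.R_S_nm - 2.0) / 2.0 < 0.01

    def test_polydisperse_order2(self):
        comps = ((1.9, 0.5), (2.1, 0.5))  # ~5% polydispersity
        corr = make_dls_correlogram(DLSTruth(components=comps))
        res = cumulant_fit(corr, order=2)
        assert res.PDI > 0
        assert abs(res.hydro.R_S_nm - 2.0) / 2.0 < 0.05

    def test_non_decaying_rejected(self):
        from idpflow.solution_biophysics import CorrelogramTable
        tau = np.geomspace(1e-6, 1e-2, 50)
        corr = CorrelogramTable(tau, np.full_like(tau, 0.5))
        with pytest.raises(ValueError):
            cumulant_fit(corr)


class TestRegularizedInversion:
    def test_monodisperse_mode(self):
        corr = make_dls_correlogram(DLSTruth(components=((2.0, 1.0),)))
        res = regularized_inversion(corr)
        assert len(res.modes()) == 1
        assert abs(res.hydro.R_S_nm - 2.0) / 2.0 < 0.03
        assert np.all(res.weights >= 0)

    def test_bimodal_resolved_within_10pct(self):
        truth = DLSTruth(components=((2.0, 0.5), (50.0, 0.5)), noise=1e-3, seed=1)
        res = regularized_inversion(make_dls_correlogram(truth))
        radii = sorted(r for r, _ in res.modes())
        assert len(radii) == 2
        assert abs(radii[0] - 2.0) / 2.0 < 0.10
        assert abs(radii[1] - 50.0) / 50.0 < 0.10

    def test_alpha_monotonicity(self):
        corr = make_dls_correlogram(
            DLSTruth(components=((2.0, 0.5), (20.0, 0.5)), noise=1e-3, seed=2))
        alphas = [1e-3, 1e-1, 1e1, 1e3]
        sols = [regularized_inversion(corr, alpha=a) for a in alphas]
        residuals = [s.residual for s in sols]
        smooth = [s.smoothness for s in sols]
        assert all(np.diff(residuals) >= -1e-12)
        assert all(np.diff(smooth) <= 1e-12)

    def test_small_grid_rejected(self):
        corr = make_dls_correlogram(DLSTruth(components=((2.0, 1.0),)))
        with pytest.raises(ValueError):
            regularized_inversion(corr, grid=np.geomspace(1e-6, 1e-3, 10))


class TestSLS:
    def test_forward_inverse_round_trip(self):
        m = 32000.0
        ratio = forward_intensity_ratio(m, 2.0, 0.185)
        assert np.isclose(apparent_mass(ratio, 2.0, 0.185), m, rtol=1e-9)

    def test_concentration_linearity(self):
        m = 50000.0
        r1 = forward_intensity_ratio(m, 1.0, 0.185)
        r2 = forward_intensity_ratio(m, 2.0, 0.185)
        assert np.isclose(r2, 2 * r1, rtol=1e-12)
        assert np.isclose(apparent_mass(r2, 2.0, 0.185),
                          apparent_mass(r1, 1.0, 0.185), rtol=1e-12)

    def test_dimer_series_m_rel(self):
        m_mono = 29000.0
        truth = SLSTruth(M_g_mol=2 * m_mono, interaction_slope=250.0,
                         noise_frac=0.005, seed=6)
        c, ratios = make_sls_series(truth)
        series = relative_mass_series(c, ratios, truth.dndc_ml_g, m_mono)
        assert abs(series.M_rel - 2.0) < 0.05

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            apparent_mass(1.0, 0.0, 0.185)


class TestExtrapolation:
    def test_flat_series(self):
        intercept, se = extrapolate_zero_concentration(
            [(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)])
        assert np.isclose(intercept, 5.0)

    def test_sloped_series_recovered(self, rng):
        c = np.linspace(0.5, 5.0, 6)
        v = 3.0 + 0.1 * c + rng.normal(0, 0.01, size=c.size)
        intercept, se = extrapolate_zero_concentration(zip(c, v))
        assert abs(intercept - 3.0) < 3 * se + 0.05

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_zero_concentration([(1.0, 2.0), (2.0, 3.0)])


class TestVolumeFraction:
    def test_zero(self):
        assert volume_fraction(CrowderSpec(0.0)) == 0.0

    def test_printed_lower_bound(self):
        phi = volume_fraction(CrowderSpec(50.0, 0.735))
        assert np.isclose(phi, 3.675)
        assert round(phi) == 4

    def test_direct_arithmetic(self):
        assert np.isclose(volume_fraction(CrowderSpec(100.0, 0.735)), 7.35)

    @given(c=st.floats(0.0, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity(self, c):
        phi = volume_fraction(CrowderSpec(c, 0.735))
        assert np.isclose(phi, c * 0.0735, rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            CrowderSpec(-1.0)


class TestCDHelicity:
    def test_coil_reference(self):
        assert cd_helicity(-2340.0).f_helix == 0.0

    def test_helix_reference(self):
        assert cd_helicity(-32640.0).f_helix == 1.0

    def test_midpoint(self):
        assert np.isclose(cd_helicity(-17490.0).f_helix, 0.5)

    def test_clipping_warns_keeps_raw(self):
        with pytest.warns(UserWarning):
            rec = cd_helicity(-40000.0)
        assert rec.f_helix == 1.0
        assert rec.f_helix_raw > 1.0

    def test_chain_length_corrected_variant(self):
        const = CDConstants()
        rec = cd_helicity(-20000.0, const, n_res=89)
        expected_ref = -39500.0 * (1 - 2.57 / 89)
        assert np.isclose(rec.theta_helix, expected_ref)
        assert 0 < rec.f_helix < 1
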