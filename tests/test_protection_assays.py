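import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpflow.protection_assays import (LiposomeGeometry, LiposomeTarget,
                                       Protectant, ProteinTarget,
                                       cf_leakage_percent, dose_response_fit,
                                       four_param_logistic, ldh_retention,
                                       lipids_per_vesicle,
                                       lt50_from_electrolyte_leakage,
                                       surface_occupancy)
from idpflow.synthetic_data import AssayTruth, make_assay_table, make_conductivity_table


def _single_species_geom(a=0.64, R=50.0, d=4.0):
    return LiposomeGeometry(lipid_fractions={"X": 1.0},
                            headgroup_areas_nm2={"X": a},
                            radius_nm=R, bilayer_thickness_nm=d)


class TestLipidsPerVesicle:
    def test_direct_arithmetic_oracle(self):
        n = lipids_per_vesicle(_single_species_geom())
        oracle = (4 * np.pi * 50.0**2 + 4 * np.pi * 46.0**2) / 0.64
        assert np.isclose(n, oracle, rtol=1e-12)

    def test_halving_area_doubles_count(self):
        n1 = lipids_per_vesicle(_single_species_geom(a=0.64))
        n2 = lipids_per_vesicle(_single_species_geom(a=0.32))
        assert np.isclose(n2, 2 * n1, rtol=1e-12)

    def test_equal_area_mixture_degenerates(self):
        mixed = LiposomeGeometry(
            lipid_fractions={"MGDG": 0.4, "DGDG": 0.3, "SQDG": 0.15, "EPG": 0.15},
            headgroup_areas_nm2={k: 0.64 for k in ("MGDG", "DGDG", "SQDG", "EPG")},
            radius_nm=50.0, bilayer_thickness_nm=4.0)
        assert np.isclose(lipids_per_vesicle(mixed),
                          lipids_per_vesicle(_single_species_geom()), rtol=1e-12)

    def test_monotonic_in_radius_and_area(self):
        base = lipids_per_vesicle(_single_species_geom(R=50.0))
        bigger = lipids_per_vesicle(_single_species_geom(R=60.0))
        smaller_area = lipids_per_vesicle(_single_species_geom(a=0.5))
        assert bigger > base
        assert smaller_area > base

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            _single_species_geom(R=3.0, d=4.0)
        with pytest.raises(ValueError):
            LiposomeGeometry(lipid_fractions={"X": 0.5},
                             headgroup_areas_nm2={"X": 0.6})


class TestSurfaceOccupancy:
    def test_linearity_in_concentrations(self):
        geom = _single_species_geom()
        t1 = LiposomeTarget(0.3, 800.0, geom)
        t2 = LiposomeTarget(0.6, 800.0, geom)
        p1 = Protectant(1.0, 2.5, 15000.0)
        p2 = Protectant(2.0, 2.5, 15000.0)
        occ = surface_occupancy(p1, t1)
        assert np.isclose(surface_occupancy(p2, t1), 2 * occ, rtol=1e-12)
        assert np.isclose(surface_occupancy(p1, t2), occ / 2, rtol=1e-12)

    def test_disc_to_sphere_quarter(self):
        # equal radii, equal molar concentrations, protein target
        R, mw = 3.0, 40000.0
        prot = Protectant(concentration_mg_mL=1.0, R_S_nm=R, MW_g_mol=mw)
        target = ProteinTarget(concentration_mg_mL=1.0, MW_g_mol=mw, R_S_nm=R)
        assert np.isclose(surface_occupancy(prot, target), 0.25, rtol=1e-12)

    def test_worked_liposome_case_matches_spreadsheet(self):
        # independent step-by-step evaluation of the printed formula
        geom = _single_species_geom()
        c_prot, rs_prot, mw_prot = 0.8, 2.5, 15000.0
        c_lip, mw_lip = 0.4, 800.0
        prot = Protectant(c_prot, rs_prot, mw_prot)
        occ = surface_occupancy(prot, LiposomeTarget(c_lip, mw_lip, geom))
        n_tot = (4 * np.pi * 2500.0 + 4 * np.pi * 2116.0) / 0.64
        spreadsheet = (c_prot * (np.pi * rs_prot**2) * n_tot * mw_lip
                       / ((4 * np.pi * 50.0**2) * c_lip * mw_prot))
        assert np.isclose(occ, spreadsheet, rtol=1e-9)

    def test_ldh_default_radius(self):
        target = ProteinTarget(concentration_mg_mL=0.15, MW_g_mol=140_000.0)
        assert target.R_S_nm == 4.3

    def test_zero_target_concentration_rejected(self):
        prot = Protectant(1.0, 2.5, 15000.0)
        with pytest.raises(ValueError):
            surface_occupancy(prot, ProteinTarget(0.0, 140000.0))

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity(self, scale):
        geom = _single_species_geom()
        base = surface_occupancy(Protectant(1.0, 2.5, 15000.0),
                                 LiposomeTarget(0.4, 800.0, geom))
        up = surface_occupancy(Protectant(scale, 2.5, 15000.0),
                               LiposomeTarget(0.4 * scale, 800.0, geom))
        assert np.isclose(up, base, rtol=1e-9)


class TestCFLeakage:
    def test_no_release(self):
        assert cf_leakage_percent(10.0, 10.0, 110.0) == 0.0

    def test_full_release(self):
        assert cf_leakage_percent(10.0, 110.0, 110.0) == 100.0

    def test_direct_arithmetic(self):
        assert np.isclose(cf_leakage_percent(10.0, 55.0, 110.0), 45.0)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            cf_leakage_percent(10.0, 5.0, 10.0)


class TestDoseResponse:
    def test_noise_free_recovery(self):
        x = np.linspace(-2, 2, 9)
        y = four_param_logistic(x, 80.0, 20.0, 0.0)
        fit = dose_response_fit(x, y)
        assert np.allclose([fit.asymptote_low_x, fit.asymptote_high_x,
                            fit.logEC50], [80.0, 20.0, 0.0], atol=1e-6)
        assert fit.stabilization_capacity == fit.asymptote_high_x

    def test_midpoint_property(self):
        x = np.linspace(-3, 3, 11)
        fit = dose_response_fit(x, four_param_logistic(x, 70.0, 10.0, 0.5))
        mid = fit.predict(fit.logEC50)
        assert np.isclose(mid, 0.5 * (70.0 + 10.0), atol=1e-6)

    def test_constant_y_degenerate(self):
        x = np.linspace(0, 4, 8)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = dose_response_fit(x, np.full_like(x, 33.0))
        assert fit.degenerate
        assert fit.asymptote_low_x == fit.asymptote_high_x == 33.0

    def test_ascending_and_descending_same_curve(self):
        x = np.linspace(-2, 2, 12)
        asc = dose_response_fit(x, four_param_logistic(x, 5.0, 95.0, 0.0))
        desc = dose_response_fit(x, four_param_logistic(x, 95.0, 5.0, 0.0))
        assert np.isclose(asc.logEC50, desc.logEC50, atol=1e-6)
        assert np.isclose(asc.asymptote_low_x, desc.asymptote_high_x, atol=1e-5)

    def test_x_shift_equivariance(self):
        x = np.linspace(-2, 2, 12)
        y = four_param_logistic(x, 80.0, 20.0, 0.3)
        f0 = dose_response_fit(x, y)
        f1 = dose_response_fit(x + 5.0, y)
        assert np.isclose(f1.logEC50, f0.logEC50 + 5.0, atol=1e-6)

    def test_too_few_x_rejected(self):
        with pytest.raises(ValueError):
            dose_response_fit(np.array([0, 1, 2, 3.0]), np.array([1, 2, 3, 4.0]))

    def test_capacity_coverage_over_seeds(self):
        # >= 90% of 200 seeds within 2 SE of the true capacity
        hits = 0
        for seed in range(200):
            truth = AssayTruth(80.0, 20.0, 0.0,
                               x_values=tuple(np.linspace(-2, 2, 12)),
                               replicate_sd=2.0, n_replicates=3, seed=seed)
            table = make_assay_table(truth)
            fit = dose_response_fit(table["x"].to_numpy(), table["y"].to_numpy())
            se = fit.se[1]
            if np.isfinite(se) and abs(fit.asymptote_high_x - 20.0) <= 2 * se:
                hits += 1
        assert hits >= 0.9 * 200


class TestLT50:
    def test_noise_free_recovery(self):
        truth = AssayTruth(100.0, 0.0, -8.0,
                           x_values=tuple(np.linspace(-20, -1, 10)),
                           n_replicates=3)
        table = make_conductivity_table(truth)
        res = lt50_from_electrolyte_leakage(table)["WT"]
        assert np.isclose(res.lt50_C, -8.0, atol=1e-4)

    def test_leakage_at_lt50_is_half_span(self):
        truth = AssayTruth(100.0, 0.0, -8.0,
                           x_values=tuple(np.linspace(-20, -1, 10)))
        res = lt50_from_electrolyte_leakage(make_conductivity_table(truth))["WT"]
        fit = res.fit
        mid = fit.predict(res.lt50_C)
        assert np.isclose(mid, 0.5 * (fit.asymptote_low_x + fit.asymptote_high_x),
                          atol=1e-6)

    def test_missing_control_rejected(self):
        truth = AssayTruth(100.0, 0.0, -8.0,
                           x_values=tuple(np.linspace(-20, -1, 10)))
        table = make_conductivity_table(truth)
        frozen_only = table[table["temperature"] != 4.0]
        with pytest.raises(ValueError, match="control"):
            lt50_from_electrolyte_leakage(frozen_only, control_temperature=4.0)

    def test_se_coverage_over_seeds(self):
        hits = 0
        for seed in range(200):
            truth = AssayTruth(100.0, 0.0, -8.0,
                               x_values=tuple(np.linspace(-20, -1, 10)),
                               replicate_sd=3.0, n_replicates=5, seed=seed)
            res = lt50_from_electrolyte_leakage(make_conductivity_table(truth))["WT"]
            if np.isfinite(res.lt50_se_C) and abs(res.lt50_C + 8.0) <= 2 * res.lt50_se_C:
                hits += 1
        assert hits >= 0.9 * 200


class TestLDHRetention:
    def _table(self, activity):
        rows = []
        for rep in range(6):
            rows.append({"variant": "WT", "occupancy": 1.0, "cycle": 0,
                         "activity": activity})
        return pd.DataFrame(rows)

    def test_control_equals_one(self):
        out = ldh_retention(self._table(2.5), unfrozen_control=2.5)
        assert np.isclose(out["retention"].iloc[0], 1.0)

    def test_all_zero(self):
        out = ldh_retention(self._table(0.0), unfrozen_control=2.5)
        assert np.allclose(out["retention"], 0.0)

    def test_cycle_decay_forward_model(self):
        truth = AssayTruth(0.0, 100.0, 0.0, x_values=(5.0,), replicate_sd=1.0,
                           n_replicates=6, seed=7, cycle_decay=0.8)
        table = make_assay_table(truth, kind="ldh_activity")
        table = table.rename(columns={"x": "occupancy", "y": "activity"})
        table["variant"] = "none"
        out = ldh_retention(table, unfrozen_control=100.0)
        r5 = out[out["cycle"] == 5]["retention"].iloc[0]
        assert abs(r5 - 0.8**5) < 0.05

    def test_bad_control_rejected(self):
        with pytest.raises(ValueError):
            ldh_retention(self._table(1.0), unfrozen_control=0.0)
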