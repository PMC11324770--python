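"""Lung PBPK simulator: flux contract, conservation laws, closed-form
limits and the exposure-to-IC50 mapping."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occlusim.doseresponse import DoseResponseFit
from occlusim.lungpbpk import (AirwayMorphometry, CompoundParams, DoseEvent,
                               build_model, elf_region_summary,
                               map_exposure_to_ic50, nernst_brunner_rate,
                               simulate)


def _quiet_morphometry(epithelium_sink: bool = False) -> AirwayMorphometry:
    """Default morphometry with mucociliary clearance switched off and,
    optionally, an effectively infinite epithelium volume."""
    t = AirwayMorphometry.default().table.copy()
    t["mucociliary_rate_per_h"] = 0.0
    if epithelium_sink:
        t["epithelium_volume_ml"] = 1e9
    return AirwayMorphometry(t)


def _gen1_solution_dose(amount: float = 100.0) -> DoseEvent:
    fr = np.zeros(24)
    fr[0] = 1.0
    return DoseEvent(total_dose_nmol=amount, formulation="solution",
                     generation_fractions=tuple(fr))


class TestMorphometry:
    def test_default_table_valid_and_alveolar_dominated(self):
        m = AirwayMorphometry.default()
        t = m.table
        assert len(t) == 24
        tb_sa = t.loc[t["generation"] <= 16, "surface_area_cm2"].sum()
        alv_sa = t.loc[t["generation"] >= 17, "surface_area_cm2"].sum()
        assert alv_sa > 10 * tb_sa

    def test_alveolar_mucociliary_must_be_zero(self):
        t = AirwayMorphometry.default().table.copy()
        t.loc[20, "mucociliary_rate_per_h"] = 1.0
        with pytest.raises(ValueError, match="alveolar"):
            AirwayMorphometry(t)

    def test_missing_generation_rejected(self):
        t = AirwayMorphometry.default().table.iloc[:-1]
        with pytest.raises(ValueError, match="1..24"):
            AirwayMorphometry(t)

    def test_shipped_table_loads_and_validates(self):
        m = AirwayMorphometry.shipped()
        assert len(m.table) == 24
        assert (m.table.loc[m.table["generation"] >= 17,
                            "mucociliary_rate_per_h"] == 0).all()

    def test_csv_round_trip(self, tmp_path):
        m = AirwayMorphometry.default()
        m.to_csv(tmp_path / "m.csv")
        back = AirwayMorphometry.from_csv(tmp_path / "m.csv")
        pd.testing.assert_frame_equal(m.table, back.table)


class TestCompoundParams:
    def test_alveolar_permeability_is_tenfold_by_default(
            self, demo_compound_params):
        cp = demo_compound_params
        assert cp.permeability_alveolar_cm_per_s \
            == pytest.approx(10 * cp.permeability_p_tb_cm_per_s)

    def test_nonpositive_parameters_rejected(self, demo_compound_params):
        with pytest.raises(ValueError):
            dataclasses.replace(demo_compound_params, solubility_cs_um=0.0)
        with pytest.raises(ValueError):
            dataclasses.replace(demo_compound_params, fu_plasma=1.5)


class TestNernstBrunner:
    def test_equilibrium_rate_zero(self):
        assert nernst_brunner_rate(100.0, 1e6, 50.0, 50.0, 6e-6, 30e-4,
                                   1.2, 450.0) == 0.0

    def test_no_solid_rate_zero(self):
        assert nernst_brunner_rate(0.0, 1e6, 50.0, 0.0, 6e-6, 30e-4,
                                   1.2, 450.0) == 0.0

    def test_supersaturation_clipped_to_zero(self):
        assert nernst_brunner_rate(100.0, 1e6, 50.0, 80.0, 6e-6, 30e-4,
                                   1.2, 450.0) == 0.0

    def test_single_sphere_hand_oracle(self):
        """One 2-um-radius sphere, sink conditions: rate must equal the
        hand-evaluated (D/h) * 4 pi r^2 * Cs."""
        d, h, cs, rho, mw = 6e-6, 30e-4, 50.0, 1.2, 450.0
        r_cm = 2e-4
        mass_g = rho * 4.0 / 3.0 * math.pi * r_cm ** 3
        mass_nmol = mass_g / mw * 1e9
        expected = (d * 3600.0 / h) * 4.0 * math.pi * r_cm ** 2 * cs
        got = nernst_brunner_rate(mass_nmol, 1.0, cs, 0.0, d, h, rho, mw)
        assert got == pytest.approx(expected, rel=1e-12)


class TestSimulate:
    def test_solution_dose_never_creates_solid(self, demo_compound_params):
        model = build_model(_quiet_morphometry(), demo_compound_params)
        res = simulate(model, _gen1_solution_dose(), t_end_h=2.0,
                       dt_output_h=0.5)
        assert np.all(res.undissolved_nmol == 0.0)

    def test_closed_system_elf_constant(self, demo_compound_params):
        cp = dataclasses.replace(demo_compound_params,
                                 permeability_p_tb_cm_per_s=0.0,
                                 cl_ml_per_h=0.0, k_in_per_h=0.0)
        model = build_model(_quiet_morphometry(), cp)
        res = simulate(model, _gen1_solution_dose(), t_end_h=4.0,
                       dt_output_h=0.5)
        assert np.ptp(res.elf_concentration_um[0]) == 0.0

    def test_permeability_only_matches_closed_form(self,
                                                   demo_compound_params):
        """Single generation, epithelium as an infinite sink: the ELF decays
        as C0 * exp(-P*SA/V * t) to 1e-6 relative."""
        cp = dataclasses.replace(demo_compound_params, cl_ml_per_h=0.0,
                                 k_in_per_h=0.0)
        model = build_model(_quiet_morphometry(epithelium_sink=True), cp)
        res = simulate(model, _gen1_solution_dose(), t_end_h=2.0,
                       dt_output_h=0.05)
        k = model.p_cm_per_h[0] * model.sa[0] / model.v_elf[0]
        analytic = (100.0 / model.v_elf[0]) * np.exp(-k * res.t_h)
        rel = np.abs(res.elf_concentration_um[0] - analytic) / analytic
        assert rel.max() < 1e-6

    def test_mass_balance_solid_default_dose(self, demo_compound_params):
        model = build_model(AirwayMorphometry.default(),
                            demo_compound_params)
        res = simulate(model, DoseEvent(total_dose_nmol=1000.0),
                       t_end_h=24.0, dt_output_h=0.5)
        assert res.mass_balance_rel_error < 1e-6

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mass_balance_random_parameter_sweep(self, seed,
                                                 demo_compound_params):
        rng = np.random.default_rng(seed)
        cp = dataclasses.replace(
            demo_compound_params,
            solubility_cs_um=float(rng.uniform(5, 200)),
            permeability_p_tb_cm_per_s=float(10 ** rng.uniform(-8, -5)),
            k_in_per_h=float(rng.uniform(0, 5)),
            k_out_per_h=float(rng.uniform(0.1, 5)),
            cl_ml_per_h=float(rng.uniform(100, 5000)),
            fu_tissue=float(rng.uniform(0.05, 1.0)))
        model = build_model(AirwayMorphometry.default(), cp)
        dose = DoseEvent(total_dose_nmol=float(rng.uniform(10, 5000)))
        res = simulate(model, dose, t_end_h=12.0, dt_output_h=1.0)
        assert res.mass_balance_rel_error < 1e-6

    def test_dissolved_fraction_monotone_below_solubility(
            self, demo_compound_params):
        model = build_model(AirwayMorphometry.default(),
                            demo_compound_params)
        res = simulate(model, DoseEvent(total_dose_nmol=100.0),
                       t_end_h=12.0, dt_output_h=0.25)
        assert np.all(res.elf_concentration_um <=
                      demo_compound_params.solubility_cs_um * (1 + 1e-9))
        solid_total = res.undissolved_nmol.sum(axis=0)
        assert np.all(np.diff(solid_total) <= 1e-9)

    def test_dose_linearity_when_not_solubility_limited(
            self, demo_compound_params):
        cp = dataclasses.replace(demo_compound_params,
                                 solubility_cs_um=1e7)
        model = build_model(AirwayMorphometry.default(), cp)
        r1 = simulate(model, DoseEvent(total_dose_nmol=10.0), 6.0, 0.5)
        r2 = simulate(model, DoseEvent(total_dose_nmol=20.0), 6.0, 0.5)
        ok = r1.elf_concentration_um > 1e-12
        ratio = r2.elf_concentration_um[ok] / r1.elf_concentration_um[ok]
        assert np.allclose(ratio, 2.0, rtol=1e-5)

    def test_upper_tb_peak_exceeds_alveolar_peak(self,
                                                 demo_compound_params):
        model = build_model(AirwayMorphometry.default(),
                            demo_compound_params)
        res = simulate(model, DoseEvent(total_dose_nmol=1000.0), 24.0, 0.25)
        summ = elf_region_summary(res)
        assert summ["upper_tb"] > summ["alveolar"]


class TestRegionSummary:
    def test_single_generation_region(self, demo_compound_params):
        model = build_model(AirwayMorphometry.default(),
                            demo_compound_params)
        res = simulate(model, DoseEvent(total_dose_nmol=100.0), 6.0, 0.5)
        one = elf_region_summary(res, {"g1": (1, 1)})["g1"]
        assert one == pytest.approx(res.elf_concentration_um[0].max())

    def test_constant_field_every_region_equal(self, demo_compound_params):
        model = build_model(AirwayMorphometry.default(),
                            demo_compound_params)
        res = simulate(model, DoseEvent(total_dose_nmol=100.0), 1.0, 0.5)
        res.elf_concentration_um[:] = 3.0
        summ = elf_region_summary(res)
        assert all(v == pytest.approx(3.0) for v in summ.values())

    def test_empty_region_rejected(self, demo_compound_params):
        model = build_model(AirwayMorphometry.default(),
                            demo_compound_params)
        res = simulate(model, DoseEvent(total_dose_nmol=100.0), 1.0, 0.5)
        with pytest.raises(ValueError):
            elf_region_summary(res, {"bad": (5, 2)})


class TestExposureMapping:
    @staticmethod
    def _fit(ic50=27.9):
        return DoseResponseFit("AZ5", np.array([]), np.array([]), None,
                               ic50, "loglinear")

    def test_regional_exposure_ratios(self):
        """ELF Cmax of 14 / 3.2 / 0.02 uM against an IC50 of 27.9 uM: the
        upper tracheobronchial ratio is ~0.50 (at risk), the lower TB ~0.11
        and the alveolar ~7e-4 (both below the at-risk threshold)."""
        out = map_exposure_to_ic50({"upper_tb": 14.0, "lower_tb": 3.2,
                                    "alveolar": 0.02}, self._fit())
        out = out.set_index("region")
        assert out.loc["upper_tb", "exposure_ratio"] \
            == pytest.approx(0.502, abs=0.01)
        assert out.loc["upper_tb", "at_risk"]
        assert out.loc["lower_tb", "exposure_ratio"] \
            == pytest.approx(0.115, abs=0.005)
        assert not out.loc["lower_tb", "at_risk"]
        assert out.loc["alveolar", "exposure_ratio"] \
            == pytest.approx(7e-4, abs=2e-4)
        assert not out.loc["alveolar", "at_risk"]

    def test_cmax_equal_ic50_predicts_half_response(self):
        fit = DoseResponseFit("X", np.array([]), np.array([]), None, 10.0,
                              "fourpl", params=(1.0, 0.0, 10.0, 1.0))
        out = map_exposure_to_ic50({"r": 10.0}, fit)
        assert out["predicted_response"].iloc[0] == pytest.approx(0.5)

    def test_not_established_fit_flags_all_regions(self):
        fit = DoseResponseFit("X", np.array([]), np.array([]), None, None,
                              "loglinear")
        out = map_exposure_to_ic50({"upper_tb": 14.0, "alveolar": 0.02}, fit)
        assert out["no_in_vitro_effect_detected"].all()
        assert not out["at_risk"].any()
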