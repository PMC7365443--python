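"""Assay arithmetic: slope extraction, unit conversion, flux, respirometry, SFE, t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mammoquant as mq
from mammoquant.functional_assays import (
    AssayConfig,
    NoLinearPhaseError,
    PhaseFit,
    activity_from_slope,
    detect_linear_phase,
    metabolite_rates,
    respirometry_summary,
    sphere_formation_efficiency,
    students_t_test,
)


class TestLinearPhase:
    def test_exact_line_recovered_exactly(self):
        trace, _ = mq.generate_kinetic_trace(-0.01, noise_sd=0.0, duration_s=300)
        fit = detect_linear_phase(trace, AssayConfig(direction="decrease"))
        assert fit.slope == pytest.approx(-0.01, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_trace_flagged_below_min_rate(self):
        trace, _ = mq.generate_kinetic_trace(0.0, noise_sd=0.0, duration_s=120)
        fit = detect_linear_phase(trace, AssayConfig(direction="decrease"))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.below_min_rate

    def test_lag_linear_plateau_recovery_within_two_percent(self):
        trace, truth = mq.generate_kinetic_trace(
            0.05, lag_s=30, plateau_onset_s=400, noise_sd=0.002,
            duration_s=600, dt_s=2, seed=5)
        fit = detect_linear_phase(
            trace, AssayConfig(direction="increase", mode="max_rate", window_points=90))
        assert fit.slope == pytest.approx(truth["true_slope_per_min"], rel=0.02)

    def test_offset_invariance(self):
        trace, _ = mq.generate_kinetic_trace(
            0.05, lag_s=30, plateau_onset_s=400, noise_sd=0.002,
            duration_s=600, seed=5)
        cfg = AssayConfig(direction="increase", mode="max_rate", window_points=90)
        f0 = detect_linear_phase(trace, cfg)
        shifted = trace.assign(value=trace["value"] + 3.7)
        f1 = detect_linear_phase(shifted, cfg)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-12)
        assert (f1.start, f1.stop) == (f0.start, f0.stop)

    def test_no_linear_phase_raises_with_diagnostics(self):
        rng = np.random.default_rng(0)
        trace = pd.DataFrame({"time_s": np.arange(50) * 2.0,
                              "value": rng.normal(0, 1, 50)})
        with pytest.raises(NoLinearPhaseError, match="best r2"):
            detect_linear_phase(trace, AssayConfig())


class TestActivityConversion:
    def test_zero_slope_is_zero_units(self):
        out = activity_from_slope(PhaseFit(0, 10, 0.0, 0.0, 1.0), AssayConfig())
        assert out["activity_U"] == 0.0

    def test_worked_unit_conversion(self):
        # 0.0622 A/min over 6.22 mM^-1 cm^-1 in 1 mL = 0.01 µmol/min
        out = activity_from_slope(PhaseFit(0, 10, 0.0622, 0.0, 1.0), AssayConfig())
        assert out["activity_U"] == pytest.approx(0.01)

    def test_doubling_protein_halves_specific_activity(self):
        fit = PhaseFit(0, 10, -0.05, 0.0, 1.0)
        a1 = activity_from_slope(fit, AssayConfig(protein_mg=1.0))
        a2 = activity_from_slope(fit, AssayConfig(protein_mg=2.0))
        assert a2["specific_activity_U_per_mg"] == pytest.approx(
            a1["specific_activity_U_per_mg"] / 2)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(
        slope=st.floats(0.001, 1.0),
        eps=st.floats(0.5, 20.0),
        path=st.floats(0.2, 5.0),
        vol=st.floats(0.1, 10.0),
        prot=st.floats(0.1, 10.0),
        k=st.floats(1.1, 5.0),
    )
    def test_unit_coherence_scalings(self, slope, eps, path, vol, prot, k):
        """U is linear in volume and inverse-linear in ε, path; specific
        activity inverse-linear in protein."""
        fit = PhaseFit(0, 10, slope, 0.0, 1.0)
        base = activity_from_slope(fit, AssayConfig(
            extinction_coeff=eps, path_cm=path, volume_mL=vol, protein_mg=prot))
        assert activity_from_slope(fit, AssayConfig(
            extinction_coeff=eps, path_cm=path, volume_mL=k * vol, protein_mg=prot)
        )["activity_U"] == pytest.approx(k * base["activity_U"])
        assert activity_from_slope(fit, AssayConfig(
            extinction_coeff=k * eps, path_cm=path, volume_mL=vol, protein_mg=prot)
        )["activity_U"] == pytest.approx(base["activity_U"] / k)
        assert activity_from_slope(fit, AssayConfig(
            extinction_coeff=eps, path_cm=k * path, volume_mL=vol, protein_mg=prot)
        )["activity_U"] == pytest.approx(base["activity_U"] / k)
        assert activity_from_slope(fit, AssayConfig(
            extinction_coeff=eps, path_cm=path, volume_mL=vol, protein_mg=k * prot)
        )["specific_activity_U_per_mg"] == pytest.approx(
            base["specific_activity_U_per_mg"] / k)

    def test_nonphysical_config_rejected(self):
        with pytest.raises(ValueError):
            AssayConfig(volume_mL=-1).validate()


class TestMetaboliteRates:
    def panel(self, **kw):
        base = dict(glucose_0=10.0, glucose_4=8.0, lactate_0=0.5, lactate_4=4.5,
                    intracellular_lactate_umol=0.2, volume_mL=2.0, protein_mg=1.0, dt_h=4.0)
        base.update(kw)
        return pd.DataFrame([base])

    def test_worked_consumption_rate(self):
        out = metabolite_rates(self.panel())
        assert out["glucose_consumption"] == pytest.approx(1.0)
        assert out["lactate_production"] == pytest.approx(2.0)
        assert out["lactate_glucose_ratio"] == pytest.approx(2.0)

    def test_no_lactate_change_gives_zero_ratio(self):
        out = metabolite_rates(self.panel(lactate_4=0.5))
        assert out["lactate_production"] == 0.0
        assert out["lactate_glucose_ratio"] == 0.0

    def test_ratio_above_glycolytic_ceiling_warns(self):
        with pytest.warns(UserWarning, match="glycolytic range"):
            metabolite_rates(self.panel(lactate_4=6.0))

    def test_nonpositive_consumption_gives_missing_ratio(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = metabolite_rates(self.panel(glucose_4=10.5))
        assert np.isnan(out["lactate_glucose_ratio"])

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            metabolite_rates(self.panel(dt_h=0.0))


class TestRespirometry:
    LEVELS = {"routine": 100, "leak": 20, "fccp": [150, 180, 170], "nonmito": 10}

    def test_noise_free_summary_is_exact(self):
        trace, events, _ = mq.generate_ocr_trace(self.LEVELS, noise_sd=0.0)
        s = respirometry_summary(trace, events)
        assert s["Cr_corrected"] == pytest.approx(90.0)
        assert s["CrO_corrected"] == pytest.approx(10.0)
        assert s["CrU_corrected"] == pytest.approx(170.0)
        assert s["spare_capacity"] == pytest.approx(80.0)
        assert s["coupling_efficiency"] == pytest.approx(8.0 / 9.0)
        assert not s["quality_flag"]

    def test_no_events_reports_only_cr(self):
        trace, events, _ = mq.generate_ocr_trace({"routine": 75.0}, noise_sd=0.0)
        with pytest.warns(UserWarning, match="ROX"):
            s = respirometry_summary(trace, events)
        assert s["Cr"] == pytest.approx(75.0)
        assert s["CrO"] is None and s["CrU"] is None
        assert s["spare_capacity"] is None and s["coupling_efficiency"] is None

    def test_noisy_plateaus_within_two_sem(self):
        trace, events, truth = mq.generate_ocr_trace(self.LEVELS, noise_sd=5.0, seed=2)
        s = respirometry_summary(trace, events)
        assert abs(s["Cr"] - 100) < 2 * s["sem"]["Cr"] + 1e-9
        assert abs(s["CrO"] - 20) < 2 * s["sem"]["CrO"] + 1e-9
        # CrU picks the max plateau; compare against the largest true level
        assert abs(s["CrU"] - 180) < 4 * s["sem"]["CrU"] + 1e-9

    def test_inverted_levels_set_quality_flag(self):
        trace, events, _ = mq.generate_ocr_trace(
            {"routine": 50, "leak": 80, "fccp": [60], "nonmito": 5}, noise_sd=0.0)
        s = respirometry_summary(trace, events)
        assert s["quality_flag"]

    def test_rox_constant_used_when_no_inhibitor(self):
        trace, events, _ = mq.generate_ocr_trace(
            {"routine": 100, "leak": 20, "fccp": [180]}, noise_sd=0.0)
        s = respirometry_summary(trace, events, rox_constant=10.0)
        assert s["Cr_corrected"] == pytest.approx(90.0)
        assert s["CrU_corrected"] == pytest.approx(170.0)


class TestSphereFormation:
    def test_worked_sfe(self):
        counts = pd.DataFrame({"well": [0], "condition": ["c"], "n_seeded": [2000],
                               "n_spheres": [40]})
        wells, summary = sphere_formation_efficiency(counts)
        assert wells["sfe_pct"].iloc[0] == pytest.approx(2.0)

    def test_all_zero_wells(self):
        counts = pd.DataFrame({"well": range(3), "condition": "c", "n_seeded": 2000,
                               "n_spheres": 0})
        _, summary = sphere_formation_efficiency(counts)
        assert summary["mean"].iloc[0] == 0.0 and summary["sd"].iloc[0] == 0.0

    def test_zero_seeded_rejected(self):
        counts = pd.DataFrame({"well": [0], "condition": ["c"], "n_seeded": [0],
                               "n_spheres": [0]})
        with pytest.raises(ValueError):
            sphere_formation_efficiency(counts)


class TestStudentsT:
    def test_identical_groups(self):
        out = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p_two_sided"] == 1.0 and out["stars"] == ""

    def test_hand_computed_case(self):
        out = students_t_test([1, 2, 3], [4, 5, 6])
        assert out["t"] == pytest.approx(-3.674, abs=1e-3)
        assert out["df"] == 4
        assert out["p_two_sided"] == pytest.approx(0.0213, abs=1e-3)
        assert out["stars"] == "*"

    def test_star_thresholds(self):
        strong = students_t_test([1.0, 1.1, 0.9, 1.05], [5.0, 5.1, 4.9, 5.05])
        assert strong["p_two_sided"] < 0.001 and strong["stars"] == "***"
        weak = students_t_test([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert weak["p_two_sided"] > 0.05 and weak["stars"] == ""

    def test_matches_scipy_reference_on_random_cases(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), rng.integers(3, 12))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), rng.integers(3, 12))
            out = students_t_test(a, b)
            ref_t, ref_p = stats.ttest_ind(a, b, equal_var=True)
            assert out["t"] == pytest.approx(ref_t, abs=1e-9)
            assert out["p_two_sided"] == pytest.approx(ref_p, abs=1e-9)

    def test_zero_variance_cases(self):
        out = students_t_test([2.0, 2.0], [2.0, 2.0])
        assert out["p_two_sided"] == 1.0
        with pytest.raises(ValueError, match="zero pooled variance"):
            students_t_test([2.0, 2.0], [3.0, 3.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            students_t_test([1.0], [2.0, 3.0])
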