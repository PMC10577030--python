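"""The measurement chain: calibration, drift correction, extraction."""

import numpy as np
import pytest

from antcut import (
    ForceTrace,
    apply_calibration,
    check_validity,
    correct_drift,
    correct_lamina_thickness,
    extract_forces,
    fit_calibration,
)
from antcut.simulate import TraceGenParams, gen_calibration_table, gen_trace_pair


def _aic_oracle(forces, readings, degree):
    """Independent AIC computation from first principles."""
    coeffs = np.polynomial.polynomial.polyfit(forces, readings, degree)
    resid = readings - np.polynomial.polynomial.polyval(forces, coeffs)
    rss = float(resid @ resid)
    n = len(forces)
    k = degree + 2  # coefficients + variance
    return n * np.log(rss / n) + 2 * k


class TestCalibration:
    def test_exactly_quadratic_readings_select_degree_two(self):
        F = np.linspace(0.01, 0.245, 10)
        r = 0.1 + 1.5 * F - 0.9 * F**2
        model = fit_calibration(F, r)
        assert model.degree == 2
        resid = r - model.force_to_reading(F)
        assert np.abs(resid).max() < 1e-12

    def test_exactly_linear_readings_favour_linear_by_penalty(self):
        F = np.linspace(0.01, 0.245, 10)
        r = 1.5 * F
        model = fit_calibration(F, r)
        assert model.degree == 1
        assert model.aic_by_degree[1] <= model.aic_by_degree[2]

    def test_aic_matches_independent_formula_on_noisy_data(self, rng):
        F = np.linspace(0.01, 0.245, 12)
        r = 1.5 * F - 0.9 * F**2 + rng.normal(0, 1e-3, 12)
        model = fit_calibration(F, r)
        for d in (1, 2, 3):
            assert model.aic_by_degree[d] == pytest.approx(_aic_oracle(F, r, d))

    def test_underdetermined_degree_rejected(self):
        F = np.array([0.01, 0.02, 0.03])
        with pytest.raises(ValueError):
            fit_calibration(F, 1.5 * F, degrees=(3,))

    def test_round_trip_identity_within_fit_range(self, default_calibration):
        F = np.linspace(0.012, 0.24, 25)
        back = default_calibration.reading_to_force(
            default_calibration.force_to_reading(F))
        np.testing.assert_allclose(back, F, atol=1e-9)

    def test_nonmonotone_readings_warn(self):
        F = np.linspace(0.01, 0.245, 10)
        r = (F - 0.12) ** 2  # folds back on itself
        with pytest.warns(UserWarning):
            model = fit_calibration(F, r)
        assert not model.monotone


def _calibrated_pair(params, calib):
    cut, spacing = gen_trace_pair(params)
    cut = correct_drift(apply_calibration(cut, calib))
    spacing = correct_drift(apply_calibration(spacing, calib))
    return cut, spacing


class TestDriftCorrection:
    def test_zero_drift_leaves_forces_unchanged(self, default_calibration):
        cut, _ = gen_trace_pair(TraceGenParams(noise_sd=0.0, drift_rate=0.0))
        calibrated = apply_calibration(cut, default_calibration)
        corrected = correct_drift(calibrated)
        np.testing.assert_allclose(corrected.force, calibrated.force, atol=1e-9)
        assert corrected.drift_rate == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_drift_rate(self, default_calibration):
        cut, _ = gen_trace_pair(TraceGenParams(noise_sd=0.0, drift_rate=1e-5))
        corrected = correct_drift(apply_calibration(cut, default_calibration))
        assert corrected.drift_rate == pytest.approx(1e-5, rel=1e-6)

    def test_pure_ramp_recovers_ramp_slope(self):
        # with no unloaded plateau the "drift" IS the ramp slope
        t = np.linspace(0, 10, 801)
        trace = ForceTrace(time=t, raw_reading=0.002 * t, motor_pos_mm=0.1 * t,
                           force=0.002 * t)
        corrected = correct_drift(trace, ((0.0, 1.5), (8.5, 10.0)))
        assert corrected.drift_rate == pytest.approx(0.002, rel=1e-12)

    def test_overlapping_windows_rejected(self):
        t = np.linspace(0, 10, 801)
        trace = ForceTrace(time=t, raw_reading=t, motor_pos_mm=t, force=t)
        with pytest.raises(ValueError):
            correct_drift(trace, ((0.0, 5.0), (4.0, 10.0)))

    def test_uncalibrated_trace_rejected(self):
        cut, _ = gen_trace_pair(TraceGenParams())
        with pytest.raises(ValueError):
            correct_drift(cut)


class TestExtraction:
    def test_noiseless_pair_recovers_configured_forces(self, default_calibration):
        params = TraceGenParams(true_cut_force=0.065, true_spacing_force=0.005,
                                noise_sd=0.0, drift_rate=0.0)
        cut, spacing = _calibrated_pair(params, default_calibration)
        m = extract_forces(cut, spacing)
        assert m.F_c == pytest.approx(0.065, abs=1e-9)
        assert m.F_s == pytest.approx(0.005, abs=1e-9)
        assert m.F_f == pytest.approx(0.060, abs=1e-9)
        assert m.valid

    def test_fracture_force_conservation(self, default_calibration):
        cut, spacing = _calibrated_pair(TraceGenParams(seed=11), default_calibration)
        m = extract_forces(cut, spacing)
        assert m.F_f == m.F_c - m.F_s  # exact, not approximate

    def test_spacing_identical_to_cut_gives_zero_fracture_force(self, default_calibration):
        cut, _ = _calibrated_pair(TraceGenParams(noise_sd=0.0), default_calibration)
        m = extract_forces(cut, cut)
        assert m.F_f == 0.0

    def test_extraction_invariant_to_linear_drift(self, default_calibration):
        no_drift = TraceGenParams(noise_sd=0.0, drift_rate=0.0)
        with_drift = TraceGenParams(noise_sd=0.0, drift_rate=2e-5)
        m0 = extract_forces(*_calibrated_pair(no_drift, default_calibration))
        m1 = extract_forces(*_calibrated_pair(with_drift, default_calibration))
        assert m1.F_c == pytest.approx(m0.F_c, abs=1e-9)
        assert m1.F_s == pytest.approx(m0.F_s, abs=1e-9)

    def test_short_steady_state_flagged_invalid(self, default_calibration):
        # 2.0 mm travel leaves ~1.5 mm of plateau, short of the 2 mm window
        params = TraceGenParams(noise_sd=0.0, drift_rate=0.0, total_travel=2.0e-3)
        cut, spacing = _calibrated_pair(params, default_calibration)
        m = extract_forces(cut, spacing)
        assert not m.flags.steady_state_long_enough
        assert not m.valid

    def test_window_positions_match_between_passes(self, default_calibration):
        cut, spacing = _calibrated_pair(TraceGenParams(noise_sd=0.0), default_calibration)
        m = extract_forces(cut, spacing)
        x0, x1 = m.window
        assert x1 - x0 == pytest.approx(2.0)
        # both passes sample the full window
        for tr in (cut, spacing):
            pos = tr.motor_pos_mm[: int(np.argmax(tr.motor_pos_mm)) + 1]
            assert pos.min() <= x0 and pos.max() >= x1

    def test_monte_carlo_recovery_under_noise_and_drift(self, default_calibration):
        errors = []
        for seed in range(60):
            params = TraceGenParams(seed=seed)
            cut, spacing = _calibrated_pair(params, default_calibration)
            m = extract_forces(cut, spacing)
            assert m.valid
            errors.append(m.F_c - params.true_cut_force)
        errors = np.asarray(errors)
        n_window = 2.0 / 0.3 * 81.4  # samples in a 2 mm window
        budget = 3 * TraceGenParams().noise_sd / np.sqrt(n_window)
        assert np.abs(errors).mean() < budget
        assert abs(errors.mean()) < budget


class TestValidity:
    def test_force_beyond_calibration_range_fails(self):
        flags = check_validity(F_c=0.250, steady_len_mm=3.0, window_mm=2.0)
        assert not flags.in_calibration_range
        assert not flags.all_pass

    def test_short_plateau_fails_steady_state(self):
        flags = check_validity(F_c=0.065, steady_len_mm=1.5, window_mm=2.0)
        assert not flags.steady_state_long_enough

    def test_clean_measurement_passes(self):
        flags = check_validity(F_c=0.065, steady_len_mm=4.0, window_mm=2.0)
        assert flags.all_pass

    def test_observational_flags_propagate(self):
        flags = check_validity(F_c=0.065, steady_len_mm=4.0, window_mm=2.0,
                               no_slip_out=False)
        assert not flags.all_pass


class TestLaminaCorrection:
    def test_equal_thickness_is_identity(self):
        assert correct_lamina_thickness(0.1, 256e-6, 256e-6) == 0.1

    def test_half_thickness_doubles_force(self):
        assert correct_lamina_thickness(0.100, 128e-6, 256e-6) == pytest.approx(0.200)

    def test_zero_force_stays_zero(self):
        assert correct_lamina_thickness(0.0, 100e-6, 256e-6) == 0.0

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            correct_lamina_thickness(0.1, 0.0, 256e-6)
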