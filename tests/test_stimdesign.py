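"""Forward model and silent-substitution solver."""

import numpy as np
import pytest

from silentpupil.spectral import Spectrum, stimulus_contrasts
from silentpupil.stimdesign import (
    DeviceCalibration,
    DeviceSettings,
    SilentSubstitutionProblem,
    gamut_is_degenerate,
    narrowband_pair,
    predict_spd,
    solve_matched_contrast,
    solve_max_contrast,
    verify_pair,
)
from silentpupil.synthetic import make_device_calibration

GRID = np.arange(380.0, 781.0, 1.0)


def three_level_cal():
    """One-primary calibration with a visibly nonlinear level response."""
    shape = np.exp(-0.5 * ((GRID - 550.0) / 20.0) ** 2)
    gains = [0.0, 0.3, 1.0]           # at levels 0, 0.5, 1
    spectra = tuple(Spectrum(GRID, g * shape) for g in gains)
    return DeviceCalibration(levels=((0.0, 0.5, 1.0),), spectra=(spectra,)), shape


class TestPredictSpd:
    def test_all_zero_settings(self, device):
        spd = predict_spd(device, DeviceSettings(np.zeros(10)))
        assert np.all(spd.values == 0.0)

    def test_exact_measured_level(self):
        cal, shape = three_level_cal()
        spd = predict_spd(cal, DeviceSettings(np.array([0.5])))
        np.testing.assert_allclose(spd.values, 0.3 * shape)

    def test_midpoint_interpolation_oracle(self):
        # hand-computed per-wavelength linear interpolation between knots
        cal, shape = three_level_cal()
        spd = predict_spd(cal, DeviceSettings(np.array([0.75])))
        expected = (0.3 + (1.0 - 0.3) * 0.5) * shape
        np.testing.assert_allclose(spd.values, expected, rtol=1e-12)

    def test_superposition(self, device):
        a = np.zeros(10); a[2] = 0.7
        b = np.zeros(10); b[7] = 0.4
        both = a + b
        sa = predict_spd(device, DeviceSettings(a)).values
        sb = predict_spd(device, DeviceSettings(b)).values
        sab = predict_spd(device, DeviceSettings(both)).values
        np.testing.assert_allclose(sab, sa + sb, rtol=1e-12)

    def test_out_of_bounds_settings_rejected(self, device):
        with pytest.raises(ValueError):
            DeviceSettings(np.full(10, 1.5))


class TestMaxContrastSolver:
    def test_boxcar_toy_closed_form(self, boxcar_toy):
        # cones see only primary 1 (silenced: equal levels both phases);
        # melanopsin sees only primary 0, so the optimum puts the pulse at
        # full output and the background at the floor:
        # contrast = 100*(1 - floor)/floor
        cal, sens_set = boxcar_toy
        floor = 0.10
        problem = SilentSubstitutionProblem(
            target=("melanopsin",), silenced=("L", "M", "S"),
            mode="maximize", background_floor=floor, restarts=6, seed=0)
        pair = solve_max_contrast(cal, problem, sens_set)
        analytic = 100.0 * (1.0 - floor) / floor
        assert pair.contrasts.melanopsin == pytest.approx(analytic, rel=1e-3)
        for cone in ("L", "M", "S"):
            assert abs(getattr(pair.contrasts, cone)) < 1e-3
        # cone-driving primary equal across phases
        assert pair.background_settings.values[1] == pytest.approx(
            pair.pulse_settings.values[1], abs=1e-5)

    def test_relaxing_silencing_cannot_reduce_objective(self, boxcar_toy):
        cal, sens_set = boxcar_toy
        kw = dict(target=("melanopsin",), mode="maximize",
                  background_floor=0.1, restarts=6, seed=0)
        constrained = solve_max_contrast(
            cal, SilentSubstitutionProblem(silenced=("L", "M", "S"), **kw),
            sens_set)
        unconstrained = solve_max_contrast(
            cal, SilentSubstitutionProblem(silenced=(), **kw), sens_set)
        assert unconstrained.contrasts.melanopsin >= \
            constrained.contrasts.melanopsin - 1e-6

    def test_seed_reproducibility(self, device):
        problem = SilentSubstitutionProblem(
            target=("melanopsin",), silenced=("L", "M", "S"),
            mode="maximize", restarts=4, seed=11)
        p1 = solve_max_contrast(device, problem)
        p2 = solve_max_contrast(device, problem)
        np.testing.assert_array_equal(p1.background_settings.values,
                                      p2.background_settings.values)
        np.testing.assert_array_equal(p1.pulse_settings.values,
                                      p2.pulse_settings.values)

    def test_reported_contrasts_match_spectra(self, device, sens):
        # solver-reported contrasts must equal contrasts recomputed from the
        # predicted spectra (the fast radiance model vs the full integral)
        problem = SilentSubstitutionProblem(
            target=("melanopsin",), silenced=("L", "M", "S"),
            mode="maximize", restarts=4, seed=2)
        pair = solve_max_contrast(device, problem)
        recomputed = stimulus_contrasts(pair.background_spectrum,
                                        pair.pulse_spectrum, sens)
        for name, val in pair.contrasts.as_dict().items():
            assert val == pytest.approx(getattr(recomputed, name), abs=1e-6)


class TestMatchedContrastSolver:
    def test_boxcar_toy_match_100(self, boxcar_toy):
        # closed form: cone contrast is linear in the cone-primary levels,
        # so match_contrast=100 needs pulse = 2 x background on primary 1
        cal, sens_set = boxcar_toy
        problem = SilentSubstitutionProblem(
            target=("L", "M", "S"), silenced=("melanopsin",),
            mode="match", match_contrast=100.0,
            background_floor=0.1, restarts=6, seed=0)
        pair = solve_matched_contrast(cal, problem, sens_set)
        assert pair.contrasts.lms_mean == pytest.approx(100.0, abs=0.1)
        assert abs(pair.contrasts.melanopsin) < 1e-3
        ratio = (pair.pulse_settings.values[1]
                 / pair.background_settings.values[1])
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_match_zero_contrast(self, boxcar_toy):
        cal, sens_set = boxcar_toy
        problem = SilentSubstitutionProblem(
            target=("L", "M", "S"), silenced=("melanopsin",),
            mode="match", match_contrast=0.0,
            background_floor=0.1, restarts=4, seed=0)
        pair = solve_matched_contrast(cal, problem, sens_set)
        for v in pair.contrasts.as_dict().values():
            assert v == pytest.approx(0.0, abs=1e-3)


class TestVerifyPair:
    def test_identical_spectra_silenced_pass_target_fail(self, device, sens):
        spd = predict_spd(device, DeviceSettings(np.full(10, 0.5)))
        from silentpupil.stimdesign import StimulusPair
        pair = StimulusPair(
            background_settings=DeviceSettings(np.full(10, 0.5)),
            pulse_settings=DeviceSettings(np.full(10, 0.5)),
            background_spectrum=spd, pulse_spectrum=spd,
            contrasts=stimulus_contrasts(spd, spd, sens),
            background_luminance=0.0, pulse_luminance=0.0)
        problem = SilentSubstitutionProblem(
            target=("melanopsin",), silenced=("L", "M", "S"), mode="maximize")
        report = verify_pair(pair, problem)
        assert report.all_silenced_ok
        assert not report.target_ok

    def test_deliberate_violation_flagged(self, device, sens):
        # push one cone past the tolerance by brightening the pulse
        bg = predict_spd(device, DeviceSettings(np.full(10, 0.4)))
        pulse = predict_spd(device, DeviceSettings(np.full(10, 0.8)))
        from silentpupil.stimdesign import StimulusPair
        pair = StimulusPair(
            background_settings=DeviceSettings(np.full(10, 0.4)),
            pulse_settings=DeviceSettings(np.full(10, 0.8)),
            background_spectrum=bg, pulse_spectrum=pulse,
            contrasts=stimulus_contrasts(bg, pulse, sens),
            background_luminance=0.0, pulse_luminance=0.0)
        problem = SilentSubstitutionProblem(
            target=("melanopsin",), silenced=("L", "M", "S"), mode="maximize")
        report = verify_pair(pair, problem)
        assert not report.all_silenced_ok


class TestNarrowband:
    def test_identical_primaries_equal_output(self):
        shape = np.exp(-0.5 * ((GRID - 500.0) / 15.0) ** 2)
        zero = Spectrum(GRID, np.zeros_like(GRID))
        sp = Spectrum(GRID, shape)
        cal = DeviceCalibration(
            levels=((0.0, 1.0), (0.0, 1.0)),
            spectra=((zero, sp), (zero, sp)))
        red, blue = narrowband_pair(cal, 0, 1)
        np.testing.assert_allclose(red.values, blue.values, rtol=1e-12)

    def test_two_to_one_ratio_scaled_by_half(self):
        shape = np.exp(-0.5 * ((GRID - 500.0) / 15.0) ** 2)
        zero = Spectrum(GRID, np.zeros_like(GRID))
        cal = DeviceCalibration(
            levels=((0.0, 1.0), (0.0, 1.0)),
            spectra=((zero, Spectrum(GRID, 2.0 * shape)),
                     (zero, Spectrum(GRID, shape))))
        big, small = narrowband_pair(cal, 0, 1)
        np.testing.assert_allclose(big.values, shape, rtol=1e-12)

    def test_synthetic_device_totals_match(self, device):
        red, blue = narrowband_pair(device, 8, 2)
        tr = np.trapezoid(red.values, red.wavelengths)
        tb = np.trapezoid(blue.values, blue.wavelengths)
        assert tr == pytest.approx(tb, rel=1e-6)


class TestGamut:
    def test_distinct_primaries_not_degenerate(self, device, sens):
        assert not gamut_is_degenerate(device, sens,
                                       ["melanopsin", "L", "M", "S"])

    def test_duplicated_primaries_degenerate(self, sens):
        cal = make_device_calibration(n_primaries=2,
                                      peak_wavelengths_nm=[500.0, 500.0])
        assert gamut_is_degenerate(cal, sens, ["melanopsin", "L", "M", "S"])

    def test_solver_warns_on_degenerate_gamut(self, sens):
        cal = make_device_calibration(n_primaries=2,
                                      peak_wavelengths_nm=[500.0, 500.0])
        problem = SilentSubstitutionProblem(
            target=("melanopsin",), silenced=("L", "M", "S"), mode="maximize",
            restarts=2, seed=0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            try:
                solve_max_contrast(cal, problem, sens)
            except Exception:
                pass  # a degenerate device may legitimately fail to solve
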