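import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanmargin.axis import default_axis
from ramanmargin.cube import HyperCube, Stage
from ramanmargin.phantom import build_phantom_scene
from ramanmargin.preprocess import (CalibrationError, ResponseCurve,
                                    calibrate_wavenumber_axis,
                                    correct_instrument_response,
                                    estimate_instrument_response,
                                    preprocess_cube, remove_cosmic_rays,
                                    snv_normalize, subtract_dark_background)
from ramanmargin.simulate import (ACETAMINOPHEN_PEAKS, AcquisitionParams,
                                  certified_srm_shape, simulate_raw_cube,
                                  simulate_reference_measurements)

AXIS = default_axis()
X = AXIS.values


def raw_cube(spectra_2d):
    """Wrap (n, bins) spectra into an n x 1 raw cube."""
    arr = np.asarray(spectra_2d, dtype=float)[:, None, :]
    return HyperCube(arr, AXIS, stage=Stage.RAW)


class TestDespike:
    def test_isolated_spike_restored_to_flat_level(self):
        flat = np.full(AXIS.n_bins, 10.0)
        spiked = flat.copy()
        spiked[50] += 1000.0
        out = remove_cosmic_rays(raw_cube([spiked]), window=5)
        np.testing.assert_allclose(out.intensities[0, 0], flat, atol=1e-9)

    def test_smooth_spectrum_untouched(self):
        smooth = 100.0 + 50.0 * np.sin(X / 200.0) + np.exp(-0.5 * ((X - 900) / 8) ** 2) * 400
        out = remove_cosmic_rays(raw_cube([smooth]), window=3)
        np.testing.assert_allclose(out.intensities[0, 0][1:-1], smooth[1:-1],
                                   rtol=0.01)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            remove_cosmic_rays(raw_cube([np.ones(AXIS.n_bins)]), window=4)

    def test_requires_raw_stage(self):
        cube = raw_cube([np.ones(AXIS.n_bins)]).advance(
            np.ones((1, 1, AXIS.n_bins)), Stage.DESPIKED, "noop")
        with pytest.raises(ValueError, match="raw cube"):
            remove_cosmic_rays(cube)

    def test_narrow_real_peaks_survive_despiking(self):
        # a genuine Raman peak two bins wide must not be eroded
        peak = 200.0 + 500.0 * np.exp(-0.5 * ((X - 1004) / 5.1) ** 2)
        out = remove_cosmic_rays(raw_cube([peak]), window=5)
        apex = AXIS.index_of(1004.0)
        assert out.intensities[0, 0, apex] == peak[apex]


class TestAxisCalibration:
    def _standard(self, pixel_map=None, noise_sd=0.0):
        params = AcquisitionParams(n_rows=2, n_cols=2, seed=3)
        acet, _, _ = simulate_reference_measurements(
            params, true_pixel_map=pixel_map, axis=AXIS, noise_sd=noise_sd)
        return acet

    def test_identity_map_recovered_with_small_residual(self):
        axis, rms = calibrate_wavenumber_axis(self._standard(), degree=2)
        assert rms < 0.5
        np.testing.assert_allclose(axis.values, AXIS.values, atol=1.0)

    def test_known_quadratic_map_recovers_reference_lines_within_1cm(self):
        coeffs = np.array([402.0, 5.6, 0.0016])
        axis, _ = calibrate_wavenumber_axis(
            self._standard(pixel_map=coeffs), degree=2)
        pix = np.arange(AXIS.n_bins, dtype=float)
        true_wn = np.polynomial.polynomial.polyval(pix, coeffs)
        for ref in ACETAMINOPHEN_PEAKS:
            true_pix = np.interp(ref, true_wn, pix)
            fitted = np.polynomial.polynomial.polyval(
                true_pix, axis.pixel_map_coeffs)
            assert abs(fitted - ref) < 1.0

    def test_too_few_peaks_reported_with_count(self):
        two_peaks = (np.exp(-0.5 * ((X - 700) / 8) ** 2)
                     + np.exp(-0.5 * ((X - 1300) / 8) ** 2))
        with pytest.raises(CalibrationError, match="2 peaks"):
            calibrate_wavenumber_axis(two_peaks * 100, degree=2)


class TestInstrumentResponse:
    def test_identity_when_measured_equals_certified(self):
        certified = certified_srm_shape(AXIS)
        response = estimate_instrument_response(certified, certified)
        np.testing.assert_allclose(response.values, 1.0, atol=0.02)

    def test_known_ramp_gain_recovered(self):
        certified = certified_srm_shape(AXIS)
        g = np.linspace(0.8, 1.2, AXIS.n_bins)
        response = estimate_instrument_response(certified * g, certified)
        interior = slice(20, -20)
        np.testing.assert_allclose(response.values[interior],
                                   (g / np.median(g))[interior], rtol=0.02)

    def test_nonpositive_certified_rejected(self):
        certified = certified_srm_shape(AXIS)
        bad = certified.copy()
        bad[100] = 0.0
        with pytest.raises(ValueError, match="positive"):
            estimate_instrument_response(certified, bad)

    def test_unit_response_leaves_cube_unchanged(self):
        cube = raw_cube([np.linspace(1, 2, AXIS.n_bins)])
        cube = remove_cosmic_rays(cube)
        out = correct_instrument_response(cube, ResponseCurve(np.ones(AXIS.n_bins)))
        np.testing.assert_array_equal(out.intensities, cube.intensities)

    def test_correction_inverts_known_gain(self):
        base = np.abs(np.sin(X / 300.0)) + 1.0
        g = np.linspace(0.8, 1.2, AXIS.n_bins)
        cube = remove_cosmic_rays(raw_cube([base * g]))
        out = correct_instrument_response(cube, ResponseCurve(g))
        np.testing.assert_allclose(out.intensities[0, 0], base, rtol=1e-6)

    def test_constant_gain_of_two_halves_intensities(self):
        cube = remove_cosmic_rays(raw_cube([np.full(AXIS.n_bins, 10.0)]))
        out = correct_instrument_response(
            cube, ResponseCurve(np.full(AXIS.n_bins, 2.0)))
        np.testing.assert_allclose(out.intensities, 5.0)

    def test_jumpy_response_curve_rejected(self):
        values = np.ones(AXIS.n_bins)
        values[100] = 2.0
        with pytest.raises(ValueError, match="smooth"):
            ResponseCurve(values)


class TestDarkSubtraction:
    def _at_baseline_stage(self, spectra):
        cube = remove_cosmic_rays(raw_cube(spectra))
        return cube.advance(cube.intensities, Stage.BASELINE_REMOVED, "jump",
                            allow_reorder=False)

    def test_zero_dark_is_identity(self):
        cube = self._at_baseline_stage([np.linspace(0, 5, AXIS.n_bins)])
        dark = HyperCube(np.zeros_like(cube.intensities), AXIS)
        out = subtract_dark_background(cube, dark)
        np.testing.assert_array_equal(out.intensities, cube.intensities)

    def test_exact_inverse_pair(self):
        signal = np.linspace(0, 5, AXIS.n_bins)
        d = np.abs(np.cos(X / 100.0)) * 3.0
        cube = self._at_baseline_stage([signal + d])
        dark = HyperCube(d[None, None, :], AXIS)
        out = subtract_dark_background(cube, dark)
        np.testing.assert_allclose(out.intensities[0, 0], signal, atol=1e-9)

    def test_integration_time_scaling(self):
        signal = np.linspace(0, 5, AXIS.n_bins)
        d = np.abs(np.cos(X / 100.0)) * 3.0
        cube = self._at_baseline_stage([signal + d])
        dark = HyperCube(2.0 * d[None, None, :], AXIS)
        out = subtract_dark_background(cube, dark, scale=0.5)
        np.testing.assert_allclose(out.intensities[0, 0], signal, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        cube = self._at_baseline_stage([np.ones(AXIS.n_bins)])
        dark = HyperCube(np.zeros((2, 2, AXIS.n_bins)), AXIS)
        with pytest.raises(ValueError, match="shape"):
            subtract_dark_background(cube, dark)


class TestSNV:
    def test_three_point_example(self):
        np.testing.assert_allclose(snv_normalize([1.0, 2.0, 3.0]),
                                   [-1.0, 0.0, 1.0], atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_zero_mean_unit_sd_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(5.0, 3.0, 64)
        s = snv_normalize(x)
        assert abs(s.mean()) < 1e-9
        assert abs(s.std(ddof=1) - 1.0) < 1e-9
        np.testing.assert_allclose(snv_normalize(s), s, atol=1e-9)

    def test_constant_spectrum_flagged_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            snv_normalize(np.full(32, 4.0))


@pytest.fixture(scope="module")
def chain():
    scene = build_phantom_scene("tumor_block", 6, 8, seed=2)
    params = AcquisitionParams(n_rows=6, n_cols=8, seed=2)
    cube = simulate_raw_cube(scene, params)
    refs = simulate_reference_measurements(
        AcquisitionParams(n_rows=6, n_cols=8, seed=4))
    return cube, refs


class TestFullChain:

    def test_column_exclusion_marks_first_five_columns(self, chain):
        cube, (acet, std, dark) = chain
        res = preprocess_cube(cube, acet, std, dark)
        assert res.column_excluded[:, :5].all()
        assert not res.column_excluded[:, 5:].any()
        assert res.column_excluded.sum() == 6 * 5

    def test_stage_log_records_published_order(self, chain):
        cube, (acet, std, dark) = chain
        res = preprocess_cube(cube, acet, std, dark)
        steps = [e["step"] for e in res.stage_log]
        assert steps == ["simulate", "remove_cosmic_rays",
                         "calibrate_wavenumber_axis",
                         "correct_instrument_response", "bubblefill_baseline",
                         "subtract_dark_background", "snv_normalize",
                         "exclude_columns"]

    def test_reordered_dark_subtraction_changes_log(self, chain):
        cube, (acet, std, dark) = chain
        res = preprocess_cube(cube, acet, std, dark, dark_before_baseline=True)
        steps = [e["step"] for e in res.stage_log]
        assert steps.index("subtract_dark_background") < steps.index(
            "bubblefill_baseline")

    def test_rerun_is_deterministic(self, chain):
        cube, (acet, std, dark) = chain
        a = preprocess_cube(cube, acet, std, dark)
        b = preprocess_cube(cube, acet, std, dark)
        assert np.array_equal(a.cube.intensities, b.cube.intensities)

    def test_missing_reference_named(self, chain):
        cube, (acet, std, dark) = chain
        with pytest.raises(ValueError, match="standard"):
            preprocess_cube(cube, acet, None, dark)

    def test_output_is_snv_per_pixel(self, chain):
        cube, (acet, std, dark) = chain
        res = preprocess_cube(cube, acet, std, dark)
        ok = ~res.degenerate
        spectra = res.cube.intensities[ok]
        np.testing.assert_allclose(spectra.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(spectra.std(axis=1, ddof=1), 1.0, atol=1e-9)
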