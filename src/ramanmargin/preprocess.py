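"""Six-step spectral conditioning chain for raw Raman hypercubes.

Order (the instrument's published processing order, configurable):

1. cosmic-ray removal (median-comparison despike per spectrum)
2. wavenumber-axis calibration against an acetaminophen standard
3. instrument-response correction against a certified intensity standard
4. baseline removal (BubbleFill)
5. subtraction of the structured system background (dark frame)
6. standard normal variate (SNV) normalisation

plus exclusion bookkeeping: the first five image columns are excluded
(the intensity standard does not cover them), and zero-variance pixels
are flagged degenerate rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, savgol_filter

from .axis import WavenumberAxis
from .bubblefill import DEFAULT_MIN_BUBBLE_WIDTH, bubblefill_baseline
from .cube import HyperCube, Stage

__all__ = [
    "ResponseCurve",
    "CalibrationError",
    "PreprocessResult",
    "remove_cosmic_rays",
    "calibrate_wavenumber_axis",
    "estimate_instrument_response",
    "correct_instrument_response",
    "subtract_dark_background",
    "snv_normalize",
    "preprocess_cube",
]

N_EXCLUDED_COLUMNS = 5  # intensity-standard coverage gap at the image edge


class CalibrationError(RuntimeError):
    """Axis calibration could not find enough reference peaks."""


@dataclass
class ResponseCurve:
    """Unitless per-bin instrument gain with a positivity floor."""

    values: np.ndarray
    floor: float = 0.05

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("response curve must be strictly positive")
        jumps = np.abs(np.diff(self.values)) / self.values[:-1]
        if np.any(jumps > 0.5):
            raise ValueError("response curve must be smooth (bin jump > 50%)")


# -- step 1: despiking -------------------------------------------------

def remove_cosmic_rays(cube: HyperCube, window: int = 5, *,
                       spike_factor: float = 5.0) -> HyperCube:
    """Remove isolated cosmic-ray spikes from every spectrum.

    Each spectrum is compared with its running median; a bin is a spike
    when it exceeds the median by ``spike_factor`` times the local signal
    amplitude (peak-to-trough of the median-filtered spectrum over a
    4-window neighbourhood, floored by a robust noise scale).  Spike bins
    are replaced by the running median, all other bins pass unchanged —
    so genuine narrow Raman peaks are not eroded.
    """
    if cube.stage != Stage.RAW:
        raise ValueError(f"despiking expects a raw cube, got stage {cube.stage!r}")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")

    spectra = cube.spectra
    med = median_filter(spectra, size=(1, window), mode="nearest")
    resid = spectra - med
    # local smooth amplitude: running peak-to-trough of the median track
    from scipy.ndimage import maximum_filter1d, minimum_filter1d
    k = 4 * window + 1
    loc_max = maximum_filter1d(med, k, axis=1, mode="nearest")
    loc_min = minimum_filter1d(med, k, axis=1, mode="nearest")
    sigma = 1.4826 * np.median(np.abs(resid), axis=1, keepdims=True)
    scale = np.maximum(loc_max - loc_min, np.maximum(6.0 * sigma, 1e-12))
    spikes = resid > spike_factor * scale
    out = np.where(spikes, med, spectra).reshape(cube.intensities.shape)
    return cube.advance(out, Stage.DESPIKED, "remove_cosmic_rays",
                        window=window, spike_factor=spike_factor,
                        n_spikes=int(spikes.sum()))


# -- step 2: wavenumber calibration ------------------------------------

def calibrate_wavenumber_axis(
    measured_standard: np.ndarray,
    reference_peaks=None,
    degree: int = 2,
    *,
    prominence_sigma: float = 5.0,
) -> tuple[WavenumberAxis, float]:
    """Fit the detector-pixel → wavenumber map from a calibration spectrum.

    Peaks are detected on the measured standard (prominence above
    ``prominence_sigma`` times a robust noise scale); the strongest
    ``len(reference_peaks)`` of them, in pixel order, are matched to the
    reference wavenumbers and a degree-``degree`` polynomial is fitted by
    least squares.  Returns the calibrated axis and the fit residual RMS
    in cm⁻¹.
    """
    from .simulate import ACETAMINOPHEN_PEAKS

    if reference_peaks is None:
        reference_peaks = ACETAMINOPHEN_PEAKS
    reference_peaks = np.sort(np.asarray(reference_peaks, dtype=float))
    measured = np.asarray(measured_standard, dtype=float)
    n = measured.size

    detail = measured - savgol_filter(measured, min(31, (n // 2) * 2 - 1), 2)
    sigma = max(1.4826 * float(np.median(np.abs(detail))), 1e-9)
    peaks, props = find_peaks(measured, prominence=prominence_sigma * sigma)
    if peaks.size < degree + 1:
        raise CalibrationError(
            f"found {peaks.size} peaks, need at least {degree + 1} "
            f"for a degree-{degree} fit"
        )
    if peaks.size > reference_peaks.size:
        top = np.argsort(props["prominences"])[::-1][: reference_peaks.size]
        peaks = np.sort(peaks[top])
    if peaks.size != reference_peaks.size:
        raise CalibrationError(
            f"found {peaks.size} peaks but {reference_peaks.size} reference "
            "positions were given"
        )

    # sub-bin apex refinement by local parabola
    pix = peaks.astype(float)
    for i, p in enumerate(peaks):
        if 1 <= p <= n - 2:
            y0, y1, y2 = measured[p - 1 : p + 2]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                pix[i] = p + 0.5 * (y0 - y2) / denom

    coeffs = np.polynomial.polynomial.polyfit(pix, reference_peaks, deg=degree)
    fitted = np.polynomial.polynomial.polyval(pix, coeffs)
    rms = float(np.sqrt(np.mean((fitted - reference_peaks) ** 2)))
    values = np.polynomial.polynomial.polyval(np.arange(n, dtype=float), coeffs)
    if not np.all(np.diff(values) > 0):
        raise CalibrationError("fitted pixel map is not monotone over the detector")
    return WavenumberAxis(values, pixel_map_coeffs=coeffs), rms


# -- step 3: instrument response ---------------------------------------

def estimate_instrument_response(
    measured_standard: np.ndarray,
    certified_shape: np.ndarray,
    *,
    smooth_window: int = 31,
    floor: float = 0.05,
) -> ResponseCurve:
    """Instrument gain = smooth(measured / certified), floored below."""
    measured = np.asarray(measured_standard, dtype=float)
    certified = np.asarray(certified_shape, dtype=float)
    if measured.shape != certified.shape:
        raise ValueError("measured and certified spectra must share one axis")
    if np.any(certified <= 0):
        raise ValueError("certified shape must be strictly positive")
    ratio = measured / certified
    ratio = ratio / np.median(ratio)  # unitless gain, median-normalised
    w = min(smooth_window | 1, (measured.size // 2) * 2 - 1)
    smooth = savgol_filter(ratio, w, 2)
    return ResponseCurve(np.maximum(smooth, floor), floor=floor)


def correct_instrument_response(cube: HyperCube, response: ResponseCurve,
                                *, allow_reorder: bool = False) -> HyperCube:
    """Divide every spectrum by the instrument gain."""
    if response.values.shape != (cube.axis.n_bins,):
        raise ValueError("response curve not on the cube axis")
    if np.any(response.values <= response.floor - 1e-12):
        raise ValueError("response at or below its floor; correction unstable")
    out = cube.intensities / response.values
    return cube.advance(out, Stage.RESPONSE_CORRECTED, "correct_instrument_response",
                        allow_reorder=allow_reorder, floor=response.floor)


# -- step 5: dark background -------------------------------------------

def subtract_dark_background(cube: HyperCube, dark: HyperCube,
                             scale: float = 1.0, *,
                             allow_reorder: bool = False) -> HyperCube:
    """Subtract ``scale`` × the dark frame, pixel-wise and bin-wise.

    ``scale`` converts the dark frame's integration time to the cube's
    (e.g. 1/5 for a dark acquired at 5× the integration time).  Negative
    results are retained.
    """
    if dark.intensities.shape != cube.intensities.shape:
        raise ValueError("dark frame shape does not match cube")
    if dark.axis != cube.axis and not np.allclose(dark.axis.values, cube.axis.values):
        raise ValueError("dark frame axis does not match cube")
    out = cube.intensities - scale * dark.intensities
    return cube.advance(out, Stage.BACKGROUND_SUBTRACTED, "subtract_dark_background",
                        allow_reorder=allow_reorder, scale=scale)


# -- step 6: SNV --------------------------------------------------------

def snv_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: zero mean, unit sample (n−1) sd."""
    spectrum = np.asarray(spectrum, dtype=float)
    sd = spectrum.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant spectrum has no SNV form")
    return (spectrum - spectrum.mean()) / sd


# -- full chain ---------------------------------------------------------

@dataclass
class PreprocessResult:
    """SNV cube plus per-pixel exclusion metadata and the stage log."""

    cube: HyperCube
    column_excluded: np.ndarray  # (rows, cols) bool
    degenerate: np.ndarray       # (rows, cols) bool
    calibration_rms: float
    response: ResponseCurve
    baselines: np.ndarray = field(repr=False, default=None)  # type: ignore

    @property
    def stage_log(self) -> list:
        return self.cube.stage_log


def preprocess_cube(
    raw: HyperCube,
    acetaminophen: np.ndarray,
    standard: np.ndarray,
    dark: HyperCube,
    *,
    reference_peaks=None,
    certified_shape: np.ndarray | None = None,
    median_window: int = 5,
    calibration_degree: int = 2,
    min_bubble_width: float = DEFAULT_MIN_BUBBLE_WIDTH,
    dark_scale: float | None = None,
    dark_integration_factor: float = 5.0,
    n_excluded_columns: int = N_EXCLUDED_COLUMNS,
    dark_before_baseline: bool = False,
) -> PreprocessResult:
    """Run the full conditioning chain on a raw cube.

    ``dark_before_baseline=True`` moves the dark subtraction ahead of
    baseline removal (physically motivated alternative); the default
    keeps the published order.  The dark frame receives the same
    response correction as the cube so the subtraction cancels the
    background it measured.
    """
    for name, ref in (("acetaminophen", acetaminophen), ("standard", standard),
                      ("dark", dark)):
        if ref is None:
            raise ValueError(f"missing reference measurement: {name}")
    if certified_shape is None:
        from .simulate import certified_srm_shape
        certified_shape = certified_srm_shape(raw.axis)
    if dark_scale is None:
        dark_scale = 1.0 / dark_integration_factor

    # 1. despike
    cube = remove_cosmic_rays(raw, window=median_window)

    # 2. axis calibration (relabels bins; no resampling)
    axis, cal_rms = calibrate_wavenumber_axis(
        np.asarray(acetaminophen, dtype=float),
        reference_peaks=reference_peaks,
        degree=calibration_degree,
    )
    if axis.n_bins != cube.axis.n_bins:
        raise ValueError("calibration spectrum not on the cube's detector grid")
    cube = cube.advance(cube.intensities, Stage.CALIBRATED,
                        "calibrate_wavenumber_axis", axis=axis,
                        residual_rms=cal_rms, degree=calibration_degree)

    # 3. response correction (cube and dark alike)
    response = estimate_instrument_response(
        np.asarray(standard, dtype=float), np.asarray(certified_shape, dtype=float))
    cube = correct_instrument_response(cube, response)
    dark_corr = dark.intensities / response.values

    def _subtract_dark(c: HyperCube, reorder: bool) -> HyperCube:
        out = c.intensities - dark_scale * dark_corr
        return c.advance(out, Stage.BACKGROUND_SUBTRACTED,
                         "subtract_dark_background", allow_reorder=reorder,
                         scale=dark_scale)

    if dark_before_baseline:
        cube = _subtract_dark(cube, False)

    # 4. baseline removal, per pixel
    n_rows, n_cols, n_bins = cube.intensities.shape
    raman = np.empty_like(cube.intensities)
    baselines = np.empty_like(cube.intensities)
    for r in range(n_rows):
        for c in range(n_cols):
            dec = bubblefill_baseline(cube.intensities[r, c], cube.axis,
                                      min_bubble_width)
            raman[r, c] = dec.raman
            baselines[r, c] = dec.baseline
    cube = cube.advance(raman, Stage.BASELINE_REMOVED, "bubblefill_baseline",
                        allow_reorder=dark_before_baseline,
                        min_bubble_width=min_bubble_width)

    # 5. dark subtraction (published order)
    if not dark_before_baseline:
        cube = _subtract_dark(cube, False)

    # 6. SNV, flagging degenerate pixels
    snv = np.zeros_like(cube.intensities)
    degenerate = np.zeros((n_rows, n_cols), dtype=bool)
    flat = cube.intensities
    sd = flat.std(axis=2, ddof=1)
    degenerate = (sd == 0) | ~np.isfinite(sd)
    ok = ~degenerate
    snv[ok] = (flat[ok] - flat[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    cube = cube.advance(snv, Stage.SNV, "snv_normalize",
                        n_degenerate=int(degenerate.sum()))

    column_excluded = np.zeros((n_rows, n_cols), dtype=bool)
    column_excluded[:, :n_excluded_columns] = True
    cube.stage_log.append({
        "step": "exclude_columns", "stage": Stage.SNV,
        "params": {"n_columns": n_excluded_columns,
                   "reason": "intensity-standard coverage"},
    })

    return PreprocessResult(cube=cube, column_excluded=column_excluded,
                            degenerate=degenerate, calibration_rms=cal_rms,
                            response=response, baselines=baselines)
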