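"""Forward model of the line-scanning Raman imager.

Generates raw hypercubes from a :class:`~ramanmargin.phantom.PhantomScene`,
the companion reference measurements needed by the preprocessing chain
(acetaminophen wavenumber standard, NIST-style intensity-response
standard, dark/chromatic background frame), and a point-probe-style
labeled training set of fully preprocessed spectra.

Signal model per pixel (counts on the detector)::

    raw = R(σ) · [ a · mix(endmember, substrate) · S  +  baseline(σ) ]
          + chromatic(σ) + shot + read noise,  averaged over accumulations,
          + cosmic-ray spikes

where ``R`` is the instrument response, ``a`` a per-pixel amplitude
jitter, ``S`` the nominal signal scale, ``baseline`` a broad smooth
autofluorescence term, and ``chromatic`` a structured background from the
collection optics that is also what a dark (nothing-in-focus) frame
records.  All randomness is driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis import WavenumberAxis, default_axis
from .cube import HyperCube, Stage
from .phantom import PhantomScene, TISSUE_CLASSES, _pseudo_voigt, emit_endmember_spectrum

__all__ = [
    "AcquisitionParams",
    "ACETAMINOPHEN_PEAKS",
    "LabeledSpectrumSet",
    "simulate_raw_cube",
    "simulate_reference_measurements",
    "make_point_probe_training_set",
    "default_true_response",
    "certified_srm_shape",
    "chromatic_background",
]

# canonical acetaminophen calibration lines (cm^-1), standard practice for
# Raman shift-axis calibration
ACETAMINOPHEN_PEAKS = (651.6, 857.9, 1168.5, 1236.8, 1323.9, 1648.4)
_ACETAMINOPHEN_REL_AMPS = (0.9, 1.0, 0.6, 0.5, 0.7, 0.8)

# structured ("chromatic triplet") background bumps: position, FWHM, rel. amp.
_CHROMATIC_BUMPS = ((620.0, 30.0, 1.0), (1090.0, 30.0, 0.7), (1510.0, 30.0, 0.5))


@dataclass
class AcquisitionParams:
    """Acquisition geometry and noise settings of one imaging run.

    Defaults mirror the study conditions: a 40-line × 42-pixel raster
    (1680 spectra per image) with three accumulations averaged.
    """

    n_rows: int = 40
    n_cols: int = 42
    n_accumulations: int = 3
    signal_scale: float = 1000.0       # peak tissue Raman counts
    shot_scale: float = 1.0            # sd = shot_scale * sqrt(counts)
    read_sd: float = 10.0              # additive detector noise, counts
    cosmic_ray_rate: float = 0.1       # expected spikes per spectrum
    baseline_amp_range: tuple[float, float] = (0.5, 2.0)  # × signal_scale
    substrate_amp: float = 0.2         # in-focus substrate Raman term, × signal_scale
    substrate_defocus: float = 0.25    # signal attenuation on bare (out-of-focus)
                                       # substrate, where only coating fluorescence
                                       # reaches the collection line efficiently
    chromatic_amp: float = 0.3         # structured background, × signal_scale
    amplitude_jitter_sd: float = 0.10  # per-pixel lognormal signal jitter
    dark_integration_factor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("raster dimensions must be >= 1")
        if self.n_accumulations < 1:
            raise ValueError("n_accumulations must be >= 1")
        for name in ("shot_scale", "read_sd", "cosmic_ray_rate", "substrate_amp",
                     "chromatic_amp", "amplitude_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.baseline_amp_range
        if lo < 0 or hi < lo:
            raise ValueError("baseline_amp_range must be ordered and nonnegative")


@dataclass
class LabeledSpectrumSet:
    """Point-probe-style labeled spectra sharing one axis."""

    spectra: np.ndarray  # (n, bins)
    labels: np.ndarray   # (n,) strings from TISSUE_CLASSES
    axis: WavenumberAxis

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError("spectra/labels length mismatch")
        if self.spectra.shape[1] != self.axis.n_bins:
            raise ValueError("spectra not on the given axis")
        bad = set(np.unique(self.labels)) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown labels {bad}")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def subset(self, keep: np.ndarray) -> "LabeledSpectrumSet":
        return LabeledSpectrumSet(self.spectra[keep], self.labels[keep], self.axis)


def default_true_response(axis: WavenumberAxis) -> np.ndarray:
    """Smooth unitless instrument gain in [0.75, 1.25]."""
    lo, hi = axis.span
    t = (axis.values - lo) / (hi - lo)
    return 1.0 + 0.25 * np.sin(np.pi * (1.3 * t + 0.1))


def certified_srm_shape(axis: WavenumberAxis) -> np.ndarray:
    """Certified broad luminescence shape of the intensity standard.

    A single wide Gaussian in relative intensity, strictly positive over
    the fingerprint region, standing in for the certified polynomial of a
    glass luminescence standard.
    """
    return 0.25 + np.exp(-0.5 * ((axis.values - 1100.0) / 600.0) ** 2)


def chromatic_background(axis: WavenumberAxis, amplitude: float) -> np.ndarray:
    """Structured background from the collection optics (counts)."""
    out = np.zeros(axis.n_bins)
    for center, fwhm, rel in _CHROMATIC_BUMPS:
        out += rel * _pseudo_voigt(axis.values, center, fwhm, eta=0.0)
    return amplitude * out


def _baseline_shape(axis: WavenumberAxis, rng: np.random.Generator) -> np.ndarray:
    """Unit-max smooth autofluorescence shape: broad Gaussian + linear tilt."""
    x = axis.values
    center = rng.uniform(700.0, 1200.0)
    fwhm = rng.uniform(900.0, 1500.0)
    tilt = rng.uniform(0.0, 0.4)
    lo, hi = axis.span
    shape = _pseudo_voigt(x, center, fwhm, eta=0.0) + tilt * (hi - x) / (hi - lo) + 0.2
    return shape / shape.max()


def simulate_raw_cube(
    scene: PhantomScene,
    params: AcquisitionParams,
    axis: WavenumberAxis | None = None,
    *,
    true_response: np.ndarray | None = None,
    return_truth: bool = False,
):
    """Render a scene into a raw hypercube.

    With ``return_truth=True`` also returns a dict holding the noise-free
    per-pixel Raman signal (counts, response- and baseline-free), the
    baseline cube, and the injected cosmic-ray coordinates — ground truth
    for recovery tests.
    """
    if axis is None:
        axis = default_axis()
    if scene.shape != (params.n_rows, params.n_cols):
        raise ValueError(
            f"scene raster {scene.shape} != params raster "
            f"({params.n_rows}, {params.n_cols})"
        )
    if true_response is None:
        true_response = default_true_response(axis)
    true_response = np.asarray(true_response, dtype=float)
    if true_response.shape != (axis.n_bins,):
        raise ValueError("response curve not on the given axis")

    rng = np.random.default_rng(params.seed)
    n_rows, n_cols, n_bins = params.n_rows, params.n_cols, axis.n_bins
    S = params.signal_scale

    endmembers = {c: emit_endmember_spectrum(c, axis) for c in np.unique(scene.label_map)}
    substrate = emit_endmember_spectrum("substrate", axis)
    chrom = chromatic_background(axis, params.chromatic_amp * S)

    signal_truth = np.zeros((n_rows, n_cols, n_bins))
    baselines = np.zeros_like(signal_truth)
    raw = np.zeros_like(signal_truth)
    spikes: list[tuple[int, int, int]] = []

    lo_b, hi_b = params.baseline_amp_range
    for r in range(n_rows):
        for c in range(n_cols):
            label = scene.label_map[r, c]
            m = scene.mixing_map[r, c]
            if label == "substrate":
                pure = np.zeros(n_bins)  # near-zero tissue signal
                mixed = params.substrate_defocus * params.substrate_amp * substrate
            else:
                pure = endmembers[label]
                mixed = (1.0 - m) * pure + m * params.substrate_amp * substrate
            jitter = float(np.exp(rng.normal(0.0, params.amplitude_jitter_sd))) \
                if params.amplitude_jitter_sd > 0 else 1.0
            signal = jitter * S * mixed
            b_amp = rng.uniform(lo_b, hi_b) * S
            baseline = b_amp * _baseline_shape(axis, rng)
            if label == "substrate":
                baseline = baseline * 1.5  # fluorescent black coating
            signal_truth[r, c] = signal
            baselines[r, c] = baseline

            clean = true_response * (signal + baseline) + chrom
            acc = np.zeros(n_bins)
            for _ in range(params.n_accumulations):
                noisy = clean.copy()
                if params.shot_scale > 0:
                    noisy = noisy + rng.normal(size=n_bins) * (
                        params.shot_scale * np.sqrt(np.clip(clean, 0.0, None))
                    )
                if params.read_sd > 0:
                    noisy = noisy + rng.normal(0.0, params.read_sd, size=n_bins)
                acc += noisy
            spectrum = acc / params.n_accumulations

            n_spikes = rng.poisson(params.cosmic_ray_rate)
            local_amp = max(float(np.ptp(clean)), 1.0)
            for _ in range(n_spikes):
                bin_i = int(rng.integers(1, n_bins - 1))
                spectrum[bin_i] += rng.uniform(10.0, 30.0) * local_amp
                spikes.append((r, c, bin_i))
            raw[r, c] = spectrum

    cube = HyperCube(raw, axis, stage=Stage.RAW,
                     stage_log=[{"step": "simulate", "stage": Stage.RAW,
                                 "params": {"layout": scene.layout_name,
                                            "seed": params.seed}}])
    if return_truth:
        return cube, {
            "signal": signal_truth,
            "baseline": baselines,
            "spikes": spikes,
            "response": true_response,
            "chromatic": chrom,
        }
    return cube


def simulate_reference_measurements(
    params: AcquisitionParams,
    true_pixel_map: np.ndarray | None = None,
    true_response: np.ndarray | None = None,
    axis: WavenumberAxis | None = None,
    *,
    noise_sd: float = 2.0,
):
    """Reference measurements consumed by the preprocessing chain.

    Returns ``(acetaminophen, standard, dark)`` where

    * ``acetaminophen`` is a spectrum over detector pixels whose sharp
      calibration lines are rendered through ``true_pixel_map`` (polynomial
      coefficients pixel → cm⁻¹, lowest order first; defaults to the
      nominal axis map),
    * ``standard`` is the certified luminescence shape seen through
      ``true_response`` (a spectrum on the nominal axis), and
    * ``dark`` is a nothing-in-focus hypercube recording the structured
      chromatic background at ``dark_integration_factor`` × the cube's
      integration time.
    """
    if axis is None:
        axis = default_axis()
    if true_pixel_map is None:
        true_pixel_map = axis.pixel_map_coeffs
    true_pixel_map = np.asarray(true_pixel_map, dtype=float)
    if true_response is None:
        true_response = default_true_response(axis)

    rng = np.random.default_rng(params.seed + 104729)  # independent stream
    n_bins = axis.n_bins
    pix = np.arange(n_bins, dtype=float)
    wn_of_pix = np.polynomial.polynomial.polyval(pix, true_pixel_map)
    if not np.all(np.diff(wn_of_pix) > 0):
        raise ValueError("true_pixel_map must be monotone over the detector range")

    S = params.signal_scale
    acet = np.zeros(n_bins)
    for peak, rel in zip(ACETAMINOPHEN_PEAKS, _ACETAMINOPHEN_REL_AMPS):
        acet += rel * _pseudo_voigt(wn_of_pix, peak, 10.0, eta=0.2)
    acet = S * acet + rng.normal(0.0, noise_sd, size=n_bins)

    standard = S * certified_srm_shape(axis) * np.asarray(true_response, dtype=float)
    standard = standard + rng.normal(0.0, noise_sd, size=n_bins)

    k = params.dark_integration_factor
    chrom = chromatic_background(axis, params.chromatic_amp * S)
    dark = np.empty((params.n_rows, params.n_cols, n_bins))
    dark[:] = k * chrom
    if noise_sd > 0:
        dark += rng.normal(0.0, noise_sd, size=dark.shape)
    dark_cube = HyperCube(dark, axis, stage=Stage.RAW,
                          stage_log=[{"step": "simulate_dark", "stage": Stage.RAW,
                                      "params": {"integration_factor": k}}])
    return acet, standard, dark_cube


_ADMIX_PARTNER = {"fat": "normal", "normal": "fat", "cancer": "fat"}


def make_point_probe_training_set(
    n_fat: int = 93,
    n_cancer: int = 87,
    n_normal: int = 58,
    snr: float = 25.0,
    seed: int = 0,
    axis: WavenumberAxis | None = None,
    *,
    band_jitter_sd: float = 0.10,
    bulk_admix_max: float = 0.25,
    interface_frac: float = 0.15,
    interface_admix: tuple[float, float] = (0.35, 0.55),
) -> LabeledSpectrumSet:
    """Labeled, fully preprocessed (SNV-form) point-probe spectra.

    Default class counts (93 fat, 87 cancer, 58 normal — 238 spectra)
    mirror the single-point probe dataset the hyperspectral classifiers
    are trained on.  ``snr`` is peak signal over per-bin noise sd before
    SNV.  Within-class variability has two sources: independent lognormal
    jitter of each band's amplitude, and an admixture of a neighbouring
    tissue class — the probe's sampling volume is rarely pure.  Most
    measurements carry a mild admixture (uniform up to
    ``bulk_admix_max``); a minority (``interface_frac``) sit at tissue
    interfaces with a much stronger admixture (uniform over
    ``interface_admix``).  Interface measurements of tumour embedded in
    adipose tissue are what make a few cancer spectra genuinely
    fat-like, so raising the fat gate's threshold trades against a real
    cost structure, as in the probe study the models come from.
    """
    if min(n_fat, n_cancer, n_normal) < 1:
        raise ValueError("all class counts must be >= 1")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not (0.0 <= bulk_admix_max < 1.0 and 0.0 <= interface_frac <= 1.0):
        raise ValueError("admixture settings out of range")
    if axis is None:
        axis = default_axis()
    from .phantom import ENDMEMBER_BANDS
    from .preprocess import snv_normalize

    rng = np.random.default_rng(seed)
    x = axis.values

    def draw(cls: str) -> np.ndarray:
        s = np.zeros(axis.n_bins)
        for center, fwhm, amp in ENDMEMBER_BANDS[cls]:
            a = amp * np.exp(rng.normal(0.0, band_jitter_sd))
            s += a * _pseudo_voigt(x, center, fwhm)
        return s / s.max()

    spectra, labels = [], []
    for cls, n in (("fat", n_fat), ("cancer", n_cancer), ("normal", n_normal)):
        for _ in range(n):
            if rng.uniform() < interface_frac:
                a = rng.uniform(*interface_admix)
            else:
                a = rng.uniform(0.0, bulk_admix_max)
            s = (1.0 - a) * draw(cls) + a * draw(_ADMIX_PARTNER[cls])
            s = s + rng.normal(0.0, 1.0 / snr, size=axis.n_bins)
            spectra.append(snv_normalize(s))
            labels.append(cls)
    return LabeledSpectrumSet(np.array(spectra), np.array(labels, dtype=object), axis)
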