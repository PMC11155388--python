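# Methods

This note documents the models and numerical choices behind
`ramanmargin`: what the synthetic-data generator emulates, how each
processing stage works, which parameters matter, and what the passing
tests do and do not establish about real data.

## Forward model of the imager

The instrument model is a line-scanning Raman imager covering
400–1900 cm⁻¹ at 6 cm⁻¹ per bin (251 bins) over a 40-line × 42-pixel
raster — 1680 spectra per image — with three repeat accumulations
averaged. Each pixel's raw counts are

    raw = R(σ) · [ a · mix(endmember, substrate) · S + b(σ) ]
          + chromatic(σ) + shot + read noise,      (averaged over
          accumulations)  + cosmic-ray spikes

* **Endmembers.** Pure-class spectra are sums of pseudo-Voigt bands
  (η = 0.3, FWHM 12–20 cm⁻¹) from an editable table. The table encodes
  the qualitative contrasts of breast tissue: adipose spectra dominated
  by the 1304/1445 cm⁻¹ lipid bands with a weak 1004 cm⁻¹ feature;
  cancer elevated at 1004 (phenylalanine) and 1129/1155 cm⁻¹ relative
  to non-fat normal stroma; the black-coated aluminum substrate a
  single sharp feature at 1004 cm⁻¹. Band FWHMs sit in the upper half
  of the plausible 8–20 cm⁻¹ range so that, at 6 cm⁻¹ sampling, a
  noise-free tissue spectrum is smooth enough for the quality factor's
  local-polynomial smoother to follow (QF 0.955–0.966); narrower tables
  are spectroscopically fine but score lower QF at this bin width.
* **Scene layouts.** Four deterministic layouts emulate specimen types:
  `tumor_block` and `fat_block` fill the field of view; `mixed_margin`
  (the default) is a specimen smaller than the FOV with a tumour /
  normal / fat margin running across it; `small_tumor_in_fat` grows a
  single connected cancer focus of ~3 % of tissue pixels inside
  adipose tissue. Layouts smaller than the FOV carry a substrate ring.
* **Edge mixing.** Tissue pixels within two pixels of the substrate mix
  substrate signal with fraction 0.8 (adjacent shell) and 0.4 (next
  shell): tissue at the specimen edge is thin, and the in-focus
  aluminum shows through. Pure substrate regions lie below the focal
  plane, so their collected Raman term is attenuated (defocus factor
  0.25) while the coating's fluorescence background is 1.5× the tissue
  range — which is what drives their low QF, mirroring the observation
  that substrate pixels are mostly excluded for spectral quality while
  edge pixels show a clear contaminating 1004 cm⁻¹ feature.
* **Backgrounds and noise.** The autofluorescence baseline is a broad
  Gaussian (FWHM 900–1500 cm⁻¹, random centre) plus a linear tilt, with
  per-pixel amplitude uniform in 0.5–2× the signal scale S = 1000
  counts. Autofluorescence in tissue varies slowly over the whole
  fingerprint window, hence the wide FWHM range. The chromatic
  (collection-optics) background is three fixed 30 cm⁻¹ bumps at 0.3 S;
  it is what the dark frame records. Noise is a Gaussian shot term
  (sd = √counts) plus additive read noise (sd 10), the standard CCD
  approximation. Cosmic rays are Poisson-distributed single-bin spikes
  of 10–30× the local signal amplitude, 0.1 per spectrum by default.
* **Point-probe training set.** 93 fat / 87 cancer / 58 normal spectra
  (238 total, the class balance of the single-point probe study the
  hyperspectral models are trained from), generated directly in
  preprocessed SNV form at SNR 25 with lognormal band-amplitude jitter
  (sd 0.10). Each measurement additionally mixes in a neighbouring
  tissue class: most carry a mild admixture (uniform 0–0.25), a 15 %
  minority sit at tissue interfaces with admixture 0.35–0.55. The
  interface mode is what gives a few cancer spectra genuinely fat-like
  features, so the fat gate's accuracy (~96–98 % cross-validated) and
  the cost structure of raising its threshold both resemble the
  original probe models rather than a trivially separable toy problem.

What the generator does **not** emulate: spatial point-spread mixing
between neighbouring tissue pixels, wavelength-dependent absorption and
scattering, detector saturation and etaloning, specimen drying over the
acquisition, and histology co-registration error. Passing tests
therefore establish that the pipeline recovers what this generative
family produces — correctness of the algorithms and their couplings —
not clinical performance on patient tissue.

## Preprocessing chain

Steps run in the published order (despike → σ-axis calibration →
response correction → baseline removal → dark subtraction → SNV); a
config switch (`dark_before_baseline`) moves the dark subtraction ahead
of baseline removal for users who prefer the physically ordered
variant. Two couplings matter:

* The dark frame receives the same response correction as the cube
  before subtraction, so the background it measured cancels exactly.
* Subtracting the dark *after* baseline removal is only coherent
  because the dark's content is spectrally structured (30 cm⁻¹ bumps,
  narrower than the minimum bubble width): BubbleFill leaves it in the
  Raman residual, where the subtraction then removes it. A smooth dark
  term would be removed twice.

**Despiking** is a median-comparison filter: a bin is replaced by the
running median (window 5) only when it exceeds it by 5× the local
signal amplitude (running peak-to-trough of the median track, floored
at 6 robust noise sd). A plain running median would erode genuine
peaks, which at 6 cm⁻¹ sampling are only 2–3 bins wide.

**Axis calibration** detects peaks with prominence ≥ 5× a robust noise
scale, refines apexes by local parabola, and fits pixel → cm⁻¹ by
least-squares polynomial (degree 2 default). Residual RMS is reported;
the fit must be monotone. The calibrated axis relabels the bins — no
resampling.

**BubbleFill.** On an aspect-normalised spectrum (y-range scaled to the
bin count), circular bubbles grow tangent from below on successively
split intervals; each interval is first detrended by its endpoint chord
so bubbles on slopes stay anchored. The bubble radius is
max(half-interval, min_bubble_width/2), and recursion continues down to
3-bin intervals: the radius floor — not a recursion cutoff — is what
preserves peaks narrower than `min_bubble_width` (default 150 cm⁻¹,
wider than any tissue Raman band, narrower than fluorescence humps). A
stop-at-width recursion was tried first and rejected: it leaves arc-sag
residuals of several percent of range on featureless slopes. The
envelope gets one light Savitzky–Golay pass (window ≈ radius/2) and is
then clipped from above by the spectrum, so baseline ≤ spectrum holds
exactly and baseline + Raman = spectrum to the last bit. Measured
behaviour: < 0.05 % residual on a straight line, 99 % of a broad
(FWHM 400 cm⁻¹) hump assigned to baseline, 99+ % of a narrow
(FWHM 10 cm⁻¹) peak preserved, ~4 ms per spectrum.

**Degenerate pixels** (zero variance after the chain) are flagged and
excluded downstream, never imputed. The first five image columns are
excluded because the intensity standard does not cover them; they never
enter quality-factor percentages (denominator choice: exclusions are
reported over eligible pixels only).

## Quality factor

QF = clip(1 − Var(s − ŝ)/Var(s), 0, 1) on the SNV spectrum, with ŝ a
Savitzky–Golay smooth, window 7, order 3. The window/order pair was
chosen jointly with the endmember bandwidths against three fixed
requirements: noise-free tissue spectra ≥ 0.95, white-noise mean well
below the 0.5 exclusion threshold (measured 0.334), and reliable
exclusion of substrate-ring pixels. The last point is subtle: after
baseline removal, a pure-noise pixel's residual is not white — the
bubble envelope rides noise minima, leaving weak smooth structure that
a wider/higher-order smoother follows, pulling noise pixels' QF toward
0.5. A 9-bin window (with order 3 or 5) failed one or other requirement;
(7, 3) satisfies all. Exclusion is strictly below threshold: a pixel at
exactly QF = 0.5 is retained.

## Classifiers

Linear SVMs (C = 1) on band features standardized by training-set
mean/sd stored in the model. Band half-width is 6 cm⁻¹ — one resolution
element — so each feature averages the bins within one instrument
linewidth of its centre. Posterior probabilities come from a sigmoid
fitted on out-of-fold decision scores (stratified 5-fold, folds seeded),
the standard Platt construction kept in-package so the stored model is a
plain record: weights, bias, standardization constants, two calibration
scalars, operating threshold, and a fingerprint of the training set.
Decision at exactly the threshold is positive (≥), fixed for
determinism.

The `protect_cancer` threshold policy sets the fat gate to the smallest
probability at which zero training cancer spectra pass as fat (one ulp
above the largest cancer p_fat; threshold 1 with a warning flag if some
cancer spectrum reaches probability 1). On the default training set
this lands well above the probabilities of substrate-contaminated edge
pixels, which is what reproduces the border artifact: edge fat pixels
with ≥ 0.3 substrate mixing show a clearly elevated 1004 cm⁻¹ feature
and roughly half of them flip from fat to normal (occasionally cancer),
while interior pixels are unaffected.

Pixel classification is strictly sequential: excluded pixels carry no
probabilities; model A assigns p_fat to every retained pixel; only
non-fat pixels receive model B's p_cancer. Fat pixels therefore never
have a cancer probability, and labelling a fat pixel as normal is
treated as clinically correct in accuracy metrics (both are healthy
tissue).

## Reporting

Per-specimen summary denominators: % excluded over eligible pixels,
% fat over included pixels, % cancer and the p statistics over included
non-fat pixels; p_std uses the sample (n−1) convention. Display
rounding is whole-number percentages and two-decimal probabilities; raw
values are retained in machine output. The burden flag uses mean p with
cutoffs 0.3 (strictly above → cancer-containing) and 0.15 (at or below
→ cancer-free), the separation observed across the study's eight
specimens — an observation, not a validated decision rule, and both
cutoffs are config-exposed. A specimen whose retained pixels are all
fat is flagged cancer-free; any other case without non-fat pixels is
indeterminate.

## Problem sizes and determinism

Default analyses use the full 40 × 42 raster (~40 s for a complete
run including training on one CPU, of which baseline removal of 1680
spectra is the bulk). Recovery and calibration suites use 100-pixel
cubes, 1000 noise draws, and a 4000-per-class oracle sample — sizes at
which the Monte-Carlo standard errors are far below the tolerances
being checked. A single global seed fans out to per-stage seeds by a
fixed affine map, so stages are independently reproducible and two runs
with the same config produce byte-identical outputs (verified down to
the PNG).

## Known limitations

* The published per-specimen table cannot be reproduced numerically
  from data (the clinical cubes were never deposited); it ships as
  package data for consistency checks only.
* The default model pair is trained on synthetic probe spectra; its
  coefficients are reproducible but not those of the original
  instrument's models.
* On the default generator the cancer/normal contrast is strong enough
  that model B is at ceiling (100 % cross-validated); the oracle
  comparison is therefore a non-degradation check rather than a
  sharpness test. Lower `train_snr` or a larger interface fraction
  produces harder problems.
* QF's variance-ratio form is calibrated for this bin width; at finer
  spectral sampling the window should scale with the resolution
  element.
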