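"""Bubble-based baseline estimation for Raman spectra.

The baseline (autofluorescence plus any other smooth background) is
modelled as the upper envelope of circular "bubbles" grown under the
spectrum in an aspect-normalised coordinate frame.  A bubble can never be
more sharply curved than the configured minimum width allows, so the
envelope follows broad background structure while being geometrically
unable to enter narrow Raman peaks.

The construction is recursive: on an interval, grow the bubble tangent
from below until it touches the spectrum, split the interval at the touch
point, and recurse on both halves.  The bubble radius is the larger of
half the interval width and half the minimum bubble width; recursion
proceeds down to 3-bin intervals so the envelope hugs featureless
regions essentially exactly, while the radius floor preserves peaks
narrower than ``min_bubble_width``.  One light smoothing pass removes the
scallop marks where adjacent bubbles meet, and the result is clipped from
above by the spectrum so admissibility (baseline ≤ spectrum) is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .axis import WavenumberAxis

__all__ = ["BaselineDecomposition", "bubblefill_baseline"]

DEFAULT_MIN_BUBBLE_WIDTH = 150.0  # cm^-1; wider than tissue Raman bands,
                                  # narrower than fluorescence humps


@dataclass
class BaselineDecomposition:
    """Additive split of one spectrum into baseline and Raman parts."""

    baseline: np.ndarray
    raman: np.ndarray

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.raman = np.asarray(self.raman, dtype=float)
        if self.baseline.shape != self.raman.shape:
            raise ValueError("baseline/raman shape mismatch")

    @property
    def reconstruction(self) -> np.ndarray:
        return self.baseline + self.raman


def _bubble_arc(lo: int, hi: int, radius: float) -> np.ndarray:
    """Top arc of a circle of ``radius`` spanning bins lo..hi (inclusive),
    anchored so the arc ends sit at height 0 at both interval edges."""
    x = np.arange(lo, hi + 1, dtype=float)
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    r = max(radius, half)
    arc = np.sqrt(np.maximum(r * r - (x - mid) ** 2, 0.0))
    return arc - np.sqrt(r * r - half * half)


def _bubble_envelope(y: np.ndarray, min_radius_bins: float) -> np.ndarray:
    """Upper envelope of all grown bubbles, in scaled coordinates.

    Each interval is detrended by the chord joining its endpoint values
    before the bubble is grown, so bubbles on sloped segments stay
    anchored at both ends; a bubble touching the spectrum strictly inside
    the interval splits it there, otherwise the interval is finished.
    """
    n = y.size
    env = np.full(n, -np.inf)
    stack = [(0, n - 1)]
    while stack:
        lo, hi = stack.pop()
        seg = y[lo : hi + 1]
        chord = np.linspace(seg[0], seg[-1], hi - lo + 1)
        arc = _bubble_arc(lo, hi, min_radius_bins)
        diff = seg - chord - arc
        lift = float(diff.min())
        touch = lo + int(diff.argmin())
        np.maximum(env[lo : hi + 1], chord + arc + lift, out=env[lo : hi + 1])
        if lo < touch < hi:  # interior touch: refine both halves
            if touch - lo >= 2:
                stack.append((lo, touch))
            if hi - touch >= 2:
                stack.append((touch, hi))
    return env


def bubblefill_baseline(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    min_bubble_width: float = DEFAULT_MIN_BUBBLE_WIDTH,
) -> BaselineDecomposition:
    """Split ``spectrum`` into a smooth baseline and a Raman residual.

    ``min_bubble_width`` (cm⁻¹) sets the smallest spectral scale the
    baseline may follow: features wider than it are absorbed into the
    baseline, narrower peaks are preserved in the Raman part.

    Guarantees: ``baseline <= spectrum`` at every bin and
    ``baseline + raman == spectrum`` exactly.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("spectrum must be one-dimensional")
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("spectrum must be finite")
    if min_bubble_width <= 0:
        raise ValueError("min_bubble_width must be positive")
    spacing = axis.median_spacing
    if min_bubble_width <= spacing:
        raise ValueError(
            f"min_bubble_width {min_bubble_width:g} cm^-1 must exceed the "
            f"bin spacing {spacing:g} cm^-1"
        )
    n = spectrum.size
    if n != axis.n_bins:
        raise ValueError("spectrum not on the given axis")

    span = float(np.ptp(spectrum))
    if span == 0.0:  # constant input: it is all baseline
        return BaselineDecomposition(spectrum.copy(), np.zeros_like(spectrum))

    # aspect normalisation: x in bins, y rescaled so its range spans n bins
    y = (spectrum - spectrum.min()) * (n / span)
    min_radius_bins = 0.5 * min_bubble_width / spacing

    env = _bubble_envelope(y, min_radius_bins)

    smooth_bins = max(int(round(min_radius_bins / 2.0)) | 1, 3)
    if smooth_bins < n:
        env = savgol_filter(env, smooth_bins, 2)
    env = np.minimum(env, y)  # admissibility is exact, not approximate

    baseline = env * (span / n) + spectrum.min()
    baseline = np.minimum(baseline, spectrum)
    return BaselineDecomposition(baseline, spectrum - baseline)
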