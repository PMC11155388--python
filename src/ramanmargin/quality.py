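"""Spectral quality factor (QF) and the pixel-exclusion rule.

QF rates how much of an SNV spectrum's variance is explained by a local
polynomial smooth of itself::

    QF = clip(1 − Var(s − ŝ) / Var(s), 0, 1)

where ŝ is a Savitzky–Golay smooth.  Structured spectra (Raman peaks a
few bins wide) are followed almost perfectly by the smoother, giving QF
near 1; white noise is mostly *not* followed, giving QF well below 0.5
at the default window/order.  Pixels with QF strictly below the
threshold (default 0.5) are excluded; ties at the threshold are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .cube import HyperCube, Stage

__all__ = ["QualityMask", "quality_factor", "apply_qf_exclusion",
           "DEFAULT_QF_WINDOW", "DEFAULT_QF_ORDER", "DEFAULT_QF_THRESHOLD"]

DEFAULT_QF_WINDOW = 7
DEFAULT_QF_ORDER = 3
DEFAULT_QF_THRESHOLD = 0.5

REASON_OK = "ok"
REASON_LOW_QF = "low_qf"
REASON_COLUMN = "column_excluded"
REASON_DEGENERATE = "degenerate"


@dataclass
class QualityMask:
    """Per-pixel QF values, inclusion flags, and exclusion reasons."""

    qf_map: np.ndarray    # (rows, cols) in [0, 1]; NaN where not computable
    included: np.ndarray  # (rows, cols) bool
    reasons: np.ndarray   # (rows, cols) strings
    threshold: float

    def __post_init__(self):
        finite = self.qf_map[np.isfinite(self.qf_map)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("qf values must lie in [0, 1]")
        if not np.array_equal(self.included, self.reasons == REASON_OK):
            raise ValueError("included grid inconsistent with reasons")

    @property
    def pct_excluded(self) -> float:
        """% of eligible (non-column, non-degenerate) pixels with low QF."""
        eligible = (self.reasons == REASON_OK) | (self.reasons == REASON_LOW_QF)
        if not eligible.any():
            return float("nan")
        return 100.0 * float((self.reasons == REASON_LOW_QF).sum()) / float(
            eligible.sum())


def quality_factor(spectrum: np.ndarray,
                   smooth_window: int = DEFAULT_QF_WINDOW,
                   smooth_order: int = DEFAULT_QF_ORDER) -> float:
    """QF of one SNV spectrum; deterministic, scale- and offset-invariant."""
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if smooth_window <= smooth_order + 1:
        raise ValueError("smooth_window must exceed smooth_order + 1")
    spectrum = np.asarray(spectrum, dtype=float)
    var = spectrum.var()
    if var == 0 or not np.isfinite(var):
        raise ValueError("zero-variance spectrum is degenerate")
    smooth = savgol_filter(spectrum, smooth_window, smooth_order)
    return float(np.clip(1.0 - np.var(spectrum - smooth) / var, 0.0, 1.0))


def apply_qf_exclusion(
    cube: HyperCube,
    threshold: float = DEFAULT_QF_THRESHOLD,
    *,
    column_excluded: np.ndarray | None = None,
    degenerate: np.ndarray | None = None,
    smooth_window: int = DEFAULT_QF_WINDOW,
    smooth_order: int = DEFAULT_QF_ORDER,
) -> QualityMask:
    """Compute the QF map of an SNV cube and apply the exclusion rule.

    Column-excluded and degenerate pixels never enter the QF percentage's
    denominator; QF is excluding strictly below ``threshold`` (a pixel at
    exactly the threshold is retained).
    """
    if cube.stage != Stage.SNV:
        raise ValueError(f"QF expects an SNV cube, got stage {cube.stage!r}")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    n_rows, n_cols = cube.n_rows, cube.n_cols
    if column_excluded is None:
        column_excluded = np.zeros((n_rows, n_cols), dtype=bool)
    if degenerate is None:
        degenerate = np.zeros((n_rows, n_cols), dtype=bool)

    qf_map = np.full((n_rows, n_cols), np.nan)
    reasons = np.full((n_rows, n_cols), REASON_OK, dtype=object)
    reasons[column_excluded] = REASON_COLUMN
    reasons[degenerate & ~column_excluded] = REASON_DEGENERATE
    for r in range(n_rows):
        for c in range(n_cols):
            if column_excluded[r, c] or degenerate[r, c]:
                continue
            qf = quality_factor(cube.intensities[r, c], smooth_window, smooth_order)
            qf_map[r, c] = qf
            if qf < threshold:
                reasons[r, c] = REASON_LOW_QF
    included = reasons == REASON_OK
    return QualityMask(qf_map=qf_map, included=included, reasons=reasons,
                       threshold=threshold)
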