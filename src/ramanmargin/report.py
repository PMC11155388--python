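"""Per-specimen maps and summary statistics.

Produces normalized band-intensity maps, rendered classification maps
(pink = fat, yellow = normal, purple = cancer, excluded transparent),
and a per-specimen summary row: % excluded, % fat among retained, %
cancer among retained non-fat, and the mean ± sd of the cancer posterior
probability over the non-fat pixels — the quantitative cancer-burden
marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .axis import WavenumberAxis
from .classify import LABEL_EXCLUDED, PixelClassMap
from .cube import HyperCube
from .quality import QualityMask

__all__ = [
    "SpecimenSummary",
    "DEFAULT_PALETTE",
    "band_intensity_map",
    "summarize_specimen",
    "flag_cancer_burden",
    "render_class_map",
]

DEFAULT_PALETTE = {
    "fat": (255, 182, 193, 255),     # pink
    "normal": (255, 221, 0, 255),    # yellow
    "cancer": (128, 0, 128, 255),    # purple
    LABEL_EXCLUDED: (0, 0, 0, 0),    # transparent
}

BURDEN_POSITIVE_CUTOFF = 0.3   # observed separation, not a validated rule
BURDEN_NEGATIVE_CUTOFF = 0.15


@dataclass
class SpecimenSummary:
    """One per-specimen report row.

    Percentages use the reporting denominators of the study: ``pct_fat``
    over included pixels, ``pct_cancer`` and the p statistics over
    included non-fat pixels.  Fields are NaN when their denominator is
    empty.
    """

    pct_excluded: float
    pct_fat: float
    pct_cancer: float
    p_mean: float
    p_std: float
    n_included: int = 0
    n_fat: int = 0
    n_cancer: int = 0

    def __post_init__(self):
        for name in ("pct_excluded", "pct_fat", "pct_cancer"):
            v = getattr(self, name)
            if not math.isnan(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} outside [0, 100]")
        if not math.isnan(self.p_mean) and not (0.0 <= self.p_mean <= 1.0):
            raise ValueError("p_mean outside [0, 1]")

    def rounded(self) -> dict:
        """Display form: whole-number percentages, 2-decimal p statistics."""
        def pct(v):
            return None if math.isnan(v) else int(round(v))

        def prob(v):
            return None if math.isnan(v) else round(v, 2)

        return {
            "pct_excluded": pct(self.pct_excluded),
            "pct_fat": pct(self.pct_fat),
            "pct_cancer": pct(self.pct_cancer),
            "p_mean": prob(self.p_mean),
            "p_std": prob(self.p_std),
        }


def band_intensity_map(cube: HyperCube, band_center: float,
                       half_width: float = 6.0,
                       mask: QualityMask | None = None) -> np.ndarray:
    """Min–max normalized per-pixel band intensity in [0, 1].

    Normalisation runs over included pixels only; excluded pixels are
    NaN.  A degenerate (constant) map renders as all zeros.
    """
    idx = cube.axis.window_indices(band_center, half_width)
    values = cube.intensities[:, :, idx].mean(axis=2)
    included = (mask.included if mask is not None
                else np.ones(values.shape, dtype=bool))
    if not included.any():
        raise ValueError("all pixels excluded; empty band map")
    out = np.full(values.shape, np.nan)
    vals = values[included]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        out[included] = (values[included] - lo) / (hi - lo)
    else:
        out[included] = 0.0
    return out


def summarize_specimen(classmap: PixelClassMap, mask: QualityMask) -> SpecimenSummary:
    """Table-row statistics for one specimen image."""
    if classmap.labels.shape != mask.included.shape:
        raise ValueError("class map and mask shapes differ")

    pct_excluded = mask.pct_excluded
    included = mask.included
    n_inc = int(included.sum())
    if n_inc == 0:
        return SpecimenSummary(pct_excluded, float("nan"), float("nan"),
                               float("nan"), float("nan"))

    is_fat = classmap.labels == "fat"
    n_fat = int((is_fat & included).sum())
    pct_fat = 100.0 * n_fat / n_inc

    nonfat = included & ~is_fat
    n_nonfat = int(nonfat.sum())
    if n_nonfat == 0:
        return SpecimenSummary(pct_excluded, pct_fat, float("nan"),
                               float("nan"), float("nan"),
                               n_included=n_inc, n_fat=n_fat)

    n_cancer = int((classmap.labels[nonfat] == "cancer").sum())
    pct_cancer = 100.0 * n_cancer / n_nonfat
    p = classmap.p_cancer[nonfat]
    p_mean = float(np.mean(p))
    p_std = float(np.std(p, ddof=1)) if p.size > 1 else 0.0
    return SpecimenSummary(pct_excluded, pct_fat, pct_cancer, p_mean, p_std,
                           n_included=n_inc, n_fat=n_fat, n_cancer=n_cancer)


def flag_cancer_burden(summary: SpecimenSummary,
                       positive_cutoff: float = BURDEN_POSITIVE_CUTOFF,
                       negative_cutoff: float = BURDEN_NEGATIVE_CUTOFF) -> str:
    """Classify a specimen's cancer burden from its mean posterior p.

    The cutoffs default to the separation observed across the study's
    specimens (cancer-containing: mean p > 0.3; cancer-free: ≤ 0.15);
    they are an observation, not a validated decision rule.  A specimen
    whose retained pixels are all fat (no p defined) is flagged
    cancer-free; any other undefined case is indeterminate.
    """
    if not (0.0 <= negative_cutoff < positive_cutoff <= 1.0):
        raise ValueError("cutoffs must satisfy 0 <= negative < positive <= 1")
    if math.isnan(summary.p_mean):
        all_fat = (summary.n_included > 0
                   and summary.n_fat == summary.n_included)
        return "cancer_free" if all_fat else "indeterminate"
    if summary.p_mean > positive_cutoff:
        return "cancer_containing"
    if summary.p_mean <= negative_cutoff:
        return "cancer_free"
    return "indeterminate"


def render_class_map(classmap: PixelClassMap, palette: dict | None = None,
                     out_path=None):
    """Render the label raster to a lossless RGBA image (one px per cell).

    Returns the PIL image; writes a PNG when ``out_path`` is given.
    """
    from PIL import Image

    if palette is None:
        palette = DEFAULT_PALETTE
    missing = set(np.unique(classmap.labels)) - set(palette)
    if missing:
        raise ValueError(f"palette missing labels {missing}")
    rows, cols = classmap.labels.shape
    rgba = np.zeros((rows, cols, 4), dtype=np.uint8)
    for label, color in palette.items():
        rgba[classmap.labels == label] = color
    img = Image.fromarray(rgba, mode="RGBA")
    if out_path is not None:
        img.save(out_path, format="PNG")
    return img
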