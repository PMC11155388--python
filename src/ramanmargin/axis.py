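"""Spectral axis handling for Raman hypercubes.

The spectral axis of the line-scanning system covers the biological
fingerprint region (400–1900 cm⁻¹) at a resolution of ~6 cm⁻¹.  A
:class:`WavenumberAxis` couples the per-bin wavenumber values with the
polynomial detector-pixel → wavenumber map that produced them, so that
axis calibration (refitting that map against a reference material) is a
first-class operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberAxis", "default_axis", "FINGERPRINT_LO", "FINGERPRINT_HI"]

FINGERPRINT_LO = 400.0
FINGERPRINT_HI = 1900.0
DEFAULT_RESOLUTION = 6.0  # cm^-1 per bin for the default instrument model


@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered spectral axis in cm⁻¹.

    Parameters
    ----------
    values : ndarray
        Strictly increasing wavenumber of each spectral bin (cm⁻¹).
    pixel_map_coeffs : ndarray
        Polynomial coefficients (lowest order first, numpy convention)
        mapping detector-pixel index to cm⁻¹.  For a synthetic axis built
        directly from values this is the least-squares polynomial of the
        values against the bin index.
    """

    values: np.ndarray
    pixel_map_coeffs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least two bins")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber values must be strictly increasing")
        object.__setattr__(self, "values", values)
        if self.pixel_map_coeffs is None:
            coeffs = np.polynomial.polynomial.polyfit(
                np.arange(values.size, dtype=float), values, deg=1
            )
            object.__setattr__(self, "pixel_map_coeffs", coeffs)
        else:
            object.__setattr__(
                self, "pixel_map_coeffs", np.asarray(self.pixel_map_coeffs, dtype=float)
            )

    # -- basic queries -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    @property
    def median_spacing(self) -> float:
        return float(np.median(np.diff(self.values)))

    def index_of(self, wavenumber: float) -> int:
        """Index of the bin nearest ``wavenumber`` (cm⁻¹)."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window_indices(self, center: float, half_width: float) -> np.ndarray:
        """Indices of all bins within ``center ± half_width``.

        Falls back to the single nearest bin when the window contains no
        bin (including ``half_width == 0``).
        """
        lo, hi = self.span
        if not (lo <= center <= hi):
            raise ValueError(
                f"band center {center:g} cm^-1 outside axis span [{lo:g}, {hi:g}]"
            )
        idx = np.nonzero(np.abs(self.values - center) <= half_width)[0]
        if idx.size == 0:
            idx = np.array([self.index_of(center)])
        return idx

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_bins

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):  # frozen dataclass with arrays: identity hash
        return id(self)


def default_axis(
    lo: float = FINGERPRINT_LO,
    hi: float = FINGERPRINT_HI,
    resolution: float = DEFAULT_RESOLUTION,
) -> WavenumberAxis:
    """Uniform fingerprint-region axis at the instrument's resolution."""
    n = int(round((hi - lo) / resolution)) + 1
    return WavenumberAxis(np.linspace(lo, hi, n))
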