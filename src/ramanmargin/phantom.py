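"""Ground-truthed phantom scenes for the line-scanning Raman imager.

The phantoms emulate ex-vivo breast specimens laid on a black-coated
aluminum substrate inside the instrument's ~1 cm field of view.  Each
scene is a label map over {fat, normal, cancer, substrate, ink} plus a
per-pixel substrate-mixing map that reproduces the signal contamination
observed at tissue/substrate borders (the substrate carries a sharp
inelastic feature near the 1004 cm⁻¹ phenylalanine band, which is what
confounds tissue classification at specimen edges).

Endmember spectra are sums of pseudo-Voigt bands.  The band tables are
synthetic but constrained to the qualitative contrasts of breast tissue
Raman spectra: adipose tissue is dominated by the lipid 1304/1445 cm⁻¹
bands; cancer shows elevated phenylalanine (1004 cm⁻¹) and the
1129/1155 cm⁻¹ protein/carotenoid region relative to non-fat normal
stroma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis import WavenumberAxis, default_axis

__all__ = [
    "TISSUE_CLASSES",
    "SCENE_CLASSES",
    "LAYOUTS",
    "ENDMEMBER_BANDS",
    "PhantomScene",
    "build_phantom_scene",
    "emit_endmember_spectrum",
]

TISSUE_CLASSES = ("fat", "normal", "cancer")
SCENE_CLASSES = ("fat", "normal", "cancer", "substrate", "ink")
LAYOUTS = ("tumor_block", "fat_block", "mixed_margin", "small_tumor_in_fat")

# Editable endmember band table: class -> list of (center cm^-1, FWHM cm^-1,
# amplitude).  Amplitudes are relative within a class; spectra are emitted
# with unit maximum.  Constraints encoded here:
#   * fat: 1304 and 1445 dominate, 1004 weak
#   * cancer vs normal: elevated 1004 and 1155 (and 1129)
#   * substrate: single sharp feature at 1004 (black-coated aluminum)
ENDMEMBER_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "fat": [
        (890.0, 18.0, 0.15),
        (940.0, 16.0, 0.08),
        (1004.0, 14.0, 0.05),
        (1078.0, 18.0, 0.45),
        (1265.0, 20.0, 0.40),
        (1304.0, 16.0, 1.00),
        (1445.0, 18.0, 0.95),
        (1657.0, 20.0, 0.40),
        (1745.0, 18.0, 0.35),
    ],
    "normal": [
        (856.0, 18.0, 0.40),
        (940.0, 16.0, 0.45),
        (1004.0, 14.0, 0.35),
        (1129.0, 16.0, 0.15),
        (1155.0, 16.0, 0.10),
        (1265.0, 20.0, 0.35),
        (1304.0, 18.0, 0.30),
        (1445.0, 18.0, 0.65),
        (1657.0, 20.0, 0.60),
    ],
    "cancer": [
        (856.0, 18.0, 0.25),
        (940.0, 16.0, 0.25),
        (1004.0, 14.0, 0.70),
        (1095.0, 18.0, 0.25),
        (1129.0, 16.0, 0.40),
        (1155.0, 16.0, 0.40),
        (1265.0, 20.0, 0.40),
        (1304.0, 18.0, 0.35),
        (1445.0, 18.0, 0.60),
        (1657.0, 20.0, 0.65),
    ],
    "substrate": [
        (1004.0, 12.0, 1.00),
        (720.0, 20.0, 0.10),
        (1590.0, 20.0, 0.12),
    ],
    # residual pathology marking ink: weak broad carbonaceous bands; in the
    # instrument it mostly absorbs, so the Raman term is small and noisy
    "ink": [
        (1350.0, 20.0, 0.10),
        (1590.0, 20.0, 0.12),
    ],
}


def _pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float = 0.3) -> np.ndarray:
    """Unit-height pseudo-Voigt profile (Gaussian/Lorentzian mix)."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gamma = fwhm / 2.0
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    lorentz = 1.0 / (1.0 + ((x - center) / gamma) ** 2)
    return (1.0 - eta) * gauss + eta * lorentz


def emit_endmember_spectrum(tissue_class: str, axis: WavenumberAxis | None = None) -> np.ndarray:
    """Noise-free pure-component spectrum of one scene class.

    Returns a nonnegative vector normalised to unit maximum.  Raises
    ``ValueError`` for a class not in the band table.
    """
    if axis is None:
        axis = default_axis()
    try:
        bands = ENDMEMBER_BANDS[tissue_class]
    except KeyError:
        raise ValueError(
            f"unknown tissue class {tissue_class!r}; expected one of {SCENE_CLASSES}"
        ) from None
    x = axis.values
    spectrum = np.zeros_like(x)
    for center, fwhm, amplitude in bands:
        spectrum += amplitude * _pseudo_voigt(x, center, fwhm)
    peak = spectrum.max()
    if peak > 0:
        spectrum = spectrum / peak
    return spectrum


@dataclass
class PhantomScene:
    """Per-pixel ground truth for one simulated specimen image."""

    label_map: np.ndarray  # (rows, cols) of strings from SCENE_CLASSES
    mixing_map: np.ndarray  # (rows, cols) substrate-signal fraction in [0, 1]
    layout_name: str
    seed: int
    endmember_params: dict = field(default_factory=lambda: dict(ENDMEMBER_BANDS))

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map, dtype=object)
        self.mixing_map = np.asarray(self.mixing_map, dtype=float)
        if self.label_map.shape != self.mixing_map.shape:
            raise ValueError("label_map and mixing_map shapes differ")
        if self.mixing_map.min() < 0 or self.mixing_map.max() > 1:
            raise ValueError("mixing fractions must lie in [0, 1]")
        bad = set(np.unique(self.label_map)) - set(SCENE_CLASSES)
        if bad:
            raise ValueError(f"unknown scene classes {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @property
    def tissue_mask(self) -> np.ndarray:
        return np.isin(self.label_map, TISSUE_CLASSES)

    def class_mask(self, name: str) -> np.ndarray:
        return self.label_map == name


def _substrate_ring(label_map: np.ndarray, ring: int) -> None:
    label_map[:ring, :] = "substrate"
    label_map[-ring:, :] = "substrate"
    label_map[:, :ring] = "substrate"
    label_map[:, -ring:] = "substrate"


def _edge_mixing(label_map: np.ndarray, band: int = 2,
                 max_mix: float = 0.8) -> np.ndarray:
    """Linear substrate-mixing coefficient decaying over ``band`` pixels.

    Tissue pixels adjacent to substrate are mostly substrate signal
    (``max_mix``: the tissue is thin at the specimen edge and the
    in-focus aluminum shows through); the fraction decays linearly to
    zero over ``band`` shells.  Pure substrate pixels carry 1.
    """
    from scipy.ndimage import distance_transform_cdt

    substrate = label_map == "substrate"
    mixing = np.zeros(label_map.shape, dtype=float)
    if not substrate.any():
        return mixing
    # chessboard distance from each tissue pixel to nearest substrate pixel
    dist = distance_transform_cdt(~substrate, metric="chessboard")
    inside = ~substrate & (dist <= band)
    mixing[inside] = max_mix * (band + 1 - dist[inside]) / band
    mixing[substrate] = 1.0
    return mixing


def build_phantom_scene(
    layout_name: str,
    n_rows: int = 40,
    n_cols: int = 42,
    seed: int = 0,
    *,
    edge_band: int = 2,
) -> PhantomScene:
    """Deterministic ground-truth scene for one of the canned layouts.

    Layouts
    -------
    ``tumor_block``
        Specimen fills the field of view; upper part cancer, lower part
        non-fat normal tissue (a margin running across the image).
    ``fat_block``
        Specimen fills the field of view; purely adipose.
    ``mixed_margin``
        Specimen smaller than the field of view (substrate ring), with
        cancer / normal / fat sectors meeting inside the tissue area.
    ``small_tumor_in_fat``
        Specimen smaller than the field of view; adipose tissue with a
        single small (1–5 % of tissue pixels) connected cancer focus.
    """
    if layout_name not in LAYOUTS:
        raise ValueError(f"unknown layout {layout_name!r}; expected one of {LAYOUTS}")
    if n_rows < 4 or n_cols < 4:
        raise ValueError("raster must be at least 4 x 4")

    rng = np.random.default_rng(seed)
    labels = np.empty((n_rows, n_cols), dtype=object)

    if layout_name == "fat_block":
        labels[:, :] = "fat"
    elif layout_name == "tumor_block":
        split = int(round(n_rows * 0.55))
        labels[:split, :] = "cancer"
        labels[split:, :] = "normal"
    elif layout_name == "mixed_margin":
        # a margin running across the specimen: tumour on the left, a band
        # of non-fat normal tissue, adipose on the right; specimen smaller
        # than the field of view
        labels[:, :] = "normal"
        ring = max(2, min(n_rows, n_cols) // 14)
        labels[:, : int(n_cols * 0.40)] = "cancer"
        labels[:, int(n_cols * 0.70):] = "fat"
        _substrate_ring(labels, ring)
    elif layout_name == "small_tumor_in_fat":
        labels[:, :] = "fat"
        ring = max(2, min(n_rows, n_cols) // 14)
        _substrate_ring(labels, ring)
        tissue = np.argwhere(labels != "substrate")
        n_tissue = len(tissue)
        target = max(1, int(round(0.03 * n_tissue)))  # ~3 % of tissue pixels
        # grow one connected blob around a random interior seed pixel
        interior = tissue[
            (tissue[:, 0] > ring + 1)
            & (tissue[:, 0] < n_rows - ring - 2)
            & (tissue[:, 1] > ring + 1)
            & (tissue[:, 1] < n_cols - ring - 2)
        ]
        r0, c0 = interior[rng.integers(len(interior))]
        blob = {(int(r0), int(c0))}
        frontier = [(int(r0), int(c0))]
        while len(blob) < target and frontier:
            r, c = frontier[rng.integers(len(frontier))]
            nbrs = [
                (r + dr, c + dc)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if labels[(r + dr) % n_rows, (c + dc) % n_cols] == "fat"
                and ring <= r + dr < n_rows - ring
                and ring <= c + dc < n_cols - ring
                and (r + dr, c + dc) not in blob
            ]
            if not nbrs:
                frontier.remove((r, c))
                continue
            pick = nbrs[rng.integers(len(nbrs))]
            blob.add(pick)
            frontier.append(pick)
        for r, c in blob:
            labels[r, c] = "cancer"

    mixing = _edge_mixing(labels, band=edge_band)
    return PhantomScene(
        label_map=labels, mixing_map=mixing, layout_name=layout_name, seed=seed
    )
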