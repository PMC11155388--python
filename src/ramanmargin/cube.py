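"""Hyperspectral cube container with processing-stage provenance.

A cube is a rows × columns raster where every pixel holds a full Raman
spectrum.  The ``stage`` tag records how far through the conditioning
chain the intensities have travelled; stage transitions are validated so
that e.g. SNV-normalised data cannot silently be despiked twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .axis import WavenumberAxis

__all__ = ["Stage", "HyperCube", "StageError"]


class Stage:
    """Enumerated provenance tags, in canonical chain order."""

    RAW = "raw"
    DESPIKED = "despiked"
    CALIBRATED = "calibrated"
    RESPONSE_CORRECTED = "response_corrected"
    BASELINE_REMOVED = "baseline_removed"
    BACKGROUND_SUBTRACTED = "background_subtracted"
    SNV = "snv"

    ORDER = (
        RAW,
        DESPIKED,
        CALIBRATED,
        RESPONSE_CORRECTED,
        BASELINE_REMOVED,
        BACKGROUND_SUBTRACTED,
        SNV,
    )


class StageError(ValueError):
    """Raised on an out-of-order or unknown stage transition."""


@dataclass
class HyperCube:
    """rows × columns × bins intensity array plus axis and provenance.

    ``stage_log`` is an append-only record of every processing step
    applied, with its parameters; it is carried (copied) through stage
    transitions so a processed cube documents its own history.
    """

    intensities: np.ndarray
    axis: WavenumberAxis
    stage: str = Stage.RAW
    stage_log: list = field(default_factory=list)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be rows x columns x bins")
        if arr.shape[2] != self.axis.n_bins:
            raise ValueError(
                f"spectral dimension {arr.shape[2]} != axis bins {self.axis.n_bins}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if self.stage not in Stage.ORDER:
            raise StageError(f"unknown stage {self.stage!r}")
        self.intensities = arr

    # -- geometry ------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_spectra(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def spectra(self) -> np.ndarray:
        """View of the cube as (n_spectra, n_bins)."""
        return self.intensities.reshape(-1, self.axis.n_bins)

    # -- stage transitions ---------------------------------------------
    def advance(
        self,
        intensities: np.ndarray,
        new_stage: str,
        step: str,
        *,
        axis: WavenumberAxis | None = None,
        allow_reorder: bool = False,
        **params,
    ) -> "HyperCube":
        """Return a new cube at ``new_stage`` with ``step`` logged.

        By default the new stage must come strictly after the current one
        in the canonical chain order; ``allow_reorder=True`` permits a
        configured reordering, which is then flagged in the log entry.
        """
        if new_stage not in Stage.ORDER:
            raise StageError(f"unknown stage {new_stage!r}")
        old_i = Stage.ORDER.index(self.stage)
        new_i = Stage.ORDER.index(new_stage)
        reordered = new_i <= old_i
        if reordered and not allow_reorder:
            raise StageError(
                f"stage transition {self.stage} -> {new_stage} violates chain order"
            )
        arr = np.asarray(intensities, dtype=float)
        if arr.shape != self.intensities.shape:
            raise ValueError("stage transitions must preserve cube shape")
        entry = {"step": step, "stage": new_stage, "params": params}
        if reordered:
            entry["reordered"] = True
        return HyperCube(
            intensities=arr,
            axis=axis if axis is not None else self.axis,
            stage=new_stage,
            stage_log=[*self.stage_log, entry],
        )

    def copy(self) -> "HyperCube":
        return replace(
            self,
            intensities=self.intensities.copy(),
            stage_log=[dict(e) for e in self.stage_log],
        )
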