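"""Hierarchical pipeline configuration.

Pydantic models with ``extra="forbid"`` so unknown keys are rejected,
and lossless YAML round-tripping.  A single global seed fans out to
per-stage seeds by a fixed derivation so stages are independently
reproducible.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "SimulateConfig", "PreprocessConfig", "QCConfig",
           "ClassifyConfig", "ReportConfig", "stage_seed"]

_STAGE_OFFSETS = {"simulate": 1, "references": 2, "train": 3, "classify": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 7919 + _STAGE_OFFSETS[stage] * 104729) % (2**31 - 1)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    layout: str = "mixed_margin"
    n_rows: int = 40
    n_cols: int = 42
    n_accumulations: int = 3
    signal_scale: float = 1000.0
    shot_scale: float = 1.0
    read_sd: float = 10.0
    cosmic_ray_rate: float = 0.1
    baseline_amp_lo: float = 0.5
    baseline_amp_hi: float = 2.0
    substrate_amp: float = 0.2
    substrate_defocus: float = 0.25
    chromatic_amp: float = 0.3
    amplitude_jitter_sd: float = 0.10
    dark_integration_factor: float = 5.0
    edge_band: int = 2


class PreprocessConfig(_Strict):
    median_window: int = 5
    spike_factor: float = 5.0
    calibration_degree: int = 2
    peak_prominence_sigma: float = 5.0
    response_smooth_window: int = 31
    response_floor: float = 0.05
    min_bubble_width: float = 150.0
    n_excluded_columns: int = 5
    dark_before_baseline: bool = False


class QCConfig(_Strict):
    threshold: float = 0.5
    smooth_window: int = 7
    smooth_order: int = 3


class ClassifyConfig(_Strict):
    half_width: float = 6.0
    svm_c: float = 1.0
    n_calibration_folds: int = 5
    threshold_policy_a: str = "protect_cancer"
    threshold_policy_b: str = "default"
    train_n_fat: int = 93
    train_n_cancer: int = 87
    train_n_normal: int = 58
    train_snr: float = 25.0


class ReportConfig(_Strict):
    positive_cutoff: float = 0.3
    negative_cutoff: float = 0.15
    band_maps: list[float] = Field(
        default_factory=lambda: [940.0, 1004.0, 1129.0, 1155.0])


class PipelineConfig(_Strict):
    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config file; explicit files must name every stage block."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for section in ("simulate", "preprocess", "qc", "classify", "report"):
            if section not in data:
                raise ValueError(f"config file missing section: {section}")
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
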