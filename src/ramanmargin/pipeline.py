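"""End-to-end orchestration: simulate → preprocess → QC → classify → report."""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classify import (BandFeatureSpec, MODEL_A_BANDS, MODEL_B_BANDS,
                       PixelClassMap, classify_pixels, select_operating_threshold,
                       train_band_classifier)
from .config import PipelineConfig, stage_seed
from .phantom import PhantomScene, build_phantom_scene
from .preprocess import PreprocessResult, preprocess_cube
from .quality import QualityMask, apply_qf_exclusion
from .report import (SpecimenSummary, band_intensity_map, flag_cancer_burden,
                     render_class_map, summarize_specimen)
from .simulate import (AcquisitionParams, make_point_probe_training_set,
                       simulate_raw_cube, simulate_reference_measurements)

__all__ = ["PipelineResult", "run_pipeline", "train_default_models",
           "acquisition_params_from_config"]


@dataclass
class PipelineResult:
    scene: PhantomScene
    preprocessed: PreprocessResult
    mask: QualityMask
    classmap: PixelClassMap
    summary: SpecimenSummary
    burden: str
    run_log: list


def acquisition_params_from_config(cfg: PipelineConfig) -> AcquisitionParams:
    s = cfg.simulate
    return AcquisitionParams(
        n_rows=s.n_rows, n_cols=s.n_cols, n_accumulations=s.n_accumulations,
        signal_scale=s.signal_scale, shot_scale=s.shot_scale, read_sd=s.read_sd,
        cosmic_ray_rate=s.cosmic_ray_rate,
        baseline_amp_range=(s.baseline_amp_lo, s.baseline_amp_hi),
        substrate_amp=s.substrate_amp, substrate_defocus=s.substrate_defocus,
        chromatic_amp=s.chromatic_amp,
        amplitude_jitter_sd=s.amplitude_jitter_sd,
        dark_integration_factor=s.dark_integration_factor,
        seed=stage_seed(cfg.seed, "simulate"),
    )


def train_default_models(cfg: PipelineConfig):
    """Train the fat gate (model A) and cancer detector (model B) on the
    seeded default point-probe set, applying the configured threshold
    policies."""
    c = cfg.classify
    seed = stage_seed(cfg.seed, "train")
    train = make_point_probe_training_set(
        n_fat=c.train_n_fat, n_cancer=c.train_n_cancer, n_normal=c.train_n_normal,
        snr=c.train_snr, seed=seed)
    spec_a = BandFeatureSpec(MODEL_A_BANDS, c.half_width)
    spec_b = BandFeatureSpec(MODEL_B_BANDS, c.half_width)
    model_a = train_band_classifier(
        train, spec_a, positive_class="fat",
        grouping={"fat": "pos", "normal": "neg", "cancer": "neg"},
        seed=seed, C=c.svm_c, n_calibration_folds=c.n_calibration_folds)
    model_a = select_operating_threshold(model_a, train, c.threshold_policy_a)
    model_b = train_band_classifier(
        train, spec_b, positive_class="cancer",
        grouping={"cancer": "pos", "normal": "neg"},
        seed=seed, C=c.svm_c, n_calibration_folds=c.n_calibration_folds)
    model_b = select_operating_threshold(model_b, train, c.threshold_policy_b)
    return train, model_a, model_b


def run_pipeline(cfg: PipelineConfig, out_dir=None, *, verbose: bool = False
                 ) -> PipelineResult:
    """Execute the full pipeline for one simulated specimen.

    When ``out_dir`` is given, writes the SNV cube (HDF5 with mask and
    ground-truth labels), the summary CSV, the rendered classification
    map and band maps (PNG), both model files, and a JSON-lines run log
    sufficient to replay the run.
    """
    log: list[dict] = []

    def note(stage: str, **info):
        entry = {"stage": stage, **info}
        log.append(entry)
        if verbose:
            print(json.dumps(entry), file=sys.stderr)

    note("config", seed=cfg.seed, config=cfg.model_dump())

    params = acquisition_params_from_config(cfg)
    scene = build_phantom_scene(cfg.simulate.layout, params.n_rows, params.n_cols,
                                seed=stage_seed(cfg.seed, "simulate"),
                                edge_band=cfg.simulate.edge_band)
    cube = simulate_raw_cube(scene, params)
    note("simulate", layout=cfg.simulate.layout, n_spectra=cube.n_spectra)

    ref_params = AcquisitionParams(
        n_rows=params.n_rows, n_cols=params.n_cols,
        signal_scale=params.signal_scale, chromatic_amp=params.chromatic_amp,
        dark_integration_factor=params.dark_integration_factor,
        seed=stage_seed(cfg.seed, "references"))
    acet, standard, dark = simulate_reference_measurements(ref_params)
    note("references", calibration_peaks=6)

    p = cfg.preprocess
    pre = preprocess_cube(
        cube, acet, standard, dark,
        median_window=p.median_window, calibration_degree=p.calibration_degree,
        min_bubble_width=p.min_bubble_width,
        dark_integration_factor=cfg.simulate.dark_integration_factor,
        n_excluded_columns=p.n_excluded_columns,
        dark_before_baseline=p.dark_before_baseline)
    note("preprocess", calibration_rms=pre.calibration_rms,
         n_degenerate=int(pre.degenerate.sum()))

    q = cfg.qc
    mask = apply_qf_exclusion(pre.cube, q.threshold,
                              column_excluded=pre.column_excluded,
                              degenerate=pre.degenerate,
                              smooth_window=q.smooth_window,
                              smooth_order=q.smooth_order)
    note("qc", pct_excluded=mask.pct_excluded)

    train, model_a, model_b = train_default_models(cfg)
    note("train", threshold_a=model_a.operating_threshold,
         threshold_b=model_b.operating_threshold,
         fingerprint_a=model_a.training_fingerprint,
         fingerprint_b=model_b.training_fingerprint)

    classmap = classify_pixels(pre.cube, mask, model_a, model_b)
    summary = summarize_specimen(classmap, mask)
    burden = flag_cancer_burden(summary, cfg.report.positive_cutoff,
                                cfg.report.negative_cutoff)
    note("report", burden=burden, **summary.rounded())

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_cube, write_model_json

        write_cube(pre.cube, out_dir / "cube_snv.h5",
                   label_map=scene.label_map, mask=mask)
        write_model_json(model_a, out_dir / "model_a.json")
        write_model_json(model_b, out_dir / "model_b.json")
        _write_summary_csv(summary, burden, out_dir / "summary.csv")
        render_class_map(classmap, out_path=out_dir / "class_map.png")
        for center in cfg.report.band_maps:
            bm = band_intensity_map(pre.cube, center, cfg.classify.half_width,
                                    mask=mask)
            np.savetxt(out_dir / f"band_{int(center)}.csv", bm, delimiter=",")
        with open(out_dir / "run_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")

    return PipelineResult(scene=scene, preprocessed=pre, mask=mask,
                          classmap=classmap, summary=summary, burden=burden,
                          run_log=log)


def _write_summary_csv(summary: SpecimenSummary, burden: str, path) -> None:
    import pandas as pd

    row = summary.rounded()
    row.update({"burden": burden,
                "p_mean_raw": summary.p_mean, "p_std_raw": summary.p_std,
                "pct_excluded_raw": summary.pct_excluded,
                "pct_fat_raw": summary.pct_fat,
                "pct_cancer_raw": summary.pct_cancer})
    pd.DataFrame([row]).to_csv(path, index=False)
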