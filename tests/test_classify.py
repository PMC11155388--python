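import dataclasses

import numpy as np
import pytest

from ramanmargin.axis import default_axis
from ramanmargin.classify import (BandClassifier, BandFeatureSpec,
                                  MODEL_A_BANDS, MODEL_B_BANDS,
                                  classify_pixels, extract_band_features,
                                  select_operating_threshold,
                                  train_band_classifier)
from ramanmargin.cube import HyperCube, Stage
from ramanmargin.phantom import emit_endmember_spectrum
from ramanmargin.preprocess import snv_normalize
from ramanmargin.quality import QualityMask
from ramanmargin.simulate import LabeledSpectrumSet, make_point_probe_training_set

AXIS = default_axis()


class TestBandFeatures:
    def test_model_band_counts(self):
        s = snv_normalize(emit_endmember_spectrum("cancer", AXIS))
        assert extract_band_features(s, AXIS, BandFeatureSpec(MODEL_A_BANDS)).shape == (3,)
        assert extract_band_features(s, AXIS, BandFeatureSpec(MODEL_B_BANDS)).shape == (4,)

    def test_delta_spectrum_with_zero_half_width(self):
        s = np.zeros(AXIS.n_bins)
        s[AXIS.index_of(1004.0)] = 1.0
        f = extract_band_features(s, AXIS, BandFeatureSpec(MODEL_A_BANDS, 0.0))
        np.testing.assert_array_equal(f, [0.0, 1.0, 0.0])

    def test_window_mean_over_known_values(self):
        s = np.zeros(AXIS.n_bins)
        i = AXIS.index_of(1004.0)
        s[i - 1 : i + 2] = [2.0, 4.0, 6.0]
        center = float(AXIS.values[i])  # window centred on the grid point
        f = extract_band_features(s, AXIS,
                                  BandFeatureSpec((center,), AXIS.median_spacing))
        assert f[0] == pytest.approx(4.0)

    def test_center_outside_axis_rejected(self):
        s = np.zeros(AXIS.n_bins)
        with pytest.raises(ValueError, match="outside axis span"):
            extract_band_features(s, AXIS, BandFeatureSpec((2500.0,)))


def separable_set(n=40, gap=4.0, seed=0):
    """Two synthetic classes separated along the 1004 band."""
    rng = np.random.default_rng(seed)
    spectra, labels = [], []
    base = emit_endmember_spectrum("normal", AXIS)
    bump = np.exp(-0.5 * ((AXIS.values - 1004.0) / 8.0) ** 2)
    for _ in range(n):
        spectra.append(snv_normalize(base + rng.normal(0, 0.01, AXIS.n_bins)))
        labels.append("normal")
        spectra.append(snv_normalize(base + gap * bump
                                     + rng.normal(0, 0.01, AXIS.n_bins)))
        labels.append("cancer")
    return LabeledSpectrumSet(np.array(spectra), np.array(labels, object), AXIS)


class TestTraining:
    GROUPING = {"cancer": "pos", "normal": "neg"}

    def test_separable_clusters_fit_perfectly(self):
        train = separable_set()
        model = train_band_classifier(train, BandFeatureSpec(MODEL_B_BANDS),
                                      "cancer", self.GROUPING, seed=0)
        feats = extract_band_features(train.spectra, AXIS, model.feature_spec)
        pred = model.predict_positive(feats)
        truth = train.labels == "cancer"
        assert (pred == truth).all()

    def test_probabilities_bounded(self, training_set):
        model = train_band_classifier(training_set, BandFeatureSpec(MODEL_B_BANDS),
                                      "cancer", self.GROUPING, seed=1)
        feats = extract_band_features(training_set.spectra, AXIS,
                                      model.feature_spec)
        p = model.predict_proba(feats)
        assert (p >= 0).all() and (p <= 1).all()

    def test_single_class_rejected(self):
        train = separable_set()
        only = train.subset(train.labels == "cancer")
        with pytest.raises(ValueError, match="both groups"):
            train_band_classifier(only, BandFeatureSpec(MODEL_B_BANDS),
                                  "cancer", self.GROUPING, seed=0)

    def test_training_deterministic_given_seed(self, training_set):
        kw = dict(spec=BandFeatureSpec(MODEL_B_BANDS), positive_class="cancer",
                  grouping=self.GROUPING, seed=3)
        a = train_band_classifier(training_set, kw["spec"], kw["positive_class"],
                                  kw["grouping"], seed=3)
        b = train_band_classifier(training_set, kw["spec"], kw["positive_class"],
                                  kw["grouping"], seed=3)
        assert np.array_equal(a.weights, b.weights)
        assert a.calibration_a == b.calibration_a


class TestThresholdPolicy:
    def test_default_policy_is_half(self, default_models):
        train, model_a, _ = default_models
        reset = select_operating_threshold(model_a, train, "default")
        assert reset.operating_threshold == 0.5

    def test_protect_cancer_sits_just_above_max_cancer_probability(self, default_models):
        train, model_a, _ = default_models
        feats = extract_band_features(train.spectra[train.labels == "cancer"],
                                      AXIS, model_a.feature_spec)
        p_max = model_a.predict_proba(feats).max()  # brute-force oracle
        assert model_a.threshold_policy == "protect_cancer"
        assert model_a.operating_threshold > p_max
        assert model_a.operating_threshold == pytest.approx(p_max, abs=1e-12)

    def test_protect_cancer_loses_no_cancer_at_the_gate(self, default_models):
        train, model_a, _ = default_models
        feats = extract_band_features(train.spectra[train.labels == "cancer"],
                                      AXIS, model_a.feature_spec)
        assert not model_a.predict_positive(feats).any()

    def test_raising_threshold_never_adds_fat_calls(self, default_models):
        train, model_a, _ = default_models
        feats = extract_band_features(train.spectra, AXIS, model_a.feature_spec)
        counts = []
        for thr in (0.1, 0.5, 0.9):
            m = dataclasses.replace(model_a, operating_threshold=thr)
            counts.append(int(m.predict_positive(feats).sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_unattainable_policy_flags_warning(self, default_models):
        train, model_a, _ = default_models
        # saturate the calibration so every spectrum has probability 1
        saturated = dataclasses.replace(model_a, calibration_a=0.0,
                                        calibration_b=-50.0)
        out = select_operating_threshold(saturated, train, "protect_cancer")
        assert out.operating_threshold == 1.0
        assert out.threshold_warning

    def test_unknown_policy_rejected(self, default_models):
        train, model_a, _ = default_models
        with pytest.raises(ValueError, match="policy"):
            select_operating_threshold(model_a, train, "yolo")


def toy_cube_and_mask(labels_grid):
    """SNV cube whose pixels are noise-free endmembers per the label grid."""
    rows, cols = labels_grid.shape
    arr = np.empty((rows, cols, AXIS.n_bins))
    for r in range(rows):
        for c in range(cols):
            arr[r, c] = snv_normalize(
                emit_endmember_spectrum(labels_grid[r, c], AXIS))
    log = [{"step": "toy", "stage": Stage.SNV, "params": {}}]
    cube = HyperCube(arr, AXIS, stage=Stage.SNV, stage_log=log)
    reasons = np.full((rows, cols), "ok", dtype=object)
    mask = QualityMask(qf_map=np.ones((rows, cols)),
                       included=np.ones((rows, cols), bool),
                       reasons=reasons, threshold=0.5)
    return cube, mask


class TestPixelClassification:
    def test_masked_pixels_carry_no_probabilities(self, default_models):
        _, model_a, model_b = default_models
        grid = np.array([["fat", "cancer"], ["normal", "fat"]], dtype=object)
        cube, mask = toy_cube_and_mask(grid)
        mask.reasons[0, 0] = "low_qf"
        mask.included[0, 0] = False
        cmap = classify_pixels(cube, mask, model_a, model_b)
        assert cmap.labels[0, 0] == "excluded"
        assert np.isnan(cmap.p_fat[0, 0]) and np.isnan(cmap.p_cancer[0, 0])

    def test_sequential_gate_never_gives_fat_a_cancer_probability(self, default_models):
        _, model_a, model_b = default_models
        grid = np.array([["fat", "cancer", "normal"]] * 3, dtype=object)
        cube, mask = toy_cube_and_mask(grid)
        cmap = classify_pixels(cube, mask, model_a, model_b)
        assert not np.isfinite(cmap.p_cancer[cmap.labels == "fat"]).any()
        assert np.isfinite(cmap.p_fat[mask.included]).all()

    def test_noise_free_endmembers_classified_correctly(self, default_models):
        _, model_a, model_b = default_models
        grid = np.array([["fat", "cancer", "normal"]] * 2, dtype=object)
        cube, mask = toy_cube_and_mask(grid)
        cmap = classify_pixels(cube, mask, model_a, model_b)
        assert (cmap.labels == grid).all()

    def test_all_fat_scene_with_protective_gate_has_no_cancer(self, default_models):
        _, model_a, model_b = default_models
        grid = np.full((4, 5), "fat", dtype=object)
        cube, mask = toy_cube_and_mask(grid)
        cmap = classify_pixels(cube, mask, model_a, model_b)
        assert cmap.count("cancer") == 0

    def test_model_b_threshold_monotonicity_on_fixed_cube(self, default_models):
        _, model_a, model_b = default_models
        grid = np.array([["cancer", "normal", "cancer", "normal"]] * 4,
                        dtype=object)
        cube, mask = toy_cube_and_mask(grid)
        counts = []
        for thr in (0.05, 0.5, 0.95):
            mb = dataclasses.replace(model_b, operating_threshold=thr)
            cmap = classify_pixels(cube, mask, model_a, mb)
            counts.append(cmap.count("cancer"))
        assert counts[0] >= counts[1] >= counts[2]

    def test_model_serialisation_round_trip(self, default_models, tmp_path):
        from ramanmargin.io import read_model_json, write_model_json

        _, model_a, _ = default_models
        path = tmp_path / "model.json"
        write_model_json(model_a, path)
        back = read_model_json(path)
        assert isinstance(back, BandClassifier)
        assert np.array_equal(back.weights, model_a.weights)
        assert back.operating_threshold == model_a.operating_threshold
        assert back.feature_spec == model_a.feature_spec
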