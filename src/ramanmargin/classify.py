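"""Sequential band-feature tissue classification.

Two linear maximum-margin models act in sequence on every retained
pixel: model A separates fat from non-fat using the mean SNV intensity
in narrow windows at 940, 1004 and 1304 cm⁻¹; model B then separates
cancer from normal among the non-fat pixels using 940, 1004, 1129 and
1155 cm⁻¹.  Each model carries Platt-calibrated posterior probabilities
(sigmoid fitted on seeded out-of-fold decision scores) and an operating
threshold; the fat gate's threshold can be raised so that no training
cancer spectrum is ever absorbed into the (unreviewed) fat class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .axis import WavenumberAxis
from .cube import HyperCube, Stage
from .quality import QualityMask
from .simulate import LabeledSpectrumSet

__all__ = [
    "BandFeatureSpec",
    "MODEL_A_BANDS",
    "MODEL_B_BANDS",
    "BandClassifier",
    "PixelClassMap",
    "extract_band_features",
    "train_band_classifier",
    "select_operating_threshold",
    "classify_pixels",
]

DEFAULT_HALF_WIDTH = 6.0  # cm^-1, one resolution element

MODEL_A_BANDS = (940.0, 1004.0, 1304.0)
MODEL_B_BANDS = (940.0, 1004.0, 1129.0, 1155.0)

LABEL_EXCLUDED = "excluded"
OUTPUT_LABELS = ("fat", "normal", "cancer", LABEL_EXCLUDED)


@dataclass(frozen=True)
class BandFeatureSpec:
    """Named band features: mean intensity in ``center ± half_width``."""

    band_centers: tuple
    half_width: float = DEFAULT_HALF_WIDTH

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        object.__setattr__(self, "band_centers",
                           tuple(float(c) for c in self.band_centers))

    def __len__(self) -> int:
        return len(self.band_centers)


def extract_band_features(spectrum: np.ndarray, axis: WavenumberAxis,
                          spec: BandFeatureSpec) -> np.ndarray:
    """Feature vector of one spectrum (one mean per band window)."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != axis.n_bins:
        raise ValueError("spectrum not on the given axis")
    feats = [spectrum[..., axis.window_indices(c, spec.half_width)].mean(axis=-1)
             for c in spec.band_centers]
    return np.stack(feats, axis=-1)


@dataclass
class BandClassifier:
    """Calibrated linear decision rule over named band features."""

    feature_spec: BandFeatureSpec
    positive_class: str
    grouping: dict                      # label -> "pos" | "neg"
    weights: np.ndarray = None          # type: ignore[assignment]
    bias: float = 0.0
    feature_mean: np.ndarray = None     # type: ignore[assignment]
    feature_sd: np.ndarray = None       # type: ignore[assignment]
    calibration_a: float = -1.0         # p = sigmoid(-(a*f + b))
    calibration_b: float = 0.0
    operating_threshold: float = 0.5
    threshold_policy: str = "default"
    threshold_warning: bool = False
    training_fingerprint: str = ""
    seed: int = 0

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        z = (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_sd
        return z @ self.weights + self.bias

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Calibrated posterior probability of the positive class."""
        f = self.decision_scores(features)
        return 1.0 / (1.0 + np.exp(self.calibration_a * f + self.calibration_b))

    def predict_positive(self, features: np.ndarray) -> np.ndarray:
        """Probability at or above the operating threshold → positive."""
        return self.predict_proba(features) >= self.operating_threshold

    def to_dict(self) -> dict:
        return {
            "band_centers": list(self.feature_spec.band_centers),
            "half_width": self.feature_spec.half_width,
            "positive_class": self.positive_class,
            "grouping": dict(self.grouping),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "calibration_a": self.calibration_a,
            "calibration_b": self.calibration_b,
            "operating_threshold": self.operating_threshold,
            "threshold_policy": self.threshold_policy,
            "threshold_warning": self.threshold_warning,
            "training_fingerprint": self.training_fingerprint,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandClassifier":
        return cls(
            feature_spec=BandFeatureSpec(tuple(d["band_centers"]), d["half_width"]),
            positive_class=d["positive_class"],
            grouping=dict(d["grouping"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_sd=np.asarray(d["feature_sd"], dtype=float),
            calibration_a=float(d["calibration_a"]),
            calibration_b=float(d["calibration_b"]),
            operating_threshold=float(d["operating_threshold"]),
            threshold_policy=d.get("threshold_policy", "default"),
            threshold_warning=bool(d.get("threshold_warning", False)),
            training_fingerprint=d.get("training_fingerprint", ""),
            seed=int(d.get("seed", 0)),
        )


def _fingerprint(features: np.ndarray, y: np.ndarray) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(features).tobytes())
    h.update("".join(map(str, y)).encode())
    return h.hexdigest()[:16]


def train_band_classifier(
    train: LabeledSpectrumSet,
    spec: BandFeatureSpec,
    positive_class: str,
    grouping: dict,
    seed: int = 0,
    *,
    C: float = 1.0,
    n_calibration_folds: int = 5,
) -> BandClassifier:
    """Fit a linear SVM on standardized band features, with Platt calibration.

    ``grouping`` maps every training label to "pos" or "neg"; labels
    absent from the mapping are dropped.  The sigmoid calibration is
    fitted on out-of-fold decision scores from a seeded stratified
    ``n_calibration_folds``-fold split, so probabilities are honest and
    the whole fit is deterministic given the seed.
    """
    keep = np.array([lbl in grouping for lbl in train.labels])
    subset = train.subset(keep)
    y = np.array([1 if grouping[lbl] == "pos" else 0 for lbl in subset.labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both groups after grouping")

    features = extract_band_features(subset.spectra, subset.axis, spec)
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    z = (features - mean) / sd

    svm = SVC(kernel="linear", C=C)
    svm.fit(z, y)
    weights = svm.coef_.ravel().copy()
    bias = float(svm.intercept_[0])

    # out-of-fold decision scores for the sigmoid
    n_folds = min(n_calibration_folds, np.bincount(y).min())
    if n_folds >= 2:
        scores = np.empty(len(y))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(z, y):
            fold = SVC(kernel="linear", C=C)
            fold.fit(z[tr], y[tr])
            scores[te] = fold.decision_function(z[te])
    else:  # tiny data: calibrate on training scores
        scores = svm.decision_function(z)
    lr = LogisticRegression(C=1e6)
    lr.fit(scores.reshape(-1, 1), y)
    # p = sigmoid(w*f + b) -> stored as 1/(1+exp(a*f + b)) with a = -w
    cal_a = -float(lr.coef_[0, 0])
    cal_b = -float(lr.intercept_[0])

    return BandClassifier(
        feature_spec=spec,
        positive_class=positive_class,
        grouping=dict(grouping),
        weights=weights,
        bias=bias,
        feature_mean=mean,
        feature_sd=sd,
        calibration_a=cal_a,
        calibration_b=cal_b,
        operating_threshold=0.5,
        training_fingerprint=_fingerprint(features, subset.labels),
        seed=seed,
    )


def select_operating_threshold(model: BandClassifier, train: LabeledSpectrumSet,
                               policy: str = "default") -> BandClassifier:
    """Set the model's operating threshold.

    ``default``
        Threshold 0.5.
    ``protect_cancer``
        For the fat gate: the smallest threshold at which no training
        cancer spectrum is classified fat (probability ≥ threshold),
        i.e. just above the largest fat-probability among cancer
        spectra.  If a cancer spectrum reaches probability 1 the policy
        is unattainable; threshold 1 is used and a warning flag raised.
    """
    import dataclasses

    if policy == "default":
        return dataclasses.replace(model, operating_threshold=0.5,
                                   threshold_policy="default",
                                   threshold_warning=False)
    if policy != "protect_cancer":
        raise ValueError(f"unknown threshold policy {policy!r}")

    cancer = train.labels == "cancer"
    if not cancer.any():
        raise ValueError("protect_cancer policy needs cancer spectra in training")
    feats = extract_band_features(train.spectra[cancer], train.axis,
                                  model.feature_spec)
    p_max = float(model.predict_proba(feats).max())
    if p_max >= 1.0:
        return dataclasses.replace(model, operating_threshold=1.0,
                                   threshold_policy=policy, threshold_warning=True)
    threshold = float(np.nextafter(p_max, 1.0))
    return dataclasses.replace(model, operating_threshold=threshold,
                               threshold_policy=policy, threshold_warning=False)


@dataclass
class PixelClassMap:
    """Per-pixel labels and posterior probabilities.

    ``p_fat`` is defined on every included pixel; ``p_cancer`` only on
    included non-fat pixels (NaN elsewhere) — the sequential gate never
    assigns a cancer probability to a fat pixel.
    """

    labels: np.ndarray   # (rows, cols) strings from OUTPUT_LABELS
    p_fat: np.ndarray    # (rows, cols), NaN on excluded pixels
    p_cancer: np.ndarray  # (rows, cols), NaN on excluded and fat pixels

    def __post_init__(self):
        bad = set(np.unique(self.labels)) - set(OUTPUT_LABELS)
        if bad:
            raise ValueError(f"unknown output labels {bad}")
        excl = self.labels == LABEL_EXCLUDED
        if np.isfinite(self.p_fat[excl]).any() or np.isfinite(self.p_cancer[excl]).any():
            raise ValueError("excluded pixels must carry no probabilities")
        if np.isfinite(self.p_cancer[self.labels == "fat"]).any():
            raise ValueError("fat pixels must carry no cancer probability")

    def count(self, label: str) -> int:
        return int((self.labels == label).sum())


def classify_pixels(cube: HyperCube, mask: QualityMask,
                    model_a: BandClassifier, model_b: BandClassifier) -> PixelClassMap:
    """Sequential two-model classification of every retained pixel.

    Model A (fat gate) runs on all included pixels; pixels it does not
    call fat receive model B's cancer-vs-normal probability and label.
    """
    if cube.stage != Stage.SNV:
        raise ValueError(f"classification expects an SNV cube, got {cube.stage!r}")
    if mask.included.shape != (cube.n_rows, cube.n_cols):
        raise ValueError("quality mask does not match cube raster")
    for m in (model_a, model_b):
        for c in m.feature_spec.band_centers:
            lo, hi = cube.axis.span
            if not (lo <= c <= hi):
                raise ValueError(f"band center {c} cm^-1 outside cube axis")

    n_rows, n_cols = cube.n_rows, cube.n_cols
    labels = np.full((n_rows, n_cols), LABEL_EXCLUDED, dtype=object)
    p_fat = np.full((n_rows, n_cols), np.nan)
    p_cancer = np.full((n_rows, n_cols), np.nan)

    inc = mask.included
    if inc.any():
        spectra = cube.intensities[inc]
        fa = extract_band_features(spectra, cube.axis, model_a.feature_spec)
        pf = model_a.predict_proba(fa)
        is_fat = pf >= model_a.operating_threshold
        p_fat[inc] = pf

        lab = np.where(is_fat, "fat", "normal").astype(object)
        if (~is_fat).any():
            fb = extract_band_features(spectra[~is_fat], cube.axis,
                                       model_b.feature_spec)
            pc = model_b.predict_proba(fb)
            lab[~is_fat] = np.where(pc >= model_b.operating_threshold,
                                    "cancer", "normal")
            pcs = np.full(len(lab), np.nan)
            pcs[~is_fat] = pc
            p_cancer[inc] = pcs
        labels[inc] = lab

    return PixelClassMap(labels=labels, p_fat=p_fat, p_cancer=p_cancer)
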