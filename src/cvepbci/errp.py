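"""Detection of error-related potentials from feedback-locked epochs.

Pipeline: common-average reference, linear detrend, 1-16 Hz bandpass,
resample to 32 Hz, extract the 300-990 ms post-feedback window on the
five midline channels Fz, Cz, CPz, Pz, POz, and classify the concatenated
time samples with an RBF-kernel SVM at its historical default parameters
(cost 1, gamma = 1/n_features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .synthetic import ERRP_CHANNELS, FeedbackEpoch

__all__ = [
    "ErrPFeatureVector",
    "ErrPDetector",
    "OracleDetector",
    "DetectorMetrics",
    "preprocess_feedback_epoch",
    "train_errp_detector",
    "evaluate_detector",
    "subjectwise_cross_validation",
]

logger = logging.getLogger(__name__)

#: Analysis window after feedback onset, half-open [start, stop) in seconds.
DEFAULT_WINDOW = (0.300, 0.990)
DEFAULT_RESAMPLE_FS = 32.0


@dataclass
class ErrPFeatureVector:
    """Concatenated resampled time samples, channel-major order."""

    values: np.ndarray
    channel_names: tuple[str, ...] = ERRP_CHANNELS
    fs: float = DEFAULT_RESAMPLE_FS
    window: tuple[float, float] = DEFAULT_WINDOW

    @property
    def n_features(self) -> int:
        return self.values.size


@dataclass
class DetectorMetrics:
    """Sensitivity is ``None`` when no error trials exist to measure it."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float

    def as_tuple(self) -> tuple[float | None, float | None, float]:
        return (self.sensitivity, self.specificity, self.accuracy)


def _bandpass_sos(fs: float, low: float = 1.0, high: float = 16.0, order: int = 4):
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _window_indices(n: int, fs: float, window: tuple[float, float]) -> np.ndarray:
    """Sample indices with start <= t < stop (half-open convention)."""
    t = np.arange(n) / fs
    return np.nonzero((t >= window[0] - 1e-9) & (t < window[1] - 1e-9))[0]


def preprocess_feedback_epoch(
    epoch: FeedbackEpoch,
    window: tuple[float, float] = DEFAULT_WINDOW,
    resample_fs: float = DEFAULT_RESAMPLE_FS,
    channels: tuple[str, ...] = ERRP_CHANNELS,
) -> ErrPFeatureVector:
    """Convert a feedback-locked epoch to the ErrP feature vector.

    Applies, in order: common-average reference over all EEG channels,
    linear detrend, zero-phase 1-16 Hz bandpass, polyphase resampling to
    32 Hz, window extraction, channel selection, concatenation.  With the
    default half-open [300, 990) ms window at 32 Hz this yields 22 samples
    per channel, 110 features in total.
    """
    missing = [c for c in channels if c not in epoch.channel_names]
    if missing:
        raise ValueError(f"epoch is missing required channel(s): {', '.join(missing)}")
    if epoch.fs < 2 * resample_fs:
        raise ValueError(f"epoch sampling rate {epoch.fs} Hz too low")
    if epoch.duration < window[1] - 1e-9:
        raise ValueError(
            f"epoch covers only {epoch.duration:.3f} s; window needs {window[1]:.3f} s"
        )
    data = np.asarray(epoch.data, dtype=np.float64)
    data = data - data.mean(axis=0, keepdims=True)  # common average reference
    data = signal.detrend(data, axis=1, type="linear")
    data = signal.sosfiltfilt(_bandpass_sos(epoch.fs), data, axis=1)
    ratio = Fraction(resample_fs / epoch.fs).limit_denominator(10000)
    data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
    idx = _window_indices(data.shape[1], resample_fs, window)
    rows = [epoch.channel_names.index(c) for c in channels]
    feats = data[np.ix_(rows, idx)].ravel()
    return ErrPFeatureVector(values=feats, channel_names=channels,
                             fs=resample_fs, window=window)


@dataclass
class ErrPDetector:
    """Binary ErrP classifier (RBF-kernel SVM, default parameters).

    ``degenerate`` marks detectors trained without any error examples:
    they always answer "no error" (the situation of a user whose BCI never
    errs, so no ErrP training data exists).
    """

    svm: SVC | None = None
    degenerate: bool = False
    class_counts: dict[int, int] = field(default_factory=dict)
    cv_metrics: DetectorMetrics | None = None
    _fitted: bool = field(default=False, repr=False)

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("detector has not been trained")
        X = np.atleast_2d(X)
        if self.degenerate:
            return np.zeros(X.shape[0], dtype=bool)
        return self.svm.predict(X).astype(bool)

    def predict(self, epochs) -> np.ndarray:
        """Predict error/no-error for FeedbackEpoch(s)."""
        if isinstance(epochs, FeedbackEpoch):
            epochs = [epochs]
        X = np.array([preprocess_feedback_epoch(e).values for e in epochs])
        return self.predict_features(X)


def train_errp_detector(
    epochs: list[FeedbackEpoch],
    labels: list[bool] | None = None,
    C: float = 1.0,
    cv_splits: int = 5,
    seed: int = 0,
) -> ErrPDetector:
    """Train the ErrP detector on labelled feedback epochs.

    Labels default to each epoch's ``is_error`` flag.  If only one class
    is present a degenerate always-no-error detector is returned with a
    logged warning.  Otherwise the SVM (RBF kernel, ``gamma=1/n_features``,
    ``C=1``) is fitted on all data and stratified cross-validated
    sensitivity/specificity/accuracy are recorded.
    """
    if len(epochs) == 0:
        raise ValueError("at least one epoch is required")
    if labels is None:
        labels = [e.is_error for e in epochs]
        if any(l is None for l in labels):
            raise ValueError("unlabelled epoch encountered; pass labels explicitly")
    y = np.asarray(labels, dtype=bool)
    X = np.array([preprocess_feedback_epoch(e).values for e in epochs])
    counts = {0: int((~y).sum()), 1: int(y.sum())}
    if counts[0] == 0 or counts[1] == 0:
        logger.warning(
            "only one class present (counts %s); returning degenerate "
            "always-no-error detector", counts,
        )
        return ErrPDetector(degenerate=True, class_counts=counts, _fitted=True)

    def make_svm() -> SVC:
        # gamma="auto" = 1/n_features, the historical LibSVM default
        return SVC(kernel="rbf", C=C, gamma="auto")

    n_splits = min(cv_splits, counts[0], counts[1])
    cv = None
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        preds = np.empty_like(y)
        for tr, te in skf.split(X, y):
            preds[te] = make_svm().fit(X[tr], y[tr]).predict(X[te])
        cv = evaluate_detector(preds, y)
    svm = make_svm().fit(X, y)
    return ErrPDetector(svm=svm, class_counts=counts, cv_metrics=cv, _fitted=True)


def evaluate_detector(predictions, truths) -> DetectorMetrics:
    """Sensitivity, specificity and accuracy of error detection.

    Sensitivity = TP/(TP+FN) over true-error trials (``None`` when there
    are none, the case of a session without a single misclassification);
    specificity = TN/(TN+FP); accuracy = (TP+TN)/total.
    """
    p = np.asarray(predictions, dtype=bool)
    t = np.asarray(truths, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("predictions and truths have different lengths")
    if p.size == 0:
        raise ValueError("empty label vectors")
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    return DetectorMetrics(
        sensitivity=tp / n_pos if n_pos else None,
        specificity=tn / n_neg if n_neg else None,
        accuracy=(tp + tn) / t.size,
    )


def subjectwise_cross_validation(
    per_subject_epochs: dict[str, tuple[list[FeedbackEpoch], list[bool]]],
    seed: int = 0,
) -> dict[str, DetectorMetrics]:
    """Leave-one-subject-out detector evaluation.

    For each subject, the detector is trained on the pooled epochs of all
    remaining subjects and evaluated on the held-out subject.
    """
    if len(per_subject_epochs) < 2:
        raise ValueError("at least 2 subjects are required")
    out: dict[str, DetectorMetrics] = {}
    for subject, (test_epochs, test_labels) in per_subject_epochs.items():
        train_epochs: list[FeedbackEpoch] = []
        train_labels: list[bool] = []
        for other, (ep, lab) in per_subject_epochs.items():
            if other != subject:
                train_epochs.extend(ep)
                train_labels.extend(lab)
        det = train_errp_detector(train_epochs, train_labels, seed=seed)
        preds = det.predict(test_epochs)
        out[subject] = evaluate_detector(preds, np.asarray(test_labels, dtype=bool))
    return out


class OracleDetector:
    """Detector stand-in with fixed sensitivity/specificity.

    Flips seeded coins against the true outcome instead of reading EEG;
    used in closed-loop studies to decouple adaptation behaviour from
    detector quality.
    """

    def __init__(self, sensitivity: float, specificity: float, seed: int = 0) -> None:
        if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
            raise ValueError("rates must lie in [0, 1]")
        self.sensitivity = sensitivity
        self.specificity = specificity
        self._rng = np.random.default_rng(seed)

    def detect(self, is_error: bool) -> bool:
        u = self._rng.random()
        if is_error:
            return u < self.sensitivity
        return u >= self.specificity
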