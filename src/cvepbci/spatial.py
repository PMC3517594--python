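"""Best-channel selection and the CCA spatial filter.

The filter is built in two steps.  First the single channel on which the
evoked response classifies best is found by leave-one-out cross-validation
with the correlation classifier.  Then canonical correlation analysis is
run between the concatenated multichannel trials ``X`` and the tiled
best-channel average waveform ``Y``; because the reference is univariate,
the canonical pair reduces to a regularized least-squares weight vector.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .codes import TargetLayout, bits_to_samples

__all__ = [
    "SpatialFilter",
    "select_best_channel",
    "build_cca_inputs",
    "compute_cca_filter",
    "loo_channel_accuracies",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialFilter:
    """Channel-weight vector from CCA plus the selected best channel."""

    weights: np.ndarray
    best_channel: int | None = None
    best_channel_accuracy: float | None = None
    canonical_correlation: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if self.canonical_correlation is not None and not (
            -1e-9 <= self.canonical_correlation <= 1 + 1e-9
        ):
            raise ValueError("canonical correlation must lie in [0, 1]")

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Project channels x samples data to the filtered 1-D signal."""
        data = np.asarray(data)
        if data.shape[-2] != self.weights.size:
            raise ValueError("channel count does not match filter weights")
        return np.einsum("c,...cs->...s", self.weights, data)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "best_channel": self.best_channel,
                "best_channel_accuracy": self.best_channel_accuracy,
                "canonical_correlation": self.canonical_correlation,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SpatialFilter":
        obj = json.loads(text)
        return cls(np.array(obj["weights"]), obj["best_channel"],
                   obj["best_channel_accuracy"], obj["canonical_correlation"])


def _as_trial_array(trials) -> np.ndarray:
    """Stack trials (TrialEEG or arrays) into (n_trials, n_channels, n_samples)."""
    arrs = [t.data if hasattr(t, "data") else np.asarray(t, float) for t in trials]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"trials have mismatching shapes: {sorted(shapes)}")
    return np.stack(arrs)


def _correlation_predictions(channel_data: np.ndarray, spb: int, layout: TargetLayout) -> np.ndarray:
    """Leave-one-out correlation classification of frame-0 trials on one channel.

    ``channel_data`` is (n_trials, n_samples).  For each trial the template
    is the average of the remaining trials; the trial is correlated with
    all circularly shifted templates and the best-matching target index is
    returned.  Correct prediction for frame-0 data is target 0.
    """
    nt, ns = channel_data.shape
    total = channel_data.sum(axis=0)
    loo = (total[None, :] - channel_data) / (nt - 1)
    # cross-correlation of trial i with all circular delays of its template
    f_x = np.fft.rfft(channel_data, axis=1)
    f_t = np.fft.rfft(loo, axis=1)
    cc = np.fft.irfft(f_x * np.conj(f_t), n=ns, axis=1)  # cc[i, s] = <x_i, roll(t_i, s)>
    # Pearson ordering at fixed i equals raw cross-correlation ordering
    # (mean and variance of a circularly shifted template are shift-invariant)
    lags = (np.array([layout.shift_of_target(k) for k in range(layout.n_targets)]) * spb) % ns
    return np.argmax(cc[:, lags], axis=1)


def loo_channel_accuracies(trials, layout: TargetLayout, fs: float | None = None,
                           refresh: float = 60.0) -> np.ndarray:
    """Per-channel LOO accuracy of the correlation classifier (frame-0 trials)."""
    arr = _as_trial_array(trials)
    nt, nc, ns = arr.shape
    if nt < 2:
        raise ValueError("at least 2 trials are required for leave-one-out selection")
    if fs is None:
        fs = trials[0].fs if hasattr(trials[0], "fs") else 600.0
    spb = bits_to_samples(1, fs, refresh)
    accs = np.empty(nc)
    for c in range(nc):
        pred = _correlation_predictions(arr[:, c, :], spb, layout)
        accs[c] = float(np.mean(pred == 0))
    return accs


def select_best_channel(trials, layout: TargetLayout, fs: float | None = None,
                        refresh: float = 60.0) -> tuple[int, float]:
    """Select the channel with the highest LOO classification accuracy.

    Trials must be label-aligned to the target-0 frame.  Ties go to the
    lowest channel index.
    """
    accs = loo_channel_accuracies(trials, layout, fs=fs, refresh=refresh)
    best = int(np.argmax(accs))  # argmax takes the first maximum
    return best, float(accs[best])


def build_cca_inputs(trials, best_channel: int) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate trials into the CCA data matrix and tiled reference.

    Returns ``X`` (channels x Nt*Ns: all trials side by side) and ``Y``
    (1 x Nt*Ns: the best channel's across-trial average waveform repeated
    Nt times).
    """
    arr = _as_trial_array(trials)
    nt, nc, ns = arr.shape
    if not 0 <= best_channel < nc:
        raise ValueError(f"best_channel {best_channel} out of range")
    X = arr.transpose(1, 0, 2).reshape(nc, nt * ns)
    mean_wave = arr[:, best_channel, :].mean(axis=0)
    Y = np.tile(mean_wave, nt)[None, :]
    return X, Y


def compute_cca_filter(
    X: np.ndarray,
    Y: np.ndarray,
    ridge: float = 1e-8,
    best_channel: int | None = None,
    best_channel_accuracy: float | None = None,
) -> SpatialFilter:
    """Canonical correlation analysis against a univariate reference.

    Finds the unit-norm channel weights ``w`` maximizing the Pearson
    correlation between ``w @ X`` and ``Y``.  With a one-dimensional
    reference the single canonical pair has the closed form
    ``w ∝ Cxx^-1 cxy`` on centered data; a small trace-scaled ridge guards
    rank-deficient covariance.  The sign is fixed so the correlation is
    nonnegative (Euclidean template matching downstream is sign-sensitive).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).ravel()
    if X.ndim != 2 or X.shape[1] != Y.size:
        raise ValueError("X must be channels x samples matching Y's length")
    y = Y - Y.mean()
    y_norm = np.linalg.norm(y)
    if y_norm == 0:
        raise ValueError("reference Y is constant; CCA undefined")
    Xc = X - X.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T
    cxy = Xc @ y
    eps = ridge * (np.trace(Cxx) / max(X.shape[0], 1) + 1e-300)
    if np.linalg.matrix_rank(Cxx) < X.shape[0]:
        logger.warning("rank-deficient data covariance; ridge regularization applied")
    w = np.linalg.solve(Cxx + eps * np.eye(X.shape[0]), cxy)
    wn = np.linalg.norm(w)
    if wn == 0:
        warnings.warn("CCA produced a zero filter (reference uncorrelated with data)")
        w = np.zeros(X.shape[0])
        corr = 0.0
    else:
        w = w / wn
        proj = w @ Xc
        denom = np.linalg.norm(proj) * y_norm
        corr = float(proj @ y / denom) if denom > 0 else 0.0
        if corr < 0:
            w, corr = -w, -corr
    return SpatialFilter(
        weights=w,
        best_channel=best_channel,
        best_channel_accuracy=best_channel_accuracy,
        canonical_correlation=min(corr, 1.0),
    )
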