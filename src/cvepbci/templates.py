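"""One-class-SVM template learning and nearest-template classification.

A single template ``T0`` is learned from spatially filtered trials that
have been aligned to the target-0 frame; the templates of all other
targets are circular shifts of ``T0`` (one target = ``bit_lag`` code bits).
The template is the support-vector-weighted mean produced by a linear
one-class SVM — an outlier-robust alternative to plain averaging: trials
inconsistent with the bulk receive dual weight capped at ``1/(nu*n)`` or
are excluded altogether.  Classification assigns a trial to the target
whose template is nearest in Euclidean distance.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import OneClassSVM

from .codes import TargetLayout, bits_to_samples

__all__ = [
    "TemplateSet",
    "ocsvm_weighted_mean",
    "fit_template",
    "shift_template",
    "classify",
    "classify_correlation",
]


class TemplateSet:
    """Target-0 template plus its circularly shifted per-target variants."""

    def __init__(
        self,
        base_template: np.ndarray,
        samples_per_bit: int,
        layout: TargetLayout | None = None,
        nu: float = 0.5,
    ) -> None:
        self.base_template = np.asarray(base_template, dtype=np.float64).ravel()
        self.samples_per_bit = int(samples_per_bit)
        self.layout = layout or TargetLayout()
        if not 0 < nu <= 1:
            raise ValueError("nu must be in (0, 1]")
        self.nu = nu

    @property
    def n_samples(self) -> int:
        return self.base_template.size

    @property
    def n_targets(self) -> int:
        return self.layout.n_targets

    def shift_samples(self, k: int) -> int:
        """Circular sample delay of target ``k``'s template."""
        return (self.layout.shift_of_target(k) * self.samples_per_bit) % self.n_samples

    def template(self, k: int) -> np.ndarray:
        return np.roll(self.base_template, self.shift_samples(k))

    @property
    def templates(self) -> dict[int, np.ndarray]:
        return {k: self.template(k) for k in range(self.n_targets)}

    def to_dict(self) -> dict:
        return {
            "base_template": self.base_template.tolist(),
            "samples_per_bit": self.samples_per_bit,
            "n_targets": self.layout.n_targets,
            "bit_lag": self.layout.bit_lag,
            "nu": self.nu,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "TemplateSet":
        layout = TargetLayout(n_targets=obj["n_targets"], bit_lag=obj["bit_lag"],
                              char_map=tuple(TargetLayout().char_map[: obj["n_targets"]]))
        return cls(np.array(obj["base_template"]), obj["samples_per_bit"], layout, obj["nu"])


def ocsvm_weighted_mean(X: np.ndarray, nu: float) -> np.ndarray:
    """Robust average of row vectors via a linear one-class SVM.

    Solves the one-class nu-SVM dual (minimize ``a' K a`` over the capped
    simplex ``sum a = 1``, ``0 <= a_i <= 1/(nu*n)``) and returns the
    weighted mean ``sum a_i x_i``.  Trials far from the bulk either hit the
    weight cap or drop out of the support set entirely, so the result
    tracks the clean cluster mean under contamination.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    if n == 0:
        raise ValueError("at least one trial is required")
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    if n == 1:
        return X[0].copy()
    svm = OneClassSVM(kernel="linear", nu=nu).fit(X)
    alpha = np.zeros(n)
    alpha[svm.support_] = svm.dual_coef_.ravel()
    return (alpha @ X) / alpha.sum()


def fit_template(
    filtered_trials,
    nu: float = 0.5,
    samples_per_bit: int = 10,
    layout: TargetLayout | None = None,
) -> TemplateSet:
    """Learn the target-0 template from frame-aligned filtered trials."""
    X = np.atleast_2d(np.asarray(
        [np.asarray(t, float).ravel() for t in filtered_trials], dtype=np.float64
    ))
    if X.size == 0:
        raise ValueError("at least one trial is required")
    base = ocsvm_weighted_mean(X, nu)
    return TemplateSet(base, samples_per_bit, layout, nu)


def shift_template(template_set: TemplateSet, k: int) -> np.ndarray:
    """Template of target ``k`` (circular shift of the base template)."""
    return template_set.template(k)


def _shift_dot_products(x: np.ndarray, base: np.ndarray) -> np.ndarray:
    """``<x, roll(base, s)>`` for every circular delay ``s`` via the FFT."""
    n = x.size
    return np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(base)), n=n)


def classify(
    filtered_trial: np.ndarray,
    template_set: TemplateSet,
    candidates: list[int] | None = None,
) -> tuple[int, np.ndarray]:
    """Minimum-Euclidean-distance classification of a filtered trial.

    Returns the selected target and the full distance vector (entries for
    non-candidate targets are ``inf`` when a candidate subset is given,
    e.g. during 2-target calibration).  Ties break to the lowest index.
    """
    x = np.asarray(filtered_trial, dtype=np.float64).ravel()
    if x.size != template_set.n_samples:
        raise ValueError(
            f"trial length {x.size} != template length {template_set.n_samples}"
        )
    dots = _shift_dot_products(x, template_set.base_template)
    base_sq = float(np.dot(template_set.base_template, template_set.base_template))
    x_sq = float(np.dot(x, x))
    ks = range(template_set.n_targets) if candidates is None else candidates
    distances = np.full(template_set.n_targets, np.inf)
    for k in ks:
        d_sq = x_sq + base_sq - 2.0 * dots[template_set.shift_samples(k)]
        distances[k] = np.sqrt(max(d_sq, 0.0))
    return int(np.argmin(distances)), distances


def classify_correlation(
    trial: np.ndarray,
    averaged_template: np.ndarray,
    samples_per_bit: int,
    layout: TargetLayout | None = None,
    candidates: list[int] | None = None,
) -> tuple[int, np.ndarray]:
    """Correlation-based baseline classifier (plain averaging + Pearson).

    Used for best-channel selection and as the classical comparison
    method; the target whose shifted template correlates highest with the
    trial is selected.
    """
    layout = layout or TargetLayout()
    x = np.asarray(trial, dtype=np.float64).ravel()
    t = np.asarray(averaged_template, dtype=np.float64).ravel()
    if x.size != t.size:
        raise ValueError("trial and template lengths differ")
    if np.std(x) == 0 or np.std(t) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    n = x.size
    dots = _shift_dot_products(x, t)
    # Pearson correlation at each circular shift (template moments are
    # shift-invariant).
    corr_all = (dots / n - x.mean() * t.mean()) / (x.std() * t.std())
    ks = range(layout.n_targets) if candidates is None else candidates
    corrs = np.full(layout.n_targets, -np.inf)
    for k in ks:
        corrs[k] = corr_all[(layout.shift_of_target(k) * samples_per_bit) % n]
    return int(np.argmax(corrs)), corrs
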