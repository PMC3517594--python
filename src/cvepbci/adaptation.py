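"""Online adaptation of the c-VEP classifier.

Four regimes over a retrainable classifier state:

* **supervised** — co-adaptive calibration: every trial is re-shifted to
  the target-0 frame using its true label, appended to the training
  buffer, and the whole pipeline (best channel, CCA filter, OCSVM
  template) is retrained.
* **unsupervised** — self-training: the predicted label is assumed
  correct and used exactly like a true label.
* **ErrP-gated** — self-training with an error veto: trials on which an
  error-related potential is detected are discarded (their true label is
  unknown).
* **2-target ErrP calibration** — classification restricted to a target
  pair; a detected ErrP flips the predicted label to the other pair
  member before the trial is added, allowing calibration without any
  supervised labels.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .codes import TargetLayout, bits_to_samples
from .spatial import SpatialFilter, build_cca_inputs, compute_cca_filter, select_best_channel
from .synthetic import TrialEEG
from .templates import TemplateSet, classify, fit_template

__all__ = [
    "ClassifierState",
    "AdaptationEvent",
    "init_random_templates",
    "classify_trial",
    "supervised_adapt",
    "unsupervised_adapt",
    "errp_gated_adapt",
    "errp_calibrate_2target",
    "run_adaptation_loop",
]


@dataclass
class AdaptationEvent:
    """Per-trial record of what the adaptation rule did."""

    trial_index: int
    predicted_label: int
    true_label: int | None = None
    errp_detected: bool | None = None
    action: str = "added_as_predicted"  # or added_as_flipped / rejected / supervised_add
    buffer_label: int | None = None
    generation: int = 0
    retrain_latency_trials: int = 0


@dataclass
class ClassifierState:
    """Retrainable decoding pipeline state.

    The training buffer holds raw multichannel trials already re-shifted
    to the target-0 frame together with the label they were added under
    (a multiset: duplicates count).  Retraining always rebuilds the
    spatial filter and template set from exactly the buffered trials.
    """

    layout: TargetLayout
    fs: float = 600.0
    refresh: float = 60.0
    nu: float = 0.5
    freeze_channel: bool = False
    frozen: bool = False
    spatial_filter: SpatialFilter | None = None
    template_set: TemplateSet | None = None
    generation: int = 0
    buffer: list[tuple[np.ndarray, int]] = field(default_factory=list)
    events: list[AdaptationEvent] = field(default_factory=list)

    @property
    def samples_per_bit(self) -> int:
        return bits_to_samples(1, self.fs, self.refresh)

    def target_shift_samples(self, k: int) -> int:
        return self.layout.shift_of_target(k) * self.samples_per_bit

    def align_to_base(self, data: np.ndarray, label: int) -> np.ndarray:
        """Undo target ``label``'s circular delay (move trial to frame 0)."""
        return np.roll(data, -self.target_shift_samples(label), axis=-1)

    def add_trial(self, trial: TrialEEG | np.ndarray, label: int) -> None:
        data = trial.data if isinstance(trial, TrialEEG) else np.asarray(trial, float)
        self.buffer.append((self.align_to_base(data, label), label))

    def retrain(self) -> None:
        """Rebuild best channel, CCA filter and template set from the buffer."""
        if self.frozen:
            return
        if not self.buffer:
            raise ValueError("cannot retrain on an empty buffer")
        trials = [d for d, _ in self.buffer]
        ns = trials[0].shape[-1]
        if len(trials) >= 2 and not (self.freeze_channel and self.spatial_filter is not None
                                     and self.spatial_filter.best_channel is not None):
            best, acc = select_best_channel(trials, self.layout, fs=self.fs,
                                            refresh=self.refresh)
        elif self.spatial_filter is not None and self.spatial_filter.best_channel is not None:
            best, acc = self.spatial_filter.best_channel, self.spatial_filter.best_channel_accuracy
        else:  # single trial, nothing selected yet: fall back to strongest channel
            best = int(np.argmax(np.var(trials[0], axis=-1)))
            acc = None
        X, Y = build_cca_inputs(trials, best)
        try:
            self.spatial_filter = compute_cca_filter(
                X, Y, best_channel=best, best_channel_accuracy=acc
            )
        except ValueError:  # constant reference (degenerate synthetic input)
            nc = X.shape[0]
            self.spatial_filter = SpatialFilter(np.full(nc, 1 / np.sqrt(nc)), best, acc)
        filtered = [self.spatial_filter.apply(d) for d in trials]
        self.template_set = fit_template(filtered, nu=self.nu,
                                         samples_per_bit=self.samples_per_bit,
                                         layout=self.layout)
        assert self.template_set.n_samples == ns
        self.generation += 1

    def clone(self) -> "ClassifierState":
        return copy.deepcopy(self)


def init_random_templates(
    layout: TargetLayout,
    n_samples: int,
    seed: int,
    fs: float = 600.0,
    refresh: float = 60.0,
    n_channels: int = 30,
    nu: float = 0.5,
) -> ClassifierState:
    """Classifier state before any data: random templates, uniform filter.

    The base template is drawn from a standard normal; the spatial filter
    is uniform unit-norm (no channel is preferred before data exist).
    """
    rng = np.random.default_rng(seed)
    state = ClassifierState(layout=layout, fs=fs, refresh=refresh, nu=nu)
    state.spatial_filter = SpatialFilter(np.full(n_channels, 1 / np.sqrt(n_channels)))
    state.template_set = TemplateSet(rng.standard_normal(n_samples),
                                     state.samples_per_bit, layout, nu)
    return state


def calibrate_batch(
    trials,
    labels,
    layout: TargetLayout | None = None,
    fs: float = 600.0,
    nu: float = 0.5,
) -> ClassifierState:
    """Fit the full pipeline once from a labelled batch of trials.

    Offline counterpart of the co-adaptive calibration: every trial is
    aligned to the target-0 frame and a single retrain builds the filter
    and templates.
    """
    state = ClassifierState(layout=layout or TargetLayout(), fs=fs, nu=nu)
    for trial, label in zip(trials, labels):
        state.add_trial(trial, label)
    state.retrain()
    return state


def classify_trial(
    state: ClassifierState,
    trial: TrialEEG | np.ndarray,
    candidates: list[int] | None = None,
) -> tuple[int, np.ndarray]:
    """Spatially filter a raw trial and classify by nearest template."""
    if state.spatial_filter is None or state.template_set is None:
        raise RuntimeError("classifier state has no filter/templates yet")
    data = trial.data if isinstance(trial, TrialEEG) else np.asarray(trial, float)
    return classify(state.spatial_filter.apply(data), state.template_set, candidates)


def _log(state: ClassifierState, event: AdaptationEvent) -> None:
    event.generation = state.generation
    state.events.append(event)


def supervised_adapt(
    state: ClassifierState, trial: TrialEEG, true_label: int, retrain: bool = True
) -> ClassifierState:
    """Add a trial under its true label and retrain (calibration step)."""
    state.layout.shift_of_target(true_label)  # validates
    pred, _ = classify_trial(state, trial)
    state.add_trial(trial, true_label)
    if retrain:
        state.retrain()
    _log(state, AdaptationEvent(trial_index=len(state.events), predicted_label=pred,
                                true_label=true_label, action="supervised_add",
                                buffer_label=true_label))
    return state


def unsupervised_adapt(state: ClassifierState, trial: TrialEEG,
                       retrain: bool = True) -> ClassifierState:
    """Self-training step: adapt with the predicted label."""
    pred, _ = classify_trial(state, trial)
    state.add_trial(trial, pred)
    if retrain:
        state.retrain()
    _log(state, AdaptationEvent(trial_index=len(state.events), predicted_label=pred,
                                true_label=trial.attended_target,
                                action="added_as_predicted", buffer_label=pred))
    return state


def errp_gated_adapt(state: ClassifierState, trial: TrialEEG, errp_detected: bool,
                     retrain: bool = True) -> ClassifierState:
    """Self-training with an error veto.

    When an ErrP is detected the trial is discarded (the true label is
    unknown and the predicted one is suspect); otherwise this is a plain
    unsupervised step.
    """
    if not errp_detected:
        state = unsupervised_adapt(state, trial, retrain=retrain)
        state.events[-1].errp_detected = False
        return state
    pred, _ = classify_trial(state, trial)
    _log(state, AdaptationEvent(trial_index=len(state.events), predicted_label=pred,
                                true_label=trial.attended_target, errp_detected=True,
                                action="rejected"))
    return state


def errp_calibrate_2target(
    state: ClassifierState,
    trial: TrialEEG,
    errp_detected: bool,
    pair: tuple[int, int],
    retrain: bool = True,
) -> ClassifierState:
    """Label-flipping calibration step on a two-target problem.

    Classification is restricted to the pair; a detected ErrP converts the
    predicted label into the other pair member before the trial is added.
    """
    a, b = pair
    if a == b:
        raise ValueError("pair members must differ")
    state.layout.shift_of_target(a)
    state.layout.shift_of_target(b)
    pred, _ = classify_trial(state, trial, candidates=[a, b])
    label = ({a, b} - {pred}).pop() if errp_detected else pred
    state.add_trial(trial, label)
    if retrain:
        state.retrain()
    _log(state, AdaptationEvent(
        trial_index=len(state.events), predicted_label=pred,
        true_label=trial.attended_target, errp_detected=errp_detected,
        action="added_as_flipped" if errp_detected else "added_as_predicted",
        buffer_label=label,
    ))
    return state


def run_adaptation_loop(
    state: ClassifierState,
    trials: list[TrialEEG],
    regime: str = "unsupervised",
    true_labels: list[int] | None = None,
    errp_flags: list[bool] | None = None,
    pair: tuple[int, int] | None = None,
    retrain_latency_trials: int = 0,
) -> list[AdaptationEvent]:
    """Feed a trial sequence through one adaptation regime.

    ``retrain_latency_trials = 0`` is the synchronous contract (retrain
    completes after every accepted trial).  A positive latency models the
    online system's parallel adaptation loop: trials arriving while a
    retrain is in flight are buffered and folded in at the next retrain,
    so classification always uses the latest *completed* generation.  The
    final training buffer is identical in both modes (order preserved).
    """
    if regime not in {"none", "unsupervised", "errp_gated", "errp_calibration", "supervised"}:
        raise ValueError(f"unknown regime {regime!r}")
    start = len(state.events)
    pending = 0
    for i, trial in enumerate(trials):
        if regime == "none":
            pred, _ = classify_trial(state, trial)
            _log(state, AdaptationEvent(trial_index=len(state.events), predicted_label=pred,
                                        true_label=trial.attended_target, action="rejected"))
            continue
        do_retrain = retrain_latency_trials == 0
        if regime == "supervised":
            state = supervised_adapt(state, trial, true_labels[i], retrain=do_retrain)
        elif regime == "unsupervised":
            state = unsupervised_adapt(state, trial, retrain=do_retrain)
        elif regime == "errp_gated":
            state = errp_gated_adapt(state, trial, errp_flags[i], retrain=do_retrain)
        else:
            state = errp_calibrate_2target(state, trial, errp_flags[i], pair,
                                           retrain=do_retrain)
        if state.events[-1].action != "rejected":
            pending += 1
        state.events[-1].retrain_latency_trials = retrain_latency_trials
        if retrain_latency_trials > 0 and pending and (i + 1) % retrain_latency_trials == 0:
            state.retrain()
            pending = 0
    if retrain_latency_trials > 0 and pending:
        state.retrain()
    return state.events[start:]
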