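"""Closed-loop simulation of the online speller experiments.

Reproduces the study designs end-to-end on synthetic EEG: supervised
co-adaptive calibration (64 trials, every letter twice), copy-spelling
test runs under a chosen adaptation regime, 2-target ErrP-based
calibration (alternating J/W intents), and free-spelling with a user
model that corrects every perceived mistake via the backspace target.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .adaptation import (
    ClassifierState,
    classify_trial,
    errp_calibrate_2target,
    errp_gated_adapt,
    init_random_templates,
    supervised_adapt,
    unsupervised_adapt,
)
from .codes import TargetLayout, TrialTiming, bits_to_samples, generate_msequence
from .errp import OracleDetector, train_errp_detector
from .evaluation import FreeSpellingSummary, SessionLog, TrialRecord
from .synthetic import (
    DEFAULT_CHANNELS,
    DriftSchedule,
    ForwardModel,
    SessionStream,
    simulate_errp_epoch,
)

__all__ = [
    "ExperimentConfig",
    "UserModel",
    "run_experiment",
    "run_session",
    "run_free_spelling",
    "adaptation_comparison_study",
]

DESIGNS = ("calibration_64", "copy_spelling_9x64", "errp_calibration", "free_spelling")


@dataclass
class ExperimentConfig:
    """Everything needed to replay a session bit-for-bit."""

    design: str = "copy_spelling_9x64"
    seed: int = 0
    regime: str = "unsupervised"  # none | unsupervised | errp_gated | supervised
    n_calibration_trials: int = 64
    n_test_trials: int = 576
    # forward model
    fs: float = 600.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    noise_sd: float = 3.0
    latency: float = 0.036
    latency_drift_per_trial: float = 0.0
    gain_drift_per_trial: float = 0.0
    # classifier
    nu: float = 0.5
    # ErrP detector: oracle | trained | none
    detector_mode: str = "oracle"
    detector_sensitivity: float = 1.0
    detector_specificity: float = 1.0
    n_detector_train_epochs: int = 200
    detector_train_error_rate: float = 0.3
    errp_amplitude_scale: float = 1.0
    # user / timing
    perception_reliability: float = 1.0
    calibration_pair: tuple[int, int] = (9, 22)  # letters J and W
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")

    def forward_model(self) -> ForwardModel:
        return ForwardModel(
            fs=self.fs,
            channel_names=tuple(self.channels),
            noise_sd=self.noise_sd,
            latency=self.latency,
            drift=DriftSchedule(self.latency_drift_per_trial, self.gain_drift_per_trial),
        )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        d["calibration_pair"] = list(self.calibration_pair)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        d["channels"] = tuple(d["channels"])
        d["calibration_pair"] = tuple(d["calibration_pair"])
        d["timing"] = TrialTiming(**d["timing"])
        return cls(**d)


@dataclass
class UserModel:
    """Intent policy of the simulated user.

    The user spells ``text``; whenever the transcript stops being a prefix
    of it (and the error is perceived, probability
    ``perception_reliability``), the next intent is the backspace target.
    """

    text: str = "HELLO_WORLD"
    perception_reliability: float = 1.0


def _make_detector(config: ExperimentConfig, seed_stream: int):
    if config.detector_mode == "none":
        return None
    if config.detector_mode == "oracle":
        return OracleDetector(config.detector_sensitivity, config.detector_specificity,
                              seed=seed_stream)
    if config.detector_mode == "trained":
        rng = np.random.default_rng([seed_stream, 7])
        n = config.n_detector_train_epochs
        labels = rng.random(n) < config.detector_train_error_rate
        epochs = [
            simulate_errp_epoch(bool(l), config.errp_amplitude_scale, rng,
                                fs=config.fs, channel_names=tuple(config.channels))
            for l in labels
        ]
        return train_errp_detector(epochs, labels.tolist(), seed=seed_stream)
    raise ValueError(f"unknown detector mode {config.detector_mode!r}")


def _detect(detector, epoch) -> bool:
    if detector is None:
        return False
    if isinstance(detector, OracleDetector):
        return detector.detect(bool(epoch.is_error))
    return bool(detector.predict(epoch)[0])


def _calibration_intents(layout: TargetLayout, n: int, rng: np.random.Generator) -> list[int]:
    """Every target the same number of times, in seeded shuffled order."""
    reps = int(np.ceil(n / layout.n_targets))
    pool = np.tile(np.arange(layout.n_targets), reps)
    rng.shuffle(pool)
    return pool[:n].tolist()


def run_session(config: ExperimentConfig) -> tuple[SessionLog, ClassifierState]:
    """Run a session and return both the log and the final classifier state."""
    layout = TargetLayout()
    code = generate_msequence(refresh_rate=60.0)
    model = config.forward_model()
    ns = bits_to_samples(len(code), config.fs, code.refresh_rate)
    rng = np.random.default_rng([config.seed, 11])
    detector = _make_detector(config, config.seed)

    state = init_random_templates(layout, ns, seed=config.seed, fs=config.fs,
                                  n_channels=len(config.channels), nu=config.nu)
    log = SessionLog(mode="copy_spelling", trial_duration=config.timing.trial_s,
                     n_targets=layout.n_targets, config={"design": config.design,
                                                         "seed": config.seed,
                                                         "regime": config.regime})

    if config.design == "errp_calibration":
        a, b = config.calibration_pair
        intents = [a if i % 2 == 0 else b for i in range(config.n_test_trials)]
        stream = SessionStream(model, layout, code, intents, config.seed,
                               config.errp_amplitude_scale, config.perception_reliability)
        log.mode = "errp_calibration"
        log.n_targets = 2
        for i, intent in enumerate(intents):
            trial = stream.next_trial()
            pred, _ = classify_trial(state, trial, candidates=[a, b])
            epoch = stream.feedback(pred == intent)
            flag = _detect(detector, epoch)
            state = errp_calibrate_2target(state, trial, flag, (a, b))
            ev = state.events[-1]
            log.append(TrialRecord(
                predicted_label=pred, true_label=intent, errp_detected=flag,
                errp_true=epoch.is_error, action=ev.action, generation=ev.generation,
                phase="test", t_start=i * config.timing.trial_s,
                t_end=(i + 1) * config.timing.trial_s,
            ))
        return log, state

    # supervised co-adaptive calibration block
    cal_intents = _calibration_intents(layout, config.n_calibration_trials, rng)
    n_test = 0 if config.design == "calibration_64" else config.n_test_trials
    test_intents = rng.integers(0, layout.n_targets, size=n_test).tolist()
    stream = SessionStream(model, layout, code, cal_intents + test_intents, config.seed,
                           config.errp_amplitude_scale, config.perception_reliability)
    for i, intent in enumerate(cal_intents):
        trial = stream.next_trial()
        pred, _ = classify_trial(state, trial)
        stream.feedback(pred == intent)
        state = supervised_adapt(state, trial, intent)
        ev = state.events[-1]
        log.append(TrialRecord(
            predicted_label=pred, true_label=intent, action=ev.action,
            generation=ev.generation, phase="calibration",
            t_start=i * config.timing.trial_s, t_end=(i + 1) * config.timing.trial_s,
        ))

    offset = len(cal_intents)
    for i, intent in enumerate(test_intents):
        trial = stream.next_trial()
        pred, _ = classify_trial(state, trial)
        epoch = stream.feedback(pred == intent)
        flag = _detect(detector, epoch) if config.regime == "errp_gated" else None
        if config.regime == "supervised":
            state = supervised_adapt(state, trial, intent)
        elif config.regime == "unsupervised":
            state = unsupervised_adapt(state, trial)
        elif config.regime == "errp_gated":
            state = errp_gated_adapt(state, trial, flag)
        elif config.regime != "none":
            raise ValueError(f"unknown regime {config.regime!r}")
        action = state.events[-1].action if config.regime != "none" else "rejected"
        gen = state.generation
        log.append(TrialRecord(
            predicted_label=pred, true_label=intent, errp_detected=flag,
            errp_true=epoch.is_error, action=action, generation=gen, phase="test",
            t_start=(offset + i) * config.timing.trial_s,
            t_end=(offset + i + 1) * config.timing.trial_s,
        ))
    return log, state


def run_experiment(config: ExperimentConfig) -> SessionLog:
    """Run a configured experiment design; see :func:`run_session`."""
    if config.design == "free_spelling":
        _, log = run_free_spelling(config, UserModel(), UserModel().text)
        return log
    return run_session(config)[0]


def run_free_spelling(
    config: ExperimentConfig,
    user: UserModel,
    text: str | None = None,
    state: ClassifierState | None = None,
    max_trials: int | None = None,
) -> tuple[FreeSpellingSummary, SessionLog]:
    """Simulate free-spelling with backspace correction.

    The classifier is calibrated first (supervised co-adaptive block)
    unless a trained ``state`` is passed in.  Returns the accounting
    summary (error-free letters per minute etc.) and the trial log.
    """
    text = text if text is not None else user.text
    layout = TargetLayout().with_backspace()
    for c in text:
        layout.target_of_char(c)  # validates spellability
    code = generate_msequence(refresh_rate=60.0)
    model = config.forward_model()
    ns = bits_to_samples(len(code), config.fs, code.refresh_rate)

    if state is None:
        cal_cfg = dataclasses.replace(config, design="calibration_64")
        _, state = run_session(cal_cfg)
    state.layout = layout  # same shifts; last target now spells backspace

    max_trials = max_trials or 4 * len(text) + 8
    stream = SessionStream(model, layout, code, None, config.seed + 1,
                           config.errp_amplitude_scale, user.perception_reliability)
    rng = np.random.default_rng([config.seed, 13])
    log = SessionLog(mode="free_spelling", trial_duration=config.timing.trial_s,
                     n_targets=layout.n_targets)
    transcript: list[str] = []
    bs = layout.backspace_target
    n = 0
    while "".join(transcript) != text and n < max_trials:
        prefix_ok = text.startswith("".join(transcript))
        if not prefix_ok and rng.random() < user.perception_reliability:
            intent = bs
        elif prefix_ok:
            intent = layout.target_of_char(text[len(transcript)])
        else:  # unnoticed error: user carries on with the next wanted letter
            intent = layout.target_of_char(text[min(len(transcript), len(text) - 1)])
        trial = stream.next_trial(intent)
        pred, _ = classify_trial(state, trial)
        stream.feedback(pred == intent)
        if config.regime == "unsupervised":
            state = unsupervised_adapt(state, trial)
        elif config.regime == "supervised":
            state = supervised_adapt(state, trial, intent)
        if pred == bs:
            deleted_char = transcript.pop() if transcript else None
            was_error = intent != bs  # an unwanted deletion is itself an error
            written_char = None
        else:
            transcript.append(layout.char_of_target(pred))
            was_error = pred != intent or intent == bs
            written_char = layout.char_of_target(pred)
        log.append(TrialRecord(
            predicted_label=pred, true_label=intent, phase="test",
            t_start=n * config.timing.trial_s, t_end=(n + 1) * config.timing.trial_s,
            intent_char=layout.char_of_target(intent), written_char=written_char,
            was_error=bool(was_error), was_backspace=pred == bs,
        ))
        n += 1
    log.transcript = "".join(transcript)
    return evaluation.free_spelling_summary(log), log


def adaptation_comparison_study(
    base_config: ExperimentConfig,
    regimes: tuple[str, ...] = ("none", "unsupervised", "errp_gated", "supervised"),
    n_seeds: int = 20,
) -> pd.DataFrame:
    """Replay identical synthetic sessions under different adaptation regimes.

    For every seed the trial stream is bitwise identical across regimes
    (trial noise draws do not depend on classification outcomes), so the
    comparison isolates the adaptation rule.  Returns one row per
    (seed, regime) with the test-phase accuracy.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rows = []
    for s in range(n_seeds):
        for regime in regimes:
            cfg = dataclasses.replace(base_config, seed=base_config.seed + s, regime=regime)
            log, _ = run_session(cfg)
            rows.append({"seed": cfg.seed, "regime": regime,
                         "accuracy": evaluation.accuracy(log)})
    return pd.DataFrame(rows)
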