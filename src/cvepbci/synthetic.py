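"""Synthetic multichannel EEG with code-locked c-VEP responses and ErrPs.

The generator emulates the signal structure the decoding pipeline relies
on: a single latent source waveform spanning one code period, delayed by a
cortical latency (~36 ms), mixed into a 30-channel montage with a
parieto-occipital focus (strongest at P4), and repeated for target ``k``
as the target-0 response circularly delayed by ``bit_lag * k`` bits.
Feedback-locked epochs carry the two fronto-central ErrP deflections
(negative ~310 ms, positive ~420 ms) on error trials only.  Additive noise
is white Gaussian by default with an optional 1/f component; slow
nonstationarity (latency / amplitude drift) is available per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .codes import BinaryCode, TargetLayout, bits_to_samples

__all__ = [
    "DEFAULT_CHANNELS",
    "ERRP_CHANNELS",
    "TrialEEG",
    "FeedbackEpoch",
    "ForwardModel",
    "DriftSchedule",
    "damped_sinusoid_kernel",
    "code_convolved_kernel",
    "default_mixing",
    "fractional_roll",
    "simulate_trial",
    "simulate_errp_epoch",
    "SessionStream",
    "save_trials_npz",
    "load_trials_npz",
]

#: 30-channel 10-20 montage (reference at Oz and ground at FCz are not recorded).
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4", "O1",
)

#: Channels carrying the feedback-locked ErrP features.
ERRP_CHANNELS = ("Fz", "Cz", "CPz", "Pz", "POz")

# Relative source projection strengths; everything else gets a small leak.
_MIXING_TABLE = {
    "P4": 1.0, "PO3": 0.92, "POz": 0.85, "PO4": 0.80, "O1": 0.75,
    "Pz": 0.70, "P3": 0.60, "P8": 0.55, "P7": 0.40,
    "CPz": 0.35, "CP1": 0.30, "CP2": 0.30, "CP5": 0.20, "CP6": 0.20,
}
_MIXING_LEAK = 0.08

# Fronto-central scalp profile of the ErrP (most prominent between Fz and Cz).
_ERRP_TOPO = {"Fz": 1.0, "Cz": 0.95, "FC1": 0.8, "FC2": 0.8, "F3": 0.6,
              "F4": 0.6, "CPz": 0.55, "C3": 0.5, "C4": 0.5, "Pz": 0.3, "POz": 0.15}


@dataclass
class TrialEEG:
    """One stimulation trial: channels x samples at the amplifier rate."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float = 600.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    attended_target: int | None = None
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class FeedbackEpoch:
    """Feedback-locked epoch covering at least 0-1000 ms after selection."""

    data: np.ndarray  # (n_channels, n_samples), microvolts, t=0 at feedback onset
    fs: float = 600.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    is_error: bool | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class DriftSchedule:
    """Slow per-trial nonstationarity of the evoked response.

    ``latency_per_trial`` shifts the response later by that many seconds
    each trial; ``gain_per_trial`` scales its amplitude multiplicatively
    per trial (e.g. -0.001 = 0.1 % loss per trial).
    """

    latency_per_trial: float = 0.0
    gain_per_trial: float = 0.0

    def latency_offset(self, trial_index: int) -> float:
        return self.latency_per_trial * trial_index

    def gain(self, trial_index: int) -> float:
        return (1.0 + self.gain_per_trial) ** trial_index


def damped_sinusoid_kernel(
    n_samples: int,
    fs: float,
    freqs: tuple[float, ...] = (7.5, 13.0, 21.0),
    amps: tuple[float, ...] = (5.0, 3.5, 2.0),
    decay_s: float = 0.35,
) -> np.ndarray:
    """Default latent c-VEP source waveform: a sum of damped sinusoids.

    Spans one code period; amplitudes in microvolts.  The real single-trial
    evoked waveform is not recoverable from scalp averages, so the kernel
    is configurable; this default gives a smooth oscillatory response whose
    autocorrelation decays over a couple of code bits.
    """
    t = np.arange(n_samples) / fs
    k = np.zeros(n_samples)
    for f, a in zip(freqs, amps):
        k += a * np.sin(2 * np.pi * f * t) * np.exp(-t / decay_s)
    return k


def code_convolved_kernel(
    code: BinaryCode,
    fs: float,
    amp: float = 4.0,
    response_freq: float = 12.0,
    response_decay_s: float = 0.04,
) -> np.ndarray:
    """Alternative kernel: the code's +/-1 impulse train convolved (circularly)
    with a short damped-oscillation impulse response.

    Produces a broadband, code-locked waveform whose circular
    autocorrelation inherits the m-sequence's near-delta shape, i.e.
    near-orthogonal target responses.
    """
    spb = bits_to_samples(1, fs, code.refresh_rate)
    n = len(code) * spb
    train = np.zeros(n)
    train[::spb] = code.signed()
    t = np.arange(n) / fs
    ir = amp * np.sin(2 * np.pi * response_freq * t) * np.exp(-t / response_decay_s)
    return np.real(np.fft.ifft(np.fft.fft(train) * np.fft.fft(ir)))


def default_mixing(channel_names: tuple[str, ...] = DEFAULT_CHANNELS) -> np.ndarray:
    """Unit-norm channel projection of the c-VEP source (maximal at P4)."""
    w = np.array([_MIXING_TABLE.get(c, _MIXING_LEAK) for c in channel_names])
    return w / np.linalg.norm(w)


def fractional_roll(x: np.ndarray, shift_samples: float) -> np.ndarray:
    """Circular delay of a 1-D signal by a possibly fractional sample count.

    Integer shifts are exact (``np.roll``); fractional shifts use the FFT
    phase ramp.
    """
    if abs(shift_samples - round(shift_samples)) < 1e-9:
        return np.roll(x, int(round(shift_samples)))
    n = x.size
    freqs = np.fft.fftfreq(n)
    return np.real(np.fft.ifft(np.fft.fft(x) * np.exp(-2j * np.pi * freqs * shift_samples)))


@dataclass
class ForwardModel:
    """Generative model of one c-VEP trial.

    The latent source emits ``kernel`` (one code period) delayed by
    ``latency``; target ``k``'s response is the target-0 response delayed
    by ``bit_lag * k`` bits.  The source projects to the scalp through the
    unit-norm ``mixing`` vector and is buried in additive noise.
    """

    fs: float = 600.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    kernel: np.ndarray | None = None  # defaults to damped_sinusoid_kernel
    mixing: np.ndarray | None = None  # defaults to default_mixing
    latency: float = 0.036
    noise_sd: float = 3.0
    pink_noise_fraction: float = 0.0  # 0 = pure white noise
    drift: DriftSchedule = field(default_factory=DriftSchedule)
    code: BinaryCode | None = None  # only needed for code-convolved kernels

    def resolve(self, code: BinaryCode) -> "ForwardModel":
        """Fill in derived defaults for a given modulation code."""
        n = bits_to_samples(len(code), self.fs, code.refresh_rate)
        kernel = self.kernel if self.kernel is not None else damped_sinusoid_kernel(n, self.fs)
        if kernel.size != n:
            raise ValueError(f"kernel length {kernel.size} != samples per trial {n}")
        mixing = self.mixing if self.mixing is not None else default_mixing(self.channel_names)
        return replace(self, kernel=np.asarray(kernel, float), mixing=np.asarray(mixing, float), code=code)

    def clean_response(
        self, layout: TargetLayout, code: BinaryCode, target: int,
        latency_offset: float = 0.0, gain: float = 1.0,
    ) -> np.ndarray:
        """Noise-free source waveform for ``target`` (1-D, one trial)."""
        m = self.resolve(code)
        spb = bits_to_samples(1, self.fs, code.refresh_rate)
        shift = layout.shift_of_target(target) * spb
        base = fractional_roll(m.kernel, (self.latency + latency_offset) * self.fs)
        return gain * np.roll(base, shift)


def _noise(model: ForwardModel, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(0.0, 1.0, size=shape)
    if model.pink_noise_fraction <= 0:
        return model.noise_sd * white
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1 / model.fs)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(np.fft.rfft(rng.normal(size=shape), axis=1) * scale, n=n, axis=1)
    pink /= pink.std() + 1e-12
    f = model.pink_noise_fraction
    return model.noise_sd * ((1 - f) * white + f * pink)


def simulate_trial(
    model: ForwardModel,
    layout: TargetLayout,
    code: BinaryCode,
    target: int,
    seed: int | np.random.Generator,
    trial_index: int = 0,
) -> TrialEEG:
    """Simulate one stimulation trial while the user attends ``target``.

    Deterministic given the seed.  Drift (if configured on the model) is a
    function of ``trial_index``.
    """
    if model.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    m = model.resolve(code)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    response = m.clean_response(
        layout, code, target,
        latency_offset=m.drift.latency_offset(trial_index),
        gain=m.drift.gain(trial_index),
    )
    data = np.outer(m.mixing, response)
    if m.noise_sd > 0:
        data = data + _noise(m, data.shape, rng)
    return TrialEEG(data=data, fs=m.fs, channel_names=m.channel_names,
                    attended_target=target, trial_index=trial_index)


def _errp_difference_waveform(n: int, fs: float, amplitude_scale: float) -> np.ndarray:
    """The planted error-minus-correct source time course (1-D)."""
    t = np.arange(n) / fs
    neg = -3.0 * np.exp(-0.5 * ((t - 0.310) / 0.022) ** 2)
    pos = 5.0 * np.exp(-0.5 * ((t - 0.420) / 0.035) ** 2)
    return amplitude_scale * (neg + pos)


def simulate_errp_epoch(
    is_error: bool,
    amplitude_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    fs: float = 600.0,
    duration: float = 1.0,
    noise_sd: float = 6.0,
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
) -> FeedbackEpoch:
    """Simulate a feedback-locked epoch.

    Error epochs contain a small negative deflection around 310 ms and a
    positive deflection around 420 ms, fronto-centrally distributed
    (largest between Fz and Cz); correct epochs contain noise only.
    """
    if amplitude_scale < 0:
        raise ValueError("amplitude_scale must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = rng.normal(0.0, noise_sd, size=(len(channel_names), n))
    if is_error:
        topo = np.array([_ERRP_TOPO.get(c, 0.05) for c in channel_names])
        data += np.outer(topo, _errp_difference_waveform(n, fs, amplitude_scale))
    return FeedbackEpoch(data=data, fs=fs, channel_names=channel_names, is_error=bool(is_error))


class SessionStream:
    """Reproducible trial/feedback-epoch source for the closed-loop harness.

    The stream hands out one :class:`TrialEEG` per intended target; after
    the harness classifies the trial and shows feedback, it reports the
    outcome back through :meth:`feedback`, which returns the corresponding
    feedback-locked epoch (an ErrP is planted when the selection was
    perceived as an error).  ``perception_reliability`` is the probability
    that the user notices a misclassification.
    """

    def __init__(
        self,
        model: ForwardModel,
        layout: TargetLayout,
        code: BinaryCode,
        intent_sequence: list[int] | None,
        seed: int,
        errp_amplitude_scale: float = 1.0,
        perception_reliability: float = 1.0,
    ) -> None:
        for k in intent_sequence or []:
            layout.shift_of_target(k)  # validates
        self.model = model.resolve(code)
        self.layout = layout
        self.code = code
        self.intents = list(intent_sequence) if intent_sequence is not None else None
        self.errp_amplitude_scale = errp_amplitude_scale
        self.perception_reliability = perception_reliability
        self._trial_rng = np.random.default_rng([seed, 1])
        self._epoch_rng = np.random.default_rng([seed, 2])
        self._perception_rng = np.random.default_rng([seed, 3])
        self._i = 0
        self._awaiting_feedback = False

    def next_trial(self, intent: int | None = None) -> TrialEEG:
        if self._awaiting_feedback:
            raise RuntimeError("feedback() must be called before the next trial")
        if intent is None:
            if self.intents is None or self._i >= len(self.intents):
                raise StopIteration
            intent = self.intents[self._i]
        trial = simulate_trial(self.model, self.layout, self.code, intent,
                               self._trial_rng, trial_index=self._i)
        self._i += 1
        self._awaiting_feedback = True
        return trial

    def feedback(self, was_correct: bool) -> FeedbackEpoch:
        """Report the classification outcome; returns the feedback epoch."""
        self._awaiting_feedback = False
        perceived_error = (not was_correct) and (
            self._perception_rng.random() < self.perception_reliability
        )
        return simulate_errp_epoch(
            perceived_error, self.errp_amplitude_scale, self._epoch_rng,
            fs=self.model.fs, channel_names=self.model.channel_names,
        )

    def __iter__(self) -> Iterator[TrialEEG]:
        while True:
            try:
                yield self.next_trial()
            except StopIteration:
                return
            self._awaiting_feedback = False  # plain iteration skips feedback


def save_trials_npz(path, trials: list[TrialEEG]) -> None:
    """Write trials to an NPZ container with JSON-style metadata."""
    data = np.stack([t.data for t in trials])
    labels = np.array([-1 if t.attended_target is None else t.attended_target for t in trials])
    np.savez_compressed(
        path, data=data, labels=labels, fs=trials[0].fs,
        channel_names=np.array(trials[0].channel_names),
    )


def load_trials_npz(path) -> list[TrialEEG]:
    with np.load(path, allow_pickle=False) as f:
        names = tuple(str(c) for c in f["channel_names"])
        return [
            TrialEEG(data=f["data"][i], fs=float(f["fs"]), channel_names=names,
                     attended_target=None if f["labels"][i] < 0 else int(f["labels"][i]),
                     trial_index=i)
            for i in range(f["data"].shape[0])
        ]
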