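"""Binary m-sequence modulation codes and the circular-shift target scheme.

All targets of the speller flash the same 63-bit maximal-length sequence
(m-sequence), each at its own circular shift; consecutive targets are two
bits apart.  The two-valued cyclic autocorrelation of m-sequences (perfect
peak at lag 0, exactly -1 elsewhere in the +/-1 mapping) is what makes the
shifts separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryCode",
    "TargetLayout",
    "TrialTiming",
    "InvalidTapsError",
    "generate_msequence",
    "shift_code",
    "bits_to_samples",
    "DEFAULT_TAPS",
    "DEFAULT_CHARSET",
]

#: Feedback taps of a primitive degree-6 polynomial (x^6 + x^5 + 1).
DEFAULT_TAPS = (6, 5)

#: Characters mapped onto the 32 targets: A-Z, underscore, digits 1-5.
DEFAULT_CHARSET = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ_12345")

#: Backspace character used when the last target is repurposed for deletion.
BACKSPACE_CHAR = "Ö"  # Ö


class InvalidTapsError(ValueError):
    """Raised when LFSR taps do not define a primitive polynomial."""


@dataclass(frozen=True)
class BinaryCode:
    """A binary modulation sequence presented at the monitor refresh rate."""

    bits: np.ndarray
    refresh_rate: float = 60.0

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be a 1-D array of 0/1 values")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.bits.size

    @property
    def bit_duration(self) -> float:
        """Seconds each bit is displayed (one refresh period)."""
        return 1.0 / self.refresh_rate

    @property
    def duration(self) -> float:
        """Length of one full stimulation sequence in seconds."""
        return len(self) * self.bit_duration

    def signed(self) -> np.ndarray:
        """Return the +/-1 mapping (1 -> +1, 0 -> -1)."""
        return self.bits.astype(np.int64) * 2 - 1

    def cyclic_autocorrelation(self) -> np.ndarray:
        """Cyclic autocorrelation of the +/-1 mapping at every lag."""
        s = self.signed()
        n = s.size
        return np.array([int(np.dot(s, np.roll(s, lag))) for lag in range(n)])

    def is_msequence(self) -> bool:
        """Check balance and the two-valued autocorrelation property.

        A length-(2^m - 1) m-sequence has (2^(m-1)) ones and, in the +/-1
        mapping, cyclic autocorrelation exactly -1 at every nonzero lag.
        The alternating 30 Hz flicker ``0101...`` fails this test.
        """
        n = len(self)
        m = int(np.log2(n + 1))
        if 2**m - 1 != n:
            return False
        if int(self.bits.sum()) != 2 ** (m - 1):
            return False
        ac = self.cyclic_autocorrelation()
        return ac[0] == n and np.all(ac[1:] == -1)

    def to_json(self) -> str:
        return json.dumps(
            {"bits": "".join(map(str, self.bits.tolist())), "refresh_rate": self.refresh_rate}
        )

    @classmethod
    def from_json(cls, text: str) -> "BinaryCode":
        obj = json.loads(text)
        bits = np.frombuffer(obj["bits"].encode(), dtype=np.uint8) - ord("0")
        return cls(bits=bits, refresh_rate=obj["refresh_rate"])


@dataclass(frozen=True)
class TargetLayout:
    """Circular-shift multiplexing scheme and character map for 32 targets.

    Target ``k`` flashes the base code delayed by ``bit_lag * k`` bits
    (modulo the code length); the delay convention is used consistently by
    the simulator and the template generator.
    """

    n_targets: int = 32
    bit_lag: int = 2
    char_map: tuple[str, ...] = field(default=DEFAULT_CHARSET)

    def __post_init__(self) -> None:
        if len(self.char_map) != self.n_targets:
            raise ValueError("char_map must have one character per target")

    def shift_of_target(self, k: int) -> int:
        """Circular shift in bits applied to the base code for target ``k``."""
        if not 0 <= k < self.n_targets:
            raise ValueError(f"target index {k} out of range [0, {self.n_targets})")
        return self.bit_lag * k

    def char_of_target(self, k: int) -> str:
        return self.char_map[k]

    def target_of_char(self, c: str) -> int:
        try:
            return self.char_map.index(c)
        except ValueError:
            raise ValueError(f"character {c!r} not in layout") from None

    def with_backspace(self) -> "TargetLayout":
        """Free-spelling variant: last target's character becomes backspace."""
        chars = list(self.char_map)
        chars[-1] = BACKSPACE_CHAR
        return TargetLayout(self.n_targets, self.bit_lag, tuple(chars))

    @property
    def backspace_target(self) -> int:
        return self.n_targets - 1

    def all_shifts_distinct(self, code_length: int) -> bool:
        shifts = {self.shift_of_target(k) % code_length for k in range(self.n_targets)}
        return len(shifts) == self.n_targets

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_targets": self.n_targets,
                "bit_lag": self.bit_lag,
                "char_map": list(self.char_map),
                "shift_table": {str(k): self.shift_of_target(k) for k in range(self.n_targets)},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TargetLayout":
        obj = json.loads(text)
        return cls(obj["n_targets"], obj["bit_lag"], tuple(obj["char_map"]))


@dataclass(frozen=True)
class TrialTiming:
    """Trial timeline constants of the online speller.

    One stimulation sequence lasts 63/60 s = 1.05 s, followed by a break of
    about 0.85 s during which the selection is highlighted for 150 ms.
    """

    stimulation_s: float = 63 / 60
    pause_s: float = 0.85
    feedback_highlight_s: float = 0.150

    @property
    def trial_s(self) -> float:
        """Nominal seconds per selection (stimulation + pause)."""
        return self.stimulation_s + self.pause_s


def generate_msequence(
    degree: int = 6,
    taps: tuple[int, ...] = DEFAULT_TAPS,
    init_state: int = 1,
    refresh_rate: float = 60.0,
) -> BinaryCode:
    """Generate a maximal-length sequence from a Fibonacci LFSR.

    Parameters
    ----------
    degree
        Register length ``m``; the sequence has period ``2**m - 1``.
    taps
        Feedback tap positions (1-based, ``degree`` included) of a primitive
        polynomial.  Non-primitive taps produce a shorter period and are
        rejected.
    init_state
        Nonzero initial register content (low bit = stage 1).

    Returns
    -------
    BinaryCode
        Sequence of ``2**degree - 1`` bits satisfying the m-sequence
        invariants (balance, two-valued cyclic autocorrelation).
    """
    if degree < 2:
        raise ValueError("degree must be >= 2")
    if init_state == 0:
        raise ValueError("init_state must be nonzero")
    period = 2**degree - 1
    if init_state >= 2**degree:
        raise ValueError("init_state exceeds register width")
    if not taps or any(t < 1 or t > degree for t in taps) or degree not in taps:
        raise InvalidTapsError(f"taps {taps} invalid for degree {degree}")

    # Fibonacci LFSR, right-shifted: polynomial tap x^t reads register
    # stage degree + 1 - t in this orientation.
    stages = [degree + 1 - t for t in taps]
    state = init_state
    bits = np.empty(period, dtype=np.uint8)
    seen_states = set()
    for i in range(period):
        if state in seen_states:  # period < 2^m - 1
            raise InvalidTapsError(f"taps {taps} are not primitive for degree {degree}")
        seen_states.add(state)
        bits[i] = state & 1  # output of stage 1
        fb = 0
        for s in stages:
            fb ^= (state >> (s - 1)) & 1
        state = (state >> 1) | (fb << (degree - 1))
    if state != init_state:  # did not return to the start after 2^m - 1 steps
        raise InvalidTapsError(f"taps {taps} are not primitive for degree {degree}")
    return BinaryCode(bits=bits, refresh_rate=refresh_rate)


def shift_code(code: BinaryCode, k: int, layout: TargetLayout | None = None) -> BinaryCode:
    """Return the modulation code of target ``k``.

    The base code is delayed by ``bit_lag * k`` bits, circularly; a shift by
    any multiple of the code length is the identity.
    """
    layout = layout or TargetLayout()
    shift = layout.shift_of_target(k)  # validates k
    return BinaryCode(bits=np.roll(code.bits, shift), refresh_rate=code.refresh_rate)


def bits_to_samples(n_bits: int, fs: float, refresh: float) -> int:
    """Number of EEG samples spanned by ``n_bits`` stimulation bits.

    Requires the sampling rate to be an integer multiple of the refresh
    rate so that every bit covers an exact number of samples (10 at 600 Hz
    and 60 Hz refresh).
    """
    if n_bits < 0:
        raise ValueError("n_bits must be >= 0")
    per_bit = fs / refresh
    if abs(per_bit - round(per_bit)) > 1e-9:
        raise ValueError(f"sampling rate {fs} not divisible by refresh rate {refresh}")
    return int(n_bits * round(per_bit))
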