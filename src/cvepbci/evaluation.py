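"""BCI performance metrics: accuracy, Wolpaw ITR, letters per minute.

The Wolpaw information transfer rate per selection is

    B = log2(N) + P*log2(P) + (1 - P)*log2((1 - P)/(N - 1))   [bits]

with N classes and accuracy P (0*log0 taken as 0), scaled to bits/min by
the selection rate.  Following the convention of the adaptive-speller
literature, ITR is reported as 0 at or below chance accuracy (the formula
itself turns positive again below chance, which has no communication
meaning).  Free-spelling performance is counted application-centered:
error-free letters per minute, with every error costing two extra trials
(the wrong letter and its backspace).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "SessionLog",
    "FreeSpellingSummary",
    "accuracy",
    "wolpaw_bits_per_selection",
    "wolpaw_itr",
    "free_spelling_summary",
    "aggregate",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (table-reproduction convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TrialRecord:
    """One selection in a session log."""

    predicted_label: int
    true_label: int | None = None
    errp_detected: bool | None = None
    errp_true: bool | None = None
    action: str | None = None
    generation: int | None = None
    phase: str = "test"  # calibration | test
    t_start: float = 0.0
    t_end: float = 0.0
    intent_char: str | None = None
    written_char: str | None = None
    was_error: bool | None = None
    was_backspace: bool = False


@dataclass
class SessionLog:
    """Per-trial record of a session, from which all metrics derive."""

    trials: list[TrialRecord] = field(default_factory=list)
    mode: Literal["copy_spelling", "free_spelling", "errp_calibration"] = "copy_spelling"
    trial_duration: float = 1.9
    n_targets: int = 32
    transcript: str = ""
    config: dict = field(default_factory=dict)

    def append(self, rec: TrialRecord) -> None:
        if self.trials and rec.t_start < self.trials[-1].t_start:
            raise ValueError("timestamps must be strictly increasing")
        self.trials.append(rec)

    def test_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.phase == "test"]

    @property
    def total_time_s(self) -> float:
        return len(self.test_trials()) * self.trial_duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])


@dataclass
class FreeSpellingSummary:
    """Free-spelling accounting row (written = error-free letters)."""

    written: int
    deleted: int
    trials: int
    time_s: float
    letters_per_min: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        if self.time_s <= 0:
            raise ValueError("time_s must be positive")
        self.letters_per_min = self.written / (self.time_s / 60.0)
        self.accuracy = (self.trials - self.deleted) / self.trials if self.trials else 0.0


def accuracy(log: SessionLog, phase: str | None = "test") -> float:
    """Fraction of correctly classified trials.

    For copy-spelling/calibration logs this compares predictions with true
    labels; for free-spelling logs (no prescribed targets) it uses the
    per-trial error flags, i.e. (trials - errors) / trials.
    """
    trials = log.trials if phase is None else [t for t in log.trials if t.phase == phase]
    if log.mode == "free_spelling":
        flagged = [t for t in trials if t.was_error is not None]
        if not flagged:
            raise ValueError("free-spelling log has no error accounting")
        return 1.0 - sum(t.was_error for t in flagged) / len(flagged)
    labelled = [t for t in trials if t.true_label is not None]
    if not labelled:
        raise ValueError("no labelled trials to score")
    return sum(t.predicted_label == t.true_label for t in labelled) / len(labelled)


def wolpaw_bits_per_selection(n_classes: int, p: float) -> float:
    """Wolpaw bits per selection, clamped to 0 at or below chance."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if p <= 1.0 / n_classes:
        return 0.0
    bits = np.log2(n_classes)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n_classes - 1))
    return float(bits)


def wolpaw_itr(n_classes: int, accuracy: float, trial_duration_s: float) -> float:
    """Wolpaw information transfer rate in bit/min."""
    if trial_duration_s <= 0:
        raise ValueError("trial duration must be positive")
    return wolpaw_bits_per_selection(n_classes, accuracy) * 60.0 / trial_duration_s


def free_spelling_summary(
    log: SessionLog | None = None,
    *,
    written: int | None = None,
    deleted: int | None = None,
    trials: int | None = None,
    time_s: float | None = None,
) -> FreeSpellingSummary:
    """Summarize a free-spelling session (or raw printed counts).

    From a log, a trial counts as written when it produced a letter that
    survived (was not subsequently deleted); each deleted letter accounts
    for two non-written trials (the error and its backspace).
    """
    if log is not None:
        recs = log.test_trials()
        n_trials = len(recs)
        n_deleted = sum(1 for t in recs if t.was_error)
        n_written = sum(
            1 for t in recs if not t.was_backspace and t.was_error is False
        )
        total_time = log.total_time_s
        return FreeSpellingSummary(n_written, n_deleted, n_trials, total_time)
    if None in (written, deleted, trials) or time_s is None:
        raise ValueError("provide either a log or all four counts")
    return FreeSpellingSummary(written, deleted, trials, time_s)


def aggregate(
    summaries: Iterable[FreeSpellingSummary],
    method: Literal["column_mean", "pooled"] = "pooled",
) -> FreeSpellingSummary:
    """Aggregate free-spelling rows.

    ``pooled`` recomputes the metrics from summed counts and times (the
    convention for an overall letters-per-minute figure); ``column_mean``
    averages each per-row metric.
    """
    rows = list(summaries)
    if not rows:
        raise ValueError("nothing to aggregate")
    if method == "pooled":
        return FreeSpellingSummary(
            written=sum(r.written for r in rows),
            deleted=sum(r.deleted for r in rows),
            trials=sum(r.trials for r in rows),
            time_s=sum(r.time_s for r in rows),
        )
    if method != "column_mean":
        raise ValueError(f"unknown aggregation method {method!r}")
    out = FreeSpellingSummary.__new__(FreeSpellingSummary)
    out.written = float(np.mean([r.written for r in rows]))
    out.deleted = float(np.mean([r.deleted for r in rows]))
    out.trials = float(np.mean([r.trials for r in rows]))
    out.time_s = float(np.mean([r.time_s for r in rows]))
    out.letters_per_min = float(np.mean([r.letters_per_min for r in rows]))
    out.accuracy = float(np.mean([r.accuracy for r in rows]))
    return out


def column_mean(values: Iterable[float]) -> float:
    """Plain column mean used for table average rows."""
    vals = list(values)
    if not vals:
        raise ValueError("nothing to average")
    return float(np.mean(vals))


def session_table(
    rows: dict[str, SessionLog], trial_durations: dict[str, float] | None = None
) -> pd.DataFrame:
    """Accuracy/ITR table for a set of copy-spelling session logs."""
    records = []
    for name, log in rows.items():
        acc = accuracy(log)
        dur = (trial_durations or {}).get(name, log.trial_duration)
        records.append({
            "session": name,
            "accuracy_pct": round_half_up(100 * acc),
            "itr_bit_per_min": round_half_up(wolpaw_itr(log.n_targets, acc, dur)),
        })
    df = pd.DataFrame(records)
    df.loc[len(df)] = {
        "session": "average",
        "accuracy_pct": round_half_up(df["accuracy_pct"].mean()),
        "itr_bit_per_min": round_half_up(df["itr_bit_per_min"].mean()),
    }
    return df
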