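"""Shared fixtures: small-geometry synthetic sessions.

Most tests run at a reduced geometry (120 Hz sampling = 2 samples per
code bit, 8-channel posterior+frontal montage) where one pipeline retrain
costs milliseconds; the physics of the simulator (shift structure,
latency, mixing) is identical to the full 600 Hz / 30-channel default.
"""

from __future__ import annotations

import numpy as np
import pytest

from cvepbci.adaptation import calibrate_batch
from cvepbci.codes import TargetLayout, bits_to_samples, generate_msequence
from cvepbci.synthetic import ForwardModel, simulate_trial

SMALL_CHANNELS = ("Fz", "Cz", "CPz", "Pz", "POz", "P4", "PO3", "O1")
SMALL_FS = 120.0


@pytest.fixture(scope="session")
def layout() -> TargetLayout:
    return TargetLayout()


@pytest.fixture(scope="session")
def code():
    return generate_msequence(refresh_rate=60.0)


@pytest.fixture(scope="session")
def small_model() -> ForwardModel:
    return ForwardModel(fs=SMALL_FS, channel_names=SMALL_CHANNELS, noise_sd=2.0)


@pytest.fixture(scope="session")
def samples_per_trial(code) -> int:
    return bits_to_samples(len(code), SMALL_FS, code.refresh_rate)


def make_trials(model, layout, code, targets, seed):
    rng = np.random.default_rng(seed)
    return [
        simulate_trial(model, layout, code, k, rng, trial_index=i)
        for i, k in enumerate(targets)
    ]


@pytest.fixture(scope="session")
def calibrated_state(layout, code, small_model):
    """Pipeline fitted once on 64 moderate-noise trials (2 per target)."""
    targets = list(range(32)) * 2
    trials = make_trials(small_model, layout, code, targets, seed=1234)
    return calibrate_batch(trials, targets, layout=layout, fs=SMALL_FS)
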