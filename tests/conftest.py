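"""Shared fixtures: small simulated datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from attndecode.preprocess import preprocess_participant
from attndecode.synth import simulate_participants


@pytest.fixture(scope="session")
def tiny_sim():
    """One simulated participant: 4 sequences, 16 channels, default signal."""
    return simulate_participants(2, base_seed=101, n_sequences=4, n_channels=16)[0]


@pytest.fixture(scope="session")
def tiny_epochs(tiny_sim):
    """Preprocessed epochs of the tiny participant (416 analysable trials)."""
    return preprocess_participant(tiny_sim)


@pytest.fixture(scope="session")
def noise_free_epochs():
    """Noise-free strong-signal epochs: decoding should be perfect inside the
    evoked-kernel support."""
    sim = simulate_participants(
        2,
        base_seed=202,
        n_sequences=2,
        n_channels=16,
        fm_overrides={"noise_sd": 0.0, "amplitude": 2.0},
    )[0]
    return preprocess_participant(sim)


@pytest.fixture(scope="session")
def null_epochs():
    """Signal-free (amplitude 0) epochs: decoding should sit at chance."""
    sim = simulate_participants(
        2,
        base_seed=303,
        n_sequences=4,
        n_channels=16,
        fm_overrides={"amplitude": 0.0},
    )[0]
    return preprocess_participant(sim)
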