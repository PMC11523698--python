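"""Shared fixtures: one default session and helpers to simulate neurons
through the full generate → count path."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import spikesel as ss

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def trials() -> pd.DataFrame:
    """A default 720-trial session (fixed seed, shared across tests)."""
    return ss.make_session(seed=123)


@pytest.fixture(scope="session")
def null_counts(trials) -> pd.DataFrame:
    """Trial count matrix of one non-selective 5 Hz Poisson neuron."""
    tuning = ss.NeuronTuning("null0", baseline_rate_hz=5.0)
    train = ss.simulate_spike_train(tuning, trials, seed=7)
    return ss.count_trials(train, trials)


@pytest.fixture(scope="session")
def selective_counts(trials) -> pd.DataFrame:
    """Counts of a neuron with gain 3 on Black, 5 Hz baseline."""
    tuning = ss.NeuronTuning("sel0", baseline_rate_hz=5.0, gain={"Black": 3.0})
    train = ss.simulate_spike_train(tuning, trials, seed=11)
    return ss.count_trials(train, trials)


def simulate_counts(
    trials: pd.DataFrame,
    seed: int,
    baseline_rate_hz: float = 5.0,
    gain: dict | None = None,
    neuron_id: str = "n0",
    area: str = "A",
) -> pd.DataFrame:
    """Generate one neuron's counts through the package's own path."""
    tuning = ss.NeuronTuning(
        neuron_id, area=area, baseline_rate_hz=baseline_rate_hz, gain=gain or {}
    )
    train = ss.simulate_spike_train(tuning, trials, seed=seed)
    return ss.count_trials(train, trials)


def counts_from_arrays(
    categories, response, background, neuron_id="n0", area="A"
) -> pd.DataFrame:
    """Build a count matrix directly from arrays (for hand-computed cases)."""
    categories = list(categories)
    return pd.DataFrame(
        {
            "neuron_id": neuron_id,
            "area": area,
            "trial_id": np.arange(len(categories)),
            "category": categories,
            "response_count": np.asarray(response, int),
            "background_count": np.asarray(background, int),
        }
    )
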