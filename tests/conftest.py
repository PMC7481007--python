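"""Shared fixtures: small synthetic datasets built programmatically."""

import numpy as np
import pandas as pd
import pytest

from lpfc_subspaces.datasets import PopulationDataset


def make_dataset(
    n_trials_per_cond=8,
    n_neurons=6,
    n_locations=4,
    bin_width=100.0,
    t_start=-500.0,
    n_bins=31,
    base_rate=10.0,
    seed=0,
    rate_fn=None,
    outcome="correct",
):
    """Poisson dataset with an optional injected rate structure.

    ``rate_fn(neuron, location, bin_center)`` returns the rate in spikes/s;
    defaults to a constant ``base_rate``.
    """
    rng = np.random.default_rng(seed)
    locs = np.arange(1, n_locations + 1)
    targets = np.repeat(locs, n_trials_per_cond)
    n_trials = targets.size
    distractors = np.array([rng.choice(locs[locs != t]) for t in targets])
    centers = t_start + bin_width * (np.arange(n_bins) + 0.5)
    rates = np.empty((n_trials, n_neurons, n_bins))
    for t in range(n_trials):
        for i in range(n_neurons):
            if rate_fn is None:
                rates[t, i] = base_rate
            else:
                rates[t, i] = [rate_fn(i, targets[t], c) for c in centers]
    counts = rng.poisson(rates * bin_width / 1000.0)
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "session_id": 0,
            "target_location": targets,
            "distractor_location": distractors,
            "outcome": outcome,
            "saccade_onset_ms": 2750.0,
        }
    )
    return PopulationDataset(
        counts=counts, bin_width=bin_width, trials=trials, t_start=t_start
    )


@pytest.fixture
def constant_dataset():
    """Every neuron fires at a constant 10 spikes/s in every bin."""
    return make_dataset(seed=1)


@pytest.fixture
def delay_tuned_dataset():
    """Neuron 0 adds location-dependent rate during Delay 1 only."""

    def rate_fn(i, loc, t):
        r = 10.0
        if i == 0 and 800 <= t < 1300:
            r += 40.0 * loc
        return r

    return make_dataset(rate_fn=rate_fn, seed=2)
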