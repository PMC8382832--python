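import numpy as np
import pytest

from miniv1.extraction import align_trials, zscore_session
from miniv1.grids import StimulusGrid
from miniv1.synthetic import (GroundTruthCell, generate_trial_table,
                              make_session, simulate_traces)

ORIS = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0)


def single_cell(pref=15.0, kappa=2.0, gain=1.5, sign=1, rf_position=9,
                centroid=(60.0, 60.0), sigma=3.0):
    return GroundTruthCell(0, centroid, sigma, rf_position, pref, kappa,
                           gain, sign)


def tensor_from_cells(cells, n_reps=10, positions=(9,), noise_sd=0.15,
                      seed=0, zscore=True, iti_mean_ms=4000.0,
                      iti_jitter_ms=1000.0):
    """Simulate a session for `cells` and return the aligned tensor.

    For noise-free oracle checks pass ``iti_mean_ms=9000, iti_jitter_ms=0``:
    gaps longer than the indicator kernel isolate every trial exactly.
    """
    trials = generate_trial_table(n_reps, positions, ORIS, seed=seed,
                                  iti_mean_ms=iti_mean_ms,
                                  iti_jitter_ms=iti_jitter_ms)
    traces = simulate_traces(cells, trials, noise_sd=noise_sd, seed=seed + 1)
    if zscore:
        traces = zscore_session(traces)
    return align_trials(traces, trials)


@pytest.fixture(scope="session")
def grid():
    return StimulusGrid()


@pytest.fixture(scope="session")
def tuned_population_tensor():
    """30 tuned ROIs, 20 trials per orientation: the standard decoding bench."""
    bundle = make_session(n_cells=30, n_reps_per_condition=20, seed=42,
                          noise_sd=0.15,
                          concentration_range=(0.5, 3.0))
    return align_trials(zscore_session(bundle.traces), bundle.trials), bundle


@pytest.fixture(scope="session")
def paired_bundles():
    """100-cell paired sessions with 0.5 px jitter and 25% turnover."""
    from miniv1.synthetic import derive_second_session
    a = make_session(n_cells=100, fov_shape=(200, 200),
                     n_reps_per_condition=20, seed=7)
    b = derive_second_session(a, shift=(3.0, -2.0), rotation=1.0,
                              centroid_jitter_sd=0.5, drop_fraction=0.25,
                              add_count=10, tuning_drift_sd=5.0, seed=8)
    return a, b
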