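"""Synthetic-session generator: trial bookkeeping, trace physics, footprints."""

import numpy as np
import pytest

from miniv1.grids import StimulusGrid, rf_attenuation
from miniv1.synthetic import (ORIENTATIONS_DEG, GroundTruthCell,
                              derive_second_session, evoked_amplitude,
                              generate_footprints, generate_trial_table,
                              make_session, response_kernel, simulate_traces)

from conftest import single_cell


class TestTrialTable:
    def test_condition_balance(self):
        trials = generate_trial_table(20, [1], ORIENTATIONS_DEG, seed=1)
        assert len(trials) == 120
        counts = trials.groupby("orientation").size()
        assert (counts == 20).all()

    def test_twelve_trials_per_location_over_two_rounds(self):
        # 2 repetitions x 6 orientations = 12 trials at each of 15 positions
        trials = generate_trial_table(2, range(1, 16), ORIENTATIONS_DEG, seed=2)
        per_loc = trials.groupby("position").size()
        assert (per_loc == 12).all()
        per_cond = trials.groupby(["position", "orientation"]).size()
        assert (per_cond == 2).all()

    def test_onset_timing_floor(self):
        trials = generate_trial_table(1, [1], [0.0], 10.0, 4000, 0, seed=7)
        assert len(trials) == 1
        assert trials["onset_s"].iloc[0] >= 0.5
        assert np.isclose(trials["onset_s"].iloc[0] - trials["fix_start_s"].iloc[0],
                          0.5)

    def test_iti_bounds(self):
        trials = generate_trial_table(10, [1], [0.0, 30.0], seed=3)
        gaps = trials["fix_start_s"].diff().dropna() - 0.5 - 0.3
        assert (gaps >= 3.0 - 1e-9).all() and (gaps <= 5.0 + 1e-9).all()

    @pytest.mark.parametrize("kwargs", [
        dict(n_reps_per_condition=0, positions=[1]),
        dict(n_reps_per_condition=1, positions=[1], frame_rate=0.0),
        dict(n_reps_per_condition=1, positions=[1], orientations=[]),
    ])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            generate_trial_table(**{"orientations": ORIENTATIONS_DEG,
                                    **kwargs})


class TestTraces:
    def test_untuned_cell_is_orientation_symmetric(self, grid):
        cell = single_cell(kappa=0.0)
        amps = [evoked_amplitude(cell, o, 9, grid) for o in ORIENTATIONS_DEG]
        assert np.allclose(amps, amps[0])

    def test_noise_free_trace_matches_convolution_oracle(self):
        """A single noiseless trial equals the impulse convolved with the kernel."""
        cell = single_cell(pref=0.0, kappa=0.0, gain=1.3)
        trials = generate_trial_table(1, [9], [0.0], seed=5)
        tm = simulate_traces([cell], trials, noise_sd=0.0, seed=0)
        fr = 10.0
        # independent oracle: direct convolution of a unit impulse
        impulse = np.zeros(tm.n_frames)
        impulse[int(round(trials["onset_s"].iloc[0] * fr))] = 1.3
        t = np.arange(0, 8.0, 1.0 / fr)
        k = np.exp(-t / 1.0) - np.exp(-t / 0.2)
        k /= k.max()
        expected = np.convolve(impulse, k)[: tm.n_frames]
        assert np.allclose(tm.values[:, 0], expected, atol=1e-12)

    def test_negative_responder_goes_below_baseline(self):
        cell = single_cell(kappa=0.0, sign=-1)
        trials = generate_trial_table(1, [9], [0.0], seed=5)
        tm = simulate_traces([cell], trials, noise_sd=0.0, seed=0)
        onset = trials["onset_s"].iloc[0]
        post = tm.values[(tm.times > onset) & (tm.times < onset + 2), 0]
        assert post.mean() < 0

    def test_area_equals_amplitude_times_kernel_integral(self, grid):
        cell = single_cell(pref=30.0, kappa=1.0, gain=2.0)
        trials = generate_trial_table(1, [9], [30.0], seed=5)
        tm = simulate_traces([cell], trials, noise_sd=0.0, seed=0)
        amp = evoked_amplitude(cell, 30.0, 9, grid)
        kernel = response_kernel(10.0)
        assert np.isclose(tm.values[:, 0].sum(), amp * kernel.sum(), atol=1e-6)

    def test_reproducibility_bit_identical(self):
        a = make_session(n_cells=5, n_reps_per_condition=2, seed=11)
        b = make_session(n_cells=5, n_reps_per_condition=2, seed=11)
        assert np.array_equal(a.traces.values, b.traces.values)
        assert a.trials.equals(b.trials)
        assert np.array_equal(a.footprints.masks, b.footprints.masks)

    def test_negative_noise_rejected(self):
        trials = generate_trial_table(1, [9], [0.0], seed=5)
        with pytest.raises(ValueError):
            simulate_traces([single_cell()], trials, noise_sd=-0.1, seed=0)


class TestFootprints:
    def test_peak_at_centroid(self):
        cell = single_cell(centroid=(60.0, 40.0))
        fps = generate_footprints([cell], (120, 120))
        r, c = np.unravel_index(np.argmax(fps.masks[0]), fps.masks[0].shape)
        assert (c, r) == (60, 40)
        assert np.isclose(fps.masks[0].max(), 1.0)

    def test_distant_cells_are_uncorrelated(self):
        cells = [single_cell(centroid=(30.0, 30.0)),
                 GroundTruthCell(1, (80.0, 80.0), 3.0, 9, 0.0, 1.0, 1.0)]
        fps = generate_footprints(cells, (120, 120))
        corr = np.corrcoef(fps.masks[0].ravel(), fps.masks[1].ravel())[0, 1]
        assert corr < 0.01

    def test_footprint_must_fit_in_fov(self):
        with pytest.raises(ValueError):
            generate_footprints([single_cell(sigma=30.0)], (120, 120))
        with pytest.raises(ValueError):
            generate_footprints([single_cell(centroid=(2.0, 60.0))], (120, 120))


class TestSecondSession:
    def test_identity_transform_gives_identity_correspondence(self):
        a = make_session(n_cells=10, n_reps_per_condition=2, seed=21)
        b = derive_second_session(a, seed=22)
        assert b.correspondence == {i: i for i in range(10)}
        ca = a.footprints.centroids()
        cb = b.footprints.centroids()
        assert np.allclose(ca, cb)

    def test_drop_fraction_count(self):
        a = make_session(n_cells=40, fov_shape=(200, 200),
                         n_reps_per_condition=2, seed=23)
        b = derive_second_session(a, drop_fraction=0.25, seed=24)
        assert len(b.correspondence) == 30

    def test_pure_shift_moves_every_centroid(self):
        a = make_session(n_cells=10, n_reps_per_condition=2, seed=25)
        b = derive_second_session(a, shift=(5.0, 3.0), seed=26)
        assert b.correspondence  # at least some cells survive the shift
        truth_a = {c.cell_id: np.array(c.centroid) for c in a.truth}
        truth_b = {c.cell_id: np.array(c.centroid) for c in b.truth}
        for old_id, new_id in b.correspondence.items():
            assert np.allclose(truth_b[new_id] - truth_a[old_id], [5.0, 3.0])
        # mask centers of gravity agree up to Gaussian-tail truncation
        ca = a.footprints.centroids()  # (row, col)
        cb = b.footprints.centroids()
        for old_id, new_id in b.correspondence.items():
            assert np.allclose(cb[new_id] - ca[old_id], [3.0, 5.0], atol=0.01)

    def test_tuning_drift_wraps(self):
        a = make_session(n_cells=20, n_reps_per_condition=2, seed=27)
        b = derive_second_session(a, tuning_drift_sd=30.0, seed=28)
        prefs = [c.preferred_orientation for c in b.truth]
        assert all(-90.0 <= p < 90.0 for p in prefs)

    def test_all_cells_out_of_view_raises(self):
        a = make_session(n_cells=5, n_reps_per_condition=2, seed=29)
        with pytest.raises(ValueError):
            derive_second_session(a, shift=(500.0, 500.0), seed=30)


def test_rf_attenuation_decays_with_grid_distance(grid):
    atts = [rf_attenuation(grid, p, 9) for p in grid.positions]
    assert np.isclose(atts[9 - 1], 1.0)
    d = [grid.grid_distance(p, 9) for p in grid.positions]
    order = np.argsort(d)
    assert np.all(np.diff(np.array(atts)[order]) <= 1e-12)
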