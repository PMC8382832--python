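"""Cross-session registration: alignment, features, mixture model, stability."""

import numpy as np
import pytest

from miniv1.extraction import align_trials, zscore_session
from miniv1.synthetic import derive_second_session, make_session
from miniv1.tracking import (align_fovs, apply_transform, fit_same_cell_model,
                             ks_uniform, pair_features, register,
                             stability_statistics, track_sessions)
from miniv1.tuning import compute_tuning

from conftest import single_cell


def _gauss(shape, cy, cx, sigma=3.0):
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return np.exp(-((r - cy) ** 2 + (c - cx) ** 2) / (2 * sigma ** 2))


def _stack(centers, shape=(80, 80)):
    from miniv1.containers import FootprintStack
    masks = np.stack([_gauss(shape, cy, cx) for cy, cx in centers])
    return FootprintStack(masks, list(range(len(centers))), shape)


class TestAlignment:
    def test_identity(self):
        s = _stack([(20, 20), (40, 55), (60, 30)])
        tf = align_fovs(s, s)
        assert abs(tf.dy) < 0.1 and abs(tf.dx) < 0.1
        assert tf.rotation == 0.0

    def test_known_shift_recovered(self):
        a = _stack([(20, 20), (40, 55), (60, 30)])
        b = _stack([(23, 25), (43, 60), (63, 35)])  # a shifted by (dy=3, dx=5)
        tf = align_fovs(a, b)
        assert tf.dy == pytest.approx(-3, abs=0.2)
        assert tf.dx == pytest.approx(-5, abs=0.2)

    def test_shift_plus_rotation_functionally_recovered(self):
        a = make_session(n_cells=40, fov_shape=(160, 160),
                         n_reps_per_condition=2, seed=31)
        b = derive_second_session(a, shift=(4.0, -3.0), rotation=2.0,
                                  centroid_jitter_sd=0.0, seed=32)
        tf = align_fovs(a.footprints, b.footprints)
        aligned = apply_transform(b.footprints, tf)
        err = np.abs(aligned.centroids() - a.footprints.centroids()).max()
        assert err < 0.5
        assert abs(abs(tf.rotation) - 2.0) <= 0.5

    def test_uncorrelatable_content_fails(self):
        from miniv1.containers import FootprintStack
        a = _stack([(20, 20)])
        rr, cc = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
        checker = ((rr + cc) % 2).astype(float)  # no blob-scale structure
        b = FootprintStack(checker[None], [0], (80, 80))
        with pytest.raises(ValueError, match="alignment"):
            align_fovs(a, b)


class TestPairFeatures:
    def test_identical_masks(self):
        s = _stack([(40, 40)])
        feats = pair_features(s, s)
        assert len(feats) == 1
        assert feats[0].distance == pytest.approx(0.0, abs=1e-9)
        assert feats[0].correlation == pytest.approx(1.0, abs=1e-9)

    def test_offset_gaussians_match_pixel_oracle(self):
        a = _stack([(40, 40)])
        b = _stack([(40, 43)])
        feats = pair_features(a, b)
        assert feats[0].distance == pytest.approx(3.0, abs=0.01)
        # independent pixel-sum oracle on the union support
        ma, mb = a.masks[0], b.masks[0]
        support = (ma > 1e-3) | (mb > 1e-3)
        expected = np.corrcoef(ma[support], mb[support])[0, 1]
        assert feats[0].correlation == pytest.approx(expected, abs=1e-9)

    def test_disjoint_supports_non_positive_correlation(self):
        a = _stack([(30, 30)], shape=(100, 100))
        b = _stack([(30, 41)], shape=(100, 100))
        feats = pair_features(a, b, max_distance=15.0)
        assert feats[0].correlation <= 0.0

    def test_distance_gate(self):
        a = _stack([(20, 20)])
        b = _stack([(50, 50)])
        assert pair_features(a, b, max_distance=12.0) == []


class TestMixtureModel:
    def _planted(self, n_same=60, n_diff=120, seed=0):
        from miniv1.tracking import PairFeature
        rng = np.random.default_rng(seed)
        feats, labels = [], []
        for i in range(n_same):
            feats.append(PairFeature(i, i, i, i,
                                     float(rng.lognormal(-0.7, 0.5)),
                                     float(np.clip(rng.normal(0.9, 0.05),
                                                   -1, 1))))
            labels.append(True)
        for i in range(n_diff):
            feats.append(PairFeature(0, 0, -1, -1,
                                     float(rng.lognormal(1.8, 0.4)),
                                     float(np.clip(rng.normal(0.1, 0.15),
                                                   -1, 1))))
            labels.append(False)
        return feats, np.array(labels)

    def test_planted_components_recovered(self):
        feats, labels = self._planted()
        model = fit_same_cell_model(feats)
        pred = model.p_same > 0.5
        assert (pred == labels).mean() >= 0.99
        assert model.converged

    def test_true_pairs_outscore_false_pairs(self):
        # no cell turnover: every candidate pair is unambiguously true/false
        a = make_session(n_cells=80, fov_shape=(200, 200),
                         n_reps_per_condition=2, seed=33)
        b = derive_second_session(a, shift=(2.0, 1.0),
                                  centroid_jitter_sd=0.5, seed=34)
        tf = align_fovs(a.footprints, b.footprints)
        feats = pair_features(a.footprints, apply_transform(b.footprints, tf))
        model = fit_same_cell_model(feats)
        truth = b.correspondence
        is_true = np.array([truth.get(f.roi_a) == f.roi_b for f in feats])
        assert is_true.any() and (~is_true).any()
        assert model.p_same[is_true].min() > model.p_same[~is_true].max()

    def test_degenerate_features_rejected(self):
        from miniv1.tracking import PairFeature
        feats = [PairFeature(i, i, i, i, 1.0, 0.5) for i in range(30)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_same_cell_model(feats)

    def test_too_few_pairs_rejected(self):
        feats, _ = self._planted(n_same=5, n_diff=5)
        with pytest.raises(ValueError, match="20 candidate"):
            fit_same_cell_model(feats)


class TestRegister:
    def test_unattainable_threshold_matches_nothing(self):
        feats, _ = TestMixtureModel()._planted()
        model = fit_same_cell_model(feats)
        result = register(feats, model.p_same, threshold=1.01)
        assert result.matches == []

    def test_identity_sessions_match_everything(self):
        centers = [(15 + 11 * i, 15 + 11 * j)
                   for i in range(5) for j in range(5)]
        s = _stack(centers)
        result, model, feats = track_sessions(s, s)
        matched = {m[0]: m[1] for m in result.matches}
        assert matched == {i: i for i in range(25)}

    def test_threshold_monotonicity(self):
        feats, _ = TestMixtureModel()._planted()
        model = fit_same_cell_model(feats)
        counts = [len(register(feats, model.p_same, thr).matches)
                  for thr in (0.1, 0.3, 0.5, 0.7, 0.9, 0.99)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_one_to_one(self, paired_bundles):
        a, b = paired_bundles
        result, _, _ = track_sessions(a.footprints, b.footprints)
        roi_a = [m[0] for m in result.matches]
        roi_b = [m[1] for m in result.matches]
        assert len(roi_a) == len(set(roi_a))
        assert len(roi_b) == len(set(roi_b))


class TestStability:
    @pytest.fixture(scope="class")
    def self_match_setup(self):
        bundle = make_session(n_cells=12, n_reps_per_condition=10, seed=51,
                              concentration_range=(0.5, 3.0))
        tensor = align_trials(zscore_session(bundle.traces), bundle.trials)
        tuning = compute_tuning(tensor)
        result, _, _ = track_sessions(bundle.footprints, bundle.footprints)
        return tensor, tuning, result

    def test_self_match_perfect_correlations(self, self_match_setup):
        tensor, tuning, result = self_match_setup
        report = stability_statistics(tensor, tensor, tuning, tuning, result,
                                      seed=0, n_orientation_shuffles=200)
        obs = np.array(report["trace_correlation"]["observed"])
        assert np.allclose(obs, 1.0, atol=1e-9)
        if "osi_correlation" in report:
            assert report["osi_correlation"]["r"] == pytest.approx(1.0)
            d = report["orientation_difference"]
            assert d["observed_counts"][0] == sum(d["observed_counts"])

    def test_ks_uniform_sanity(self):
        rng = np.random.default_rng(1)
        rejections = sum(ks_uniform(rng.uniform(0, 90, 25))["p_value"] < 0.05
                        for _ in range(200))
        assert rejections / 200 < 0.1  # calibrated, not anti-conservative

    def test_concentrated_differences_reject_uniformity(self):
        diffs = np.abs(np.random.default_rng(2).normal(0, 4, 30))
        assert ks_uniform(diffs)["p_value"] < 0.001
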