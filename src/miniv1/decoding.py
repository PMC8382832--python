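"""Population decoding of stimulus orientation.

A multiclass error-correcting output-code model built from binary linear
support vector machines (one-vs-one coding) is evaluated with stratified
10-fold cross-validation; decoding performance is 1 minus the classification
loss, i.e. the fraction of correctly classified trials.  Time courses use a
500-ms window sliding in 166-ms steps over the trial-aligned data, each
window scored against a 100-repetition shuffled-label null by a two-tailed
two-sample t-test.  ROI-count curves compare random ROI selection with
selection in descending OSI order, plus a shuffled-label control, in the
fixed 500–1500 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import ResponseTensor


@dataclass
class DecodingCurve:
    window_centers: np.ndarray  # seconds relative to onset
    performance: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float


@dataclass
class RoiCountCurve:
    n_rois: np.ndarray
    random_mean: np.ndarray
    random_sd: np.ndarray
    osi_ordered: np.ndarray
    shuffled_mean: np.ndarray
    shuffled_sd: np.ndarray


def _classifier():
    # linear-kernel binary SVMs in one-vs-one coding, box constraint 1
    return SVC(kernel="linear", C=1.0, decision_function_shape="ovo")


def decode_window_folds(features: np.ndarray, labels, n_folds: int = 10,
                        seed: int = 0) -> np.ndarray:
    """Per-fold accuracies of the ECOC-SVM under stratified k-fold CV.

    ``features`` is trials x ROIs.  Folds are stratified by class and seeded.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on trial count")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification failure: a class has {counts.min()} trials for "
            f"{n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = np.empty(n_folds)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        clf = _classifier().fit(X[tr], y[tr])
        accs[k] = float(np.mean(clf.predict(X[te]) == y[te]))
    return accs


def decode_window(features: np.ndarray, labels, n_folds: int = 10,
                  seed: int = 0) -> float:
    """Cross-validated fraction correct (1 - classification loss)."""
    return float(decode_window_folds(features, labels, n_folds, seed).mean())


def window_features(tensor: ResponseTensor, start_ms: float,
                    window_ms: float) -> np.ndarray:
    """Trials x ROIs matrix of per-ROI means within [start, start+window) ms."""
    mask = tensor.bin_mask((start_ms, start_ms + window_ms))
    if not mask.any():
        raise ValueError("window holds no frames")
    return tensor.values[:, :, mask].mean(axis=2).T


def decode_timecourse(tensor: ResponseTensor, window_ms: float = 500.0,
                      step_ms: float = 166.0, n_shuffles: int = 100,
                      alpha: float = 0.05, n_folds: int = 10,
                      seed: int = 0) -> DecodingCurve:
    """Sliding-window decoding time course with a shuffled-label null.

    The observed side of the per-window t-test is the vector of per-fold
    accuracies (making the stated two-sample test well-posed); the null side
    is the distribution of mean accuracies over ``n_shuffles`` label
    permutations.
    """
    rng = np.random.default_rng(seed)
    labels = tensor.trial_meta["orientation"].to_numpy()
    t_ms = tensor.rel_time * 1000.0
    starts = []
    s = t_ms[0]
    while s + window_ms <= t_ms[-1] + 1e-9:
        starts.append(s)
        s += step_ms
    if not starts:
        raise ValueError("tensor shorter than one decoding window")

    centers, perf, null_mu, null_sd, pvals, signif = [], [], [], [], [], []
    for s in starts:
        feats = window_features(tensor, s, window_ms)
        obs_folds = decode_window_folds(feats, labels, n_folds,
                                        seed=int(rng.integers(2 ** 31)))
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            null[i] = decode_window(feats, rng.permutation(labels), n_folds,
                                    seed=int(rng.integers(2 ** 31)))
        t_res = stats.ttest_ind(obs_folds, null)
        centers.append((s + window_ms / 2.0) / 1000.0)
        perf.append(obs_folds.mean())
        null_mu.append(null.mean())
        null_sd.append(null.std(ddof=1))
        pvals.append(float(t_res.pvalue))
        signif.append(bool(t_res.pvalue < alpha))
    return DecodingCurve(np.array(centers), np.array(perf), np.array(null_mu),
                         np.array(null_sd), np.array(pvals),
                         np.array(signif), alpha)


def decode_by_roi_count(features: np.ndarray, labels, osi_values,
                        counts, n_reps: int = 100, n_folds: int = 10,
                        seed: int = 0) -> RoiCountCurve:
    """Decoding performance versus number of ROIs used.

    Three curves over ``counts``: mean ± sd over ``n_reps`` random ROI
    subsets; a deterministic curve taking the top-n ROIs by descending OSI;
    and a shuffled-label control on random subsets.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    osi = np.asarray(osi_values, dtype=float)
    n_total = X.shape[1]
    counts = np.asarray(sorted(int(c) for c in counts))
    if counts[0] < 1 or counts[-1] > n_total:
        raise ValueError("counts must lie within [1, total ROIs]")
    rng = np.random.default_rng(seed)
    osi_order = np.argsort(-osi, kind="stable")

    rand_mu, rand_sd = [], []
    shuf_mu, shuf_sd = [], []
    ordered = []
    for c in counts:
        r = np.empty(n_reps)
        sh = np.empty(n_reps)
        for i in range(n_reps):
            sub = rng.choice(n_total, size=c, replace=False)
            r[i] = decode_window(X[:, sub], y, n_folds,
                                 seed=int(rng.integers(2 ** 31)))
            sub = rng.choice(n_total, size=c, replace=False)
            sh[i] = decode_window(X[:, sub], rng.permutation(y), n_folds,
                                  seed=int(rng.integers(2 ** 31)))
        rand_mu.append(r.mean())
        rand_sd.append(r.std(ddof=1))
        shuf_mu.append(sh.mean())
        shuf_sd.append(sh.std(ddof=1))
        ordered.append(decode_window(X[:, osi_order[:c]], y, n_folds,
                                     seed=int(rng.integers(2 ** 31))))
    return RoiCountCurve(counts, np.array(rand_mu), np.array(rand_sd),
                         np.array(ordered), np.array(shuf_mu),
                         np.array(shuf_sd))
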