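"""Cross-session ROI registration and stability statistics.

Two sessions' fields of view are first rigidly aligned (translation plus a
small rotation search) on their summed-footprint projections.  For every
cross-session ROI pair within a centroid-distance gate, two features are
computed: the distance between footprint centers of gravity and the Pearson
correlation of the footprint shapes.  A two-component mixture model — a
"same cell" component (small distance, high correlation) and a "different
cell" component — is fitted to these features by expectation-maximization
with lognormal distance and beta-transformed correlation margins; each
pair's P_same is its posterior probability under the same-cell component,
and pairs scoring above a threshold (default P_same = 0.5) are registered as
identical, one-to-one, greedily by descending score.

Stability statistics for registered pairs: per-orientation Pearson
correlation of trial-averaged 0–2000 ms response time courses (averaged over
orientations) against shuffled pairings; Pearson correlation of OSI values;
and the histogram of absolute preferred-orientation differences in 10° bins
against a 10,000-repetition shuffled-pair null, with KS tests against the
uniform distribution on [0°, 90°] and against an exponential curve fitted to
the observed bin proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.special import logsumexp
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _rotate_image

from .containers import DEFAULT_WINDOWS, FootprintStack, ResponseTensor
from .extraction import orientation_averages
from .tuning import orientation_difference

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 12.0  # px; about one footprint diameter
# same-FOV sessions correlate >= ~0.5 after alignment even with heavy cell
# turnover; unrelated content stays below ~0.2
ALIGNMENT_CORR_FLOOR = 0.25


@dataclass
class RigidTransform:
    """Maps session-B pixel coordinates into session-A coordinates."""
    dy: float
    dx: float
    rotation: float  # degrees, applied about the FOV center before the shift
    score: float = float("nan")  # correlation of projections after alignment


@dataclass
class PairFeature:
    index_a: int
    index_b: int
    roi_a: object
    roi_b: object
    distance: float
    correlation: float


@dataclass
class SameCellModel:
    weight_same: float
    logdist_mean: np.ndarray  # (same, different)
    logdist_sd: np.ndarray
    corr_beta_a: np.ndarray
    corr_beta_b: np.ndarray
    p_same: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    degenerate: bool = False


@dataclass
class RegistrationResult:
    matches: list  # (roi_a, roi_b, p_same)
    unmatched_a: list
    unmatched_b: list
    transform: RigidTransform = None
    threshold: float = 0.5


def _projection(stack: FootprintStack) -> np.ndarray:
    return stack.masks.sum(axis=0)


def apply_transform(stack: FootprintStack, tf: RigidTransform) -> FootprintStack:
    """Resample every mask of ``stack`` into the reference coordinate frame."""
    out = np.empty_like(stack.masks)
    for i, m in enumerate(stack.masks):
        im = m
        if tf.rotation != 0.0:
            im = _rotate_image(im, tf.rotation, preserve_range=True, order=1)
        im = ndimage.shift(im, (tf.dy, tf.dx), order=1, mode="constant")
        out[i] = np.clip(im, 0.0, None)
    return FootprintStack(out, list(stack.roi_ids), stack.fov_shape)


def align_fovs(stack_a: FootprintStack, stack_b: FootprintStack,
               rotation_search=np.arange(-4.0, 4.01, 0.25),
               upsample_factor: int = 20) -> RigidTransform:
    """Recover the rigid transform taking stack_b into stack_a coordinates.

    Phase cross-correlation of summed-footprint projections over a small grid
    of candidate rotations; the candidate whose shifted projection correlates
    best with the reference wins.  Raises if the best correlation stays below
    a floor (no overlapping content).
    """
    ref = _projection(stack_a)
    mov = _projection(stack_b)
    best = None
    for rot in np.atleast_1d(rotation_search):
        im = _rotate_image(mov, rot, preserve_range=True, order=1) \
            if rot != 0.0 else mov
        # plain cross-correlation: spectral whitening is unstable on sparse
        # blob projections whose cell content partly changes between sessions
        shift, _, _ = phase_cross_correlation(ref, im,
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        aligned = ndimage.shift(im, shift, order=1, mode="constant")
        denom = ref.std() * aligned.std()
        score = float(((ref - ref.mean()) * (aligned - aligned.mean())).mean()
                      / denom) if denom > 0 else -1.0
        if best is None or score > best.score:
            best = RigidTransform(float(shift[0]), float(shift[1]),
                                  float(rot), score)
    if best.score < ALIGNMENT_CORR_FLOOR:
        raise ValueError(
            f"field-of-view alignment failed: best projection correlation "
            f"{best.score:.3f} below floor {ALIGNMENT_CORR_FLOOR}")
    return best


def pair_features(stack_a: FootprintStack, stack_b_aligned: FootprintStack,
                  max_distance: float = DEFAULT_MAX_DISTANCE,
                  support_threshold: float = 1e-3) -> list:
    """Centroid distance and footprint-shape correlation for gated pairs.

    For every cross-session pair whose mass-weighted centroids are within
    ``max_distance`` pixels, the Pearson correlation of the two masks is
    computed over the union of their supports (pixels where either mask
    exceeds ``support_threshold`` of its peak).
    """
    ca = stack_a.centroids()
    cb = stack_b_aligned.centroids()
    feats = []
    for i in range(stack_a.n_rois):
        for j in range(stack_b_aligned.n_rois):
            d = float(np.hypot(*(ca[i] - cb[j])))
            if d > max_distance:
                continue
            ma = stack_a.masks[i]
            mb = stack_b_aligned.masks[j]
            support = (ma > support_threshold * ma.max()) | \
                      (mb > support_threshold * mb.max())
            if support.sum() < 3:
                continue
            x, y = ma[support], mb[support]
            sx, sy = x.std(), y.std()
            corr = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)) \
                if sx > 0 and sy > 0 else 0.0
            feats.append(PairFeature(i, j, stack_a.roi_ids[i],
                                     stack_b_aligned.roi_ids[j], d, corr))
    return feats


def _beta_moments(u: np.ndarray, w: np.ndarray) -> tuple:
    """Method-of-moments beta parameters from weighted data, clipped sane."""
    wsum = w.sum()
    m = float((w * u).sum() / wsum)
    v = float((w * (u - m) ** 2).sum() / wsum)
    m = min(max(m, 1e-3), 1 - 1e-3)
    v = max(v, 1e-6)
    common = max(m * (1 - m) / v - 1.0, 0.1)
    a = np.clip(m * common, 0.05, 1000.0)
    b = np.clip((1 - m) * common, 0.05, 1000.0)
    return float(a), float(b)


def fit_same_cell_model(features, max_iter: int = 500,
                        tol: float = 1e-10) -> SameCellModel:
    """EM fit of the two-component same-cell mixture; P_same per pair.

    Marginals per component: lognormal over centroid distance and beta over
    the correlation mapped to (0, 1).  The component with the smaller mean
    log-distance is identified as the "same cell" component.
    """
    if len(features) < 20:
        raise ValueError("need at least 20 candidate pairs for a stable fit")
    d = np.array([f.distance for f in features], dtype=float)
    r = np.array([f.correlation for f in features], dtype=float)
    if d.std() < 1e-9 and r.std() < 1e-9:
        raise ValueError("degenerate pair features: all pairs identical")
    logd = np.log(np.clip(d, 1e-3, None))
    u = np.clip((r + 1.0) / 2.0, 1e-4, 1.0 - 1e-4)

    # init: near pairs are probably the same cell
    resp = np.where(d <= np.quantile(d, 0.25), 0.95, 0.05)
    resp = np.column_stack([resp, 1.0 - resp])

    prev_ll = -np.inf
    ll = -np.inf
    mu = np.zeros(2)
    sd = np.ones(2)
    ba = np.ones(2)
    bb = np.ones(2)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # M step
        w = resp.sum(axis=0)
        pi = np.clip(w / w.sum(), 1e-6, 1 - 1e-6)
        for k in range(2):
            wk = resp[:, k]
            mu[k] = (wk * logd).sum() / w[k]
            sd[k] = max(np.sqrt((wk * (logd - mu[k]) ** 2).sum() / w[k]), 1e-3)
            ba[k], bb[k] = _beta_moments(u, wk)
        # E step
        logp = np.empty((d.size, 2))
        for k in range(2):
            logp[:, k] = (np.log(pi[k])
                          + stats.norm.logpdf(logd, mu[k], sd[k]) - logd
                          + stats.beta.logpdf(u, ba[k], bb[k]))
        norm = logsumexp(logp, axis=1)
        resp = np.exp(logp - norm[:, None])
        ll = float(norm.sum())
        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            converged = True
            break
        prev_ll = ll
    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(final log-likelihood {ll:.3f})")
    same = int(np.argmin(mu))
    order = [same, 1 - same]
    p_same = resp[:, same]
    sep = abs(mu[same] - mu[1 - same]) / max(sd.max(), 1e-6)
    model = SameCellModel(float(pi[same]), mu[order], sd[order], ba[order],
                          bb[order], p_same, ll, n_iter, converged,
                          degenerate=bool(sep < 0.1))
    if model.degenerate:
        logger.warning("same-cell mixture components barely separated "
                       "(standardized separation %.3f)", sep)
    return model


def register(features, p_same, threshold: float = 0.5,
             transform: RigidTransform = None) -> RegistrationResult:
    """One-to-one assignment of pairs with P_same >= threshold.

    Conflicts are resolved greedily by descending P_same; each ROI is
    consumed at most once.
    """
    p_same = np.asarray(p_same, dtype=float)
    if p_same.shape[0] != len(features):
        raise ValueError("p_same length must match features")
    order = sorted(range(len(features)),
                   key=lambda i: (-p_same[i], features[i].distance))
    used_a, used_b, matches = set(), set(), []
    for i in order:
        f = features[i]
        if p_same[i] < threshold:
            break
        if f.roi_a in used_a or f.roi_b in used_b:
            continue
        used_a.add(f.roi_a)
        used_b.add(f.roi_b)
        matches.append((f.roi_a, f.roi_b, float(p_same[i])))
    all_a = sorted({f.roi_a for f in features})
    all_b = sorted({f.roi_b for f in features})
    return RegistrationResult(
        matches,
        [a for a in all_a if a not in used_a],
        [b for b in all_b if b not in used_b],
        transform, threshold)


def track_sessions(stack_a: FootprintStack, stack_b: FootprintStack,
                   threshold: float = 0.5,
                   max_distance: float = DEFAULT_MAX_DISTANCE) -> tuple:
    """Full tracking chain: align, featurize, fit mixture, register.

    Returns (RegistrationResult, SameCellModel, list of PairFeature).
    """
    tf = align_fovs(stack_a, stack_b)
    aligned = apply_transform(stack_b, tf)
    feats = pair_features(stack_a, aligned, max_distance=max_distance)
    model = fit_same_cell_model(feats)
    result = register(feats, model.p_same, threshold, tf)
    return result, model, feats


# ---------------------------------------------------------------------------
# stability statistics


def _pair_trace_correlation(avg_a: np.ndarray, avg_b: np.ndarray,
                            ia: int, ib: int) -> float:
    """Mean over orientations of the Pearson r between averaged time courses."""
    rs = []
    for k in range(avg_a.shape[0]):
        x, y = avg_a[k, ia], avg_b[k, ib]
        sx, sy = x.std(), y.std()
        rs.append(float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
                  if sx > 0 and sy > 0 else 0.0)
    return float(np.mean(rs))


def stability_statistics(tensor_a: ResponseTensor, tensor_b: ResponseTensor,
                         tuning_a: pd.DataFrame, tuning_b: pd.DataFrame,
                         result: RegistrationResult, seed: int = 0,
                         corr_window_ms=DEFAULT_WINDOWS["correlation"],
                         shuffled_pair_factor: int = 10,
                         n_orientation_shuffles: int = 10_000,
                         bin_width_deg: float = 10.0) -> dict:
    """Response-stability report for registered cross-session pairs.

    Components of the returned dict:

    - ``trace_correlation``: per-pair mean-over-orientations Pearson r of
      trial-averaged 0–2000 ms time courses, its shuffled-pair counterpart
      (``shuffled_pair_factor`` x the pair count) and the two-sample t-test.
    - ``osi_correlation``: Pearson r of OSI across pairs responsive in both
      sessions.
    - ``orientation_difference``: 10°-bin histogram of absolute preferred-
      orientation differences, the shuffled-pair expected counts (shuffle
      repeated ``n_orientation_shuffles`` times, counts divided by that
      number), the uniform chance level, a KS test against Uniform(0°, 90°)
      and a KS test against an exponential curve fitted to the observed bin
      proportions.

    With fewer than 3 pairs responsive in both sessions the tuning-stability
    statistics are suppressed with a notice.
    """
    rng = np.random.default_rng(seed)
    idx_a = {rid: i for i, rid in enumerate(tensor_a.roi_ids)}
    idx_b = {rid: i for i, rid in enumerate(tensor_b.roi_ids)}
    pairs = [(a, b) for a, b, _ in result.matches]
    if not pairs:
        return {"n_pairs": 0, "suppressed": True,
                "notice": "no registered pairs"}

    oris_a, avg_a = orientation_averages(tensor_a, corr_window_ms)
    oris_b, avg_b = orientation_averages(tensor_b, corr_window_ms)
    if not np.array_equal(oris_a, oris_b):
        raise ValueError("sessions present different orientation sets")

    obs = np.array([_pair_trace_correlation(avg_a, avg_b, idx_a[a], idx_b[b])
                    for a, b in pairs])
    n_pairs = len(pairs)
    n_shuffled = shuffled_pair_factor * n_pairs
    ia_all = np.array([idx_a[a] for a, _ in pairs])
    ib_all = np.array([idx_b[b] for _, b in pairs])
    shuf = np.empty(n_shuffled)
    for s in range(n_shuffled):
        i = int(rng.integers(n_pairs))
        j = int(rng.integers(n_pairs - 1))
        if j >= i:
            j += 1  # mismatched pairing
        shuf[s] = _pair_trace_correlation(avg_a, avg_b, ia_all[i], ib_all[j])
    tt = stats.ttest_ind(obs, shuf)
    report = {
        "n_pairs": n_pairs,
        "suppressed": False,
        "trace_correlation": {
            "observed_mean": float(obs.mean()),
            "observed": obs.tolist(),
            "shuffled_mean": float(shuf.mean()),
            "t_statistic": float(tt.statistic),
            "p_value": float(tt.pvalue),
            "df": n_pairs + n_shuffled - 2,
        },
    }

    both = [(a, b) for a, b in pairs
            if bool(tuning_a.loc[a, "responsive"])
            and bool(tuning_b.loc[b, "responsive"])
            and np.isfinite(tuning_a.loc[a, "preferred_orientation"])
            and np.isfinite(tuning_b.loc[b, "preferred_orientation"])]
    report["n_pairs_responsive_both"] = len(both)
    if len(both) < 3:
        report["suppressed"] = True
        report["notice"] = ("fewer than 3 pairs responsive in both sessions; "
                            "tuning-stability statistics suppressed")
        return report

    osi_a = np.array([tuning_a.loc[a, "osi"] for a, _ in both])
    osi_b = np.array([tuning_b.loc[b, "osi"] for _, b in both])
    pr = stats.pearsonr(osi_a, osi_b)
    report["osi_correlation"] = {"r": float(pr.statistic),
                                 "p_value": float(pr.pvalue),
                                 "n": len(both)}

    pref_a = np.array([tuning_a.loc[a, "preferred_orientation"] for a, _ in both])
    pref_b = np.array([tuning_b.loc[b, "preferred_orientation"] for _, b in both])
    diffs = np.array([orientation_difference(x, y)
                      for x, y in zip(pref_a, pref_b)])
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    obs_counts, _ = np.histogram(diffs, bins=edges)

    shuf_counts = np.zeros(edges.size - 1)
    for _ in range(n_orientation_shuffles):
        perm = rng.permutation(len(both))
        sd = [orientation_difference(pref_a[i], pref_b[perm[i]])
              for i in range(len(both))]
        c, _ = np.histogram(sd, bins=edges)
        shuf_counts += c
    shuf_expected = shuf_counts / n_orientation_shuffles

    ks_u = ks_uniform(diffs)
    ks_e = ks_fitted_exponential(diffs, edges, obs_counts)
    report["orientation_difference"] = {
        "bin_edges": edges.tolist(),
        "observed_counts": obs_counts.tolist(),
        "shuffled_expected_counts": shuf_expected.tolist(),
        "chance_level": len(both) / (edges.size - 1),
        "ks_uniform": ks_u,
        "ks_exponential": ks_e,
    }
    return report


def ks_uniform(diffs: np.ndarray, upper: float = 90.0) -> dict:
    """KS test of the differences against the theoretical Uniform(0, upper)."""
    res = stats.kstest(np.asarray(diffs, dtype=float),
                       stats.uniform(loc=0.0, scale=upper).cdf)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def ks_fitted_exponential(diffs: np.ndarray, edges: np.ndarray,
                          counts: np.ndarray, n_reference: int = 1000) -> dict:
    """KS test against an exponential curve fitted to the bin proportions.

    An exponential ``A exp(-x / tau)`` is least-squares fitted to the observed
    histogram proportions at the bin centers; the comparison sample is a
    deterministic quantile draw from the fitted exponential truncated to the
    histogram range.  (Fitting and testing on the same data biases this test
    toward non-rejection; it is reported as described, with that caveat.)
    """
    diffs = np.asarray(diffs, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    props = counts / max(counts.sum(), 1)
    try:
        (amp, tau), _ = optimize.curve_fit(
            lambda x, a, t: a * np.exp(-x / t), centers, props,
            p0=(props.max() if props.max() > 0 else 1.0, 30.0),
            bounds=((1e-9, 1e-3), (np.inf, 1e6)), maxfev=10_000)
    except RuntimeError:
        return {"statistic": float("nan"), "p_value": float("nan"),
                "tau": float("nan"), "note": "exponential fit failed"}
    upper = float(edges[-1])
    q = (np.arange(n_reference) + 0.5) / n_reference
    # inverse CDF of the exponential truncated to [0, upper]
    mass = 1.0 - np.exp(-upper / tau)
    ref = -tau * np.log(1.0 - q * mass)
    res = stats.ks_2samp(diffs, ref)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "tau": float(tau), "amplitude": float(amp)}
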