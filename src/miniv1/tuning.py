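"""Stimulus responsiveness, orientation selectivity and preferred orientation.

The orientation selectivity index is the resultant-vector length of the
per-orientation responses R(θ) in the doubled angle:

    OSI = |Σ R(θ) e^{i 2θ}| / Σ R(θ)

computed after adding a constant so the minimum response is zero (responses
are in z-units and can be negative).  Because some ROIs are suppressed by the
stimulus, a negative branch repeats the computation on -R; the branch with
the larger OSI wins and its sign is reported.  OSI is 1 for a cell that
responds to exactly one orientation and 0 for a flat tuning curve; it equals
one minus the circular variance in the doubled angle.  The preferred
orientation is half the argument of the winning branch's resultant vector,
wrapped to [-90°, 90°).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DEFAULT_WINDOWS, ResponseTensor
from .extraction import orientation_averages, window_stat


def _branch_resultant(responses: np.ndarray, theta_rad: np.ndarray) -> tuple:
    """(osi, resultant complex) for one branch after the min-to-zero shift."""
    shifted = responses - responses.min()
    total = shifted.sum()
    if total <= 0:  # all responses equal: no selectivity to measure
        return 0.0, 0j
    resultant = np.sum(shifted * np.exp(2j * theta_rad))
    return float(abs(resultant) / total), resultant


def compute_osi(per_orientation_response, orientations_deg) -> tuple:
    """OSI and winning sign for one ROI.

    Evaluates the positive branch on R and the negative branch on -R (each
    shifted so its minimum is zero) and returns ``(osi, osi_sign)`` for the
    branch with the larger OSI (ties go to the positive branch).
    """
    r = np.asarray(per_orientation_response, dtype=float)
    theta = np.radians(np.asarray(orientations_deg, dtype=float))
    if r.shape != theta.shape:
        raise ValueError("responses and orientations must have equal length")
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite response values")
    osi_pos, _ = _branch_resultant(r, theta)
    osi_neg, _ = _branch_resultant(-r, theta)
    if osi_neg > osi_pos:
        return osi_neg, -1
    return osi_pos, 1


def preferred_orientation(per_orientation_response, orientations_deg) -> float:
    """Preferred orientation in degrees in [-90, 90), from the winning branch.

    Half the argument of the resultant vector Σ R e^{i2θ} of the shifted
    responses.  Returns NaN when the shifted responses are all zero (a flat
    tuning curve has no preferred orientation; such ROIs are excluded from
    preferred-orientation analyses).
    """
    r = np.asarray(per_orientation_response, dtype=float)
    theta = np.radians(np.asarray(orientations_deg, dtype=float))
    _, sign = compute_osi(r, orientations_deg)
    _, resultant = _branch_resultant(sign * r, theta)
    if resultant == 0:
        return float("nan")
    ang = 0.5 * np.angle(resultant)  # radians, in (-pi/2, pi/2]
    deg = np.degrees(ang)
    return float((deg + 90.0) % 180.0 - 90.0)


def orientation_difference(a: float, b: float) -> float:
    """Absolute preferred-orientation difference on the 180°-periodic circle.

    Result is in [0, 90] degrees.
    """
    d = abs(a - b) % 180.0
    return float(min(d, 180.0 - d))


def responsiveness_test(tensor: ResponseTensor, alpha: float = 0.05,
                        baseline_ms=DEFAULT_WINDOWS["baseline_test"],
                        response_ms=DEFAULT_WINDOWS["response_mean"]) -> pd.DataFrame:
    """Bonferroni-corrected per-orientation stimulus-responsiveness test.

    For each ROI and orientation, per-trial means of the pre-stimulus
    baseline (-1000..0 ms) are compared with per-trial means of the
    post-stimulus period (500..1500 ms) by a two-sided two-sample t-test; the
    ROI is responsive if any orientation is significant at alpha divided by
    the number of orientations.

    Returns a DataFrame indexed by roi_id with columns ``responsive`` (bool),
    ``min_p`` and ``n_significant_orientations``.
    """
    base = window_stat(tensor, baseline_ms, "mean")
    post = window_stat(tensor, response_ms, "mean")
    labels = tensor.trial_meta["orientation"].to_numpy()
    oris = np.sort(np.unique(labels))
    n_ori = oris.size
    pvals = np.ones((tensor.n_rois, n_ori))
    for k, ori in enumerate(oris):
        sel = labels == ori
        if sel.sum() < 2:
            raise ValueError(f"fewer than 2 trials for orientation {ori}")
        b, p = base[:, sel], post[:, sel]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(b, p, axis=1)
        pv = np.asarray(res.pvalue)
        if np.any(~np.isfinite(pv)):
            warnings.warn("zero-variance ROI/orientation group; treated as "
                          "non-significant")
            pv = np.where(np.isfinite(pv), pv, 1.0)
        pvals[:, k] = pv
    sig = pvals < alpha / n_ori
    return pd.DataFrame(
        {
            "responsive": sig.any(axis=1),
            "min_p": pvals.min(axis=1),
            "n_significant_orientations": sig.sum(axis=1),
        },
        index=pd.Index(tensor.roi_ids, name="roi_id"),
    )


def compute_tuning(tensor: ResponseTensor, alpha: float = 0.05,
                   peak_window_ms=DEFAULT_WINDOWS["response_peak"]) -> pd.DataFrame:
    """Full per-ROI tuning table.

    R(θ) is the signed peak of the trial-averaged response time course within
    the 500..1500 ms post-stimulus window, per orientation.  Columns:
    responsive, per-orientation peaks (``peak_<θ>``), osi, osi_sign,
    preferred_orientation (NaN for flat curves).
    """
    resp = responsiveness_test(tensor, alpha=alpha)
    oris, avg = orientation_averages(tensor, window_ms=peak_window_ms)
    peaks = avg.max(axis=2)  # orientations x ROIs, signed maximum
    rows = []
    for j, roi in enumerate(tensor.roi_ids):
        r = peaks[:, j]
        osi, sign = compute_osi(r, oris)
        pref = preferred_orientation(r, oris)
        row = {"roi_id": roi, "responsive": bool(resp["responsive"].iloc[j]),
               "osi": osi, "osi_sign": sign, "preferred_orientation": pref}
        row.update({f"peak_{ori:g}": r[k] for k, ori in enumerate(oris)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi_id")
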