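"""Receptive-field identification on the 15-position mapping grid.

One representative ROI per hemisphere (cells seen through one lens share
nearly the same receptive field) is tested with the Tukey–Kramer honest
significant difference procedure across the 15 position groups, using the
per-trial mean response in the 500–1500 ms post-stimulus window.  The
position with the strongest mean response is accepted as the receptive field
only if it differs significantly from every non-neighboring position, where
neighbors are the 8-connected lattice positions (ring ± 1, azimuth ± 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import RectBivariateSpline

from .containers import DEFAULT_WINDOWS, ResponseTensor
from .extraction import window_stat
from .grids import StimulusGrid
from .tuning import responsiveness_test


@dataclass
class RFResult:
    best_position: int
    mean_response_by_position: np.ndarray  # indexed by position-1
    pairwise_significant: np.ndarray  # (n_positions, n_positions) bool
    pairwise_p: np.ndarray  # NaN where not evaluated
    passed: bool
    roi_id: object = None
    alpha: float = 0.05


def select_representative_roi(tensor: ResponseTensor, alpha: float = 0.05) -> int:
    """Index of the ROI responding to the most orientations.

    Mirrors the practice of analyzing one representative ROI per hemisphere
    that shows stimulus responses to many orientations; ties are broken by
    the larger mean response in the 500–1500 ms window.
    """
    resp = responsiveness_test(tensor, alpha=alpha)
    counts = resp["n_significant_orientations"].to_numpy()
    means = window_stat(tensor, DEFAULT_WINDOWS["response_mean"],
                        "mean").mean(axis=1)
    order = np.lexsort((means, counts))
    return int(order[-1])


def tukey_kramer_p(values: np.ndarray, groups: np.ndarray,
                   pairs) -> np.ndarray:
    """Tukey–Kramer p-values for the requested group pairs.

    The honest-significant-difference test on the studentized range, with
    the Kramer adjustment for unequal group sizes: for groups i, j with
    means m, sizes n and pooled within-group mean square s2 on N - k degrees
    of freedom,  q = |m_i - m_j| / sqrt(s2/2 * (1/n_i + 1/n_j)).
    """
    uniq, inv = np.unique(groups, return_inverse=True)
    k = uniq.size
    n = np.bincount(inv)
    if np.any(n < 2):
        raise ValueError("every group needs at least 2 observations")
    sums = np.bincount(inv, weights=values)
    means = sums / n
    ss_within = float(np.sum((values - means[inv]) ** 2))
    df = values.size - k
    s2 = ss_within / df
    gi = np.array([np.searchsorted(uniq, a) for a, _ in pairs])
    gj = np.array([np.searchsorted(uniq, b) for _, b in pairs])
    se = np.sqrt(s2 / 2.0 * (1.0 / n[gi] + 1.0 / n[gj]))
    q = np.abs(means[gi] - means[gj]) / se
    return np.asarray(stats.studentized_range.sf(q, k, df), dtype=float)


def rf_position_test(tensor: ResponseTensor, grid: StimulusGrid = None,
                     alpha: float = 0.05, roi_index: int = None,
                     response_ms=DEFAULT_WINDOWS["response_mean"],
                     pairwise: str = "full") -> RFResult:
    """Tukey–Kramer receptive-field localization for one ROI.

    Per-trial 500–1500 ms mean responses are grouped by stimulus position and
    compared pairwise with the Tukey–Kramer test at level ``alpha`` (the
    procedure tolerates unequal group sizes).  ``passed`` is true iff the
    argmax position differs significantly from every non-neighbor position.

    ``pairwise="full"`` evaluates all position pairs; ``pairwise="best"``
    evaluates only the pairs involving the argmax position (sufficient for
    the pass decision and much cheaper; the studentized-range tail costs are
    per pair).
    """
    grid = grid or StimulusGrid()
    if pairwise not in ("full", "best"):
        raise ValueError("pairwise must be 'full' or 'best'")
    if roi_index is None:
        roi_index = select_representative_roi(tensor, alpha=alpha)
    vals = window_stat(tensor, response_ms, "mean")[roi_index]
    groups = tensor.trial_meta["position"].to_numpy().astype(int)
    present = np.unique(groups)
    if present.size < 2:
        raise ValueError("need at least 2 position groups")

    n = grid.n_positions
    means = np.full(n, np.nan)
    for pos in present:
        means[pos - 1] = vals[groups == pos].mean()
    best = int(np.nanargmax(means) + 1)

    if pairwise == "full":
        pairs = [(a, b) for i, a in enumerate(present)
                 for b in present[i + 1:]]
    else:
        pairs = [(min(best, p), max(best, p)) for p in present if p != best]
    pvals = tukey_kramer_p(vals, groups, pairs)
    pmat = np.full((n, n), np.nan)
    sig = np.zeros((n, n), dtype=bool)
    for (a, b), p in zip(pairs, pvals):
        pmat[a - 1, b - 1] = pmat[b - 1, a - 1] = p
        sig[a - 1, b - 1] = sig[b - 1, a - 1] = p < alpha

    passed = all(
        sig[best - 1, pos - 1]
        for pos in present
        if pos != best and not grid.are_neighbors(best, pos))
    return RFResult(best, means, sig, pmat, passed,
                    tensor.roi_ids[roi_index], alpha)


def rf_surface(result: RFResult, grid: StimulusGrid = None,
               upsample: int = 41) -> tuple:
    """Smooth interpolated response surface over (azimuth, eccentricity).

    Spline interpolation of the 3 x 5 mean-response lattice onto a finer
    grid, for visualization only — never used in downstream statistics.
    Returns (azimuth_grid, eccentricity_grid, surface).
    """
    grid = grid or StimulusGrid()
    n_ring = len(grid.eccentricities)
    n_az = len(grid.clock_positions)
    z = np.asarray(result.mean_response_by_position, dtype=float).reshape(
        n_ring, n_az)
    if np.any(np.isnan(z)):
        raise ValueError("surface requires responses at all grid positions")
    ecc = np.asarray(grid.eccentricities, dtype=float)
    az = np.arange(n_az, dtype=float)
    spline = RectBivariateSpline(ecc, az, z, kx=min(2, n_ring - 1),
                                 ky=min(3, n_az - 1))
    ecc_f = np.linspace(ecc[0], ecc[-1], upsample)
    az_f = np.linspace(az[0], az[-1], upsample)
    return az_f, ecc_f, spline(ecc_f, az_f)
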