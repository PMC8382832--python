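"""Trace normalization, trial alignment and windowed response statistics.

Traces are z-scored against the mean and standard deviation of the entire
recording session, aligned to stimulus onsets at the native frame rate
(nearest-frame assignment, no interpolation), and baseline-corrected by
subtracting the mean of the -500..0 ms pre-stimulus window per ROI and trial.
Only successful trials enter any analysis.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import DEFAULT_WINDOWS, ResponseTensor, TraceMatrix

logger = logging.getLogger(__name__)


def zscore_session(traces: TraceMatrix) -> TraceMatrix:
    """Normalize each ROI trace by its whole-session mean and sd.

    Constant-trace ROIs carry no signal and cannot be normalized; they are
    excluded from the output with a warning rather than propagating NaNs.
    Raises if fewer than 2 frames or if every ROI is constant.
    """
    if traces.n_frames < 2:
        raise ValueError("need at least 2 frames to z-score")
    sd = traces.values.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all ROI traces are constant; nothing to normalize")
    if not np.all(keep):
        dropped = [traces.roi_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"excluding constant-trace ROIs: {dropped}")
    vals = traces.values[:, keep]
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    ids = [rid for rid, k in zip(traces.roi_ids, keep) if k]
    return TraceMatrix(z, traces.times.copy(), ids)


def align_trials(traces: TraceMatrix, trials: pd.DataFrame,
                 pre_s: float = 1.0, post_s: float = 2.0,
                 baseline_ms=DEFAULT_WINDOWS["baseline_subtract"]) -> ResponseTensor:
    """Cut trial-aligned snippets and subtract the pre-stimulus baseline.

    For every successful trial, frames within [onset - pre_s, onset + post_s]
    are assigned to a common relative-time grid at the native frame rate (the
    onset maps to the nearest frame).  The mean of the ``baseline_ms`` window
    is subtracted per ROI x trial.  Trials whose window is truncated by the
    session edge are dropped with a log entry.
    """
    fr = traces.frame_rate
    n_pre = int(round(pre_s * fr))
    n_post = int(round(post_s * fr))
    rel_time = np.arange(-n_pre, n_post + 1) / fr

    use = trials[trials["success"].astype(bool)]
    snippets, meta_rows = [], []
    for row in use.itertuples(index=False):
        onset_idx = int(np.argmin(np.abs(traces.times - row.onset_s)))
        lo, hi = onset_idx - n_pre, onset_idx + n_post + 1
        if lo < 0 or hi > traces.n_frames:
            logger.info("dropping trial %s: window truncated by session edge",
                        row.trial_id)
            continue
        snippets.append(traces.values[lo:hi, :].T)  # ROIs x bins
        meta_rows.append((row.trial_id, row.orientation, row.position))
    if not snippets:
        raise ValueError("no trial fits inside the session")

    values = np.stack(snippets, axis=1)  # ROIs x trials x bins
    meta = pd.DataFrame(meta_rows, columns=["trial_id", "orientation",
                                            "position"])
    tensor = ResponseTensor(values, rel_time, meta, list(traces.roi_ids))
    base = tensor.bin_mask(baseline_ms)
    if not base.any():
        raise ValueError("baseline window contains no frames")
    tensor.values -= tensor.values[:, :, base].mean(axis=2, keepdims=True)
    return tensor


def window_stat(tensor: ResponseTensor, window_ms, stat: str = "mean") -> np.ndarray:
    """Windowed statistic per ROI x trial.

    ``stat="mean"`` averages over bins whose rel_time lies in [start, end) ms;
    ``stat="peak"`` takes the signed maximum (most-positive value) there.
    """
    mask = tensor.bin_mask(window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms holds no frames after "
                         "quantization")
    sub = tensor.values[:, :, mask]
    if stat == "mean":
        return sub.mean(axis=2)
    if stat == "peak":
        return sub.max(axis=2)
    raise ValueError("stat must be 'mean' or 'peak'")


def orientation_averages(tensor: ResponseTensor, window_ms=None) -> tuple:
    """Trial-averaged time courses per ROI and orientation.

    Returns (orientations, array of shape (n_orientations, n_rois, n_bins)),
    optionally restricted to bins inside ``window_ms``.
    """
    oris = np.sort(tensor.trial_meta["orientation"].unique())
    if window_ms is not None:
        mask = tensor.bin_mask(window_ms)
    else:
        mask = np.ones(tensor.rel_time.size, dtype=bool)
    out = np.empty((oris.size, tensor.n_rois, int(mask.sum())))
    labels = tensor.trial_meta["orientation"].to_numpy()
    for i, ori in enumerate(oris):
        sel = labels == ori
        out[i] = tensor.values[:, sel, :][:, :, mask].mean(axis=1)
    return oris, out
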