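"""Core in-memory containers shared across the pipeline.

The working signal unit throughout is the session-normalized fluorescence
(z-units of the per-session ΔF/F0 trace); traces arrive already extracted,
one column per ROI (putative neuron).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Analysis windows in ms relative to stimulus onset.  Two baselines coexist
#: deliberately: the -500..0 ms window is subtracted trial-by-trial when the
#: response tensor is built, while the -1000..0 ms window serves as the
#: baseline side of the per-orientation responsiveness test.
DEFAULT_WINDOWS = {
    "baseline_subtract": (-500.0, 0.0),
    "baseline_test": (-1000.0, 0.0),
    "response_mean": (500.0, 1500.0),
    "response_peak": (500.0, 1500.0),
    "correlation": (0.0, 2000.0),
}


@dataclass
class TraceMatrix:
    """Session-long fluorescence traces, frames x ROIs.

    Attributes
    ----------
    values : ndarray, shape (n_frames, n_rois)
        Fluorescence signal (ΔF/F0 or z-units after :func:`zscore_session`).
    times : ndarray, shape (n_frames,)
        Frame timestamps in seconds, strictly increasing.
    roi_ids : list of int
        Identifier per column.
    """

    values: np.ndarray
    times: np.ndarray
    roi_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace values must be 2D (frames x ROIs)")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times length must match number of frames")
        if len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length must match number of columns")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timebase must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class ResponseTensor:
    """Trial-aligned, baseline-subtracted responses: ROIs x trials x time bins.

    ``rel_time`` is in seconds with 0 at stimulus onset.  ``trial_meta`` keeps
    one row per retained trial (orientation, position, trial_id).
    """

    values: np.ndarray
    rel_time: np.ndarray
    trial_meta: pd.DataFrame
    roi_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.rel_time = np.asarray(self.rel_time, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3D (ROIs x trials x bins)")
        if self.values.shape[2] != self.rel_time.shape[0]:
            raise ValueError("rel_time length must match bin count")
        if self.values.shape[1] != len(self.trial_meta):
            raise ValueError("trial_meta rows must match trial count")
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("roi_ids length must match ROI count")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def bin_mask(self, window_ms) -> np.ndarray:
        """Boolean mask of bins whose rel_time falls in [start, end) ms."""
        start, end = window_ms
        t_ms = self.rel_time * 1000.0
        return (t_ms >= start) & (t_ms < end)


@dataclass
class FootprintStack:
    """Per-ROI spatial footprints: non-negative weight images in a shared FOV."""

    masks: np.ndarray  # (n_rois, height, width)
    roi_ids: list
    fov_shape: tuple = field(default=None)

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=float)
        if self.masks.ndim != 3:
            raise ValueError("masks must be 3D (ROIs x height x width)")
        if self.fov_shape is None:
            self.fov_shape = self.masks.shape[1:]
        if tuple(self.fov_shape) != self.masks.shape[1:]:
            raise ValueError("all masks must share fov_shape")
        if np.any(self.masks < 0):
            raise ValueError("footprint masks must be non-negative")
        if len(self.roi_ids) != self.masks.shape[0]:
            raise ValueError("roi_ids length must match mask count")
        if self.masks.shape[0] and np.any(self.masks.sum(axis=(1, 2)) <= 0):
            raise ValueError("each footprint must have positive total mass")

    @property
    def n_rois(self) -> int:
        return self.masks.shape[0]

    def centroids(self) -> np.ndarray:
        """Mass-weighted centers of gravity, (n_rois, 2) in (row, col) pixels."""
        n, h, w = self.masks.shape
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        mass = self.masks.sum(axis=(1, 2))
        cy = (self.masks * rows).sum(axis=(1, 2)) / mass
        cx = (self.masks * cols).sum(axis=(1, 2)) / mass
        return np.column_stack([cy, cx])
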