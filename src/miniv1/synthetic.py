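"""Ground-truth-labeled synthetic sessions.

Generates fluorescence traces, spatial footprints and trial tables with the
statistical structure the downstream analysis assumes: a fixation task in
which an oriented Gabor patch (6 orientations: -90°, -60°, -30°, 0°, 30°,
60°) flashes for 300 ms, 500 ms after fixation onset, at one of 15 grid
positions, followed by a 4000 ± 1000 ms inter-trial interval.  Cells carry a
von Mises orientation-tuning curve in the doubled angle (180° period), a
Gaussian receptive-field falloff on the stimulus grid, and GCaMP6s-like slow
double-exponential response kinetics.

Paired sessions for cross-day tracking are derived by rigidly transforming
the field of view, jittering centroids, dropping/adding cells and drifting
preferred orientations, with the true correspondence returned alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import FootprintStack, TraceMatrix
from .grids import StimulusGrid, rf_attenuation

ORIENTATIONS_DEG = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0)

# Task timing (ms) fixed by the behavioral design.
FIXATION_TO_ONSET_MS = 500.0
STIMULUS_DURATION_MS = 300.0
ITI_MEAN_MS = 4000.0
ITI_JITTER_MS = 1000.0

DEFAULT_FRAME_RATE = 10.0  # fps; top of the 6-10 fps acquisition range
KERNEL_RISE_S = 0.2   # GCaMP6s-like indicator kinetics
KERNEL_DECAY_S = 1.0

_SESSION_PAD_S = 1.5   # leading pad so the first trial's 1-s baseline exists
_SESSION_TAIL_S = 4.0  # trailing pad covering the last response + decay


@dataclass
class GroundTruthCell:
    """Latent parameters of one simulated neuron.

    preferred_orientation is in degrees in [-90, 90); tuning_concentration is
    the von Mises concentration in the doubled angle (0 = untuned);
    response_gain is the noise-free peak ΔF/F0 amplitude at the preferred
    orientation inside the receptive field; response_sign of -1 models ROIs
    whose fluorescence is suppressed by the stimulus.
    """

    cell_id: int
    centroid: tuple  # (x, y) pixels
    footprint_sigma: float
    rf_position: int
    preferred_orientation: float
    tuning_concentration: float
    response_gain: float
    response_sign: int = 1
    baseline_rate: float = 0.0

    def __post_init__(self):
        if not -90.0 <= self.preferred_orientation < 90.0:
            raise ValueError("preferred_orientation must lie in [-90, 90)")
        if self.tuning_concentration < 0:
            raise ValueError("tuning_concentration must be >= 0")
        if self.response_sign not in (-1, 1):
            raise ValueError("response_sign must be +1 or -1")

    def tuning_factor(self, orientation_deg: float) -> float:
        """Von Mises factor in doubled angle, 1 at the preferred orientation."""
        d = math.radians(orientation_deg - self.preferred_orientation)
        return math.exp(self.tuning_concentration * (math.cos(2.0 * d) - 1.0))


@dataclass
class SessionBundle:
    """One simulated session plus its ground truth and generation parameters."""

    traces: TraceMatrix
    footprints: FootprintStack
    trials: pd.DataFrame
    truth: list
    seed: int
    params: dict = field(default_factory=dict)
    correspondence: dict = None  # prior-session cell_id -> this-session cell_id


def generate_trial_table(n_reps_per_condition: int,
                         positions,
                         orientations=ORIENTATIONS_DEG,
                         frame_rate: float = DEFAULT_FRAME_RATE,
                         iti_mean_ms: float = ITI_MEAN_MS,
                         iti_jitter_ms: float = ITI_JITTER_MS,
                         seed: int = 0,
                         failure_rate: float = 0.0) -> pd.DataFrame:
    """Build a trial table with conditions interleaved in sequence.

    Each repetition round cycles through every position, presenting the full
    orientation sequence at each, so every (position, orientation) condition
    receives exactly ``n_reps_per_condition`` trials.  The stimulus appears
    500 ms after fixation start; the inter-trial interval is drawn uniformly
    from mean ± jitter.

    Returns a DataFrame with columns trial_id, fix_start_s, onset_s,
    orientation, position, success.
    """
    if n_reps_per_condition < 1:
        raise ValueError("n_reps_per_condition must be >= 1")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    orientations = list(orientations)
    positions = list(positions)
    if not orientations:
        raise ValueError("orientation list must not be empty")
    if not positions:
        raise ValueError("position list must not be empty")

    rng = np.random.default_rng(seed)
    rows = []
    t = _SESSION_PAD_S  # fixation start of the first trial
    trial_id = 0
    for _ in range(n_reps_per_condition):
        for pos in positions:
            for ori in orientations:
                onset = t + FIXATION_TO_ONSET_MS / 1000.0
                success = bool(rng.random() >= failure_rate)
                rows.append((trial_id, t, onset, float(ori), int(pos), success))
                iti = rng.uniform(iti_mean_ms - iti_jitter_ms,
                                  iti_mean_ms + iti_jitter_ms) / 1000.0
                t = onset + STIMULUS_DURATION_MS / 1000.0 + iti
                trial_id += 1
    return pd.DataFrame(
        rows,
        columns=["trial_id", "fix_start_s", "onset_s", "orientation",
                 "position", "success"],
    )


def response_kernel(frame_rate: float, rise_s: float = KERNEL_RISE_S,
                    decay_s: float = KERNEL_DECAY_S) -> np.ndarray:
    """Unit-peak double-exponential response kernel sampled on the frame grid."""
    if not (decay_s > rise_s > 0):
        raise ValueError("require decay > rise > 0")
    t_end = decay_s * 8.0
    t = np.arange(0.0, t_end, 1.0 / frame_rate)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def evoked_amplitude(cell: GroundTruthCell, orientation_deg: float,
                     position: int, grid: StimulusGrid) -> float:
    """Noise-free evoked peak amplitude for one trial."""
    return (cell.response_sign * cell.response_gain
            * cell.tuning_factor(orientation_deg)
            * rf_attenuation(grid, position, cell.rf_position))


def simulate_traces(cells, trials: pd.DataFrame,
                    frame_rate: float = DEFAULT_FRAME_RATE,
                    kernel_rise_s: float = KERNEL_RISE_S,
                    kernel_decay_s: float = KERNEL_DECAY_S,
                    noise_sd: float = 0.1,
                    seed: int = 0,
                    grid: StimulusGrid = None) -> TraceMatrix:
    """Render session-long ΔF/F0 traces for a list of cells.

    Each trial contributes ``evoked_amplitude`` times the unit-peak kernel,
    placed at the frame nearest the stimulus onset; i.i.d. Gaussian noise of
    sd ``noise_sd`` is added per frame.  Deterministic given ``seed``.
    """
    if not 1.0 <= frame_rate <= 100.0:
        raise ValueError("frame_rate must be within [1, 100] fps")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = grid or StimulusGrid()
    kernel = response_kernel(frame_rate, kernel_rise_s, kernel_decay_s)

    # tail long enough that the kernel of the last trial is never truncated
    tail = max(_SESSION_TAIL_S, kernel.size / frame_rate + 0.5)
    duration = float(trials["onset_s"].max()) + tail
    n_frames = int(math.ceil(duration * frame_rate))
    if n_frames > 50_000_000:
        raise ValueError("trial table extends beyond representable duration")
    times = np.arange(n_frames) / frame_rate

    rng = np.random.default_rng(seed)
    values = np.zeros((n_frames, len(cells)))
    onset_idx = np.rint(trials["onset_s"].to_numpy() * frame_rate).astype(int)
    for j, cell in enumerate(cells):
        col = values[:, j]
        for idx, ori, pos in zip(onset_idx, trials["orientation"],
                                 trials["position"]):
            amp = evoked_amplitude(cell, float(ori), int(pos), grid)
            stop = min(idx + kernel.size, n_frames)
            col[idx:stop] += amp * kernel[: stop - idx]
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    return TraceMatrix(values, times, [c.cell_id for c in cells])


def generate_footprints(cells, fov_shape) -> FootprintStack:
    """One unit-peak 2D Gaussian blob per cell, ordered by cell_id.

    Footprints must lie fully inside the field of view (centroid at least
    3 sigma from every edge).
    """
    h, w = int(fov_shape[0]), int(fov_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("fov_shape must be positive")
    cells = sorted(cells, key=lambda c: c.cell_id)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    masks = np.empty((len(cells), h, w), dtype=np.float32)
    for i, cell in enumerate(cells):
        cx, cy = cell.centroid
        s = cell.footprint_sigma
        if not (3 * s <= cx <= w - 1 - 3 * s and 3 * s <= cy <= h - 1 - 3 * s):
            raise ValueError(
                f"cell {cell.cell_id}: footprint (centroid ({cx:.1f}, {cy:.1f}),"
                f" sigma {s:.1f}) does not fit inside the {h}x{w} field of view")
        masks[i] = np.exp(-((cols - cx) ** 2 + (rows - cy) ** 2) / (2.0 * s ** 2))
    return FootprintStack(masks, [c.cell_id for c in cells], (h, w))


def random_cells(n_cells: int, fov_shape, seed: int,
                 rf_position: int = 9,
                 footprint_sigma: float = 3.0,
                 gain_range=(0.8, 2.0),
                 concentration_range=(0.0, 3.0),
                 negative_fraction: float = 0.1,
                 min_separation: float = 6.0,
                 grid: StimulusGrid = None) -> list:
    """Draw a population of cells with realistic tuning diversity.

    Preferred orientations are uniform on [-90, 90); concentrations uniform on
    ``concentration_range`` (so measured OSIs span weak to strong selectivity,
    as observed populations do); a small fraction responds negatively.  All
    cells share ``rf_position``, emulating the near-identical receptive fields
    seen within one lens's field of view.  Centroids are rejection-sampled to
    keep at least ``min_separation`` pixels between cells.
    """
    rng = np.random.default_rng(seed)
    h, w = int(fov_shape[0]), int(fov_shape[1])
    margin = 3.0 * footprint_sigma + 1.0
    centroids = []
    attempts = 0
    while len(centroids) < n_cells:
        attempts += 1
        if attempts > 10_000 * max(n_cells, 1):
            raise ValueError("cannot place cells with requested separation")
        c = (rng.uniform(margin, w - 1 - margin),
             rng.uniform(margin, h - 1 - margin))
        if all(math.hypot(c[0] - o[0], c[1] - o[1]) >= min_separation
               for o in centroids):
            centroids.append(c)
    cells = []
    for i, c in enumerate(centroids):
        sign = -1 if rng.random() < negative_fraction else 1
        cells.append(GroundTruthCell(
            cell_id=i,
            centroid=c,
            footprint_sigma=footprint_sigma,
            rf_position=rf_position,
            preferred_orientation=float(rng.uniform(-90.0, 90.0)),
            tuning_concentration=float(rng.uniform(*concentration_range)),
            response_gain=float(rng.uniform(*gain_range)),
            response_sign=sign,
        ))
    return cells


def make_session(n_cells: int = 30,
                 fov_shape=(120, 120),
                 n_reps_per_condition: int = 20,
                 positions=(9,),
                 orientations=ORIENTATIONS_DEG,
                 frame_rate: float = DEFAULT_FRAME_RATE,
                 noise_sd: float = 0.15,
                 seed: int = 0,
                 rf_position: int = 9,
                 cells=None,
                 min_separation: float = 6.0,
                 **cell_kwargs) -> SessionBundle:
    """Convenience constructor: cells + trial table + traces + footprints."""
    child = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in child]
    if cells is None:
        cells = random_cells(n_cells, fov_shape, seeds[0],
                             rf_position=rf_position,
                             min_separation=min_separation, **cell_kwargs)
    trials = generate_trial_table(n_reps_per_condition, positions,
                                  orientations, frame_rate, seed=seeds[1])
    traces = simulate_traces(cells, trials, frame_rate, noise_sd=noise_sd,
                             seed=seeds[2])
    footprints = generate_footprints(cells, fov_shape)
    params = dict(fov_shape=tuple(fov_shape),
                  n_reps_per_condition=n_reps_per_condition,
                  positions=list(positions), orientations=list(orientations),
                  frame_rate=frame_rate, noise_sd=noise_sd,
                  rf_position=rf_position, min_separation=min_separation)
    return SessionBundle(traces, footprints, trials, list(cells), seed, params)


def _wrap_orientation(deg: float) -> float:
    return float((deg + 90.0) % 180.0 - 90.0)


def derive_second_session(bundle: SessionBundle,
                          shift=(0.0, 0.0),
                          rotation: float = 0.0,
                          centroid_jitter_sd: float = 0.0,
                          drop_fraction: float = 0.0,
                          add_count: int = 0,
                          tuning_drift_sd: float = 0.0,
                          seed: int = 1) -> SessionBundle:
    """Derive a later session from ``bundle`` for cross-session tracking.

    Centroids are rotated about the FOV center and translated by ``shift``
    (dx, dy), then independently jittered; a random ``drop_fraction`` of cells
    disappears and ``add_count`` new cells appear; surviving cells' preferred
    orientations drift by Gaussian(0, tuning_drift_sd) degrees.  Traces are
    regenerated from a fresh trial table.  The returned bundle's
    ``correspondence`` maps first-session cell_id -> second-session cell_id
    for every surviving cell.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = bundle.params
    h, w = p["fov_shape"]
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    theta = math.radians(rotation)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    n = len(bundle.truth)
    n_drop = int(round(drop_fraction * n))
    drop_ids = set(rng.choice([c.cell_id for c in bundle.truth],
                              size=n_drop, replace=False).tolist())

    new_cells = []
    correspondence = {}
    occupied = []  # every soma location, detected this session or not
    next_id = 0
    for cell in sorted(bundle.truth, key=lambda c: c.cell_id):
        x, y = cell.centroid
        xr = cx0 + cos_t * (x - cx0) - sin_t * (y - cy0) + shift[0]
        yr = cy0 + sin_t * (x - cx0) + cos_t * (y - cy0) + shift[1]
        occupied.append((xr, yr))
        if cell.cell_id in drop_ids:
            continue
        if centroid_jitter_sd > 0:
            xr += rng.normal(0.0, centroid_jitter_sd)
            yr += rng.normal(0.0, centroid_jitter_sd)
        s = cell.footprint_sigma
        if not (3 * s <= xr <= w - 1 - 3 * s and 3 * s <= yr <= h - 1 - 3 * s):
            continue  # pushed out of view: cell is lost, not a survivor
        pref = cell.preferred_orientation
        if tuning_drift_sd > 0:
            pref = _wrap_orientation(pref + rng.normal(0.0, tuning_drift_sd))
        new_cells.append(replace(cell, cell_id=next_id, centroid=(xr, yr),
                                 preferred_orientation=pref))
        correspondence[cell.cell_id] = next_id
        next_id += 1
    if not new_cells and n > 0:
        raise ValueError("transform pushed every cell out of the field of view")

    if add_count > 0:
        margin = 3.0 * (bundle.truth[0].footprint_sigma if bundle.truth else 3.0) + 1.0
        min_sep = float(p.get("min_separation", 6.0))
        for _ in range(add_count):
            # new somata cannot overlap existing ones — including cells that
            # went undetected this session, whose tissue locations remain
            # occupied
            for _attempt in range(10_000):
                c = (rng.uniform(margin, w - 1 - margin),
                     rng.uniform(margin, h - 1 - margin))
                if all(math.hypot(c[0] - o[0], c[1] - o[1]) >= min_sep
                       for o in occupied):
                    break
            else:
                raise ValueError("cannot place added cells with requested "
                                 "separation")
            occupied.append(c)
            template = bundle.truth[0] if bundle.truth else None
            new_cells.append(GroundTruthCell(
                cell_id=next_id, centroid=c,
                footprint_sigma=template.footprint_sigma if template else 3.0,
                rf_position=p["rf_position"],
                preferred_orientation=float(rng.uniform(-90.0, 90.0)),
                tuning_concentration=float(rng.uniform(0.0, 3.0)),
                response_gain=float(rng.uniform(0.8, 2.0)),
            ))
            next_id += 1

    child = np.random.SeedSequence(seed).spawn(2)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in child]
    trials = generate_trial_table(p["n_reps_per_condition"], p["positions"],
                                  p["orientations"], p["frame_rate"],
                                  seed=seeds[0])
    traces = simulate_traces(new_cells, trials, p["frame_rate"],
                             noise_sd=p["noise_sd"], seed=seeds[1])
    footprints = generate_footprints(new_cells, (h, w))
    return SessionBundle(traces, footprints, trials, new_cells, seed,
                         dict(p), correspondence)
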