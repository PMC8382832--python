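"""End-to-end orchestration: simulate → extract → rf → tuning → decode → track.

A single :class:`RunConfig` seed fans out deterministically to per-stage
child seeds, so a stage can be rerun in isolation and two runs with the same
configuration produce bit-identical outputs.  Every run writes a manifest
recording the configuration, any overrides from the defaults, per-stage
seeds and SHA-256 checksums of all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import DEFAULT_WINDOWS
from .decoding import decode_by_roi_count, decode_timecourse, window_features
from .extraction import align_trials, zscore_session
from .grids import StimulusGrid
from .io import read_session, read_tensor, write_json, write_session, \
    write_tensor
from .receptive_field import rf_position_test, rf_surface
from .synthetic import ORIENTATIONS_DEG, derive_second_session, make_session
from .tracking import stability_statistics, track_sessions
from .tuning import compute_tuning

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "rf", "tuning", "decode", "track")


@dataclass
class RunConfig:
    """Run parameters; defaults follow the study design.

    Task/stimulus: 6 Gabor orientations, receptive-field mapping over the 15
    position grid with 2 repetitions per condition (12 trials per location),
    orientation sessions with 20 trials per orientation at the identified
    receptive field.  Decoding: 500-ms window, 166-ms step, 10 folds, 100
    shuffles.  Tracking: P_same threshold 0.5.
    """

    seed: int = 0
    n_cells: int = 30
    fov_shape: tuple = (120, 120)
    frame_rate: float = 10.0
    noise_sd: float = 0.15
    orientations: tuple = ORIENTATIONS_DEG
    rf_position: int = 9  # 7 deg eccentricity, 4 o'clock
    n_reps_rf: int = 2
    n_reps_tuning: int = 20
    alpha: float = 0.05
    decode_window_ms: float = 500.0
    decode_step_ms: float = 166.0
    decode_folds: int = 10
    decode_shuffles: int = 100
    roi_count_reps: int = 100
    roi_counts: tuple = None  # None -> spaced counts up to n_cells
    tracking_threshold: float = 0.5
    tracking_max_distance: float = 12.0
    second_session_shift: tuple = (3.0, -2.0)
    second_session_rotation: float = 1.0
    second_session_jitter_sd: float = 0.5
    second_session_drop_fraction: float = 0.25
    second_session_add_count: int = 5
    second_session_tuning_drift_sd: float = 5.0
    stability_shuffles: int = 10_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        extra = set(d) - {f.name for f in dataclasses.fields(cls)}
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def overrides(self) -> dict:
        ref = RunConfig().to_dict()
        cur = self.to_dict()
        return {k: cur[k] for k in cur if cur[k] != ref[k]}


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage child seeds (all below 2^31)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input for this stage: {what} expected at {path}")
    return path


def _stage_simulate(cfg: RunConfig, out: Path, seed: int) -> list:
    grid = StimulusGrid()
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    session_a = make_session(
        n_cells=cfg.n_cells, fov_shape=cfg.fov_shape,
        n_reps_per_condition=cfg.n_reps_tuning, positions=(cfg.rf_position,),
        orientations=cfg.orientations, frame_rate=cfg.frame_rate,
        noise_sd=cfg.noise_sd, seed=seeds[0], rf_position=cfg.rf_position)
    rf_session = make_session(
        cells=session_a.truth, fov_shape=cfg.fov_shape,
        n_reps_per_condition=cfg.n_reps_rf, positions=grid.positions,
        orientations=cfg.orientations, frame_rate=cfg.frame_rate,
        noise_sd=cfg.noise_sd, seed=seeds[1], rf_position=cfg.rf_position)
    session_b = derive_second_session(
        session_a, shift=cfg.second_session_shift,
        rotation=cfg.second_session_rotation,
        centroid_jitter_sd=cfg.second_session_jitter_sd,
        drop_fraction=cfg.second_session_drop_fraction,
        add_count=cfg.second_session_add_count,
        tuning_drift_sd=cfg.second_session_tuning_drift_sd, seed=seeds[2])
    written = []
    for name, bundle in (("rf_session", rf_session), ("session_a", session_a),
                         ("session_b", session_b)):
        write_session(bundle, out / name)
        written.append(out / name)
    return written


def _stage_extract(cfg: RunConfig, out: Path, seed: int) -> list:
    written = []
    for name in ("rf_session", "session_a", "session_b"):
        bundle = read_session(_require(out / name, f"session '{name}'"))
        traces = zscore_session(bundle.traces)
        tensor = align_trials(traces, bundle.trials)
        write_tensor(tensor, out / f"tensor_{name}")
        written.append(out / f"tensor_{name}")
    return written


def _stage_rf(cfg: RunConfig, out: Path, seed: int) -> list:
    tensor = read_tensor(_require(out / "tensor_rf_session",
                                  "RF-session tensor"))
    grid = StimulusGrid()
    result = rf_position_test(tensor, grid, alpha=cfg.alpha)
    write_json(out / "rf.json", {
        "best_position": result.best_position,
        "best_position_label": grid.label(result.best_position),
        "passed": result.passed,
        "roi_id": result.roi_id,
        "alpha": result.alpha,
        "mean_response_by_position": result.mean_response_by_position,
    })
    az, ecc, surf = rf_surface(result, grid)
    pd.DataFrame(surf, index=ecc, columns=az).to_csv(out / "rf_surface.csv",
                                                     float_format="%.6g")
    return [out / "rf.json", out / "rf_surface.csv"]


def _stage_tuning(cfg: RunConfig, out: Path, seed: int) -> list:
    written = []
    for name in ("session_a", "session_b"):
        tensor = read_tensor(_require(out / f"tensor_{name}",
                                      f"tensor for '{name}'"))
        table = compute_tuning(tensor, alpha=cfg.alpha)
        path = out / f"tuning_{name}.csv"
        table.to_csv(path, float_format="%.9g")
        written.append(path)
    return written


def _stage_decode(cfg: RunConfig, out: Path, seed: int) -> list:
    ss = np.random.SeedSequence(seed).spawn(2)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    tensor = read_tensor(_require(out / "tensor_session_a",
                                  "tensor for 'session_a'"))
    curve = decode_timecourse(
        tensor, window_ms=cfg.decode_window_ms, step_ms=cfg.decode_step_ms,
        n_shuffles=cfg.decode_shuffles, alpha=cfg.alpha,
        n_folds=cfg.decode_folds, seed=seeds[0])
    pd.DataFrame({
        "window_center_s": curve.window_centers,
        "performance": curve.performance,
        "null_mean": curve.null_mean,
        "null_sd": curve.null_sd,
        "p_value": curve.p_values,
        "significant": curve.significant,
    }).to_csv(out / "decode_timecourse.csv", index=False,
              float_format="%.9g")

    tuning = pd.read_csv(_require(out / "tuning_session_a.csv",
                                  "tuning table for 'session_a'"),
                         index_col="roi_id")
    start, end = DEFAULT_WINDOWS["response_mean"]
    feats = window_features(tensor, start, end - start)
    labels = tensor.trial_meta["orientation"].to_numpy()
    n = feats.shape[1]
    counts = cfg.roi_counts or tuple(sorted({1, 2, 5, 10, 20, n} &
                                            set(range(1, n + 1)))) or (n,)
    counts = tuple(c for c in counts if 1 <= c <= n)
    rc = decode_by_roi_count(feats, labels,
                             tuning.loc[tensor.roi_ids, "osi"].to_numpy(),
                             counts, n_reps=cfg.roi_count_reps,
                             n_folds=cfg.decode_folds, seed=seeds[1])
    pd.DataFrame({
        "n_rois": rc.n_rois,
        "random_mean": rc.random_mean, "random_sd": rc.random_sd,
        "osi_ordered": rc.osi_ordered,
        "shuffled_mean": rc.shuffled_mean, "shuffled_sd": rc.shuffled_sd,
    }).to_csv(out / "decode_roi_count.csv", index=False, float_format="%.9g")
    return [out / "decode_timecourse.csv", out / "decode_roi_count.csv"]


def _stage_track(cfg: RunConfig, out: Path, seed: int) -> list:
    bundle_a = read_session(_require(out / "session_a", "session_a"))
    bundle_b = read_session(_require(out / "session_b", "session_b"))
    result, model, feats = track_sessions(
        bundle_a.footprints, bundle_b.footprints,
        threshold=cfg.tracking_threshold,
        max_distance=cfg.tracking_max_distance)
    write_json(out / "registration.json", {
        "matches": [{"roi_a": a, "roi_b": b, "p_same": p}
                    for a, b, p in result.matches],
        "unmatched_a": result.unmatched_a,
        "unmatched_b": result.unmatched_b,
        "threshold": result.threshold,
        "transform": {"dy": result.transform.dy, "dx": result.transform.dx,
                      "rotation": result.transform.rotation,
                      "score": result.transform.score},
        "mixture": {"weight_same": model.weight_same,
                    "n_iter": model.n_iter,
                    "log_likelihood": model.log_likelihood,
                    "n_candidate_pairs": len(feats)},
    })
    tensor_a = read_tensor(_require(out / "tensor_session_a",
                                    "tensor for 'session_a'"))
    tensor_b = read_tensor(_require(out / "tensor_session_b",
                                    "tensor for 'session_b'"))
    tuning_a = pd.read_csv(out / "tuning_session_a.csv", index_col="roi_id")
    tuning_b = pd.read_csv(out / "tuning_session_b.csv", index_col="roi_id")
    report = stability_statistics(tensor_a, tensor_b, tuning_a, tuning_b,
                                  result, seed=seed,
                                  n_orientation_shuffles=cfg.stability_shuffles)
    write_json(out / "stability.json", report)
    written = [out / "registration.json", out / "stability.json"]
    od = report.get("orientation_difference")
    if od:
        edges = np.asarray(od["bin_edges"])
        pd.DataFrame({
            "bin_start_deg": edges[:-1], "bin_end_deg": edges[1:],
            "observed_count": od["observed_counts"],
            "shuffled_expected_count": od["shuffled_expected_counts"],
        }).to_csv(out / "orientation_difference_histogram.csv", index=False)
        written.append(out / "orientation_difference_histogram.csv")
    return written


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "rf": _stage_rf,
    "tuning": _stage_tuning,
    "decode": _stage_decode,
    "track": _stage_track,
}


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir, stages=None) -> Path:
    """Execute the requested stages in dependency order; returns the run dir.

    Writes ``manifest.json`` with the configuration, overrides from the
    defaults, per-stage seeds and SHA-256 checksums of every output file.
    A stage failure halts downstream stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seeds = stage_seeds(config.seed)

    outputs = {}
    for name in STAGES:
        if name not in stages:
            continue
        logger.info("running stage %s (seed %d)", name, seeds[name])
        written = _STAGE_FUNCS[name](config, out, seeds[name])
        files = []
        for w in written:
            w = Path(w)
            files.extend(sorted(p for p in w.rglob("*") if p.is_file())
                         if w.is_dir() else [w])
        outputs[name] = [str(p.relative_to(out)) for p in files]

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "overrides": config.overrides(),
        "stage_seeds": seeds,
        "stages_run": stages,
        "outputs": outputs,
        "checksums": {rel: _checksum(out / rel)
                      for rels in outputs.values() for rel in rels},
    }
    write_json(out / "manifest.json", manifest)
    return out
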