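"""Plain-text/TIFF persistence for sessions, tensors and results.

A session directory holds:

- ``traces.csv``    — first column ``time_s``, one column per ROI
- ``footprints.tif``— multi-page float32 TIFF, one page per ROI, unit peak
- ``trials.csv``    — the trial table
- ``truth.json``    — ground-truth cell parameters (synthetic sessions only)
- ``manifest.json`` — ties the files together with seeds and parameters

A response-tensor directory holds one CSV per ROI (trials x bins) plus an
``index.json`` with the relative timebase, trial metadata and ROI ids.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import FootprintStack, ResponseTensor, TraceMatrix
from .synthetic import GroundTruthCell, SessionBundle


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def write_session(bundle: SessionBundle, out_dir) -> Path:
    """Persist a session bundle; returns the directory written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    df = pd.DataFrame(bundle.traces.values,
                      columns=[f"roi_{rid}" for rid in bundle.traces.roi_ids])
    df.insert(0, "time_s", bundle.traces.times)
    df.to_csv(out / "traces.csv", index=False, float_format="%.9g")

    tifffile.imwrite(out / "footprints.tif",
                     bundle.footprints.masks.astype(np.float32))
    bundle.trials.to_csv(out / "trials.csv", index=False)
    write_json(out / "truth.json",
               [dataclasses.asdict(c) for c in bundle.truth])
    write_json(out / "manifest.json", {
        "files": {"traces": "traces.csv", "footprints": "footprints.tif",
                  "trials": "trials.csv", "truth": "truth.json"},
        "seed": bundle.seed,
        "params": bundle.params,
        "roi_ids": list(bundle.traces.roi_ids),
        "fov_shape": list(bundle.footprints.fov_shape),
        "correspondence": bundle.correspondence,
    })
    return out


def read_session(session_dir) -> SessionBundle:
    """Load a session directory written by :func:`write_session`.

    Externally produced data with the same layout loads too; ``truth.json``
    is optional.
    """
    d = Path(session_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"session directory not found: {d}")
    manifest = json.loads((d / "manifest.json").read_text())
    df = pd.read_csv(d / manifest["files"]["traces"])
    roi_ids = [int(c.split("_", 1)[1]) for c in df.columns[1:]]
    traces = TraceMatrix(df.iloc[:, 1:].to_numpy(),
                         df["time_s"].to_numpy(), roi_ids)
    masks = tifffile.imread(d / manifest["files"]["footprints"])
    if masks.ndim == 2:
        masks = masks[None]
    footprints = FootprintStack(masks, roi_ids, tuple(manifest["fov_shape"]))
    trials = pd.read_csv(d / manifest["files"]["trials"])
    truth_path = d / manifest["files"].get("truth", "truth.json")
    truth = []
    if truth_path.exists():
        truth = [GroundTruthCell(**{**c, "centroid": tuple(c["centroid"])})
                 for c in json.loads(truth_path.read_text())]
    corr = manifest.get("correspondence")
    if corr is not None:
        corr = {int(k): int(v) for k, v in corr.items()}
    return SessionBundle(traces, footprints, trials, truth,
                         manifest.get("seed", 0), manifest.get("params", {}),
                         corr)


def write_tensor(tensor: ResponseTensor, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, rid in enumerate(tensor.roi_ids):
        pd.DataFrame(tensor.values[i]).to_csv(
            out / f"roi_{rid}.csv", index=False, header=False,
            float_format="%.9g")
    tensor.trial_meta.to_csv(out / "trials.csv", index=False)
    write_json(out / "index.json", {
        "rel_time": tensor.rel_time,
        "roi_ids": list(tensor.roi_ids),
        "trials": "trials.csv",
    })
    return out


def read_tensor(tensor_dir) -> ResponseTensor:
    d = Path(tensor_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"tensor directory not found: {d}")
    index = json.loads((d / "index.json").read_text())
    meta = pd.read_csv(d / index["trials"])
    values = np.stack([
        pd.read_csv(d / f"roi_{rid}.csv", header=None).to_numpy()
        for rid in index["roi_ids"]
    ])
    return ResponseTensor(values, np.asarray(index["rel_time"]), meta,
                          list(index["roi_ids"]))
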