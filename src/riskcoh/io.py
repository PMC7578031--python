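"""On-disk session bundle format.

A bundle is a directory with ``trials.csv`` (one row per trial),
``units.csv`` (unit_id, area, quality), ``spikes.csv`` (event list:
unit_id, trial_id, time_ms), ``lfp.h5`` (one dataset per area,
electrodes x trials x samples, with sampling_rate and t0 attributes) and
``ground_truth.json`` (absent for real recordings). The round trip is
lossless to floating-point precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .task_synth import (GroundTruth, SessionBundle, UnitGroundTruth,
                         UnitRecord, ground_truth_dict)

SCHEMA_VERSION = 1

__all__ = ["write_bundle", "read_bundle"]


def write_bundle(bundle: SessionBundle, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(path / "trials.csv", index=False)
    pd.DataFrame({
        "unit_id": [u.unit_id for u in bundle.units],
        "area": [u.area for u in bundle.units],
        "quality": [u.quality for u in bundle.units],
    }).to_csv(path / "units.csv", index=False)
    rows = [(u.unit_id, tr, t)
            for u in bundle.units
            for tr, st in enumerate(u.spike_times)
            for t in st]
    pd.DataFrame(rows, columns=["unit_id", "trial_id", "time_ms"]).to_csv(
        path / "spikes.csv", index=False)
    with h5py.File(path / "lfp.h5", "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate"] = bundle.sampling_rate
        f.attrs["t0"] = bundle.t0
        for area, traces in bundle.lfps.items():
            f.create_dataset(area, data=traces)
    if bundle.ground_truth is not None:
        gt = ground_truth_dict(bundle.ground_truth)
        gt["schema_version"] = SCHEMA_VERSION
        (path / "ground_truth.json").write_text(json.dumps(gt))
    return path


def read_bundle(path: str | Path) -> SessionBundle:
    path = Path(path)
    if not (path / "trials.csv").exists():
        raise FileNotFoundError(f"not a session bundle: {path}")
    trials = pd.read_csv(path / "trials.csv")
    units_meta = pd.read_csv(path / "units.csv")
    spikes = pd.read_csv(path / "spikes.csv")
    n_trials = len(trials)
    units = []
    grouped = {k: g for k, g in spikes.groupby("unit_id")}
    for _, row in units_meta.iterrows():
        g = grouped.get(row["unit_id"])
        trains = [np.empty(0) for _ in range(n_trials)]
        if g is not None:
            for tr, gg in g.groupby("trial_id"):
                trains[int(tr)] = np.sort(gg["time_ms"].to_numpy(float))
        units.append(UnitRecord(int(row["unit_id"]), str(row["area"]), trains,
                                str(row["quality"])))
    lfps: dict[str, np.ndarray] = {}
    fs, t0 = 1000.0, -1200.0
    lfp_path = path / "lfp.h5"
    if lfp_path.exists():
        with h5py.File(lfp_path, "r") as f:
            if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
                raise ValueError("bundle schema version mismatch")
            fs = float(f.attrs["sampling_rate"])
            t0 = float(f.attrs["t0"])
            for area in f:
                lfps[area] = f[area][:]
    gt = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        d = json.loads(gt_path.read_text())
        gt = GroundTruth(
            lick_coeffs=d["lick_coeffs"],
            unit_coding=[UnitGroundTruth(**u) for u in d["unit_coding"]],
            shared_latents=d["shared_latents"],
            lfp_band_effects={a: {b: tuple(v) for b, v in bands.items()}
                              for a, bands in d["lfp_band_effects"].items()},
            coupling=d["coupling"],
            artifact_labels={a: np.array(v, dtype=bool)
                             for a, v in d.get("artifact_labels", {}).items()},
            artifact_kinds={a: np.array(v, dtype=object)
                            for a, v in d.get("artifact_kinds", {}).items()},
            rt_coeffs=d.get("rt_coeffs", {}),
        )
    return SessionBundle(trials=trials, units=units, lfps=lfps,
                         sampling_rate=fs, t0=t0, ground_truth=gt)
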