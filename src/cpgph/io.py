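"""File formats: trace/event CSV, experiment HDF5 bundles, annotations,
YAML configuration and JSON manifests.

Traces are CSV with columns ``time_s, voltage_mV``; spike events are CSV
with columns ``unit, time_s``; experiment bundles are HDF5 with one group
per protocol step (events per unit as datasets, ground-truth parameters
and state as attributes); annotations are CSV ``state, start_s, end_s``
or BED-like intervals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import SpikeTrain, Trace
from .protocol import PHProtocol, PHStep
from .simulate import BursterParams, Experiment, StepGroundTruth
from .states import StateAnnotation

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_events_csv", "read_events_csv",
    "write_experiment_h5", "read_experiment_h5",
    "write_annotation_csv", "read_annotation_csv", "write_annotation_bed",
    "load_config", "write_manifest",
]


def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "voltage_mV": trace.samples}) \
        .to_csv(path, index=False)


def read_trace_csv(path, label: str = "") -> Trace:
    """Read a trace CSV; the sample rate is inferred from the time column."""
    df = pd.read_csv(path)
    for col in ("time_s", "voltage_mV"):
        if col not in df.columns:
            raise ValueError(f"trace file {path} lacks column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace file must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace time stamps are not regularly spaced")
    return Trace(df["voltage_mV"].to_numpy(dtype=float), 1.0 / float(np.median(dt)),
                 float(t[0]), label)


def write_events_csv(trains: dict[str, SpikeTrain], path) -> None:
    rows = [(u, t) for u, tr in trains.items() for t in tr.times]
    pd.DataFrame(rows, columns=["unit", "time_s"]).to_csv(path, index=False)


def read_events_csv(path) -> dict[str, SpikeTrain]:
    df = pd.read_csv(path)
    for col in ("unit", "time_s"):
        if col not in df.columns:
            raise ValueError(f"events file {path} lacks column {col!r}")
    return {
        str(u): SpikeTrain(np.sort(g["time_s"].to_numpy(dtype=float)), str(u))
        for u, g in df.groupby("unit")
    }


def _params_to_json(params: dict[str, BursterParams]) -> str:
    return json.dumps({u: dataclasses.asdict(p) for u, p in params.items()},
                      sort_keys=True)


def write_experiment_h5(exp: Experiment, path) -> None:
    """Write an experiment bundle: one group per step, events per unit,
    ground truth as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["ganglion"] = exp.ganglion
        f.attrs["seed"] = exp.seed
        f.attrs["direction"] = exp.protocol.direction
        f.attrs["temperature"] = exp.protocol.temperature
        for i, gt in enumerate(exp.ground_truth):
            g = f.create_group(f"step_{i:02d}")
            g.attrs["ph"] = gt.step.ph
            g.attrs["duration"] = gt.step.duration
            g.attrs["role"] = gt.step.role
            g.attrs["t_start"] = gt.t_start
            g.attrs["t_end"] = gt.t_end
            g.attrs["state"] = gt.state if gt.state is not None else ""
            g.attrs["params_json"] = _params_to_json(gt.params)
            ev = g.create_group("events")
            for u, train in exp.spike_trains.items():
                ev.create_dataset(u, data=train.between(gt.t_start, gt.t_end).times)


def read_experiment_h5(path) -> Experiment:
    with h5py.File(path, "r") as f:
        ganglion = str(f.attrs["ganglion"])
        seed = int(f.attrs["seed"])
        direction = str(f.attrs["direction"])
        temperature = float(f.attrs["temperature"])
        names = sorted(k for k in f.keys() if k.startswith("step_"))
        steps, gts = [], []
        times: dict[str, list[np.ndarray]] = {}
        for name in names:
            g = f[name]
            step = PHStep(float(g.attrs["ph"]), float(g.attrs["duration"]),
                          str(g.attrs["role"]))
            params = {u: BursterParams(**d)
                      for u, d in json.loads(g.attrs["params_json"]).items()}
            state = str(g.attrs["state"]) or None
            gts.append(StepGroundTruth(step, float(g.attrs["t_start"]),
                                       float(g.attrs["t_end"]), state, params))
            steps.append(step)
            for u in g["events"]:
                times.setdefault(u, []).append(g["events"][u][()])
    protocol = PHProtocol(tuple(steps), direction, temperature)
    trains = {u: SpikeTrain(np.concatenate(ts), u) for u, ts in times.items()}
    return Experiment(ganglion, protocol, trains, gts, seed)


def write_annotation_csv(annotation: StateAnnotation, path) -> None:
    pd.DataFrame(annotation.segments, columns=["state", "start_s", "end_s"]) \
        .to_csv(path, index=False)


def read_annotation_csv(path) -> StateAnnotation:
    df = pd.read_csv(path)
    segments = [(str(r.state), float(r.start_s), float(r.end_s))
                for r in df.itertuples()]
    return StateAnnotation(segments, (segments[0][1], segments[-1][2]))


def write_annotation_bed(annotation: StateAnnotation, path,
                         name: str = "rhythm") -> None:
    """BED-like intervals (ms resolution) for browser-style visualization."""
    with open(path, "w") as fh:
        for state, s, e in annotation.segments:
            fh.write(f"{name}\t{int(round(s * 1000))}\t{int(round(e * 1000))}\t{state}\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
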