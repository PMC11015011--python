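"""File formats: traces (HDF5/CSV), schedules, behavior, rasters, ground truth.

Schemas are deliberately small and text-friendly: HDF5 holds the fluorescence
matrices (datasets ``F_roi``, ``F_neuropil``, attribute ``frame_period_s``);
schedules and behavior are plain CSV; planted ground truth round-trips
through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signals import TraceSet
from .synthgen import (
    BehaviorTrace,
    PopulationConfig,
    Raster,
    StimulusSchedule,
    SyntheticGroundTruth,
    Trial,
)


class SchemaError(ValueError):
    """A file is missing a required dataset or column."""


def write_traces(path: str | Path, traces: TraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("F_roi", data=traces.f_roi)
        f.create_dataset("F_neuropil", data=traces.f_neuropil)
        f.attrs["frame_period_s"] = traces.frame_period_s


def load_traces(path: str | Path) -> TraceSet:
    """Load a TraceSet from HDF5 (or the CSV dialect, by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _load_traces_csv(path)
    with h5py.File(path, "r") as f:
        for name in ("F_roi", "F_neuropil"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset {name!r}")
        if "frame_period_s" not in f.attrs:
            raise SchemaError(f"{path}: missing attribute 'frame_period_s'")
        return TraceSet(
            f_roi=f["F_roi"][...],
            f_neuropil=f["F_neuropil"][...],
            frame_period_s=float(f.attrs["frame_period_s"]),
        )


def write_traces_csv(path: str | Path, traces: TraceSet) -> None:
    """Long-format CSV dialect: roi_id, frame, f_roi, f_neuropil."""
    n, f = traces.f_roi.shape
    df = pd.DataFrame(
        {
            "roi_id": np.repeat(np.arange(n), f),
            "frame": np.tile(np.arange(f), n),
            "f_roi": traces.f_roi.ravel(),
            "f_neuropil": traces.f_neuropil.ravel(),
            "frame_period_s": traces.frame_period_s,
        }
    )
    df.to_csv(path, index=False)


def _load_traces_csv(path: Path) -> TraceSet:
    df = pd.read_csv(path)
    required = {"roi_id", "frame", "f_roi", "f_neuropil", "frame_period_s"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    n = df["roi_id"].nunique()
    f = df["frame"].nunique()
    df = df.sort_values(["roi_id", "frame"])
    return TraceSet(
        f_roi=df["f_roi"].to_numpy().reshape(n, f),
        f_neuropil=df["f_neuropil"].to_numpy().reshape(n, f),
        frame_period_s=float(df["frame_period_s"].iloc[0]),
    )


def write_schedule(path: str | Path, schedule: StimulusSchedule) -> None:
    df = pd.DataFrame(
        [(t.onset_frame, t.duration_frames, t.direction_deg) for t in schedule.trials],
        columns=["onset_frame", "duration_frames", "direction_deg"],
    )
    df.attrs = {}
    header = f"# frame_period_s={schedule.frame_period_s} session_frames={schedule.session_frames}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def load_schedule(path: str | Path) -> StimulusSchedule:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError(f"{path}: missing schedule metadata header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh)
    required = {"onset_frame", "duration_frames", "direction_deg"}
    if required - set(df.columns):
        raise SchemaError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    trials = [
        Trial(int(r.onset_frame), int(r.duration_frames), float(r.direction_deg))
        for r in df.itertuples()
    ]
    return StimulusSchedule(
        trials, float(meta["frame_period_s"]), int(meta["session_frames"])
    )


def write_behavior(path: str | Path, behavior: BehaviorTrace) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(behavior.speed_cm_s)),
            "speed_cm_s": behavior.speed_cm_s,
            "whisking": behavior.whisking_energy,
        }
    ).to_csv(path, index=False)


def load_behavior(path: str | Path) -> BehaviorTrace:
    df = pd.read_csv(path)
    required = {"frame", "speed_cm_s", "whisking"}
    if required - set(df.columns):
        raise SchemaError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    return BehaviorTrace(df["speed_cm_s"].to_numpy(), df["whisking"].to_numpy())


def write_raster_csv(path: str | Path, raster: Raster) -> None:
    """Sparse event list (frame, neuron_id) plus metadata header."""
    neurons, frames = np.nonzero(raster.spikes)
    with open(path, "w") as fh:
        fh.write(
            f"# frame_period_s={raster.frame_period_s} "
            f"n_neurons={raster.n_neurons} n_frames={raster.n_frames}\n"
        )
        pd.DataFrame({"frame": frames, "neuron_id": neurons}).to_csv(fh, index=False)


def load_raster_csv(path: str | Path) -> Raster:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError(f"{path}: missing raster metadata header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh)
    spikes = np.zeros((int(meta["n_neurons"]), int(meta["n_frames"])), dtype=np.uint8)
    spikes[df["neuron_id"].to_numpy(int), df["frame"].to_numpy(int)] = 1
    return Raster(spikes, float(meta["frame_period_s"]))


def write_ground_truth(path: str | Path, gt: SyntheticGroundTruth) -> None:
    payload = {
        "membership": gt.membership.tolist(),
        "ensemble_orientations_deg": gt.ensemble_orientations_deg.tolist(),
        "neuron_class": gt.neuron_class,
        "neuron_pref_deg": [None if np.isnan(v) else v for v in gt.neuron_pref_deg],
        "tau_decay_spont_s": gt.tau_decay_spont_s.tolist(),
        "tau_decay_suppressed_s": gt.tau_decay_suppressed_s.tolist(),
        "amplitude": gt.amplitude.tolist(),
        "tuning_width_deg": gt.tuning_width_deg,
        "seed": gt.seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticGroundTruth(
        membership=np.asarray(payload["membership"], dtype=np.int8),
        ensemble_orientations_deg=np.asarray(payload["ensemble_orientations_deg"]),
        neuron_class=payload["neuron_class"],
        neuron_pref_deg=np.array(
            [np.nan if v is None else v for v in payload["neuron_pref_deg"]]
        ),
        tau_decay_spont_s=np.asarray(payload["tau_decay_spont_s"]),
        tau_decay_suppressed_s=np.asarray(payload["tau_decay_suppressed_s"]),
        amplitude=np.asarray(payload["amplitude"]),
        tuning_width_deg=float(payload["tuning_width_deg"]),
        seed=int(payload["seed"]),
        config=None,
    )
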