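"""Reading and writing the pipeline's on-disk formats.

HDF5 holds signals and stacks (datasets ``lfp``, ``mua``, ``emg``,
``stack`` with ``rate_hz``/``t0_s`` attributes), CSV holds event and
state tables, JSON holds ground truth and summary metrics, and the
atlas travels as a TIFF label image plus a JSON name map.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, RegionAtlas, TimeSeries
from .neuralstates import StateInterval
from .ripples import RippleEvent
from .synthio import GroundTruth

__all__ = [
    "save_timeseries", "load_timeseries",
    "save_stack", "load_stack",
    "write_events_csv", "read_events_csv",
    "write_states_csv", "read_states_csv",
    "save_atlas", "load_atlas",
    "save_truth", "load_truth",
]


def save_timeseries(path: str | Path, name: str, ts: TimeSeries) -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=ts.samples)
        d.attrs["rate_hz"] = ts.rate
        d.attrs["t0_s"] = ts.t0


def load_timeseries(path: str | Path, name: str) -> TimeSeries:
    with h5py.File(path, "r") as f:
        d = f[name]
        return TimeSeries(d[...], rate=float(d.attrs["rate_hz"]),
                          t0=float(d.attrs.get("t0_s", 0.0)))


def save_stack(path: str | Path, stack: ImageStack, name: str = "stack") -> None:
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(p, stack.frames.astype(np.float32),
                         metadata={"rate_hz": stack.rate, "t0_s": stack.t0})
        return
    with h5py.File(p, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=stack.frames)
        d.attrs["rate_hz"] = stack.rate
        d.attrs["t0_s"] = stack.t0


def load_stack(path: str | Path, name: str = "stack",
               rate: float | None = None) -> ImageStack:
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        frames = tifffile.imread(p)
        if rate is None:
            raise ValueError("rate must be given when loading TIFF stacks")
        return ImageStack(frames, rate=rate)
    with h5py.File(p, "r") as f:
        d = f[name]
        return ImageStack(d[...], rate=float(d.attrs["rate_hz"]),
                          t0=float(d.attrs.get("t0_s", 0.0)))


def write_events_csv(path: str | Path, events: list[RippleEvent]) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "center_s": [e.center for e in events],
            "offset_s": [e.offset for e in events],
            "peak_power_z": [e.peak_power for e in events],
            "is_bundled": [e.is_bundled for e in events],
            "n_ripples": [e.n_ripples for e in events],
        }
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[RippleEvent]:
    df = pd.read_csv(path)
    return [
        RippleEvent(
            onset=r.onset_s, center=r.center_s, offset=r.offset_s,
            peak_power=r.peak_power_z, is_bundled=bool(r.is_bundled),
            n_ripples=int(r.n_ripples),
        )
        for r in df.itertuples()
    ]


def write_states_csv(path: str | Path, states: list[StateInterval]) -> None:
    pd.DataFrame(
        {
            "start_s": [s.start for s in states],
            "end_s": [s.end for s in states],
            "kind": [s.kind for s in states],
        }
    ).to_csv(path, index=False)


def read_states_csv(path: str | Path) -> list[StateInterval]:
    df = pd.read_csv(path)
    return [StateInterval(start=r.start_s, end=r.end_s, kind=r.kind)
            for r in df.itertuples()]


def save_atlas(labels_path: str | Path, json_path: str | Path,
               atlas: RegionAtlas) -> None:
    tifffile.imwrite(labels_path, atlas.labels.astype(np.uint16))
    meta = {
        "names": {str(k): v for k, v in atlas.names.items()},
        "subnetworks": atlas.subnetworks,
        "axes": {"columns_increase": "lateral (0 deg)",
                 "rows_increase": "posterior (270 deg)"},
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def load_atlas(labels_path: str | Path, json_path: str | Path) -> RegionAtlas:
    labels = tifffile.imread(labels_path).astype(int)
    meta = json.loads(Path(json_path).read_text())
    return RegionAtlas(
        labels=labels,
        names={int(k): v for k, v in meta["names"].items()},
        subnetworks=meta.get("subnetworks", {}),
    )


def save_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "ripple_times": truth.ripple_times.tolist(),
        "bundle_membership": truth.bundle_membership.tolist(),
        "mua_skew": truth.mua_skew.tolist(),
        "wave_angle": truth.wave_angle.tolist(),
        "region_lags": truth.region_lags,
        "state_schedule": [list(s) for s in truth.state_schedule],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        ripple_times=np.asarray(d["ripple_times"]),
        bundle_membership=np.asarray(d["bundle_membership"], dtype=int),
        mua_skew=np.asarray(d["mua_skew"]),
        wave_angle=np.asarray(d["wave_angle"]),
        region_lags=d.get("region_lags", {}),
        state_schedule=[tuple(s) for s in d.get("state_schedule", [])],
    )
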