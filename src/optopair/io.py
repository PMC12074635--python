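"""Reading and writing traces, spike trains, opsin tables, protocols and
video stacks (CSV / JSON / HDF5 / TIFF)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .neuron_sim import SimResult
from .opsin_models import LightEpoch, LightProtocol, OpsinParams, Trace
from .spike_analysis import SpikeTrain
from .whisker_kinematics import AngleTrace, VideoStack

__all__ = [
    "trace_to_csv",
    "trace_from_csv",
    "traces_to_hdf5",
    "traces_from_hdf5",
    "opsin_to_json",
    "opsin_from_json",
    "opsin_table_to_json",
    "opsin_table_from_json",
    "protocol_to_json",
    "protocol_from_json",
    "spikes_to_csv",
    "spikes_from_csv",
    "sim_result_to_hdf5",
    "video_to_tiff",
    "video_from_tiff",
    "angles_to_csv",
    "angles_from_csv",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file."""


# --- traces ----------------------------------------------------------------


def trace_to_csv(trace: Trace, path: PathLike) -> None:
    pd.DataFrame({"t_s": trace.times, "value": trace.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def trace_from_csv(path: PathLike, units: str = "pA", kind: str = "current") -> Trace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_s", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    t = df["t_s"].to_numpy()
    if t.size < 2:
        raise ParseError(f"{path}: need at least two samples")
    dt = float(t[1] - t[0])
    return Trace(t0=float(t[0]), dt=dt, values=df["value"].to_numpy(), units=units, kind=kind)


def traces_to_hdf5(traces: Dict[str, Trace], path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("traces")
        for name, tr in traces.items():
            ds = grp.create_dataset(name, data=tr.values)
            ds.attrs["t0"] = tr.t0
            ds.attrs["dt"] = tr.dt
            ds.attrs["units"] = tr.units
            ds.attrs["kind"] = tr.kind


def traces_from_hdf5(path: PathLike) -> Dict[str, Trace]:
    out: Dict[str, Trace] = {}
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise ParseError(f"{path}: missing /traces group")
        for name, ds in f["traces"].items():
            out[name] = Trace(
                t0=float(ds.attrs["t0"]),
                dt=float(ds.attrs["dt"]),
                values=ds[()],
                units=str(ds.attrs["units"]),
                kind=str(ds.attrs["kind"]),
            )
    return out


# --- opsins & protocols ----------------------------------------------------


def opsin_to_json(params: OpsinParams, path: PathLike) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(params), indent=2))


def opsin_from_json(path: PathLike) -> OpsinParams:
    try:
        data = json.loads(Path(path).read_text())
        return OpsinParams(**data)
    except (json.JSONDecodeError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def opsin_table_to_json(table: Dict[str, OpsinParams], path: PathLike) -> None:
    Path(path).write_text(
        json.dumps({k: dataclasses.asdict(v) for k, v in table.items()}, indent=2)
    )


def opsin_table_from_json(path: PathLike) -> Dict[str, OpsinParams]:
    try:
        data = json.loads(Path(path).read_text())
        return {k: OpsinParams(**v) for k, v in data.items()}
    except (json.JSONDecodeError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def protocol_to_json(protocol: LightProtocol, path: PathLike) -> None:
    data = {
        "t_end": protocol.t_end,
        "epochs": [dataclasses.asdict(ep) for ep in protocol.epochs],
    }
    Path(path).write_text(json.dumps(data, indent=2))


def protocol_from_json(path: PathLike) -> LightProtocol:
    try:
        data = json.loads(Path(path).read_text())
        return LightProtocol(
            epochs=[LightEpoch(**ep) for ep in data["epochs"]], t_end=data["t_end"]
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --- spikes & sim results ---------------------------------------------------


def spikes_to_csv(spikes: SpikeTrain, path: PathLike) -> None:
    pd.DataFrame({"t_s": spikes.times}).to_csv(path, index=False, float_format="%.17g")


def spikes_from_csv(path: PathLike) -> SpikeTrain:
    df = pd.read_csv(path, float_precision="round_trip")
    if "t_s" not in df.columns:
        raise ParseError(f"{path}: missing column 't_s'")
    return SpikeTrain(df["t_s"].to_numpy())


def sim_result_to_hdf5(result: SimResult, path: PathLike, run: str = "run0") -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group(f"sim/{run}")
        v = grp.create_dataset("voltage", data=result.voltage.values)
        v.attrs["dt"] = result.voltage.dt
        v.attrs["t0"] = result.voltage.t0
        v.attrs["units"] = result.voltage.units
        grp.create_dataset("spikes", data=result.spikes.times)
        og = grp.create_group("open")
        for name, tr in result.opsin_open.items():
            ds = og.create_dataset(name, data=tr.values)
            ds.attrs["dt"] = tr.dt


# --- video -----------------------------------------------------------------


def video_to_tiff(stack: VideoStack, path: PathLike, sidecar: PathLike | None = None,
                  extra: dict | None = None) -> None:
    """Write a multi-page grayscale TIFF; fps (and extras) go to a JSON sidecar."""
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {"fps": stack.fps}
    if extra:
        meta.update(extra)
    sidecar = sidecar or Path(str(path) + ".json")
    Path(sidecar).write_text(json.dumps(meta, indent=2))


def video_from_tiff(path: PathLike, sidecar: PathLike | None = None) -> VideoStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = sidecar or Path(str(path) + ".json")
    fps = 750.0
    if Path(sidecar).exists():
        try:
            fps = float(json.loads(Path(sidecar).read_text())["fps"])
        except (json.JSONDecodeError, KeyError) as exc:
            raise ParseError(f"{sidecar}: {exc}") from exc
    return VideoStack(frames=frames.astype(np.uint8), fps=fps)


# --- angle traces -----------------------------------------------------------


def angles_to_csv(trace: AngleTrace, path: PathLike) -> None:
    df = pd.DataFrame(
        {"frame": np.arange(trace.n_frames)}
        | {f"whisker_{i}": trace.angles[j] for j, i in enumerate(trace.whisker_ids)}
    )
    df.insert(1, "t_s", df["frame"] / trace.fps)
    df.to_csv(path, index=False)


def angles_from_csv(path: PathLike, fps: float = 750.0) -> AngleTrace:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("whisker_")]
    if not cols:
        raise ParseError(f"{path}: no whisker_* columns")
    angles = np.vstack([df[c].to_numpy() for c in cols])
    ids = [int(c.split("_")[1]) for c in cols]
    return AngleTrace(fps=fps, whisker_ids=ids, angles=angles,
                      quality=np.full_like(angles, np.nan))
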