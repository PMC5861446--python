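"""Reading and writing of movies, spots, traces and fiducials.

Movies are multi-page TIFF, one file per channel, with a JSON sidecar
holding the simulation configuration and ground truth when the data are
synthetic; tabular outputs (spots, traces, fiducials, pairings, step fits)
are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import ImageStack, Spot
from .register import ChromaticMap
from .steps import BleachTrace


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, ChromaticMap):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.frames.astype(np.float32),
                     metadata={"exposure_ms": stack.exposure_ms,
                               "channel": stack.channel,
                               "excitation_nm": stack.excitation_nm})


def read_stack(path: str | Path, exposure_ms: float = 50.0,
               channel: str = "", excitation_nm: float | None = None) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return ImageStack(frames=np.asarray(frames, float),
                      exposure_ms=float(meta.get("exposure_ms", exposure_ms)),
                      channel=str(meta.get("channel", channel)),
                      excitation_nm=meta.get("excitation_nm", excitation_nm))


def spots_to_frame(spots: list[Spot], field_id: int = 0) -> pd.DataFrame:
    return pd.DataFrame([{
        "field_id": field_id, "spot_id": s.spot_id, "channel": s.channel,
        "x": s.x, "y": s.y, "sigma_x": s.sigma_x, "sigma_y": s.sigma_y,
        "amplitude": s.amplitude} for s in spots])


def frame_to_spots(df: pd.DataFrame) -> list[Spot]:
    return [Spot(x=row.x, y=row.y, channel=getattr(row, "channel", ""),
                 sigma_x=getattr(row, "sigma_x", np.nan),
                 sigma_y=getattr(row, "sigma_y", np.nan),
                 amplitude=getattr(row, "amplitude", np.nan),
                 spot_id=int(row.spot_id) if not pd.isna(row.spot_id) else None)
            for row in df.itertuples()]


def traces_to_frame(traces: list[BleachTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        sid = t.spot_id
        rows.append(pd.DataFrame({"spot_id": sid,
                                  "frame": np.arange(len(t)),
                                  "intensity": t.intensities}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["spot_id", "frame", "intensity"])


def frame_to_traces(df: pd.DataFrame, exposure_ms: float = 50.0,
                    channel: str = "green") -> list[BleachTrace]:
    traces = []
    for sid, grp in df.groupby("spot_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(BleachTrace(intensities=grp["intensity"].to_numpy(),
                                  exposure_ms=exposure_ms, spot_id=sid,
                                  channel=channel))
    return traces
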