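"""Reading and writing of movies, localization tables, traces and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from latkit.core import ImageStack, IntensityTrace
from latkit.synthdata import LOC_COLUMNS


class ParseError(ValueError):
    """A table failed validation; the message names the offending row/field."""


def write_imagestack(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    meta = {"pixel_size_um": stack.pixel_size,
            "frame_interval_s": stack.frame_interval}
    tifffile.imwrite(path, stack.data, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_imagestack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        px = float(meta["pixel_size_um"])
        dt = float(meta["frame_interval_s"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing or malformed calibration metadata") from exc
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data, pixel_size=px, frame_interval=dt)


def _validate_table(df: pd.DataFrame, columns: list[str], path: Path) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    numeric = [c for c in columns if c != "channel"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ParseError(f"{path}: non-numeric or missing value in column "
                             f"'{col}' at row {row}")
        df[col] = vals
    return df


def write_localizations(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_localizations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df = _validate_table(df, LOC_COLUMNS, path)
    return df.astype({"frame": int, "x_nm": float, "y_nm": float,
                      "intensity": float, "precision_nm": float})


def write_traces(traces: list[IntensityTrace], path: str | Path) -> Path:
    rows = []
    for i, tr in enumerate(traces):
        tid = tr.traj_id if tr.traj_id is not None else i
        for frame, value in zip(tr.frames, tr.values):
            rows.append((tid, int(frame), float(value), tr.origin_frame,
                         tr.back_extended_frames, tr.frame_interval))
    pd.DataFrame(rows, columns=["traj_id", "frame", "intensity", "origin_frame",
                                "back_extended_frames", "frame_interval"]
                 ).to_csv(path, index=False)
    return Path(path)


def read_traces(path: str | Path) -> list[IntensityTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    df = _validate_table(df, ["traj_id", "frame", "intensity", "origin_frame",
                              "back_extended_frames", "frame_interval"], path)
    out = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(IntensityTrace(
            grp["intensity"].to_numpy(),
            frame_interval=float(grp["frame_interval"].iloc[0]),
            origin_frame=int(grp["origin_frame"].iloc[0]),
            back_extended_frames=int(grp["back_extended_frames"].iloc[0]),
            traj_id=int(tid)))
    return out


def write_pairs(pairs: list[tuple[np.ndarray, np.ndarray]], path: str | Path) -> Path:
    rows = []
    for pid, (t1, t2) in enumerate(pairs):
        for frame, (a, b) in enumerate(zip(t1, t2)):
            rows.append((pid, frame, float(a), float(b)))
    pd.DataFrame(rows, columns=["traj_id", "frame", "intensity_ch1",
                                "intensity_ch2"]).to_csv(path, index=False)
    return Path(path)


def read_pairs(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    path = Path(path)
    df = pd.read_csv(path)
    df = _validate_table(df, ["traj_id", "frame", "intensity_ch1",
                              "intensity_ch2"], path)
    out = []
    for _, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("frame")
        out.append((grp["intensity_ch1"].to_numpy(),
                    grp["intensity_ch2"].to_numpy()))
    return out


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
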