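"""Table readers/writers and schema validation shared by all modules.

CSV dialect is fixed: comma-separated, dot decimal, UTF-8, mandatory header
row. Column names carry their unit (``x_nm``, ``x_um``, ``lag_s``...);
pixel-unit track tables are converted to micrometres when a pixel size is
available and rejected with an instructive error otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CurveTrace, PointPattern, Region, Track, TrackSet

logger = logging.getLogger("memnano")

POINTS_COLUMNS = ("sheet_id", "x_nm", "y_nm")
TRACKS_COLUMNS = ("track_id", "frame", "x_um", "y_um")
PEAKS_COLUMNS = ("residue", "H_ref_ppm", "N_ref_ppm", "H_alt_ppm", "N_alt_ppm")
INTENSITY_COLUMNS = ("residue", "I_tagged", "I_untagged")


@dataclass(frozen=True)
class TableSchema:
    """Expected columns (with units in their names) for one CSV table."""

    columns: tuple[str, ...]
    numeric: tuple[str, ...]


def load_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV table against a schema.

    Raises a schema error naming the offending column or cell for a missing
    column, a non-numeric cell in a numeric column, or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file (no header row)") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: table has a header but no rows")
    for col in schema.columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in schema.numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} in column "
                f"{col!r} (row {row})"
            )
        df[col] = coerced
    logger.info("loaded %d row(s) from %s", df.shape[0], path)
    return df


# ---------------------------------------------------------------------------
# point patterns


def write_points_csv(patterns: list[PointPattern], path: str | Path) -> None:
    rows = [
        {"sheet_id": p.sheet_id, "x_nm": x, "y_nm": y}
        for p in patterns
        for x, y in p.points
    ]
    pd.DataFrame(rows, columns=list(POINTS_COLUMNS)).to_csv(path, index=False)


def read_points_csv(path: str | Path, region: Region) -> list[PointPattern]:
    schema = TableSchema(columns=POINTS_COLUMNS, numeric=("x_nm", "y_nm"))
    df = load_table(path, schema)
    patterns = []
    for sheet, grp in df.groupby("sheet_id", sort=False):
        patterns.append(
            PointPattern(
                points=grp[["x_nm", "y_nm"]].to_numpy(),
                region=region,
                sheet_id=str(sheet),
            )
        )
    return patterns


# ---------------------------------------------------------------------------
# tracks


def write_tracks_csv(ts: TrackSet, path: str | Path) -> None:
    unit = ts.unit
    cols = ("track_id", "frame", f"x_{unit}", f"y_{unit}")
    rows = [
        {cols[0]: t.id, cols[1]: f, cols[2]: x, cols[3]: y}
        for t in ts.tracks
        for f, (x, y) in zip(t.frames, t.xy)
    ]
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, index=False)


def read_tracks_csv(
    path: str | Path,
    frame_interval: float = 0.010,
    pixel_size: float | None = None,
) -> TrackSet:
    """Read a tracks CSV in um or px; px requires ``pixel_size`` to convert."""
    head = pd.read_csv(path, nrows=0)
    if {"x_um", "y_um"} <= set(head.columns):
        xcol, ycol, unit = "x_um", "y_um", "um"
    elif {"x_px", "y_px"} <= set(head.columns):
        if pixel_size is None:
            raise ValueError(
                f"{path}: track positions are in pixels; supply --pixel-size "
                "(um/px) to convert to um"
            )
        xcol, ycol, unit = "x_px", "y_px", "px"
    else:
        raise ValueError(f"{path}: expected x_um/y_um or x_px/y_px columns")
    schema = TableSchema(
        columns=("track_id", "frame", xcol, ycol), numeric=("frame", xcol, ycol)
    )
    df = load_table(path, schema)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        xy = grp[[xcol, ycol]].to_numpy()
        if unit == "px":
            xy = xy * pixel_size
        tracks.append(Track(id=int(tid), frames=grp["frame"].to_numpy(int), xy=xy))
    return TrackSet(tracks=tracks, frame_interval=frame_interval, unit="um")


# ---------------------------------------------------------------------------
# curves and results


def write_curve_csv(trace: CurveTrace, path: str | Path) -> None:
    xname = f"x_{trace.x_unit}" if trace.x_unit else "x"
    yname = f"y_{trace.y_unit}" if trace.y_unit else "y"
    pd.DataFrame({xname: trace.x, yname: trace.y}).to_csv(path, index=False)


def read_curve_csv(path: str | Path, kind: str = "") -> CurveTrace:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: curve CSV needs two columns (x, y)")
    xname, yname = df.columns[:2]
    x_unit = xname.split("_", 1)[1] if "_" in xname else ""
    y_unit = yname.split("_", 1)[1] if "_" in yname else "au"
    return CurveTrace(
        x=df[xname].to_numpy(float),
        y=df[yname].to_numpy(float),
        kind=kind,
        x_unit=x_unit,
        y_unit=y_unit,
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
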