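"""Readers and writers for the on-disk formats of a tracking campaign.

All tabular inputs are comma-separated UTF-8 files with a header row.  The
time column may hold either epoch seconds (any numeric) or ISO-8601 strings;
it is auto-detected and always converted to seconds since the flight epoch.
Rasters are ESRI ASCII grids (.asc), the one raster format that needs no
binary dependency; row 0 of the stored array is the northernmost row.

Readers validate rather than coerce: structurally malformed rows are dropped
with a logged count, while physically impossible values (a pressure of
50 hPa, a latitude of 95 degrees) raise :class:`ValidationError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """File does not conform to the expected schema."""


class ValidationError(ValueError):
    """A value violates a physical-range invariant."""


class EmptyInputError(ValueError):
    """File contains a header but no usable rows."""


@dataclass(frozen=True)
class Morphology:
    """Per-bird morphometrics used by the flight-power model."""

    bird_id: str
    mass: float       # kg
    wingspan: float   # m
    wing_area: float  # m^2

    def __post_init__(self):
        if min(self.mass, self.wingspan, self.wing_area) <= 0:
            raise ValidationError(f"morphology of {self.bird_id}: all fields must be positive")
        ar = self.wingspan**2 / self.wing_area
        if not 2.0 < ar < 25.0:
            raise ValidationError(
                f"morphology of {self.bird_id}: aspect ratio {ar:.2f} outside plausible (2, 25)"
            )

    @property
    def aspect_ratio(self) -> float:
        return self.wingspan**2 / self.wing_area


@dataclass
class RasterGrid:
    """A georeferenced grid in WGS84 decimal degrees, cell-centre registered.

    ``values[0, :]`` is the northernmost row (ESRI ASCII convention);
    NODATA cells hold NaN.
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center_x(self, col):
        return self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize

    def cell_center_y(self, row):
        # row 0 is the northernmost row
        return self.yllcorner + (self.nrows - 1 - np.asarray(row) + 0.5) * self.cellsize


def _read_table(path, required, column_map=None):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: header only, no rows")
    return df


def _parse_time(series, path):
    """Epoch/relative seconds or ISO-8601 -> float seconds."""
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601", utc=True)
    if parsed.notna().sum() == 0:
        raise FormatError(f"{path}: time column is neither numeric nor ISO-8601")
    return (parsed - parsed.iloc[0]).dt.total_seconds() + 0.0


def _drop_bad_rows(df, cols, path):
    bad = df[cols].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d malformed rows", path, int(bad.sum()))
        df = df[~bad]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no valid rows after rejecting malformed ones")
    return df


def read_gps_csv(path, column_map=None) -> pd.DataFrame:
    """Read a GPS log into a time-sorted frame of columns time, lat, lon.

    Duplicate timestamps are collapsed to the first occurrence; sampling
    gaps larger than 1.5x the median interval are logged.
    """
    df = _read_table(path, ("time", "lat", "lon"), column_map)
    df = df.copy()
    df["time"] = _parse_time(df["time"], path)
    for c in ("lat", "lon"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = _drop_bad_rows(df, ["time", "lat", "lon"], path)
    if (df["lat"].abs() > 90).any():
        raise ValidationError(f"{path}: latitude outside [-90, 90]")
    if (df["lon"].abs() > 180).any():
        raise ValidationError(f"{path}: longitude outside [-180, 180]")
    df = df.sort_values("time", kind="mergesort")
    dup = df["time"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: collapsed %d duplicate timestamps", path, int(dup.sum()))
        df = df[~dup]
    dt = np.diff(df["time"].to_numpy())
    if len(dt) > 0:
        med = np.median(dt)
        gaps = int(np.sum(dt > 1.5 * med)) if med > 0 else 0
        if gaps:
            logger.warning("%s: %d sampling gaps > 1.5x median interval", path, gaps)
    return df[["time", "lat", "lon"]].reset_index(drop=True)


def read_pressure_csv(path, column_map=None) -> pd.DataFrame:
    """Read a barometric log into a time-sorted frame of time, pressure [hPa]."""
    df = _read_table(path, ("time", "pressure"), column_map)
    df = df.copy()
    df["time"] = _parse_time(df["time"], path)
    df["pressure"] = pd.to_numeric(df["pressure"], errors="coerce")
    df = _drop_bad_rows(df, ["time", "pressure"], path)
    p = df["pressure"]
    if ((p < 300) | (p > 1100)).any():
        raise ValidationError(f"{path}: pressure outside the physical range [300, 1100] hPa")
    df = df.sort_values("time", kind="mergesort")
    return df[["time", "pressure"]].reset_index(drop=True)


def read_wind_log(path, column_map=None) -> pd.DataFrame:
    """Read an anemometer log: time, speed [m/s], direction_from [deg, 0-360).

    Directions are meteorological (the direction the wind blows FROM) and
    are normalized into [0, 360); raw values outside [-360, 720] are treated
    as sensor garbage and rejected.
    """
    df = _read_table(path, ("time", "speed", "direction_from"), column_map)
    df = df.copy()
    df["time"] = _parse_time(df["time"], path)
    for c in ("speed", "direction_from"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = _drop_bad_rows(df, ["time", "speed", "direction_from"], path)
    if (df["speed"] < 0).any():
        raise ValidationError(f"{path}: negative wind speed")
    d = df["direction_from"]
    if ((d < -360) | (d > 720)).any():
        raise FormatError(f"{path}: wind direction outside [-360, 720]")
    df["direction_from"] = np.mod(d, 360.0)
    df = df.sort_values("time", kind="mergesort")
    return df[["time", "speed", "direction_from"]].reset_index(drop=True)


def read_morphology_csv(path) -> dict[str, Morphology]:
    """Read the per-bird morphology table keyed by bird_id."""
    df = _read_table(path, ("bird_id", "mass", "wingspan", "wing_area"))
    out = {}
    for _, row in df.iterrows():
        m = Morphology(str(row["bird_id"]), float(row["mass"]),
                       float(row["wingspan"]), float(row["wing_area"]))
        out[m.bird_id] = m
    return out


# ---------------------------------------------------------------- rasters

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in _ASC_HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: malformed ESRI ASCII header, missing '{key}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    body = " ".join(lines[i:]).split()
    if len(body) != ncols * nrows:
        raise FormatError(
            f"{path}: body holds {len(body)} cells, header promises {ncols * nrows}"
        )
    values = np.array(body, dtype=float).reshape(nrows, ncols)
    values[values == nodata] = np.nan
    return RasterGrid(values, header["xllcorner"], header["yllcorner"],
                      header["cellsize"], nodata)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10f}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10f}\n")
        fh.write(f"cellsize {grid.cellsize:.10f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
        for row in vals:
            fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")


# ----------------------------------------------------------- track tables

_FLAG_COLUMNS = ("flag_circling", "flag_trimmed", "flag_resting")

_META_KEYS = ("flight_id", "bird_id", "date", "mean_wind_speed",
              "mean_wind_direction", "route_class", "include_in_analysis",
              "exclusion_reason")


def write_track_csv(flight, path) -> None:
    """Write a derived flight to CSV: metadata as '# key: value' comment
    lines, then one row per track point with flags as boolean columns.
    Numeric fields round-trip at 6 decimal places."""
    df = flight.points
    with open(path, "w") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key}: {getattr(flight, key)}\n")
        cols = list(df.columns)
        fh.write(",".join(cols) + "\n")
        for _, row in df.iterrows():
            cells = []
            for c in cols:
                v = row[c]
                if isinstance(v, (bool, np.bool_)):
                    cells.append("True" if v else "False")
                elif isinstance(v, (float, np.floating)):
                    cells.append("" if np.isnan(v) else f"{v:.6f}")
                else:
                    cells.append(str(v))
            fh.write(",".join(cells) + "\n")


def read_track_csv(path):
    """Inverse of :func:`write_track_csv`; returns a Flight."""
    from .segmentation import Flight  # deferred: io sits below segmentation

    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    for c in _FLAG_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(bool)
    wind = meta.get("mean_wind_speed", "nan")
    wdir = meta.get("mean_wind_direction", "nan")
    return Flight(
        flight_id=meta.get("flight_id", ""),
        bird_id=meta.get("bird_id", ""),
        date=meta.get("date", ""),
        points=df,
        mean_wind_speed=float(wind) if wind not in ("", "None") else float("nan"),
        mean_wind_direction=float(wdir) if wdir not in ("", "None") else float("nan"),
        route_class=meta.get("route_class", "unset"),
        include_in_analysis=meta.get("include_in_analysis", "True") == "True",
        exclusion_reason=meta.get("exclusion_reason", "") or "",
    )
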