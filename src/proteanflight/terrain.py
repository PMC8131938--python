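"""Terrain and land-cover annotation of flight tracks.

Tracks are sampled against two rasters: a digital surface model (elevation,
bilinearly interpolated between cell centres) and a categorical land-cover
grid (nearest cell, integer codes mapped to {open, woodland}).  On top of
the annotation sit the route-level analyses: valley/hill classification
against the 465 m contour, the along-track terrain slope, the distance at
which a bird begins its sustained climb ahead of a hill, and the altitude
contrast between hill-bound and valley-bound flights over the plain that
precedes the hill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodesy import step_distances
from .io_formats import RasterGrid
from .kinematics import smooth_series


@dataclass
class LandCoverMapping:
    """Integer raster codes -> {'open', 'woodland'}; unmapped codes -> 'unknown'."""

    mapping: dict[int, str]

    def classify(self, codes) -> np.ndarray:
        codes = np.asarray(codes)
        out = np.full(codes.shape, "unknown", dtype=object)
        for code, label in self.mapping.items():
            out[codes == code] = label
        out[~np.isfinite(codes.astype(float))] = "unknown"
        return out


@dataclass
class TerrainConfig:
    elevation_threshold: float = 465.0   # m, valley/hill contour
    hill_fraction: float = 0.10          # min fraction of travel time over high ground
    onset_vz: float = 0.3                # m/s sustained climb defining onset
    onset_hold_s: float = 10.0
    onset_smooth_s: float = 20.0         # trend window so protean wiggles don't trigger
    plain_window_m: tuple = (500.0, 1700.0)  # along-track window over the pre-hill plain


def sample_grid(grid: RasterGrid, lat, lon, method: str = "bilinear"):
    """Sample a raster at WGS84 points; cell-centre registered.

    Bilinear interpolation for continuous fields, nearest cell for
    categorical ones.  Points outside the grid return NaN (flagged missing
    rather than raising).
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    # fractional column/row in cell-centre coordinates
    fc = (lon - grid.xllcorner) / grid.cellsize - 0.5
    fr = (grid.nrows - 1) - ((lat - grid.yllcorner) / grid.cellsize - 0.5)
    out = np.full(lat.shape, np.nan)
    if method == "nearest":
        c = np.round(fc).astype(int)
        r = np.round(fr).astype(int)
        ok = (c >= 0) & (c < grid.ncols) & (r >= 0) & (r < grid.nrows)
        out[ok] = grid.values[r[ok], c[ok]]
    elif method == "bilinear":
        c0 = np.clip(np.floor(fc).astype(int), 0, grid.ncols - 1)
        r0 = np.clip(np.floor(fr).astype(int), 0, grid.nrows - 1)
        c1 = np.clip(c0 + 1, 0, grid.ncols - 1)
        r1 = np.clip(r0 + 1, 0, grid.nrows - 1)
        wc = np.clip(fc - c0, 0.0, 1.0)
        wr = np.clip(fr - r0, 0.0, 1.0)
        ok = (fc >= -0.5) & (fc <= grid.ncols - 0.5) & (fr >= -0.5) & (fr <= grid.nrows - 0.5)
        v00 = grid.values[r0, c0]
        v01 = grid.values[r0, c1]
        v10 = grid.values[r1, c0]
        v11 = grid.values[r1, c1]
        interp = (v00 * (1 - wr) * (1 - wc) + v01 * (1 - wr) * wc
                  + v10 * wr * (1 - wc) + v11 * wr * wc)
        out[ok] = interp[ok]
    else:
        raise ValueError(f"unknown sampling method '{method}'")
    return out if out.shape != (1,) else float(out[0])


def altitude_agl(altitude_asl, ground_elevation):
    """AGL = ASL - ground; may be negative (barometric calibration drift)."""
    return np.asarray(altitude_asl, dtype=float) - np.asarray(ground_elevation, dtype=float)


def annotate(points: pd.DataFrame, terrain: RasterGrid,
             landcover: RasterGrid | None = None,
             mapping: LandCoverMapping | None = None) -> pd.DataFrame:
    """Add ground_elevation, altitude_agl, landcover and along-track columns."""
    pts = points.copy()
    ground = sample_grid(terrain, pts["lat"].to_numpy(), pts["lon"].to_numpy())
    pts["ground_elevation"] = ground
    pts["altitude_agl"] = altitude_agl(pts["altitude_asl"].to_numpy(), ground)
    if landcover is not None and mapping is not None:
        codes = sample_grid(landcover, pts["lat"].to_numpy(), pts["lon"].to_numpy(),
                            method="nearest")
        pts["landcover"] = mapping.classify(codes)
    else:
        pts["landcover"] = "unknown"
    steps = step_distances(pts["lat"].to_numpy(), pts["lon"].to_numpy()) if len(pts) > 1 else np.array([])
    pts["along_track_m"] = np.concatenate([[0.0], np.cumsum(steps)]) if len(pts) else []
    return pts


def classify_route(points: pd.DataFrame, elevation_threshold: float = 465.0,
                   hill_fraction: float = 0.10) -> str:
    """'hill' if the bird flies above the threshold over high ground for at
    least ``hill_fraction`` of the travel time, 'valley' if the ground stays
    below the threshold throughout, else 'mixed'."""
    if "ground_elevation" not in points.columns:
        raise ValueError("track not annotated with ground elevation")
    ground = points["ground_elevation"].to_numpy()
    alt = points["altitude_asl"].to_numpy()
    ok = np.isfinite(ground)
    if not ok.any():
        raise ValueError("no terrain annotation available")
    over_hill = (ground >= elevation_threshold) & (alt > elevation_threshold) & ok
    frac = over_hill.sum() / ok.sum()
    if frac >= hill_fraction:
        return "hill"
    if np.all(ground[ok] < elevation_threshold):
        return "valley"
    return "mixed"


def terrain_slope_along_track(points: pd.DataFrame) -> np.ndarray:
    """Ground slope (m per m along track) under the bird; forward
    differences, zero-length steps carry the previous value."""
    ground = points["ground_elevation"].to_numpy()
    s = points["along_track_m"].to_numpy()
    if len(ground) < 2:
        raise ValueError("need at least two annotated points")
    dg = np.diff(ground)
    ds = np.diff(s)
    slope = np.zeros(len(dg))
    for i in range(len(dg)):
        slope[i] = dg[i] / ds[i] if ds[i] > 0 else (slope[i - 1] if i > 0 else 0.0)
    return np.append(slope, slope[-1])


def climb_onset_distance(points: pd.DataFrame, hill_threshold: float = 465.0,
                         onset_vz: float = 0.3, onset_hold_s: float = 10.0,
                         onset_smooth_s: float = 20.0,
                         merge_gap_s: float = 10.0,
                         rate_hz: float = 1.0) -> float:
    """Along-track distance (km) between climb onset and the hill base.

    The hill base is the first point whose ground elevation reaches
    ``hill_threshold``.  Climb onset is the start of the last sustained
    climb run (trend climb rate >= ``onset_vz`` held for ``onset_hold_s``)
    that begins before the hill base; the climb rate is smoothed over
    ``onset_smooth_s`` first so that fine-scale altitude variability does
    not masquerade as the onset of the ascent.  Positive values mean the
    climb anticipates the hill.  NaN when the track never reaches the hill.
    """
    ground = points["ground_elevation"].to_numpy()
    s = points["along_track_m"].to_numpy()
    vz = points["vz"].to_numpy()
    base_idx = np.flatnonzero(np.isfinite(ground) & (ground >= hill_threshold))
    if len(base_idx) == 0:
        return float("nan")
    base = base_idx[0]
    trend = smooth_series(np.nan_to_num(vz, nan=0.0), rate_hz, onset_smooth_s)
    climbing = trend >= onset_vz
    hold = max(int(round(onset_hold_s * rate_hz)), 1)
    # runs of sustained climbing; brief interruptions (protean dips in the
    # trend) are merged so one ascent is not split into fragments
    runs = []
    i = 0
    n = len(climbing)
    while i < n:
        if climbing[i]:
            j = i
            while j < n and climbing[j]:
                j += 1
            if j - i >= hold:
                runs.append([i, j])
            i = j
        else:
            i += 1
    gap = max(int(round(merge_gap_s * rate_hz)), 0)
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    # the ascent into the hill: the run that contains the hill base,
    # else the last run starting before it
    containing = [r for r in merged if r[0] <= base < r[1]]
    candidates = containing or [r for r in merged if r[0] <= base]
    if not candidates:
        return 0.0
    onset = candidates[-1][0]
    return float((s[base] - s[onset]) / 1000.0)


def plain_altitude_contrast(flights_points: dict[str, pd.DataFrame],
                            route_classes: dict[str, str],
                            plain_window_m: tuple = (500.0, 1700.0)):
    """Mean ASL difference (hill minus valley) over the pre-hill plain.

    ``flights_points`` maps flight_id -> annotated travel points with an
    along_track_m column.  Returns (contrast_m, per-flight DataFrame with
    flight_id, route_class, mean ASL over the plain).
    """
    rows = []
    s0, s1 = plain_window_m
    for fid, pts in flights_points.items():
        rc = route_classes.get(fid, "unset")
        if rc not in ("hill", "valley"):
            continue
        sel = pts[(pts["along_track_m"] >= s0) & (pts["along_track_m"] <= s1)]
        if len(sel) == 0:
            continue
        rows.append({"flight_id": fid, "route_class": rc,
                     "mean_asl": float(sel["altitude_asl"].mean())})
    per_flight = pd.DataFrame(rows)
    if len(per_flight) == 0 or per_flight["route_class"].nunique() < 2:
        raise ValueError("need at least one hill-class and one valley-class flight over the plain")
    hill = per_flight.loc[per_flight["route_class"] == "hill", "mean_asl"].mean()
    valley = per_flight.loc[per_flight["route_class"] == "valley", "mean_asl"].mean()
    return float(hill - valley), per_flight
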