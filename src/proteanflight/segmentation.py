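"""Exclusion rules that isolate the travelling section of a homing flight.

Four masks are applied to each derived track, mirroring a standard homing
protocol: flights with mean wind above 2 m/s are dropped entirely (so that
wind does not confound speed selection); circling bouts, the post-release
ascent and pre-landing descent, and resting on the ground are flagged
point-wise and removed.  The masks commute: the surviving point set does
not depend on the order in which they are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodesy import geodesic_inverse, path_length


@dataclass
class Flight:
    """A derived, annotated flight: metadata plus a table of track points."""

    flight_id: str
    bird_id: str
    date: str
    points: pd.DataFrame
    mean_wind_speed: float = float("nan")
    mean_wind_direction: float = float("nan")
    route_class: str = "unset"        # valley | hill | mixed | unset
    include_in_analysis: bool = True
    exclusion_reason: str = ""

    def copy(self) -> "Flight":
        return Flight(self.flight_id, self.bird_id, self.date,
                      self.points.copy(), self.mean_wind_speed,
                      self.mean_wind_direction, self.route_class,
                      self.include_in_analysis, self.exclusion_reason)


@dataclass
class SegmentationConfig:
    wind_threshold: float = 2.0          # m/s, flight-level filter
    circling_window_s: float = 30.0
    circling_net_rotation_deg: float = 270.0
    trim_radius_m: float = 200.0
    rest_speed_floor: float = 3.0        # m/s, well below pigeon Vmp
    rest_min_duration_s: float = 5.0
    rate_hz: float = 1.0
    # Optional guard band: also drop unflagged points within guard_s of a
    # flagged point, so values smoothed across an exclusion boundary do not
    # leak excluded behaviour into the travel segment.  Off by default; the
    # campaign pipeline sets it to the smoothing window.
    guard_s: float = 0.0


def wind_filter(flights: list[Flight], threshold: float = 2.0) -> list[Flight]:
    """Set include_in_analysis from the flight-level mean wind speed."""
    for fl in flights:
        if np.isnan(fl.mean_wind_speed):
            fl.include_in_analysis = False
            fl.exclusion_reason = "wind_missing"
        elif fl.mean_wind_speed > threshold:
            fl.include_in_analysis = False
            fl.exclusion_reason = "wind"
        else:
            fl.include_in_analysis = True
            fl.exclusion_reason = ""
    return flights


def detect_circling(headings_deg, window_s: float = 30.0,
                    net_rotation_deg: float = 270.0,
                    rate_hz: float = 1.0) -> np.ndarray:
    """Flag points belonging to circling bouts.

    A point is circling if any window of ``window_s`` containing it
    accumulates at least ``net_rotation_deg`` of signed heading rotation
    (headings unwrapped); the mask is the union over all such windows.
    """
    h = np.asarray(headings_deg, dtype=float)
    n = len(h)
    mask = np.zeros(n, dtype=bool)
    w = int(round(window_s * rate_hz))
    if n < 2 or w < 2:
        return mask
    cum = np.unwrap(np.radians(h))
    cum = np.degrees(cum)
    w = min(w, n)
    # window [i, i+w): net rotation = cum[i+w-1] - cum[i]
    net = np.abs(cum[w - 1:] - cum[: n - w + 1])
    hits = np.flatnonzero(net >= net_rotation_deg)
    for i in hits:
        mask[i:i + w] = True
    return mask


def _within_radius(points: pd.DataFrame, lat0: float, lon0: float,
                   radius_m: float) -> np.ndarray:
    d, _ = geodesic_inverse(points["lat"].to_numpy(), points["lon"].to_numpy(),
                            lat0, lon0)
    return np.atleast_1d(d) <= radius_m


def trim_takeoff_landing(points: pd.DataFrame, release: tuple[float, float],
                         loft: tuple[float, float],
                         radius_m: float = 200.0) -> np.ndarray:
    """Flag the ascent after take-off and the descent before landing.

    Points inside ``radius_m`` of the release before the track first leaves
    that radius, and inside the loft radius after the track last enters it,
    are flagged.  A flight that never leaves the release radius is flagged
    in full (degenerate case, caller should warn).
    """
    n = len(points)
    mask = np.zeros(n, dtype=bool)
    if n == 0 or radius_m <= 0:
        return mask
    near_release = _within_radius(points, release[0], release[1], radius_m)
    outside = np.flatnonzero(~near_release)
    if len(outside) == 0:
        return np.ones(n, dtype=bool)
    mask[: outside[0]] = near_release[: outside[0]]
    near_loft = _within_radius(points, loft[0], loft[1], radius_m)
    out_loft = np.flatnonzero(~near_loft)
    last_entry = out_loft[-1] + 1 if len(out_loft) else 0
    mask[last_entry:] |= near_loft[last_entry:]
    return mask


def detect_rest(vg, speed_floor: float = 3.0, min_duration_s: float = 5.0,
                rate_hz: float = 1.0) -> np.ndarray:
    """Flag runs of groundspeed below ``speed_floor`` lasting at least
    ``min_duration_s``."""
    v = np.asarray(vg, dtype=float)
    below = v < speed_floor
    mask = np.zeros(len(v), dtype=bool)
    min_len = int(round(min_duration_s * rate_hz))
    i = 0
    while i < len(v):
        if below[i]:
            j = i
            while j < len(v) and below[j]:
                j += 1
            if j - i >= min_len:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def apply_masks(flight: Flight, release: tuple[float, float],
                loft: tuple[float, float],
                config: SegmentationConfig | None = None) -> Flight:
    """Compute all three point-wise masks and store them as flag columns."""
    cfg = config or SegmentationConfig()
    pts = flight.points
    pts = pts.copy()
    pts["flag_circling"] = detect_circling(
        pts["heading"].to_numpy(), cfg.circling_window_s,
        cfg.circling_net_rotation_deg, cfg.rate_hz)
    pts["flag_trimmed"] = trim_takeoff_landing(pts, release, loft, cfg.trim_radius_m)
    pts["flag_resting"] = detect_rest(
        pts["vg"].to_numpy(), cfg.rest_speed_floor, cfg.rest_min_duration_s,
        cfg.rate_hz)
    out = flight.copy()
    out.points = pts
    return out


def travel_segment(flight: Flight, guard_s: float = 0.0,
                   rate_hz: float = 1.0) -> tuple[Flight, dict]:
    """Drop all flagged points; report duration (min) and path length (km).

    ``guard_s`` > 0 additionally drops unflagged points within that many
    seconds of a flagged one (values smoothed across an exclusion boundary
    carry excluded behaviour).  Raises ValueError when nothing survives.
    """
    pts = flight.points
    for col in ("flag_circling", "flag_trimmed", "flag_resting"):
        if col not in pts.columns:
            raise ValueError(f"mask column {col} missing; run apply_masks first")
    flagged = (pts["flag_circling"] | pts["flag_trimmed"] | pts["flag_resting"]).to_numpy()
    if guard_s > 0 and flagged.any():
        g = int(round(guard_s * rate_hz))
        dilated = flagged.copy()
        for i in np.flatnonzero(flagged):
            dilated[max(i - g, 0):i + g + 1] = True
        flagged = dilated
    keep = pd.Series(~flagged, index=pts.index)
    if not keep.any():
        raise ValueError(f"flight {flight.flight_id}: no points survive the exclusion masks")
    travel = pts[keep].reset_index(drop=True)
    out = flight.copy()
    out.points = travel
    stats = {
        "duration_min": float(len(travel) / 60.0),
        "path_km": path_length(travel["lat"].to_numpy(), travel["lon"].to_numpy()) / 1000.0,
        "n_points": int(len(travel)),
        "n_excluded_points": int((~keep).sum()),
    }
    return out, stats
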