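"""Derivation of altitude, speeds, headings and airspeed from raw samples.

The chain implemented here is the standard biologging airspeed
decomposition: barometric pressure, calibrated against the release site in
the seconds before take-off, gives altitude above sea level through the
hypsometric equation; consecutive GPS fixes give groundspeed and heading on
the WGS84 ellipsoid; the measured wind vector is removed from the ground
vector to give the horizontal airspeed

    Vx = sqrt(Vg^2 + Vw^2 + 2 Vg Vw cos(theta)),

where theta in [0, 180] is the angle between the track heading and the
meteorological wind direction (theta = 0 a pure headwind, theta = 180 a pure
tailwind, so that a tailwind reduces Vx to |Vg - Vw|); and the total
airspeed is the vector sum with the climb rate, Va = sqrt(Vx^2 + Vz^2).

Altitude and groundspeed are smoothed over 5 s before differencing, to
suppress wingbeat and sensor noise; all first differences are forward
differences assigned to the earlier sample, with the final sample carrying
the last defined value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodesy import geodesic_inverse

# ISA constants for the hypsometric equation
LAPSE_RATE = 0.0065        # K / m
GAS_CONSTANT = 8.31446     # J / (mol K)
GRAVITY = 9.80665          # m / s^2
MOLAR_MASS_AIR = 0.0289644  # kg / mol
HYPSO_EXPONENT = GAS_CONSTANT * LAPSE_RATE / (GRAVITY * MOLAR_MASS_AIR)


@dataclass(frozen=True)
class CalibrationContext:
    """Barometric reference measured at the release site before take-off."""

    reference_pressure: float          # hPa
    reference_altitude: float          # m ASL
    reference_temperature: float = 288.15  # K

    def __post_init__(self):
        if not 300.0 < self.reference_pressure < 1100.0:
            raise ValueError(f"reference pressure {self.reference_pressure} hPa out of range")
        if not -430.0 < self.reference_altitude < 9000.0:
            raise ValueError(f"reference altitude {self.reference_altitude} m out of range")


@dataclass
class KinematicsConfig:
    """Tunables of the derivation chain (defaults follow the study design)."""

    smooth_window_s: float = 5.0       # altitude and speed smoothing
    smooth_heading: bool = True        # circular 5-s smoothing of headings
    gps_rate_hz: float = 1.0
    pressure_rate_hz: float = 4.0
    calibration_window_s: float = 10.0


def pressure_to_altitude(pressure, calib: CalibrationContext):
    """Invert the barometric formula, anchored at the calibration point.

    altitude = h_ref + (T_ref / L) * (1 - (p / p_ref)^(R L / (g M)))

    Strictly decreasing in pressure; exact at p = p_ref.
    """
    p = np.asarray(pressure, dtype=float)
    if np.any((p < 300.0) | (p > 1100.0)):
        raise ValueError("pressure outside the physical range [300, 1100] hPa")
    ratio = p / calib.reference_pressure
    alt = calib.reference_altitude + (calib.reference_temperature / LAPSE_RATE) * (
        1.0 - ratio**HYPSO_EXPONENT
    )
    return float(alt) if np.ndim(pressure) == 0 else alt


def altitude_to_pressure(altitude, calib: CalibrationContext):
    """Inverse of :func:`pressure_to_altitude` (used to synthesize sensors)."""
    h = np.asarray(altitude, dtype=float)
    base = 1.0 - LAPSE_RATE * (h - calib.reference_altitude) / calib.reference_temperature
    p = calib.reference_pressure * base ** (1.0 / HYPSO_EXPONENT)
    return float(p) if np.ndim(altitude) == 0 else p


def calibrate_reference(pressure: pd.DataFrame, site_elevation: float,
                        takeoff_time: float, window_s: float = 10.0,
                        reference_temperature: float = 288.15) -> CalibrationContext:
    """Mean pressure over the window preceding take-off, anchored at the
    release-site elevation."""
    t = pressure["time"].to_numpy()
    mask = (t >= takeoff_time - window_s) & (t < takeoff_time)
    if not mask.any():
        raise ValueError(
            f"no pressure samples in the {window_s} s window before take-off at t={takeoff_time}"
        )
    p_ref = float(pressure.loc[mask, "pressure"].mean())
    return CalibrationContext(p_ref, float(site_elevation), reference_temperature)


def resample_pressure_to_track(pressure: pd.DataFrame, fix_times) -> np.ndarray:
    """Mean of the pressure samples in [t - 0.5, t + 0.5) per GPS fix.

    Fixes outside sensor coverage get NaN (flagged missing, not raised).
    """
    t = pressure["time"].to_numpy()
    p = pressure["pressure"].to_numpy()
    fix_times = np.asarray(fix_times, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(p)])
    lo = np.searchsorted(t, fix_times - 0.5, side="left")
    hi = np.searchsorted(t, fix_times + 0.5, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, (csum[hi] - csum[lo]) / np.where(n == 0, 1, n), np.nan)
    return out


def smooth_series(values, rate_hz: float, window_s: float) -> np.ndarray:
    """Centered moving average over round(window_s * rate_hz) points.

    The window is truncated (not padded) at the series ends, so output
    length equals input length and constants are preserved exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    n = int(round(window_s * rate_hz))
    if n < 1:
        raise ValueError("window shorter than one sample")
    return (
        pd.Series(x).rolling(window=n, center=True, min_periods=1).mean().to_numpy()
    )


def smooth_heading(headings_deg, rate_hz: float, window_s: float) -> np.ndarray:
    """Circular moving average of headings via unit-vector components."""
    h = np.radians(np.asarray(headings_deg, dtype=float))
    s = smooth_series(np.sin(h), rate_hz, window_s)
    c = smooth_series(np.cos(h), rate_hz, window_s)
    return np.mod(np.degrees(np.arctan2(s, c)), 360.0)


def ground_speed_heading(fixes: pd.DataFrame):
    """Groundspeed (m/s) and heading (deg) from consecutive GPS fixes.

    Values are assigned to the earlier fix; the final fix inherits the
    previous value.  Zero-displacement steps keep Vg = 0 and carry the
    previous heading.
    """
    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    t = fixes["time"].to_numpy()
    if len(lat) < 2:
        raise ValueError("need at least two fixes")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-positive time step between fixes")
    dist, azim = geodesic_inverse(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dist = np.atleast_1d(dist)
    azim = np.atleast_1d(azim)
    vg = dist / dt
    # carry heading through zero-displacement steps
    stationary = dist == 0.0
    for i in np.flatnonzero(stationary):
        azim[i] = azim[i - 1] if i > 0 else azim[~stationary][0] if (~stationary).any() else 0.0
    vg = np.append(vg, vg[-1])
    heading = np.append(azim, azim[-1])
    return vg, heading


def relative_wind_angle(heading, direction_from):
    """Unsigned circular difference between track heading and wind-from
    direction, folded to [0, 180]; 0 = headwind, 180 = tailwind."""
    h = np.asarray(heading, dtype=float)
    d = np.asarray(direction_from, dtype=float)
    theta = np.abs(np.mod(h - d + 180.0, 360.0) - 180.0)
    return float(theta) if np.ndim(heading) == 0 and np.ndim(direction_from) == 0 else theta


def horizontal_airspeed(vg, vw, theta):
    """Law-of-cosines wind correction (air vector = ground vector - wind vector)."""
    vg = np.asarray(vg, dtype=float)
    vw = np.asarray(vw, dtype=float)
    if np.any(vg < 0) or np.any(vw < 0):
        raise ValueError("speeds must be non-negative")
    th = np.radians(np.asarray(theta, dtype=float))
    vx2 = vg**2 + vw**2 + 2.0 * vg * vw * np.cos(th)
    vx = np.sqrt(np.maximum(vx2, 0.0))
    return float(vx) if vx.ndim == 0 else vx


def first_difference(values) -> np.ndarray:
    """Forward first differences assigned to the earlier sample; the last
    sample inherits the previous value."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    d = np.diff(x)
    return np.append(d, d[-1])


def climb_rate(altitude_asl) -> np.ndarray:
    """Vz (m/s, + up) as first differences of the smoothed 1 Hz altitude."""
    return first_difference(altitude_asl)


def total_airspeed(vx, vz):
    """Va = sqrt(Vx^2 + Vz^2)."""
    vx = np.asarray(vx, dtype=float)
    if np.any(vx < 0):
        raise ValueError("Vx must be non-negative")
    va = np.sqrt(vx**2 + np.asarray(vz, dtype=float) ** 2)
    return float(va) if va.ndim == 0 else va


def acceleration(va) -> np.ndarray:
    """Forward acceleration (m/s^2): first differences of Va at 1 Hz."""
    return first_difference(va)


def climb_angle(vz, vx):
    """Signed climb angle in degrees, atan2(Vz, Vx); NaN where both are 0."""
    vz = np.asarray(vz, dtype=float)
    vx = np.asarray(vx, dtype=float)
    ang = np.degrees(np.arctan2(vz, vx))
    ang = np.where((vz == 0) & (vx == 0), np.nan, ang)
    return float(ang) if ang.ndim == 0 else ang


def mean_wind(wind: pd.DataFrame, t_start: float | None = None,
              t_end: float | None = None):
    """Flight-level mean wind: arithmetic mean speed and circular mean
    direction over the anemometer records spanning the flight."""
    w = wind
    if t_start is not None:
        w = w[w["time"] >= t_start]
    if t_end is not None:
        w = w[w["time"] <= t_end]
    if len(w) == 0:
        w = wind  # fall back to the full log
    speed = float(w["speed"].mean())
    d = np.radians(w["direction_from"].to_numpy())
    direction = float(np.mod(np.degrees(np.arctan2(np.sin(d).mean(), np.cos(d).mean())), 360.0))
    return speed, direction


def derive_track(gps: pd.DataFrame, pressure: pd.DataFrame, wind: pd.DataFrame,
                 calib: CalibrationContext,
                 config: KinematicsConfig | None = None) -> pd.DataFrame:
    """Run the full per-flight derivation chain on raw samples.

    Returns one row per GPS fix with columns time, lat, lon, pressure,
    altitude_asl (smoothed), vg, heading, theta, vx, vz, va, accel,
    climb_angle, plus the flight-level wind columns.
    """
    cfg = config or KinematicsConfig()
    t = gps["time"].to_numpy()

    p_fix = resample_pressure_to_track(pressure, t)
    missing_p = np.isnan(p_fix)
    p_smooth = p_fix.copy()
    if (~missing_p).any():
        # smooth over valid samples only; isolated NaNs stay NaN
        p_smooth = smooth_series(np.where(missing_p, np.nanmean(p_fix), p_fix),
                                 cfg.gps_rate_hz, cfg.smooth_window_s)
        p_smooth[missing_p] = np.nan
    alt = np.full_like(p_smooth, np.nan)
    ok = ~np.isnan(p_smooth)
    if ok.any():
        alt[ok] = pressure_to_altitude(p_smooth[ok], calib)

    vg_raw, heading_raw = ground_speed_heading(gps)
    vg = smooth_series(vg_raw, cfg.gps_rate_hz, cfg.smooth_window_s)
    heading = (smooth_heading(heading_raw, cfg.gps_rate_hz, cfg.smooth_window_s)
               if cfg.smooth_heading else heading_raw)

    # first differences propagate NaN from missing-pressure fixes
    vz = climb_rate(alt) if len(alt) >= 2 else np.full_like(alt, np.nan)

    w_speed, w_dir = mean_wind(wind, t[0], t[-1])
    theta = relative_wind_angle(heading, w_dir)
    vx = horizontal_airspeed(vg, w_speed, theta)
    va = total_airspeed(vx, np.nan_to_num(vz, nan=0.0))
    va[np.isnan(vz)] = np.nan
    accel = acceleration(va) if len(va) >= 2 else np.full_like(va, np.nan)
    angle = climb_angle(np.nan_to_num(vz, nan=0.0), vx)
    angle = np.where(np.isnan(vz), np.nan, angle)

    return pd.DataFrame({
        "time": t,
        "lat": gps["lat"].to_numpy(),
        "lon": gps["lon"].to_numpy(),
        "pressure": p_fix,
        "altitude_asl": alt,
        "vg": vg,
        "heading": heading,
        "theta": theta,
        "vx": vx,
        "vz": vz,
        "va": va,
        "accel": accel,
        "climb_angle": angle,
        "wind_speed": np.full_like(vg, w_speed),
        "wind_direction": np.full_like(vg, w_dir),
    })
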