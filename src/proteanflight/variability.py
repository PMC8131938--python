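"""Protean-variability statistics of travelling flight.

These metrics quantify how unsteady a flight is: the spread and range of
airspeed within a flight, the distributions of climb and descent rates and
of forward acceleration, climb angles, the extra vertical distance flown
relative to a 20-s-smoothed altitude profile (fine-scale up-and-down that a
steady flier would not incur), and the horizontal tortuosity of the path.
Unpredictable fine-scale variation of this kind is interpreted as protean
behaviour: it degrades a pursuing predator's ability to anticipate the
bird's position, at an energetic cost.

All quantiles use linear interpolation (Hyndman-Fan type 7, the numpy
default) for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodesy import geodesic_distance, path_length
from .kinematics import smooth_series


def speed_stats(va) -> dict:
    """Mean, s.d., within-flight range (max - min) and max of airspeed."""
    v = np.asarray(va, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no airspeed samples")
    return {
        "va_mean": float(np.mean(v)),
        "va_sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "va_range": float(np.max(v) - np.min(v)),
        "va_max": float(np.max(v)),
    }


def _median_iqr(x) -> tuple[float, float]:
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 linear interpolation
    return float(q2), float(q3 - q1)


def climb_descent_stats(vz) -> dict:
    """Median and IQR of the climbing (Vz > 0) and descending (Vz < 0)
    subsets; NaN where a subset is empty."""
    v = np.asarray(vz, dtype=float)
    v = v[np.isfinite(v)]
    climb = v[v > 0]
    desc = v[v < 0]
    out = {"climb_median": float("nan"), "climb_iqr": float("nan"),
           "descent_median": float("nan"), "descent_iqr": float("nan")}
    if climb.size:
        out["climb_median"], out["climb_iqr"] = _median_iqr(climb)
    if desc.size:
        out["descent_median"], out["descent_iqr"] = _median_iqr(desc)
    return out


def accel_stats(accel) -> dict:
    """Median, IQR and range of forward acceleration."""
    a = np.asarray(accel, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no acceleration samples")
    med, iqr = _median_iqr(a)
    return {"accel_median": med, "accel_iqr": iqr,
            "accel_min": float(np.min(a)), "accel_max": float(np.max(a))}


def climb_angle_stats(angles_deg) -> dict:
    """Max climb angle and the fraction of strictly positive angles <= 5 deg."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no climb-angle samples")
    pos = a[a > 0]
    frac = float(np.mean(pos <= 5.0)) if pos.size else float("nan")
    return {"max_climb_angle": float(np.max(a)), "frac_pos_angles_le_5deg": frac}


def extra_vertical_distance(altitude_fine, window_s: float = 20.0,
                            rate_hz: float = 1.0) -> float:
    """Fine-scale vertical distance in excess of the 20-s-smoothed profile.

    D_fine = sum |delta altitude|; D_smooth = the same on the smoothed
    profile; returns max(D_fine - D_smooth, 0).  Zero for constants and
    (up to end effects) for monotone ramps, invariant to adding a constant.
    """
    alt = np.asarray(altitude_fine, dtype=float)
    n_win = int(round(window_s * rate_hz))
    if alt.size < n_win:
        raise ValueError(f"flight shorter than the {window_s} s smoothing window")
    # both sums run over the full-window interior, so truncated windows at
    # the series ends cannot register as vertical distance (a ramp is 0)
    k = n_win // 2
    smooth = smooth_series(alt, rate_hz, window_s)
    d_fine = float(np.sum(np.abs(np.diff(alt[k:alt.size - k]))))
    d_smooth = float(np.sum(np.abs(np.diff(smooth[k:alt.size - k]))))
    return max(d_fine - d_smooth, 0.0)


def tortuosity(lat, lon) -> float:
    """Along-track path length over the geodesic start-to-end distance (>= 1)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) < 2:
        raise ValueError("need at least two points")
    straight = geodesic_distance(lat[0], lon[0], lat[-1], lon[-1])
    if straight == 0:
        raise ValueError("zero straight-line displacement")
    return path_length(lat, lon) / straight


def flight_report(points: pd.DataFrame, window_s: float = 20.0,
                  rate_hz: float = 1.0) -> dict:
    """All per-flight variability metrics from a travel-segment table."""
    rep = {}
    rep.update(speed_stats(points["va"]))
    rep.update(climb_descent_stats(points["vz"]))
    rep.update(accel_stats(points["accel"]))
    rep.update(climb_angle_stats(points["climb_angle"]))
    rep["extra_vertical_distance_m"] = extra_vertical_distance(
        points["altitude_asl"].to_numpy(), window_s, rate_hz)
    rep["tortuosity"] = tortuosity(points["lat"].to_numpy(), points["lon"].to_numpy())
    return rep


def pooled_report(per_flight: pd.DataFrame) -> pd.DataFrame:
    """Grand mean and s.d. of each per-flight metric across flights.

    Permutation-invariant: rows may arrive in any order.
    """
    numeric = per_flight.select_dtypes(include=[np.number])
    return pd.DataFrame({
        "metric": numeric.columns,
        "mean": numeric.mean(axis=0).to_numpy(),
        "sd": numeric.std(axis=0, ddof=1).to_numpy(),
    })
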