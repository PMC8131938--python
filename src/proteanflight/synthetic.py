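"""Synthetic homing-flight campaign generator.

Emits raw logger files (1 Hz GPS, 4 Hz barometric pressure, 10 s anemometer
records), terrain and land-cover grids and per-bird morphology with the
statistical structure the analysis pipeline assumes, together with a
ground-truth record for every emitted flight, so that each pipeline stage
can be tested end-to-end without any field data.

The simulated world is a valley running north from a release site to a
loft ~7 km away, flanked by a ridge (Gaussian profile, peak above the
465 m valley/hill contour) east of the direct route.  Valley-route birds
follow a gently sinuous corridor at a fixed target altitude; hill-route
birds bow east over the ridge, fly a programmed 50 m higher over the plain,
and begin a sustained climb a programmed distance (default 2 km) before the
ground reaches the 465 m contour.  On top of the route programme, speed and
altitude carry mean-reverting (discrete Ornstein-Uhlenbeck) perturbations —
the protean variability the analysis quantifies — and airspeed follows the
programmed linear dependence on climb rate plus bird and day random
intercepts.  Ground velocity is air velocity plus the per-flight wind
vector; true altitude is converted to pressure through the inverse
hypsometric formula before sensor noise is added, and GPS positions get
independent Gaussian noise.

Route class and wind speed follow a deterministic schedule over the
bird x day grid (independent of the RNG), so the campaign composition
(28 flights, 7 hill-class, 7 wind-excluded by the 2 m/s filter) is
invariant across seeds; every stochastic ingredient is driven by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geodesy
from .io_formats import Morphology, RasterGrid, write_ascii_grid
from .kinematics import CalibrationContext, altitude_to_pressure


@dataclass
class SimConfig:
    """Study conditions of the synthetic campaign (defaults are the
    conditions every test and the acceptance harness run under)."""

    seed: int = 0
    n_birds: int = 7
    flights_per_bird: int = 4           # one flight per bird per day
    duration_s: int = 360               # travelling time at 1 Hz
    base_airspeed: float = 20.0         # m/s
    airspeed_climb_slope: float = -1.24  # dVa/dVz
    climb_slope: float | None = None    # optional asymmetric slopes
    descent_slope: float | None = None
    landcover_effect: float = -0.165    # m/s, woodland relative to open

    # protean (mean-reverting) perturbations
    speed_sd: float = 2.0               # m/s stationary sd
    speed_tau_s: float = 10.0           # correlation time
    alt_sd: float = 3.0                 # m stationary sd
    alt_tau_s: float = 8.0

    # random intercepts
    bird_sd: float = 1.0                # m/s
    day_sd: float = 1.0                 # m/s

    # sensor noise
    gps_noise_sd: float = 1.0           # m
    pressure_noise_sd: float = 0.05     # hPa (4 Hz sensor)
    anemometer_speed_sd: float = 0.1    # m/s per 10 s record
    anemometer_dir_sd: float = 3.0      # degrees per record

    # release-area geometry (local tangent plane, x east / y north, metres)
    release_lat: float = 47.80
    release_lon: float = 9.00
    route_length_m: float = 8000.0
    loft_along_m: float = 7200.0
    valley_floor: float = 430.0         # m ASL
    ridge_height: float = 160.0         # above the valley floor -> 590 m peak
    ridge_y: float = 4500.0
    ridge_sigma_y: float = 400.0
    ridge_x: float = 1800.0
    ridge_sigma_x: float = 700.0
    stripe_width_m: float = 500.0       # land-cover striping along y
    terrain_cellsize_m: float = 30.0
    landcover_cellsize_m: float = 100.0

    # altitude programme
    valley_asl: float = 490.0           # m, valley-route target
    hill_plain_asl: float = 540.0       # m, hill route over the plain (+50 contrast)
    crest_clearance: float = 60.0       # m above the ridge peak
    climb_anticipation_m: float = 2000.0  # climb onset ahead of the 465 m contour
    hill_threshold: float = 465.0

    # circling bout at release
    circling_duration_s: int = 45
    circling_turn_rate: float = 12.0    # deg/s
    circling_speed: float = 8.4         # m/s -> radius ~40 m

    # deterministic schedules
    route_hill_modulus: int = 4         # hill when (bird + day) % modulus == 1
    wind_calm_max: float = 1.9          # scheduled calm flights stay below this
    wind_excluded_min: float = 2.4      # scheduled windy flights start here

    def __post_init__(self):
        if self.duration_s < 60:
            raise ValueError("flight duration must be at least 60 s")
        for name in ("speed_sd", "alt_sd", "bird_sd", "day_sd",
                     "gps_noise_sd", "pressure_noise_sd",
                     "anemometer_speed_sd", "anemometer_dir_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimFlight:
    """One simulated flight: raw logger tables plus its ground truth."""

    flight_id: str
    bird_id: str
    date: str
    gps: pd.DataFrame
    pressure: pd.DataFrame
    wind: pd.DataFrame
    truth: dict


@dataclass
class Campaign:
    config: SimConfig
    flights: list
    morphology: dict
    terrain: RasterGrid
    landcover: RasterGrid
    landcover_mapping: dict
    release: tuple
    loft: tuple
    site_elevation: float
    manifest: pd.DataFrame


# --------------------------------------------------------------- terrain

def _elevation_fn(cfg: SimConfig):
    def elev(x, y):
        return cfg.valley_floor + cfg.ridge_height * np.exp(
            -((np.asarray(x) - cfg.ridge_x) ** 2) / (2 * cfg.ridge_sigma_x**2)
        ) * np.exp(-((np.asarray(y) - cfg.ridge_y) ** 2) / (2 * cfg.ridge_sigma_y**2))
    return elev


def _local_frame(cfg: SimConfig):
    m_lat, m_lon = geodesy.local_scale(cfg.release_lat, cfg.release_lon)
    def to_latlon(x, y):
        return cfg.release_lat + np.asarray(y) / m_lat, cfg.release_lon + np.asarray(x) / m_lon
    return to_latlon, m_lat, m_lon


def make_terrain(cfg: SimConfig):
    """Build the elevation and land-cover grids for the campaign area."""
    to_latlon, m_lat, m_lon = _local_frame(cfg)
    elev = _elevation_fn(cfg)

    def build(cell_m, values_fn):
        cs_deg = cell_m / m_lat
        x0, x1 = -1500.0, 3900.0
        y0, y1 = -600.0, cfg.route_length_m + 600.0
        ncols = int(np.ceil((x1 - x0) / (cell_m * m_lon / m_lat)))
        nrows = int(np.ceil((y1 - y0) / cell_m))
        xll = cfg.release_lon + x0 / m_lon
        yll = cfg.release_lat + y0 / m_lat
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        lon = xll + (cols + 0.5) * cs_deg
        lat = yll + (nrows - 1 - rows + 0.5) * cs_deg
        x = (lon - cfg.release_lon) * m_lon
        y = (lat[:, None] - cfg.release_lat) * m_lat
        vals = values_fn(x[None, :] + 0 * y, y + 0 * x[None, :])
        return RasterGrid(vals.astype(float), xll, yll, cs_deg)

    terrain = build(cfg.terrain_cellsize_m, elev)

    def stripes(x, y):
        band = np.floor(np.asarray(y) / cfg.stripe_width_m).astype(int)
        return np.where(band % 2 == 0, 1.0, 2.0)  # 1 open, 2 woodland

    landcover = build(cfg.landcover_cellsize_m, stripes)
    mapping = {1: "open", 2: "woodland"}
    return terrain, landcover, mapping


# ---------------------------------------------------------------- routes

def _centerline(cfg: SimConfig, route: str):
    """Arc-length parametrized centerline: s -> (x, y, tangent angle)."""
    u = np.arange(0.0, cfg.route_length_m + 1.0, 1.0)
    if route == "valley":
        x = 150.0 * np.sin(2 * np.pi * u / 2400.0)
    else:
        x = cfg.ridge_x * np.exp(-((u - cfg.ridge_y) ** 2) / (2 * 1200.0**2))
    y = u
    ds = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(ds)])

    def interp(si):
        si = np.clip(si, 0.0, s[-1] - 1e-9)
        xi = np.interp(si, s, x)
        yi = np.interp(si, s, y)
        eps = 1.0
        x2 = np.interp(np.minimum(si + eps, s[-1]), s, x)
        y2 = np.interp(np.minimum(si + eps, s[-1]), s, y)
        tangent = np.arctan2(x2 - xi, y2 - yi)  # deg cw from north, in radians
        return xi, yi, tangent

    return interp, float(s[-1])


def _route_altitude_profile(cfg: SimConfig, route: str, interp, total_s: float):
    """Target-ASL profile A(s) and the programmed climb-onset bookkeeping."""
    elev = _elevation_fn(cfg)
    s_grid = np.arange(0.0, total_s, 5.0)
    xg, yg, _ = interp(s_grid)
    ground = elev(xg, yg)
    if route == "valley":
        A = np.full_like(s_grid, cfg.valley_asl)
        return s_grid, A, {"s_base": np.nan, "s_onset": np.nan}
    above = np.flatnonzero(ground >= cfg.hill_threshold)
    if len(above) == 0:
        raise ValueError("hill route never crosses the hill threshold")
    s_base = s_grid[above[0]]
    s_crest = s_grid[np.argmax(ground)]
    s_onset = max(s_base - cfg.climb_anticipation_m, 0.0)
    peak_alt = cfg.valley_floor + cfg.ridge_height + cfg.crest_clearance
    s_down_end = min(s_crest + (s_crest - s_onset), total_s)
    A = np.interp(
        s_grid,
        [0.0, s_onset, s_crest, s_down_end, total_s],
        [cfg.hill_plain_asl, cfg.hill_plain_asl, peak_alt, cfg.hill_plain_asl,
         cfg.hill_plain_asl],
    )
    # birds change climb rate smoothly, not as a step: round the profile
    # kinks over ~150 m so the programmed Vz has no discontinuities
    k = 31  # 150 m at the 5 m grid step
    kernel = np.ones(k) / k
    A = np.convolve(np.pad(A, k // 2, mode="edge"), kernel, mode="valid")
    return s_grid, A, {"s_base": float(s_base), "s_onset": float(s_onset)}


# --------------------------------------------------------------- flights

def _schedule(cfg: SimConfig, i: int, j: int):
    """Deterministic route class and wind speed for bird i, day j."""
    route = "hill" if (i + j) % cfg.route_hill_modulus == 1 else "valley"
    k = (3 * i + 5 * j) % 14
    if k >= 10:
        speed = cfg.wind_excluded_min + 0.4 * (k - 10) / 3.0
    else:
        speed = 0.3 + (cfg.wind_calm_max - 0.3) * k / 9.0
    direction = float((40.0 * i + 95.0 * j) % 360.0)
    return route, float(speed), direction


def _ou_series(rng, n, sd, tau_s):
    """Discrete mean-reverting (OU) series at 1 Hz with stationary sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / tau_s)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def simulate_flight(cfg: SimConfig, bird_idx: int, day_idx: int, route: str,
                    wind_speed: float, wind_dir: float,
                    bird_effect: float, day_effect: float,
                    rng: np.random.Generator) -> SimFlight:
    """Simulate one flight; returns raw logger tables plus ground truth."""
    to_latlon, m_lat, m_lon = _local_frame(cfg)
    elev = _elevation_fn(cfg)
    interp, total_s = _centerline(cfg, route)
    s_grid, A_prof, onset_info = _route_altitude_profile(cfg, route, interp, total_s)
    A = lambda si: np.interp(si, s_grid, A_prof)

    n = cfg.duration_s
    eta = _ou_series(rng, n + 1, cfg.alt_sd, cfg.alt_tau_s)       # altitude wiggle
    eps = _ou_series(rng, n, cfg.speed_sd, cfg.speed_tau_s)       # speed wiggle
    w_to = np.radians((wind_dir + 180.0) % 360.0)
    w_vec = wind_speed * np.array([np.sin(w_to), np.cos(w_to)])

    slope_up = cfg.climb_slope if cfg.climb_slope is not None else cfg.airspeed_climb_slope
    slope_dn = cfg.descent_slope if cfg.descent_slope is not None else cfg.airspeed_climb_slope
    base = cfg.base_airspeed + bird_effect + day_effect

    xs = np.empty(n); ys = np.empty(n)
    alt = np.empty(n); va_true = np.empty(n); vz_true = np.empty(n)
    vg_true = np.empty(n)
    s = 0.0
    alt_cur = float(A(0.0)) + eta[0]
    stripe = cfg.stripe_width_m
    for t in range(n):
        xi, yi, tan_rad = interp(s)
        xs[t], ys[t] = xi, yi
        alt[t] = alt_cur
        grad = (A(s + 5.0) - A(s - 5.0)) / 10.0 if s > 5.0 else (A(s + 5.0) - A(s)) / 5.0
        # gradient term uses the nominal cruise speed, not the realized
        # ground speed, so Vz stays independent of the speed perturbation
        # and the programmed linear Va-Vz relation holds exactly
        vz = grad * cfg.base_airspeed + (eta[t + 1] - eta[t])
        slope_eff = slope_up if vz > 0 else slope_dn
        band = int(np.floor(yi / stripe))
        lc_eff = cfg.landcover_effect if band % 2 == 1 else 0.0
        va = base + slope_eff * vz + eps[t] + lc_eff
        va = max(va, abs(vz) + 3.0)
        vx = np.sqrt(va**2 - vz**2)
        t_hat = np.array([np.sin(tan_rad), np.cos(tan_rad)])
        dot = float(t_hat @ w_vec)
        disc = dot**2 - wind_speed**2 + vx**2
        vg = dot + np.sqrt(max(disc, 0.0))
        va_true[t] = va; vz_true[t] = vz; vg_true[t] = vg
        s += vg
        alt_cur += vz

    # circling bout prepended at the release
    nc = cfg.circling_duration_s
    omega = np.radians(cfg.circling_turn_rate)
    radius = cfg.circling_speed / omega
    phi = omega * np.arange(nc) - omega * nc  # ends at phi = 0
    cx, cy = 0.0, radius  # so the bout ends at the origin heading north-ish
    xc = cx + radius * np.sin(phi + np.pi)
    yc = cy + radius * np.cos(phi + np.pi)
    site_elev = float(elev(0.0, 0.0))
    alt_c = np.linspace(site_elev + 5.0, alt[0], nc, endpoint=False)

    x_all = np.concatenate([xc, xs])
    y_all = np.concatenate([yc, ys])
    alt_all = np.concatenate([alt_c, alt])
    times = np.arange(len(x_all), dtype=float)

    gx = x_all + rng.normal(0.0, cfg.gps_noise_sd, len(x_all))
    gy = y_all + rng.normal(0.0, cfg.gps_noise_sd, len(y_all))
    lat, lon = to_latlon(gx, gy)
    gps = pd.DataFrame({"time": times, "lat": lat, "lon": lon})

    # 4 Hz pressure, including a 20 s pre-take-off window on the ground
    p_ref = float(960.0 + 4.0 * np.sin(1.7 * day_idx) + rng.normal(0.0, 0.5))
    calib = CalibrationContext(p_ref, site_elev)
    t4 = np.arange(-20.0, times[-1] + 0.25, 0.25)
    alt4 = np.interp(t4, times, alt_all, left=site_elev)
    p4 = altitude_to_pressure(alt4, calib)
    p4 = p4 + rng.normal(0.0, cfg.pressure_noise_sd, len(p4))
    pressure = pd.DataFrame({"time": t4, "pressure": p4})

    tw = np.arange(-20.0, times[-1] + 1.0, 10.0)
    wind = pd.DataFrame({
        "time": tw,
        "speed": np.clip(
            wind_speed + rng.normal(0.0, cfg.anemometer_speed_sd, len(tw)), 0.0, None),
        "direction_from": np.mod(
            wind_dir + rng.normal(0.0, cfg.anemometer_dir_sd, len(tw)), 360.0),
    })

    loft_lat, loft_lon = to_latlon(
        *interp(min(cfg.loft_along_m, total_s))[:2])
    truth = {
        "route": route,
        "wind_speed": wind_speed,
        "wind_direction": wind_dir,
        "base_airspeed": base,
        "bird_effect": bird_effect,
        "day_effect": day_effect,
        "slope_climb": slope_up,
        "slope_descent": slope_dn,
        "landcover_effect": cfg.landcover_effect,
        "plain_target_asl": cfg.hill_plain_asl if route == "hill" else cfg.valley_asl,
        "climb_onset_distance_m": (onset_info["s_base"] - onset_info["s_onset"])
        if route == "hill" else float("nan"),
        "s_base": onset_info["s_base"],
        "reference_pressure": p_ref,
        "site_elevation": site_elev,
        "wind_excluded": wind_speed > 2.0,
        "loft": (float(loft_lat), float(loft_lon)),
        "true_altitude": alt_all,
        "true_va": va_true,
        "true_vz": vz_true,
        "true_vg": vg_true,
        "travel_start_index": nc,
    }
    bird_id = f"bird{bird_idx + 1:02d}"
    date = f"2019-04-{3 + day_idx:02d}"
    return SimFlight(f"{bird_id}_d{day_idx + 1}", bird_id, date, gps, pressure,
                     wind, truth)


def simulate_campaign(cfg: SimConfig) -> Campaign:
    """Simulate the full bird x day campaign in memory."""
    root = np.random.SeedSequence(cfg.seed)
    keys = root.spawn(3 + cfg.n_birds * cfg.flights_per_bird)
    rng_effects = np.random.default_rng(keys[0])
    rng_morph = np.random.default_rng(keys[1])

    bird_effects = rng_effects.normal(0.0, cfg.bird_sd, cfg.n_birds)
    day_effects = rng_effects.normal(0.0, cfg.day_sd, cfg.flights_per_bird)

    morphology = {}
    for i in range(cfg.n_birds):
        bird_id = f"bird{i + 1:02d}"
        morphology[bird_id] = Morphology(
            bird_id,
            mass=float(np.clip(rng_morph.normal(0.455, 0.015), 0.40, 0.52)),
            wingspan=float(np.clip(rng_morph.normal(0.66, 0.02), 0.60, 0.72)),
            wing_area=float(np.clip(rng_morph.normal(0.0350, 0.0015), 0.030, 0.040)),
        )

    terrain, landcover, mapping = make_terrain(cfg)
    to_latlon, _, _ = _local_frame(cfg)
    site_elev = float(_elevation_fn(cfg)(0.0, 0.0))
    release = (cfg.release_lat, cfg.release_lon)

    flights = []
    rows = []
    k = 3
    loft = None
    for i in range(cfg.n_birds):
        for j in range(cfg.flights_per_bird):
            route, w_speed, w_dir = _schedule(cfg, i, j)
            rng = np.random.default_rng(keys[k]); k += 1
            fl = simulate_flight(cfg, i, j, route, w_speed, w_dir,
                                 float(bird_effects[i]), float(day_effects[j]), rng)
            flights.append(fl)
            if loft is None:
                loft = fl.truth["loft"]
            rows.append({
                "flight_id": fl.flight_id, "bird_id": fl.bird_id, "date": fl.date,
                "route_truth": route, "wind_speed_truth": w_speed,
                "wind_direction_truth": w_dir,
                "wind_excluded_truth": fl.truth["wind_excluded"],
                "takeoff_time": 0.0,
            })
    manifest = pd.DataFrame(rows)
    return Campaign(cfg, flights, morphology, terrain, landcover, mapping,
                    release, loft, site_elev, manifest)


def write_campaign(campaign: Campaign, out_dir) -> Path:
    """Write raw logger files, grids, morphology, manifest and ground truth."""
    out = Path(out_dir)
    (out / "raw").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    cfg = campaign.config

    write_ascii_grid(campaign.terrain, out / "terrain.asc")
    write_ascii_grid(campaign.landcover, out / "landcover.asc")
    pd.DataFrame(
        [{"code": c, "label": l} for c, l in campaign.landcover_mapping.items()]
    ).to_csv(out / "landcover_mapping.csv", index=False)

    morph = pd.DataFrame([{"bird_id": m.bird_id, "mass": m.mass,
                           "wingspan": m.wingspan, "wing_area": m.wing_area}
                          for m in campaign.morphology.values()])
    morph.to_csv(out / "morphology.csv", index=False, float_format="%.6f")

    rows = []
    for fl in campaign.flights:
        stem = fl.flight_id
        fl.gps.to_csv(out / "raw" / f"{stem}_gps.csv", index=False, float_format="%.8f")
        fl.pressure.to_csv(out / "raw" / f"{stem}_pressure.csv", index=False,
                           float_format="%.5f")
        fl.wind.to_csv(out / "raw" / f"{stem}_wind.csv", index=False,
                       float_format="%.4f")
        truth_flat = {kk: vv for kk, vv in fl.truth.items()
                      if not isinstance(vv, (np.ndarray, tuple))}
        truth_flat["flight_id"] = stem
        rows.append(truth_flat)
        pd.DataFrame({
            "time": np.arange(len(fl.truth["true_altitude"]), dtype=float),
            "true_altitude": fl.truth["true_altitude"],
            "true_va": np.concatenate([
                np.full(fl.truth["travel_start_index"], np.nan), fl.truth["true_va"]]),
            "true_vz": np.concatenate([
                np.full(fl.truth["travel_start_index"], np.nan), fl.truth["true_vz"]]),
        }).to_csv(out / "truth" / f"{stem}_truth.csv", index=False,
                  float_format="%.6f")

    man = campaign.manifest.copy()
    man["gps_path"] = ["raw/" + f + "_gps.csv" for f in man["flight_id"]]
    man["pressure_path"] = ["raw/" + f + "_pressure.csv" for f in man["flight_id"]]
    man["wind_path"] = ["raw/" + f + "_wind.csv" for f in man["flight_id"]]
    man["release_lat"] = campaign.release[0]
    man["release_lon"] = campaign.release[1]
    man["loft_lat"] = campaign.loft[0]
    man["loft_lon"] = campaign.loft[1]
    man["site_elevation"] = campaign.site_elevation
    man.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "truth" / "flights_truth.csv", index=False)
    return out
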