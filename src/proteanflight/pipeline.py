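"""End-to-end orchestration: raw logger files -> derived tracks -> report.

The pipeline reads a campaign directory (manifest of flights, logger CSVs,
terrain and land-cover grids, morphology), derives every flight, applies
the exclusion rules, annotates terrain, computes variability metrics and
power-curve reference speeds, fits the mixed-effects models, and writes a
report bundle.  A failure in one flight is recorded in the exclusion
ledger and does not stop the remaining flights; the ledger partitions the
campaign: included + wind-excluded + failed = total.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats, kinematics, segmentation, terrain as terrain_mod
from . import variability, flight_power, stats_models
from .segmentation import Flight, SegmentationConfig
from .kinematics import KinematicsConfig
from .terrain import TerrainConfig, LandCoverMapping

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of the pipeline, serializable to/from YAML."""

    raw_dir: str = "."
    manifest: str = "manifest.csv"
    terrain_grid: str = "terrain.asc"
    landcover_grid: str = "landcover.asc"
    landcover_mapping: str = "landcover_mapping.csv"
    morphology: str = "morphology.csv"
    out_dir: str = "out"
    seed: int = 0
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    # guard band = the smoothing window, so smoothed values never straddle
    # an exclusion boundary
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(guard_s=5.0))
    terrain: TerrainConfig = field(default_factory=TerrainConfig)
    power: flight_power.PowerCurveConfig = field(default_factory=flight_power.PowerCurveConfig)
    lme_thin: int = 1           # full-rate Table-1-style fits mirror the field convention
    recovery_thin: int = 15     # ~1.5 residual correlation times: honest CIs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sub = {
            "kinematics": KinematicsConfig,
            "segmentation": SegmentationConfig,
            "terrain": TerrainConfig,
            "power": flight_power.PowerCurveConfig,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in sub:
                if key == "terrain" and "plain_window_m" in val:
                    val["plain_window_m"] = tuple(val["plain_window_m"])
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["terrain"]["plain_window_m"] = list(data["terrain"]["plain_window_m"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def derive_flight(row, base_dir: Path, cfg: RunConfig) -> Flight:
    """Raw logger files of one manifest row -> derived, masked Flight."""
    gps = io_formats.read_gps_csv(base_dir / row["gps_path"])
    pressure = io_formats.read_pressure_csv(base_dir / row["pressure_path"])
    wind = io_formats.read_wind_log(base_dir / row["wind_path"])
    calib = kinematics.calibrate_reference(
        pressure, row["site_elevation"], row.get("takeoff_time", gps["time"].iloc[0]),
        cfg.kinematics.calibration_window_s)
    points = kinematics.derive_track(gps, pressure, wind, calib, cfg.kinematics)
    w_speed, w_dir = kinematics.mean_wind(wind, gps["time"].iloc[0], gps["time"].iloc[-1])
    fl = Flight(flight_id=str(row["flight_id"]), bird_id=str(row["bird_id"]),
                date=str(row["date"]), points=points,
                mean_wind_speed=w_speed, mean_wind_direction=w_dir)
    release = (row["release_lat"], row["release_lon"])
    loft = (row["loft_lat"], row["loft_lon"])
    return segmentation.apply_masks(fl, release, loft, cfg.segmentation)


def analyze_campaign(travel_flights: dict, terrain_grid, landcover_grid,
                     mapping: LandCoverMapping, morphology: dict,
                     cfg: RunConfig) -> dict:
    """All campaign-level statistics from the travel segments."""
    tcfg = cfg.terrain
    annotated = {}
    route_classes = {}
    var_rows = []
    obs_frames = []
    for fid, fl in travel_flights.items():
        pts = terrain_mod.annotate(fl.points, terrain_grid, landcover_grid, mapping)
        pts["terrain_slope"] = terrain_mod.terrain_slope_along_track(pts)
        route_classes[fid] = terrain_mod.classify_route(
            pts, tcfg.elevation_threshold, tcfg.hill_fraction)
        annotated[fid] = pts
        rep = variability.flight_report(pts)
        rep["flight_id"] = fid
        rep["route_class"] = route_classes[fid]
        if route_classes[fid] == "hill":
            rep["climb_onset_km"] = terrain_mod.climb_onset_distance(
                pts, tcfg.elevation_threshold, tcfg.onset_vz, tcfg.onset_hold_s,
                tcfg.onset_smooth_s)
        var_rows.append(rep)
        obs = pts[["va", "vz", "altitude_asl", "landcover", "terrain_slope",
                   "along_track_m"]].copy()
        obs["bird"] = fl.bird_id
        obs["day"] = fl.date
        obs["flight_id"] = fid
        obs["route_class"] = route_classes[fid]
        obs_frames.append(obs)

    per_flight = pd.DataFrame(var_rows)
    pooled = variability.pooled_report(per_flight)
    obs = pd.concat(obs_frames, ignore_index=True).dropna(subset=["va", "vz"])

    results = {"per_flight": per_flight, "pooled": pooled,
               "route_classes": route_classes, "observations": obs}

    # flight-mechanics reference speeds per bird
    power_rows = []
    for bird_id, morph in morphology.items():
        curve = flight_power.power_curve(morph, cfg.power)
        power_rows.append({
            "bird_id": bird_id, "mass": morph.mass, "wingspan": morph.wingspan,
            "wing_area": morph.wing_area,
            "wing_loading": flight_power.wing_loading(morph.mass, morph.wing_area),
            "vmp": curve.vmp, "vmr": curve.vmr,
        })
    results["power_curves"] = pd.DataFrame(power_rows)

    # mixed models
    lme = {}
    open_woodland = obs[obs["landcover"].isin(["open", "woodland"])]
    try:
        lme["airspeed_full"] = stats_models.fit_lme(
            open_woodland,
            "va ~ vz + C(landcover) + altitude_asl + vz:altitude_asl",
            thin=cfg.lme_thin)
    except Exception as exc:  # singular or degenerate designs should not kill the run
        logger.warning("full airspeed model failed: %s", exc)
    try:
        lme["climbing"], lme["descending"] = stats_models.fit_phase_models(
            obs, thin=cfg.lme_thin)
    except Exception as exc:
        logger.warning("phase models failed: %s", exc)
    try:
        lme["slope_vs_terrain"] = stats_models.slope_vs_terrain(obs, thin=cfg.lme_thin)
    except Exception as exc:
        logger.warning("terrain-slope model failed: %s", exc)
    try:
        contrast, plain_per_flight = terrain_mod.plain_altitude_contrast(
            annotated, route_classes, tcfg.plain_window_m)
        results["plain_contrast_m"] = contrast
        results["plain_per_flight"] = plain_per_flight
        s0, s1 = tcfg.plain_window_m
        plain_obs = obs[(obs["along_track_m"] >= s0) & (obs["along_track_m"] <= s1)
                        & obs["route_class"].isin(["hill", "valley"])]
        lme["route_altitude"] = stats_models.route_altitude_model(
            plain_obs, thin=cfg.recovery_thin)
    except (ValueError, KeyError) as exc:
        logger.warning("route-contrast analysis skipped: %s", exc)
    results["lme"] = lme
    results["annotated"] = annotated
    return results


def campaign_observations(campaign, cfg: RunConfig | None = None):
    """Derive an in-memory synthetic campaign without touching disk.

    Runs the same chain as the file-based pipeline (derivation, wind filter,
    masks, travel segment, terrain annotation) and returns
    ``(travel, route_classes, obs)`` where ``obs`` pools the per-point
    model variables of every included flight.
    """
    cfg = cfg or RunConfig()
    mapping = LandCoverMapping(campaign.landcover_mapping)
    flights = []
    for fl in campaign.flights:
        calib = kinematics.calibrate_reference(
            fl.pressure, campaign.site_elevation, fl.gps["time"].iloc[0],
            cfg.kinematics.calibration_window_s)
        pts = kinematics.derive_track(fl.gps, fl.pressure, fl.wind, calib,
                                      cfg.kinematics)
        w_speed, w_dir = kinematics.mean_wind(
            fl.wind, fl.gps["time"].iloc[0], fl.gps["time"].iloc[-1])
        f = Flight(fl.flight_id, fl.bird_id, fl.date, pts, w_speed, w_dir)
        flights.append(segmentation.apply_masks(
            f, campaign.release, campaign.loft, cfg.segmentation))
    segmentation.wind_filter(flights, cfg.segmentation.wind_threshold)

    travel = {}
    route_classes = {}
    frames = []
    for f in flights:
        if not f.include_in_analysis:
            continue
        seg, _ = segmentation.travel_segment(
            f, cfg.segmentation.guard_s, cfg.segmentation.rate_hz)
        pts = terrain_mod.annotate(seg.points, campaign.terrain,
                                   campaign.landcover, mapping)
        pts["terrain_slope"] = terrain_mod.terrain_slope_along_track(pts)
        seg.points = pts
        seg.route_class = terrain_mod.classify_route(
            pts, cfg.terrain.elevation_threshold, cfg.terrain.hill_fraction)
        travel[f.flight_id] = seg
        route_classes[f.flight_id] = seg.route_class
        o = pts[["va", "vz", "altitude_asl", "landcover", "terrain_slope",
                 "along_track_m"]].copy()
        o["bird"] = f.bird_id
        o["day"] = f.date
        o["flight_id"] = f.flight_id
        o["route_class"] = seg.route_class
        frames.append(o)
    obs = pd.concat(frames, ignore_index=True).dropna(subset=["va", "vz"])
    return travel, route_classes, obs


def run_pipeline(cfg: RunConfig, base_dir=None) -> dict:
    """Full run: derive, segment, analyze, and write the report bundle."""
    t0 = time.time()
    base = Path(base_dir) if base_dir is not None else Path(cfg.raw_dir)
    out = Path(cfg.out_dir)
    (out / "derived").mkdir(parents=True, exist_ok=True)
    (out / "report").mkdir(exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("proteanflight")
    root_logger.addHandler(fh)
    try:
        return _run(cfg, base, out, t0)
    finally:
        root_logger.removeHandler(fh)
        fh.close()


def _run(cfg: RunConfig, base: Path, out: Path, t0: float) -> dict:
    manifest = pd.read_csv(base / cfg.manifest)
    terrain_grid = io_formats.read_ascii_grid(base / cfg.terrain_grid)
    landcover_grid = io_formats.read_ascii_grid(base / cfg.landcover_grid)
    map_df = pd.read_csv(base / cfg.landcover_mapping)
    mapping = LandCoverMapping({int(r["code"]): str(r["label"])
                                for _, r in map_df.iterrows()})
    morphology = io_formats.read_morphology_csv(base / cfg.morphology)

    flights = []
    failed = []
    for _, row in manifest.iterrows():
        try:
            flights.append(derive_flight(row, base, cfg))
        except Exception as exc:
            logger.error("flight %s failed at derivation: %s", row["flight_id"], exc)
            failed.append({"flight_id": row["flight_id"], "stage": "derive",
                           "error": str(exc)})

    segmentation.wind_filter(flights, cfg.segmentation.wind_threshold)

    travel = {}
    stats_rows = []
    for fl in flights:
        io_formats.write_track_csv(fl, out / "derived" / f"{fl.flight_id}.csv")
        if not fl.include_in_analysis:
            continue
        try:
            seg, seg_stats = segmentation.travel_segment(
                fl, cfg.segmentation.guard_s, cfg.segmentation.rate_hz)
            travel[fl.flight_id] = seg
            seg_stats["flight_id"] = fl.flight_id
            stats_rows.append(seg_stats)
        except ValueError as exc:
            logger.error("flight %s failed at segmentation: %s", fl.flight_id, exc)
            failed.append({"flight_id": fl.flight_id, "stage": "segment",
                           "error": str(exc)})

    ledger_rows = []
    failed_ids = {f["flight_id"] for f in failed}
    for _, row in manifest.iterrows():
        fid = row["flight_id"]
        fl = next((f for f in flights if f.flight_id == fid), None)
        if fid in failed_ids:
            status = "failed"
            reason = next(f["error"] for f in failed if f["flight_id"] == fid)
        elif fl is not None and not fl.include_in_analysis:
            status, reason = "wind_excluded", fl.exclusion_reason
        else:
            status, reason = "included", ""
        ledger_rows.append({"flight_id": fid, "status": status, "reason": reason})
    ledger = pd.DataFrame(ledger_rows)

    results = analyze_campaign(travel, terrain_grid, landcover_grid, mapping,
                               morphology, cfg)
    results["exclusions"] = ledger
    results["segment_stats"] = pd.DataFrame(stats_rows)
    results["flights"] = flights
    results["travel"] = travel

    _write_report(results, cfg, out)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return results


def _lme_table(res: stats_models.LMEResult) -> pd.DataFrame:
    t = res.terms.copy()
    t["r2_marginal"] = res.r2_marginal
    t["r2_conditional"] = res.r2_conditional
    return t


def _write_report(results: dict, cfg: RunConfig, out: Path) -> None:
    rep = out / "report"
    results["exclusions"].to_csv(rep / "exclusions.csv", index=False)
    results["per_flight"].to_csv(rep / "variability_per_flight.csv", index=False,
                                 float_format="%.6f")
    results["pooled"].to_csv(rep / "summary.csv", index=False, float_format="%.6f")
    results["power_curves"].to_csv(rep / "power_curves.csv", index=False,
                                   float_format="%.4f")
    if "airspeed_full" in results["lme"]:
        _lme_table(results["lme"]["airspeed_full"]).to_csv(
            rep / "table1_style.csv", index=False, float_format="%.6f")
    model_rows = []
    for name, res in results["lme"].items():
        t = _lme_table(res)
        t.insert(0, "model", name)
        model_rows.append(t)
    if model_rows:
        pd.concat(model_rows, ignore_index=True).to_csv(
            rep / "lme_models.csv", index=False, float_format="%.6f")
    cfg.to_yaml(out / "resolved-config.yaml")
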