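import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteanflight import kinematics as kin
from proteanflight.kinematics import CalibrationContext


@pytest.fixture
def calib():
    return CalibrationContext(1013.25, 0.0)


class TestHypsometric:
    def test_reference_pressure_gives_reference_altitude(self, calib):
        assert kin.pressure_to_altitude(1013.25, calib) == pytest.approx(0.0)
        c2 = CalibrationContext(960.0, 447.0)
        assert kin.pressure_to_altitude(960.0, c2) == pytest.approx(447.0)

    def test_standard_atmosphere_500m(self, calib):
        # independent evaluation of the ISA hypsometric formula:
        # p(500 m) = 1013.25*(1 - 0.0065*500/288.15)^(1/0.1902632) = 954.61 hPa
        assert kin.pressure_to_altitude(954.61, calib) == pytest.approx(500.0, abs=1.0)

    def test_monotone_decreasing_in_pressure(self, calib):
        p = np.linspace(900.0, 1013.0, 50)
        alt = kin.pressure_to_altitude(p, calib)
        assert np.all(np.diff(alt) < 0)
        assert kin.pressure_to_altitude(1013.0, calib) > 0  # just below p_ref

    def test_out_of_range_pressure_raises(self, calib):
        with pytest.raises(ValueError):
            kin.pressure_to_altitude(120.0, calib)

    def test_inverse_closure(self, calib):
        h = np.linspace(0.0, 1000.0, 101)
        back = kin.pressure_to_altitude(kin.altitude_to_pressure(h, calib), calib)
        assert np.max(np.abs(back - h)) < 0.1


class TestCalibration:
    def make(self, values, t0=-10.0, dt=0.25):
        t = t0 + dt * np.arange(len(values))
        return pd.DataFrame({"time": t, "pressure": values})

    def test_constant_window(self):
        c = kin.calibrate_reference(self.make([960.0] * 40), 447.0, 0.0)
        assert (c.reference_pressure, c.reference_altitude) == (960.0, 447.0)

    def test_mean_of_window(self):
        c = kin.calibrate_reference(self.make([959.0, 960.0, 961.0], dt=1.0, t0=-3),
                                    447.0, 0.0, window_s=10)
        assert c.reference_pressure == pytest.approx(960.0)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            kin.calibrate_reference(self.make([960.0], t0=5.0), 447.0, 0.0)


class TestResample:
    def test_constant_series(self):
        p = pd.DataFrame({"time": np.arange(0, 10, 0.25), "pressure": 960.0})
        out = kin.resample_pressure_to_track(p, [1.0, 5.0, 9.0])
        np.testing.assert_allclose(out, 960.0)

    def test_linear_ramp_matches_window_mean_oracle(self):
        t = np.arange(0, 30, 0.25)
        p = pd.DataFrame({"time": t, "pressure": 900.0 + 1.0 * t})  # 1 hPa/s
        fixes = np.array([5.0, 10.0, 20.0])
        out = kin.resample_pressure_to_track(p, fixes)
        for f, v in zip(fixes, out):
            sel = (t >= f - 0.5) & (t < f + 0.5)
            assert v == pytest.approx((900.0 + t[sel]).mean())

    def test_fix_outside_coverage_flagged_missing(self):
        p = pd.DataFrame({"time": np.arange(5, 10, 0.25), "pressure": 960.0})
        out = kin.resample_pressure_to_track(p, [0.0, 7.0])
        assert np.isnan(out[0]) and out[1] == 960.0


class TestSmoothing:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(kin.smooth_series(np.full(20, 7.0), 1.0, 5.0), 7.0)

    def test_linear_unchanged_in_interior(self):
        x = np.arange(30.0)
        out = kin.smooth_series(x, 1.0, 5.0)
        np.testing.assert_allclose(out[2:-2], x[2:-2], atol=1e-9)

    def test_unit_impulse_spreads_to_one_fifth(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = kin.smooth_series(x, 1.0, 5.0)
        np.testing.assert_allclose(out[3:8], 0.2)
        assert out[2] == 0.0 and out[8] == 0.0

    def test_mean_preserved_away_from_ends(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        out = kin.smooth_series(x, 1.0, 5.0)
        # interior of a centred truncated moving average preserves the mean
        assert out[2:-2].mean() == pytest.approx(
            np.convolve(x, np.ones(5) / 5, mode="valid").mean(), abs=1e-9)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            kin.smooth_series(np.array([]), 1.0, 5.0)


class TestGroundSpeedHeading:
    def fixes(self, coords):
        return pd.DataFrame({"time": np.arange(len(coords), dtype=float),
                             "lat": [c[0] for c in coords],
                             "lon": [c[1] for c in coords]})

    def test_due_north_20m(self):
        # 20 m north of (47.8, 9.0): 20 m / 111188 m-per-deg
        dlat = 20.0 / 111188.0
        vg, hd = kin.ground_speed_heading(self.fixes([(47.8, 9.0), (47.8 + dlat, 9.0)]))
        assert vg[0] == pytest.approx(20.0, abs=0.01)
        assert hd[0] == pytest.approx(0.0, abs=1e-6) or hd[0] == pytest.approx(360.0)

    def test_due_east_heading_90(self):
        dlon = 20.0 / (111320.0 * np.cos(np.radians(47.8)))
        _, hd = kin.ground_speed_heading(self.fixes([(47.8, 9.0), (47.8, 9.0 + dlon)]))
        assert hd[0] == pytest.approx(90.0, abs=0.1)

    def test_stationary_fix_carries_heading(self):
        dlat = 20.0 / 111188.0
        vg, hd = kin.ground_speed_heading(
            self.fixes([(47.8, 9.0), (47.8 + dlat, 9.0), (47.8 + dlat, 9.0)]))
        assert vg[1] == 0.0
        assert hd[1] == pytest.approx(hd[0])

    def test_last_fix_inherits(self):
        dlat = 20.0 / 111188.0
        vg, hd = kin.ground_speed_heading(self.fixes([(47.8, 9.0), (47.8 + dlat, 9.0)]))
        assert vg[1] == vg[0] and hd[1] == hd[0]

    def test_non_positive_dt_raises(self):
        f = self.fixes([(47.8, 9.0), (47.81, 9.0)])
        f.loc[1, "time"] = 0.0
        with pytest.raises(ValueError):
            kin.ground_speed_heading(f)


class TestWindAngle:
    @pytest.mark.parametrize("heading,wind_from,theta", [
        (0.0, 0.0, 0.0),      # pure headwind
        (90.0, 270.0, 180.0),  # pure tailwind
        (350.0, 10.0, 20.0),
        (10.0, 350.0, 20.0),
        (180.0, 90.0, 90.0),
    ])
    def test_examples(self, heading, wind_from, theta):
        assert kin.relative_wind_angle(heading, wind_from) == pytest.approx(theta)

    def test_matches_brute_force_circular_difference(self):
        rng = np.random.default_rng(1)
        for h, d in rng.uniform(0, 360, size=(200, 2)):
            brute = min(abs(h - d), 360 - abs(h - d))
            assert kin.relative_wind_angle(h, d) == pytest.approx(brute)


class TestHorizontalAirspeed:
    def test_tailwind_subtracts(self):
        assert kin.horizontal_airspeed(20.0, 2.0, 180.0) == pytest.approx(18.0)

    def test_headwind_adds(self):
        assert kin.horizontal_airspeed(20.0, 2.0, 0.0) == pytest.approx(22.0)

    def test_crosswind(self):
        assert kin.horizontal_airspeed(20.0, 2.0, 90.0) == pytest.approx(np.sqrt(404.0))

    def test_zero_wind_identity(self):
        for theta in (0.0, 45.0, 180.0):
            assert kin.horizontal_airspeed(17.3, 0.0, theta) == pytest.approx(17.3)

    def test_negative_speed_raises(self):
        with pytest.raises(ValueError):
            kin.horizontal_airspeed(-1.0, 2.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(vg=st.floats(0.0, 25.0), vw=st.floats(0.0, 5.0),
           heading=st.floats(0.0, 360.0), wind_from=st.floats(0.0, 360.0))
    def test_wind_triangle_matches_vector_oracle(self, vg, vw, heading, wind_from):
        """Law-of-cosines form equals |Vg_vec - Vw_to_vec| component-wise."""
        h, d = np.radians(heading), np.radians(wind_from + 180.0)
        gvec = vg * np.array([np.sin(h), np.cos(h)])
        wvec = vw * np.array([np.sin(d), np.cos(d)])
        oracle = float(np.hypot(*(gvec - wvec)))
        theta = kin.relative_wind_angle(heading, wind_from)
        assert kin.horizontal_airspeed(vg, vw, theta) == pytest.approx(oracle, abs=1e-9)


class TestDerivatives:
    def test_climb_rate_forward_difference(self):
        np.testing.assert_allclose(kin.climb_rate([100.0, 101.0, 102.0]), 1.0)
        np.testing.assert_allclose(kin.climb_rate([50.0, 50.0, 50.0]), 0.0)

    def test_climb_rate_matches_diff_oracle_on_sinusoid(self):
        t = np.arange(100.0)
        alt = 5.0 * np.sin(2 * np.pi * t / 20.0)
        vz = kin.climb_rate(alt)
        np.testing.assert_allclose(vz[:-1], np.diff(alt))
        assert vz[-1] == vz[-2]

    def test_total_airspeed_345(self):
        assert kin.total_airspeed(3.0, 4.0) == pytest.approx(5.0)
        assert kin.total_airspeed(19.9, -1.2) == pytest.approx(np.hypot(19.9, 1.2))
        assert kin.total_airspeed(17.0, 0.0) == 17.0

    def test_acceleration_examples(self):
        np.testing.assert_allclose(kin.acceleration([18.0, 20.0, 19.0]),
                                   [2.0, -1.0, -1.0])
        np.testing.assert_allclose(kin.acceleration(np.full(5, 20.0)), 0.0)
        ramp = 10.0 + 0.5 * np.arange(10)
        np.testing.assert_allclose(kin.acceleration(ramp), 0.5)

    def test_climb_angle(self):
        assert kin.climb_angle(1.0, 1.0) == pytest.approx(45.0)
        assert kin.climb_angle(1.0, 20.0) == pytest.approx(np.degrees(np.arctan2(1, 20)))
        assert kin.climb_angle(-1.0, 20.0) == pytest.approx(-kin.climb_angle(1.0, 20.0))
        assert np.isnan(kin.climb_angle(0.0, 0.0))


class TestDeriveTrack:
    def test_airspeed_identity_holds_everywhere(self, campaign):
        fl = campaign.flights[0]
        calib = kin.calibrate_reference(fl.pressure, campaign.site_elevation, 0.0)
        pts = kin.derive_track(fl.gps, fl.pressure, fl.wind, calib)
        ok = pts.dropna(subset=["va"])
        np.testing.assert_allclose(ok["va"] ** 2, ok["vx"] ** 2 + ok["vz"] ** 2,
                                   atol=1e-9)
        assert (ok["va"] >= ok["vz"].abs() - 1e-12).all()
        assert ok["theta"].between(0.0, 180.0).all()

    def test_deterministic(self, campaign):
        fl = campaign.flights[0]
        calib = kin.calibrate_reference(fl.pressure, campaign.site_elevation, 0.0)
        a = kin.derive_track(fl.gps, fl.pressure, fl.wind, calib)
        b = kin.derive_track(fl.gps, fl.pressure, fl.wind, calib)
        pd.testing.assert_frame_equal(a, b)
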