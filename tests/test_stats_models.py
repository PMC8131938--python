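import warnings

import numpy as np
import pandas as pd
import pytest

from proteanflight import stats_models as sm


def simulate_lme(seed=0, slope=-1.24, bird_sd=1.0, day_sd=1.0, resid_sd=2.0,
                 n_birds=7, n_days=4, n_obs=360, interaction=0.0):
    """Direct draw from the random-intercept data-generating process."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0, bird_sd, n_birds)
    d = rng.normal(0, day_sd, n_days)
    frames = []
    for i in range(n_birds):
        for j in range(n_days):
            vz = rng.normal(0, 1.0, n_obs)
            x2 = rng.normal(0, 1.0, n_obs)
            va = (16.2 + slope * vz + interaction * vz * x2 + b[i] + d[j]
                  + rng.normal(0, resid_sd, n_obs))
            frames.append(pd.DataFrame({"va": va, "vz": vz, "x2": x2,
                                        "bird": f"b{i}", "day": f"d{j}"}))
    return pd.concat(frames, ignore_index=True)


class TestStandardize:
    def test_closed_form(self):
        z, mu, sd = sm.standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (mu, sd) == (2.0, 1.0)

    def test_output_is_standard(self):
        rng = np.random.default_rng(0)
        z, _, _ = sm.standardize(rng.normal(5, 3, 1000))
        assert abs(z.mean()) < 1e-12 and z.std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            sm.standardize(np.full(10, 3.0))


class TestFitLme:
    def test_slope_recovered_with_honest_ci(self):
        """Across seeded replicates the 95% CI covers the true slope at
        close to the nominal rate (the data here are iid, no thinning)."""
        hits = 0
        for seed in range(20):
            r = sm.fit_lme(simulate_lme(seed=seed), "va ~ vz", thin=3)
            lo, hi = r.conf_int("vz")
            hits += lo <= -1.24 <= hi
        assert hits >= 17

    def test_standardized_estimate_convertible(self):
        df = simulate_lme(seed=1)
        r = sm.fit_lme(df, "va ~ vz", thin=5)
        sd_vz = df.iloc[::5]["vz"].std(ddof=1)
        assert r.terms.set_index("term").loc["vz", "estimate_std"] == pytest.approx(
            r.estimate("vz") * sd_vz, rel=1e-6)

    def test_no_random_variation_gives_near_equal_r2(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = sm.fit_lme(simulate_lme(seed=2, bird_sd=0.0, day_sd=0.0),
                           "va ~ vz", thin=5)
        assert sum(r.vc.values()) < 0.05
        assert r.r2_conditional == pytest.approx(r.r2_marginal, abs=0.02)
        assert r.singular

    def test_conditional_at_least_marginal(self):
        r = sm.fit_lme(simulate_lme(seed=3), "va ~ vz", thin=10)
        assert 0.0 <= r.r2_marginal <= r.r2_conditional <= 1.0

    def test_wald_chi2_is_squared_t(self):
        r = sm.fit_lme(simulate_lme(seed=4), "va ~ vz", thin=10)
        row = r.terms.set_index("term").loc["vz"]
        assert row["chi2"] == pytest.approx(row["t"] ** 2)

    def test_single_level_random_factor_raises(self):
        df = simulate_lme(seed=5, n_days=1)
        with pytest.raises(ValueError):
            sm.fit_lme(df, "va ~ vz")


class TestPhaseModels:
    def test_asymmetric_slopes_recovered(self):
        rng = np.random.default_rng(6)
        frames = []
        for i in range(7):
            for j in range(4):
                vz = rng.normal(0, 1.0, 360)
                slope = np.where(vz > 0, -1.09, -1.16)
                va = 16.2 + slope * vz + rng.normal(0, 1.0, 360)
                frames.append(pd.DataFrame({"va": va, "vz": vz,
                                            "bird": f"b{i}", "day": f"d{j}"}))
        df = pd.concat(frames, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            climb, desc = sm.fit_phase_models(df, thin=2)
        lo, hi = climb.conf_int("vz")
        assert lo <= -1.09 <= hi
        lo, hi = desc.conf_int("vz")
        assert lo <= -1.16 <= hi

    def test_descending_only_data_raises(self):
        df = simulate_lme(seed=7)
        df = df[df["vz"] < 0]
        with pytest.raises(ValueError, match="climbing"):
            sm.fit_phase_models(df)


class TestModelComparison:
    def test_null_extra_term_not_supported(self):
        df = simulate_lme(seed=8, interaction=0.0)
        out = sm.compare_models(df, "va ~ vz + vz:x2", "va ~ vz", thin=5)
        assert out["df"] == 1
        assert out["p"] > 0.01  # no true interaction to find

    def test_true_interaction_detected(self):
        df = simulate_lme(seed=9, interaction=0.5)
        out = sm.compare_models(df, "va ~ vz + vz:x2", "va ~ vz", thin=5)
        assert out["p"] < 0.001
        assert out["aic_difference"] > 0  # full model wins on AIC

    def test_non_nested_raises(self):
        df = simulate_lme(seed=10)
        with pytest.raises(ValueError):
            sm.compare_models(df, "va ~ vz", "va ~ vz + x2")


class TestRouteAltitudeModel:
    def plain_data(self, seed=11, contrast=-50.0):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(6):
            rc = "valley" if i % 2 == 0 else "hill"
            base = 540.0 + (contrast if rc == "valley" else 0.0)
            frames.append(pd.DataFrame({
                "altitude_asl": base + rng.normal(0, 5.0, 60),
                "route_class": rc, "bird": f"b{i % 3}", "day": f"d{i % 2}"}))
        return pd.concat(frames, ignore_index=True)

    def test_programmed_contrast_recovered(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = sm.route_altitude_model(self.plain_data())
        term = [t for t in r.terms["term"] if "valley" in t][0]
        assert r.estimate(term) == pytest.approx(-50.0, abs=5.0)

    def test_null_contrast_near_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = sm.route_altitude_model(self.plain_data(contrast=0.0))
        term = [t for t in r.terms["term"] if "valley" in t][0]
        lo, hi = r.conf_int(term)
        assert lo <= 0.0 <= hi

    def test_sign_flips_with_labels(self):
        df = self.plain_data()
        swapped = df.copy()
        swapped["route_class"] = swapped["route_class"].map(
            {"valley": "hill", "hill": "valley"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = sm.route_altitude_model(df)
            r2 = sm.route_altitude_model(swapped)
        t1 = [t for t in r1.terms["term"] if "valley" in t][0]
        t2 = [t for t in r2.terms["term"] if "valley" in t][0]
        assert r1.estimate(t1) == pytest.approx(-r2.estimate(t2), abs=2.0)

    def test_single_class_raises(self):
        df = self.plain_data()
        with pytest.raises(ValueError):
            sm.route_altitude_model(df[df["route_class"] == "valley"])


class TestSlopeVsTerrain:
    def terrain_data(self, seed=12, coupling=0.06, resid=0.6):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(7):
            for j in range(4):
                slope = rng.normal(0, 0.05, 300)
                vz = coupling * slope / 0.05 * 0.6 + rng.normal(0, resid, 300)
                frames.append(pd.DataFrame({"vz": vz, "terrain_slope": slope,
                                            "bird": f"b{i}", "day": f"d{j}"}))
        return pd.concat(frames, ignore_index=True)

    def test_weak_coupling_small_marginal_r2(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = sm.slope_vs_terrain(self.terrain_data(coupling=0.06), thin=2)
        assert 0.002 <= r.r2_marginal <= 0.05

    def test_zero_coupling_ci_covers_zero(self):
        # any single 95% CI misses 5% of the time; require a majority
        hits = 0
        for seed in (12, 13, 14):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = sm.slope_vs_terrain(self.terrain_data(seed=seed, coupling=0.0),
                                        thin=3)
            lo, hi = r.conf_int("terrain_slope")
            hits += lo <= 0.0 <= hi
        assert hits >= 2

    def test_strong_coupling_high_r2(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = sm.slope_vs_terrain(self.terrain_data(coupling=0.6, resid=0.05),
                                    thin=3)
        assert r.r2_marginal > 0.5
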