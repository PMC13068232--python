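"""Synthetic study generator: geography, predictors, surface and surveys."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from malnupred import anthropometry as a
from malnupred import synthetic_data as syn


class TestGeography:
    def test_counts_multiply(self):
        region = syn.generate_geography(6, 4, seed=1)
        assert len(region.subcounties) == 24
        assert len(region.counties) == 6

    def test_degenerate_minimum_valid(self):
        region = syn.generate_geography(1, 1, seed=7)
        assert len(region.subcounties) == 1
        assert len(region.markets) >= 1

    def test_seeded_determinism(self):
        r1 = syn.generate_geography(3, 2, seed=5)
        r2 = syn.generate_geography(3, 2, seed=5)
        pd.testing.assert_frame_equal(r1.subcounties, r2.subcounties)
        pd.testing.assert_frame_equal(r1.markets, r2.markets)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_geography(0, 3, seed=1)

    def test_markets_subset_of_centroids(self):
        region = syn.generate_geography(4, 3, seed=2)
        cent = set(zip(region.subcounties["lat"], region.subcounties["lon"]))
        for _, mk in region.markets.iterrows():
            assert (mk["lat"], mk["lon"]) in cent


class TestScenarioValidation:
    def test_drought_outside_period_rejected(self):
        with pytest.raises(ValueError):
            syn.ScenarioConfig(period_start="2017-01", drought_start="2015-01")

    def test_cluster_minimums(self):
        with pytest.raises(ValueError):
            syn.ScenarioConfig(clusters_per_stratum=1)


class TestPredictors:
    def test_null_scenario_constant_series(self):
        region = syn.generate_geography(2, 2, seed=3)
        sc = syn.ScenarioConfig(
            seed=3, default_noise_sd=0.0, seasonal_amplitude=0.0,
            drought_rain_multiplier=1.0, drought_ndvi_multiplier=1.0,
            drought_price_multiplier=1.0, drought_admissions_multiplier=1.0,
            drought_insecurity_multiplier=1.0, drought_vaccine_multiplier=1.0,
            epidemic_intensity=0.0,
        )
        long = syn.generate_predictors(region, sc)
        # every non-price series is constant per unit; prices only carry inflation
        for (name, unit), grp in long.groupby(["predictor", "unit_id"]):
            if name == "price":
                continue
            assert grp["value"].nunique() == 1, (name, unit)

    def test_drought_rainfall_multiplier_recovered(self):
        region = syn.generate_geography(2, 2, seed=4)
        sc = syn.ScenarioConfig(seed=4, seasonal_amplitude=0.0,
                                drought_rain_multiplier=0.5, default_noise_sd=0.1)
        long = syn.generate_predictors(region, sc)
        rain = long[long["predictor"] == "rainfall"].copy()
        months = pd.PeriodIndex(rain["month"], freq="M")
        in_drought = sc.in_drought(months)
        in_period = months >= pd.Period(sc.period_start)
        ratios = []
        for unit, grp in rain.assign(dr=in_drought, per=in_period).groupby("unit_id"):
            base = grp[~grp["dr"]]["value"].mean()
            drought = grp[grp["dr"]]["value"].mean()
            ratios.append(drought / base)
        # mean-one noise: in-window mean ~ multiplier x baseline within MC error
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.03)

    def test_seeded_determinism(self):
        region = syn.generate_geography(2, 2, seed=5)
        sc = syn.ScenarioConfig(seed=5)
        l1 = syn.generate_predictors(region, sc)
        l2 = syn.generate_predictors(region, sc)
        pd.testing.assert_frame_equal(l1, l2)


class TestTrueSurface:
    def _surface(self, beta, seed=6):
        region = syn.generate_geography(2, 2, seed=seed)
        sc = syn.ScenarioConfig(seed=seed, beta=beta)
        long = syn.generate_predictors(region, sc)
        return region, sc, syn.build_true_surface(region, long, sc)

    def test_intercept_zero_gives_half(self):
        region, sc, surface = self._surface({"intercept": 0.0})
        cell = syn.true_prevalence(surface, region.subcounties["subcounty"].iloc[0],
                                   "2016-06")
        assert cell["p_gam"] == pytest.approx(0.5)

    def test_logistic_evaluation(self):
        region, sc, surface = self._surface({"intercept": -2.0})
        cell = surface.cell(region.subcounties["subcounty"].iloc[0], "2017-01")
        assert cell["p_gam"] == pytest.approx(float(expit(-2.0)), abs=1e-12)
        assert cell["p_gam"] == pytest.approx(0.1192, abs=1e-4)

    def test_sam_below_gam_everywhere(self):
        region, sc, surface = self._surface(
            {"intercept": -1.5, "ndvi": -0.6, "price": 0.4}
        )
        t = surface.table
        assert (t["p_sam"] <= t["p_gam"] + 1e-12).all()

    def test_unknown_cell_raises(self):
        region, sc, surface = self._surface({"intercept": 0.0})
        with pytest.raises(KeyError):
            surface.cell("nowhere", "2016-06")

    def test_mean_whz_consistent_with_gam(self):
        # P(N(mu,1) < -2) must reproduce the stored GAM probability
        region, sc, surface = self._surface({"intercept": -1.8, "ndvi": -0.5})
        t = surface.table
        assert np.allclose(norm.cdf(-2.0 - t["mean_whz"]), t["p_gam"], atol=1e-12)


class TestSurveys:
    def test_round_trip_whz_exact(self, small_study, lms_ref):
        children = small_study["children"]
        clean = a.clean_table(
            children, lms_ref,
            known_subcounties=small_study["region"].subcounties["subcounty"],
        )
        elig = clean[clean["exclusion"] == "none"]
        assert len(elig) > 500
        assert np.abs(elig["whz"] - elig["true_whz"]).max() < 1e-6

    def test_no_corruption_full_retention(self, small_region, lms_ref):
        sc = syn.ScenarioConfig(
            seed=9, corruption_fraction=0.0, strata_per_county=1,
            clusters_per_stratum=3, children_per_cluster=10,
            survey_months=("2017-02",),
        )
        long = syn.generate_predictors(small_region, sc)
        surface = syn.build_true_surface(small_region, long, sc)
        children, _ = syn.generate_surveys(small_region, surface, sc, lms_ref)
        clean = a.clean_table(children, lms_ref,
                              known_subcounties=small_region.subcounties["subcounty"])
        assert (clean["exclusion"] == "none").all()

    def test_age_corruption_retention_rate(self, small_region, lms_ref):
        sc = syn.ScenarioConfig(
            seed=10, corruption_fraction=0.10, corruption_modes=("age_range",),
            strata_per_county=2, clusters_per_stratum=5, children_per_cluster=30,
            survey_months=("2016-06", "2017-10"),
        )
        long = syn.generate_predictors(small_region, sc)
        surface = syn.build_true_surface(small_region, long, sc)
        children, _ = syn.generate_surveys(small_region, surface, sc, lms_ref)
        clean = a.clean_table(children, lms_ref,
                              known_subcounties=small_region.subcounties["subcounty"])
        retained = (clean["exclusion"] == "none").mean()
        n = len(clean)
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(retained - 0.9) < 4 * se

    def test_prevalence_calibration(self, lms_ref):
        # large clusters, no cluster effect: observed GAM -> surface value
        region = syn.generate_geography(1, 1, seed=11)
        sc = syn.ScenarioConfig(
            seed=11, beta={"intercept": -1.5}, cluster_sd=0.0,
            corruption_fraction=0.0, strata_per_county=1,
            clusters_per_stratum=10, children_per_cluster=400,
            survey_months=("2017-02",), oedema_rate=0.0,
        )
        long = syn.generate_predictors(region, sc)
        surface = syn.build_true_surface(region, long, sc)
        children, _ = syn.generate_surveys(region, surface, sc, lms_ref)
        clean = a.clean_table(children, lms_ref,
                              known_subcounties=region.subcounties["subcounty"])
        p_true = float(expit(-1.5))
        observed = clean[clean["exclusion"] == "none"]["gam"].astype(bool).mean()
        se = np.sqrt(p_true * (1 - p_true) / len(clean))
        assert abs(observed - p_true) < 3 * se

    def test_seeded_determinism(self, small_region, lms_ref):
        sc = syn.ScenarioConfig(seed=12, strata_per_county=1,
                                survey_months=("2017-02",))
        long = syn.generate_predictors(small_region, sc)
        surface = syn.build_true_surface(small_region, long, sc)
        c1, cal1 = syn.generate_surveys(small_region, surface, sc, lms_ref)
        c2, cal2 = syn.generate_surveys(small_region, surface, sc, lms_ref)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(cal1, cal2)

    def test_uncovered_survey_month_raises(self, small_region, lms_ref):
        sc = syn.ScenarioConfig(seed=13, survey_months=("2017-02",))
        long = syn.generate_predictors(small_region, sc)
        surface = syn.build_true_surface(small_region, long, sc)
        bad = syn.ScenarioConfig(seed=13, period_end="2020-12",
                                 survey_months=("2020-06",))
        with pytest.raises(KeyError):
            syn.generate_surveys(small_region, surface, bad, lms_ref)


class TestBundleIO:
    def test_write_bundle_files_and_manifest(self, small_study, lms_ref, tmp_path):
        manifest = syn.write_bundle(
            tmp_path, small_study["region"], small_study["scenario"],
            small_study["predictors"],
            syn.generate_population(small_study["region"], small_study["scenario"]),
            small_study["children"], small_study["calendar"], lms_ref,
        )
        for f in ("children.csv", "predictors.csv", "population.csv",
                  "geography.csv", "centroids.geojson", "markets.geojson",
                  "scenario_manifest.json", "lms_reference.csv"):
            assert (tmp_path / f).exists(), f
        assert manifest["n_children"] == len(small_study["children"])
        assert manifest["seed"] == small_study["scenario"].seed
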