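"""SPI, rolling means, price handling, rates, population and encoding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from malnupred import predictors as p


def _monthly(values, start="2000-01"):
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(values, index=idx, dtype=float)


class TestSpi:
    def test_zero_at_fitted_median(self):
        # long positive series, no zeros: SPI at the fitted median is ~0 and
        # the reference sample itself is ~N(0,1) (probability integral transform)
        rng = np.random.default_rng(1)
        n_years = 35
        vals = rng.gamma(2.0, 50.0, size=12 * n_years)
        s = _monthly(vals, "1985-01")
        spi = p.compute_spi(s)
        assert abs(spi.mean()) < 0.1
        assert 0.9 < spi.std() < 1.1

    def test_known_gamma_quantile(self):
        # x at the 97.7th percentile of the generating gamma scores ~Phi^-1(0.977)
        rng = np.random.default_rng(2)
        vals = rng.gamma(2.0, 50.0, size=12 * 60)
        s = _monthly(vals, "1960-01")
        x977 = stats.gamma.ppf(0.977, 2.0, scale=50.0)
        s.iloc[-1] = x977
        spi = p.compute_spi(s)
        assert spi.iloc[-1] == pytest.approx(stats.norm.ppf(0.977), abs=0.15)

    def test_zero_observation_uses_half_q(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2.0, 50.0, size=12 * 30)
        vals[rng.uniform(size=len(vals)) < 0.25] = 0.0  # ~25% zeros
        s = _monthly(vals, "1985-01")
        spi = p.compute_spi(s)
        zero_spis = spi[s == 0]
        assert zero_spis.notna().all()
        # zero observations map to Phi^-1(q/2), well inside the dry tail
        assert (stats.norm.cdf(zero_spis) < 0.25).all()

    def test_insufficient_reference_raises(self):
        s = _monthly(np.ones(36), "2015-01")
        with pytest.raises(ValueError):
            p.compute_spi(s, min_reference=20)


class TestRollingMean:
    def test_window_three(self):
        s = _monthly([1, 2, 3, 4])
        out = p.rolling_mean(s, 3)
        assert out.iloc[-1] == pytest.approx(3.0)

    def test_missing_values_absorbed(self):
        s = _monthly([1, np.nan, 3])
        out = p.rolling_mean(s, 3)
        assert out.iloc[-1] == pytest.approx(2.0)

    def test_constant_series_idempotent(self):
        s = _monthly([5.0] * 12)
        assert np.allclose(p.rolling_mean(s, 6), 5.0)

    def test_window_one_is_identity(self):
        s = _monthly([1.0, 4.0, 9.0])
        assert np.allclose(p.rolling_mean(s, 1), s.to_numpy())

    def test_calendar_gaps_count_as_missing(self):
        s = _monthly([1.0, 2.0, 3.0, 4.0])
        s = s.drop(s.index[2])  # remove month 3
        out = p.rolling_mean(s, 3)
        # at month 4 the window is (2,3,4] with month 3 missing -> mean(2, 4)
        assert out.iloc[-1] == pytest.approx(3.0)


class TestPrices:
    @pytest.mark.parametrize(
        "nominal,index,expected", [(100, 100, 100.0), (100, 125, 80.0), (50, 80, 62.5)]
    )
    def test_deflation_arithmetic(self, nominal, index, expected):
        s = _monthly([nominal], "2016-01")
        out = p.deflate_price(s, {2015: 100.0, 2016: float(index)})
        assert out.iloc[0] == pytest.approx(expected)

    def test_deflate_inflate_roundtrip(self):
        s = _monthly([123.4, 99.1, 87.0], "2016-01")
        idx = {2015: 100.0, 2016: 117.3}
        real = p.deflate_price(s, idx)
        nominal_again = real * 117.3 / 100.0
        assert np.allclose(nominal_again, s, atol=1e-9)

    def test_rebase_applied(self):
        s = _monthly([100.0], "2016-01")
        # index with base 2010=100: 2015=110, 2016=121 -> rebased 2016 = 110
        out = p.deflate_price(s, {2015: 110.0, 2016: 121.0})
        assert out.iloc[0] == pytest.approx(100 * 110 / 121)

    def test_missing_year_raises(self):
        with pytest.raises(KeyError):
            p.deflate_price(_monthly([1.0], "2019-01"), {2015: 100.0})

    def test_smoothing_median_and_endpoints(self):
        s = _monthly([10.0, 100.0, 12.0])
        out = p.smooth_price(s)
        assert list(out) == [10.0, 12.0, 12.0]
        mono = _monthly([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(p.smooth_price(mono), mono)
        short = _monthly([5.0, 6.0])
        assert np.allclose(p.smooth_price(short), short)


class TestNearestMarket:
    MARKETS = pd.DataFrame(
        {"market_id": ["M1", "M2"], "lat": [0.0, 3.0], "lon": [36.0, 40.0]}
    )

    def test_haversine_oracle(self):
        d1 = p.haversine_km(0.5, 36.2, 0.0, 36.0)
        d2 = p.haversine_km(0.5, 36.2, 3.0, 40.0)
        assert d1 < d2
        assert p.nearest_market((0.5, 36.2), self.MARKETS) == "M1"

    def test_coincident_and_single(self):
        assert p.nearest_market((3.0, 40.0), self.MARKETS) == "M2"
        single = self.MARKETS.iloc[[1]]
        assert p.nearest_market((0.0, 0.0), single) == "M2"

    def test_tie_breaks_by_id(self):
        twins = pd.DataFrame(
            {"market_id": ["MB", "MA"], "lat": [1.0, 1.0], "lon": [36.0, 36.0]}
        )
        assert p.nearest_market((1.0, 36.0), twins.drop_duplicates(["lat"])) == "MB"


class TestRatesAndPopulation:
    def test_rate_arithmetic(self):
        counts = _monthly([50.0, 0.0], "2017-01")
        pop = _monthly([10000.0, 10000.0], "2017-01")
        out = p.per_capita_rate(counts, pop, 1000.0)
        assert list(out) == [5.0, 0.0]

    def test_missing_population_month_raises(self):
        with pytest.raises(KeyError):
            p.per_capita_rate(_monthly([1.0], "2017-01"), _monthly([1.0], "2018-01"))

    def test_population_interpolation(self):
        pop = p.interpolate_population([(2016, 12000.0), (2017, 13200.0)])
        assert pop[pd.Period("2016-07")] == pytest.approx(12000.0)
        assert pop[pd.Period("2017-07")] == pytest.approx(13200.0)
        assert pop[pd.Period("2017-01")] == pytest.approx(12600.0)
        # constant extrapolation before the first anchor
        assert pop[pd.Period("2016-01")] == pytest.approx(12000.0)


class TestQuintileEncoder:
    def test_zero_category_plus_quintiles(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([np.zeros(40), rng.gamma(2, 10, 60)])
        codes, enc = p.quintile_encode(v)
        assert enc.has_zero_category
        assert enc.n_categories == 6
        assert set(codes[v == 0]) == {0.0}
        assert set(codes[v > 0]) <= {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_plain_quintiles_balanced(self):
        v = np.arange(1.0, 101.0)
        codes, enc = p.quintile_encode(v)
        assert not enc.has_zero_category
        counts = pd.Series(codes).value_counts()
        n5 = len(v) / 5
        assert all(n5 - 1 <= c <= n5 + 1 for c in counts)

    def test_out_of_sample_clamping(self):
        v = np.arange(1.0, 101.0)
        _, enc = p.quintile_encode(v)
        assert enc.transform([-5.0])[0] == 1.0
        assert enc.transform([1e6])[0] == 5.0

    def test_few_distinct_values_collapse(self):
        v = np.array([0.0] * 50 + [1.0] * 25 + [2.0] * 25)
        _, enc = p.quintile_encode(v)
        assert enc.n_categories < 6


class TestLinkChildren:
    def test_join_broadcast_and_flag(self):
        children = pd.DataFrame(
            {
                "child_id": ["a", "b", "c"],
                "subcounty": ["A1", "A1", "B1"],
                "survey_month": ["2017-03", "2017-03", "2017-04"],
            }
        )
        sub = pd.DataFrame(
            {
                "subcounty": ["A1", "A1", "B1"],
                "month": ["2017-03", "2017-04", "2017-04"],
                "maize": [10.0, 11.0, np.nan],
            }
        )
        cty = pd.DataFrame(
            {"county": ["A", "B"], "month": ["2017-03", "2017-04"],
             "cholera": [1.5, 0.0]}
        )
        out = p.link_children(children, sub, cty, {"A1": "A", "B1": "B"})
        assert len(out) == len(children)
        assert out.loc[0, "maize"] == 10.0
        assert out.loc[0, "cholera"] == 1.5  # county value broadcast
        assert not out.loc[2, "complete_predictors"]  # missing maize flagged
        assert out.loc[0, "complete_predictors"]

    def test_unknown_subcounty_raises(self):
        children = pd.DataFrame(
            {"child_id": ["a"], "subcounty": ["ZZ"], "survey_month": ["2017-01"]}
        )
        sub = pd.DataFrame({"subcounty": ["A1"], "month": ["2017-01"], "x": [1.0]})
        with pytest.raises(KeyError):
            p.link_children(children, sub, None, {"A1": "A"})
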