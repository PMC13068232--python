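"""Self-contained synthetic study region, predictors and SMART-like surveys.

Emulates the data landscape of a drought-prone multi-county region: monthly
sub-county predictor series (rainfall with a long historical archive, NDVI,
staple price, treatment admissions, insecurity events) and county series
(epidemic cases, vaccine doses), a drought window that depresses rainfall and
vegetation while elevating prices and admissions, and cluster-sampled surveys
of children aged 6-59 months whose malnutrition risk follows a known logistic
link to the predictors.

Ground truth is explicit: a :class:`TrueRiskSurface` maps every (sub-county,
month) cell to the true GAM/SAM probabilities and mean WHZ/MUACZ implied by
the linear predictor, so every downstream stage (cleaning, feature
engineering, model fitting, cross-validation) can be tested for recovery of
known quantities.  Child weights are back-computed from the drawn WHZ through
a synthetic LMS reference (constant Box-Cox power L = 1), so re-scoring the
emitted records reproduces the generating Z-scores exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .anthropometry import DAYS_PER_MONTH, LMSReference, lms_inverse
from .predictors import month_range, nearest_market, to_period

__all__ = [
    "RegionSpec",
    "ScenarioConfig",
    "TrueRiskSurface",
    "generate_geography",
    "synthetic_lms_reference",
    "generate_predictors",
    "generate_population",
    "synthetic_deflator",
    "build_true_surface",
    "true_prevalence",
    "generate_surveys",
    "simulate_logistic_table",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# Region and scenario
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """Study geography: counties, sub-counties with centroids, sentinel markets."""

    counties: list
    subcounties: pd.DataFrame  # columns: subcounty, county, lat, lon
    markets: pd.DataFrame  # columns: market_id, lat, lon

    def __post_init__(self):
        sc = self.subcounties
        if sc["subcounty"].duplicated().any():
            raise ValueError("duplicate subcounty ids")
        if sc.duplicated(subset=["lat", "lon"]).any():
            raise ValueError("centroids must be unique")
        if not set(sc["county"]) <= set(self.counties):
            raise ValueError("every subcounty needs a parent county")
        if len(self.markets) < 1:
            raise ValueError("at least one market required")

    @property
    def subcounty_to_county(self) -> dict:
        return dict(zip(self.subcounties["subcounty"], self.subcounties["county"]))


@dataclass
class ScenarioConfig:
    """Study conditions: period, drought window, true link and survey plan.

    ``beta`` is the true coefficient vector on the logit scale for GAM risk:
    an ``intercept`` entry plus one entry per predictor name, applied to the
    predictor's z-scored monthly values.  Noise standard deviations are
    multiplicative (log-scale) per predictor.  The survey plan draws
    ``strata_per_county`` sub-counties per county, surveyed at each of
    ``survey_months``, with ``clusters_per_stratum`` clusters of
    ``children_per_cluster`` children and a Gaussian cluster random intercept
    (SD ``cluster_sd``) on the logit of GAM risk.
    """

    period_start: str = "2015-01"
    period_end: str = "2018-12"
    history_start: str = "1996-01"  # rainfall archive start, for SPI reference
    drought_start: str = "2016-10"
    drought_end: str = "2018-12"
    beta: dict = field(
        default_factory=lambda: {
            "intercept": -1.9,
            "ndvi": -0.55,
            "rainfall": -0.25,
            "price": 0.35,
            "mam_admissions": 0.3,
        }
    )
    noise_sd: dict = field(default_factory=dict)
    default_noise_sd: float = 0.15
    seasonal_amplitude: float = 0.6
    drought_rain_multiplier: float = 0.55
    drought_ndvi_multiplier: float = 0.75
    drought_price_multiplier: float = 1.35
    drought_admissions_multiplier: float = 1.8
    drought_insecurity_multiplier: float = 1.5
    drought_vaccine_multiplier: float = 0.7
    epidemic_intensity: float = 1.0
    strata_per_county: int = 2
    clusters_per_stratum: int = 6
    children_per_cluster: int = 20
    survey_months: tuple = ("2015-06", "2016-06", "2017-02", "2017-10", "2018-06")
    cluster_sd: float = 0.3
    corruption_fraction: float = 0.02
    corruption_modes: tuple = (
        "missing_field",
        "age_range",
        "implausible",
        "unknown_subcounty",
    )
    oedema_rate: float = 0.02  # among children already below -3 WHZ
    muac_mm_fraction: float = 0.3
    round_weight: bool = False
    seed: int = 0

    def __post_init__(self):
        if to_period(self.period_start) > to_period(self.period_end):
            raise ValueError("empty study period")
        if not (
            to_period(self.period_start)
            <= to_period(self.drought_start)
            <= to_period(self.drought_end)
            <= to_period(self.period_end)
        ):
            raise ValueError("drought window must lie within the study period")
        if self.clusters_per_stratum < 2:
            raise ValueError("clusters per stratum must be >= 2")
        if self.children_per_cluster < 1:
            raise ValueError("children per cluster must be >= 1")

    def sd(self, predictor: str) -> float:
        return float(self.noise_sd.get(predictor, self.default_noise_sd))

    def months(self) -> pd.PeriodIndex:
        return month_range(self.period_start, self.period_end)

    def in_drought(self, months: pd.PeriodIndex) -> np.ndarray:
        return (months >= to_period(self.drought_start)) & (
            months <= to_period(self.drought_end)
        )


def generate_geography(
    n_counties: int, subcounties_per_county: int, seed: int
) -> RegionSpec:
    """Random but seed-deterministic geography in a bounded lat/lon box.

    Centroids are drawn in a box spanning roughly an arid-region extent
    (lat 0..5 N, lon 34..41 E); one market is placed at a centroid of each
    county (so markets are a subset of centroids and every region has >= 1).
    """
    if n_counties < 1 or subcounties_per_county < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    counties = [f"C{c + 1:02d}" for c in range(n_counties)]
    rows = []
    for ci, county in enumerate(counties):
        for s in range(subcounties_per_county):
            rows.append(
                {
                    "subcounty": f"{county}-S{s + 1:02d}",
                    "county": county,
                    "lat": float(rng.uniform(0.0, 5.0)),
                    "lon": float(rng.uniform(34.0, 41.0)),
                }
            )
    sc = pd.DataFrame(rows)
    # one sentinel market per county, at the centroid of a random member subcounty
    midx = []
    for county in counties:
        members = sc.index[sc["county"] == county].to_numpy()
        midx.append(int(rng.choice(members)))
    markets = sc.loc[midx, ["lat", "lon"]].reset_index(drop=True)
    markets.insert(0, "market_id", [f"M{j + 1:02d}" for j in range(len(midx))])
    return RegionSpec(counties, sc, markets)


# ---------------------------------------------------------------------------
# Synthetic LMS reference
# ---------------------------------------------------------------------------

def synthetic_lms_reference(
    height_grid=(45.0, 130.0, 0.5),
    age_grid=(3.0, 62.0, 1.0),
    whz_S: float = 0.08,
    muac_S: float = 0.07,
) -> LMSReference:
    """Smooth parametric LMS tables for weight-for-height and MUAC-for-age.

    Constant Box-Cox power L = 1 and constant coefficient of variation S; the
    medians follow smooth increasing curves (a power law of height for
    weight, linear-in-age for MUAC), with a small sex offset.  Real growth
    standards tabulated in the same (indicator, sex, key, L, M, S) schema are
    drop-in replacements.
    """
    rows = []
    heights = np.arange(*height_grid)
    for sex, mult in (("male", 1.0), ("female", 0.97)):
        med = 0.0021 * heights**1.9 * mult
        for h, m in zip(heights, med):
            rows.append(
                {"indicator": "wfh", "sex": sex, "key": float(h), "L": 1.0,
                 "M": float(m), "S": whz_S}
            )
    ages = np.arange(*age_grid)
    for sex, off in (("male", 0.0), ("female", -0.15)):
        med = 12.6 + 0.045 * ages + off
        for a, m in zip(ages, med):
            rows.append(
                {"indicator": "mfa", "sex": sex, "key": float(a), "L": 1.0,
                 "M": float(m), "S": muac_S}
            )
    return LMSReference(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Predictor series
# ---------------------------------------------------------------------------

def _lognormal_noise(rng, sd: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise: exp(sd*Z - sd^2/2)."""
    if sd == 0:
        return np.ones(size)
    return np.exp(sd * rng.standard_normal(size) - sd * sd / 2.0)


def generate_predictors(region: RegionSpec, scenario: ScenarioConfig) -> pd.DataFrame:
    """Monthly predictor series in long format.

    Columns: (predictor, unit_level, unit_id, month, value).  Sub-county
    level: rainfall (with history back to ``history_start`` to serve as the
    SPI reference archive), ndvi, price (market series attributed to the
    nearest sub-county centroid), mam_admissions, sam_admissions,
    insecurity_events, plus static safe_births and literacy proportions.
    County level: cholera_cases, measles_cases, mmr1_doses, penta3_doses,
    school_attendance (static).  During the drought window rainfall and NDVI
    are depressed and prices/admissions/insecurity elevated by the configured
    multipliers, with mean-one multiplicative noise on top.
    """
    rng = np.random.default_rng(scenario.seed + 101)
    months = scenario.months()
    hist_months = month_range(scenario.history_start, scenario.period_end)
    drought_hist = scenario.in_drought(hist_months)
    drought = scenario.in_drought(months)
    rows = []

    def emit(predictor, level, unit, mindex, values):
        rows.extend(
            {"predictor": predictor, "unit_level": level, "unit_id": unit,
             "month": str(m), "value": float(v)}
            for m, v in zip(mindex, values)
        )

    season_hist = 1.0 + scenario.seasonal_amplitude * np.sin(
        2 * np.pi * (hist_months.month - 4) / 12.0
    )
    season = 1.0 + 0.1 * scenario.seasonal_amplitude * np.sin(
        2 * np.pi * (months.month - 4) / 12.0
    )

    pop_annual = generate_population(region, scenario)
    pop_mid = pop_annual.groupby("subcounty")["population"].mean()

    for _, sc in region.subcounties.iterrows():
        sid = sc["subcounty"]
        base_rain = rng.uniform(40.0, 120.0)
        rain = (
            base_rain
            * season_hist
            * np.where(drought_hist, scenario.drought_rain_multiplier, 1.0)
            * _lognormal_noise(rng, scenario.sd("rainfall"), len(hist_months))
        )
        emit("rainfall", "subcounty", sid, hist_months, rain)

        base_ndvi = rng.uniform(0.35, 0.55)
        ndvi = (
            base_ndvi
            * season
            * np.where(drought, scenario.drought_ndvi_multiplier, 1.0)
            * _lognormal_noise(rng, scenario.sd("ndvi"), len(months))
        )
        emit("ndvi", "subcounty", sid, months, np.clip(ndvi, 0.02, 0.95))

        pop = pop_mid[sid]
        for name, lo, hi, mult in (
            ("mam_admissions", 2.0, 6.0, scenario.drought_admissions_multiplier),
            ("sam_admissions", 0.5, 2.0, scenario.drought_admissions_multiplier),
            ("insecurity_events", 0.05, 0.4, scenario.drought_insecurity_multiplier),
        ):
            base_rate = rng.uniform(lo, hi)  # per 1,000 persons per month
            mu = base_rate * pop / 1000.0 * np.where(drought, mult, 1.0)
            counts = np.round(mu * _lognormal_noise(rng, scenario.sd(name), len(months)))
            emit(name, "subcounty", sid, months, np.maximum(counts, 0.0))

        emit("safe_births", "subcounty", sid, months,
             np.full(len(months), rng.uniform(0.3, 0.8)))
        emit("literacy", "subcounty", sid, months,
             np.full(len(months), rng.uniform(0.2, 0.7)))

    # market price series, attributed to sub-counties by nearest centroid
    inflation = {
        y: (1.03 ** (y - 2015)) * 100.0
        for y in range(hist_months[0].year, months[-1].year + 1)
    }
    market_price = {}
    for _, mk in region.markets.iterrows():
        base = rng.uniform(35.0, 55.0)
        infl = np.array([inflation[m.year] / 100.0 for m in months])
        price = (
            base
            * infl
            * np.where(drought, scenario.drought_price_multiplier, 1.0)
            * _lognormal_noise(rng, scenario.sd("price"), len(months))
        )
        market_price[str(mk["market_id"])] = price
    for _, sc in region.subcounties.iterrows():
        mkt = nearest_market((sc["lat"], sc["lon"]), region.markets)
        emit("price", "subcounty", sc["subcounty"], months, market_price[mkt])

    pop_county = (
        pop_annual.merge(region.subcounties[["subcounty", "county"]], on="subcounty")
        .groupby("county")["population"]
        .mean()
    )
    for county in region.counties:
        cpop = pop_county[county]
        for name in ("cholera_cases", "measles_cases"):
            cases = np.zeros(len(months))
            if scenario.epidemic_intensity > 0:
                for j in range(0, len(months), 6):
                    if rng.uniform() < 0.15 * scenario.epidemic_intensity:
                        peak = rng.uniform(20.0, 80.0) * cpop / 1e5
                        span = min(4, len(months) - j)
                        cases[j : j + span] += peak * 0.5 ** np.arange(span)
            emit(name, "county", county, months, np.round(cases))

        for name in ("mmr1_doses", "penta3_doses"):
            base = cpop * rng.uniform(0.0025, 0.0040)
            mu = base * np.where(drought, scenario.drought_vaccine_multiplier, 1.0)
            doses = np.round(mu * _lognormal_noise(rng, scenario.sd(name), len(months)))
            emit(name, "county", county, months, np.maximum(doses, 0.0))

        emit("school_attendance", "county", county, months,
             np.full(len(months), rng.uniform(0.5, 0.9)))

    return pd.DataFrame(rows)


def generate_population(region: RegionSpec, scenario: ScenarioConfig) -> pd.DataFrame:
    """Annual sub-county population totals (columns: subcounty, year, population)."""
    rng = np.random.default_rng(scenario.seed + 77)
    years = range(to_period(scenario.period_start).year,
                  to_period(scenario.period_end).year + 1)
    rows = []
    for _, sc in region.subcounties.iterrows():
        base = rng.uniform(2e4, 1.5e5)
        for i, y in enumerate(years):
            rows.append(
                {"subcounty": sc["subcounty"], "year": int(y),
                 "population": float(base * 1.028**i)}
            )
    return pd.DataFrame(rows)


def synthetic_deflator(scenario: ScenarioConfig, annual_inflation: float = 0.03) -> dict:
    """Annual sector deflator index, base year 2015 = 100."""
    years = range(to_period(scenario.history_start).year,
                  to_period(scenario.period_end).year + 1)
    return {int(y): 100.0 * (1 + annual_inflation) ** (y - 2015) for y in years}


# ---------------------------------------------------------------------------
# True risk surface
# ---------------------------------------------------------------------------

@dataclass
class TrueRiskSurface:
    """Ground truth per (sub-county, month): GAM/SAM probability and mean Z.

    Derived from the scenario's logistic link: the GAM probability is
    logit^-1 of the linear predictor on z-scored predictor values; the mean
    WHZ is the unit-SD Gaussian mean that yields that probability below -2
    (mu = -2 - Phi^-1(p)); the SAM probability Phi(-3 - mu) is then always
    below the GAM probability; the mean MUACZ tracks the mean WHZ with slope
    0.8.
    """

    table: pd.DataFrame  # index (subcounty, month str); columns p_gam, p_sam, mean_whz, mean_muacz

    def __post_init__(self):
        t = self.table
        if ((t["p_gam"] < 0) | (t["p_gam"] > 1)).any():
            raise ValueError("GAM probabilities must be in [0,1]")
        if (t["p_sam"] > t["p_gam"] + 1e-12).any():
            raise ValueError("SAM probability must not exceed GAM probability")

    def cell(self, subcounty: str, month) -> dict:
        key = (str(subcounty), str(to_period(month)))
        try:
            row = self.table.loc[key]
        except KeyError:
            raise KeyError(f"no surface cell for {key}")
        return {
            "p_gam": float(row["p_gam"]),
            "p_sam": float(row["p_sam"]),
            "mean_whz": float(row["mean_whz"]),
            "mean_muacz": float(row["mean_muacz"]),
        }


def true_prevalence(surface: TrueRiskSurface, subcounty: str, month) -> dict:
    """Stored ground truth at one (sub-county, month) cell."""
    return surface.cell(subcounty, month)


def build_true_surface(
    region: RegionSpec,
    predictors_long: pd.DataFrame,
    scenario: ScenarioConfig,
) -> TrueRiskSurface:
    """Evaluate the scenario's true logistic link on the generated predictors.

    Each non-intercept ``beta`` key names a predictor in the long table; its
    concurrent monthly value (county-level series broadcast to member
    sub-counties) is z-scored over all study-period cells and multiplied by
    the coefficient.  GAM probability = logit^-1 of the sum.
    """
    months = [str(m) for m in scenario.months()]
    cells = pd.MultiIndex.from_product(
        [region.subcounties["subcounty"], months], names=["subcounty", "month"]
    )
    lp = np.full(len(cells), float(scenario.beta.get("intercept", 0.0)))
    sc2c = region.subcounty_to_county
    for name, coef in scenario.beta.items():
        if name == "intercept" or coef == 0:
            continue
        sub = predictors_long[predictors_long["predictor"] == name]
        if sub.empty:
            raise KeyError(f"beta names unknown predictor {name!r}")
        level = sub["unit_level"].iloc[0]
        ser = sub.set_index(["unit_id", "month"])["value"]
        if level == "county":
            vals = np.array(
                [ser.get((sc2c[s], m), np.nan) for s, m in cells], dtype=float
            )
        else:
            vals = np.array([ser.get((s, m), np.nan) for s, m in cells], dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"predictor {name!r} does not cover the study period")
        sd = vals.std()
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        lp = lp + float(coef) * z
    p_gam = expit(lp)
    mean_whz = -2.0 - norm.ppf(p_gam)
    p_sam = norm.cdf(-3.0 - mean_whz)
    table = pd.DataFrame(
        {
            "p_gam": p_gam,
            "p_sam": p_sam,
            "mean_whz": mean_whz,
            "mean_muacz": 0.8 * mean_whz,
        },
        index=cells,
    )
    return TrueRiskSurface(table)


# ---------------------------------------------------------------------------
# Surveys
# ---------------------------------------------------------------------------

def generate_surveys(
    region: RegionSpec,
    surface: TrueRiskSurface,
    scenario: ScenarioConfig,
    ref: LMSReference | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-sampled SMART-like surveys with known ground truth.

    Returns ``(children, calendar)``.  Strata are (sub-county, survey month)
    pairs; within each stratum, clusters carry a Gaussian random intercept on
    the logit of GAM risk, and each child's WHZ is drawn from a unit-SD
    Gaussian whose mean solves the cluster's GAM probability.  The child's
    weight is back-computed from the drawn WHZ through the LMS reference at
    the emitted (rounded) height, so the cleaning stage re-derives the
    generating WHZ exactly.  A configurable fraction of records is corrupted
    (missing fields, out-of-range ages, doubled weights, unknown sub-county)
    to exercise the exclusion criteria.  Ground-truth columns ``true_whz``
    and ``true_muacz`` are carried for testing and are not part of the
    minimal variable set.
    """
    if ref is None:
        ref = synthetic_lms_reference()
    rng = np.random.default_rng(scenario.seed + 202)
    sc_by_county = {
        c: list(region.subcounties.loc[region.subcounties["county"] == c, "subcounty"])
        for c in region.counties
    }
    surveyed = []
    for county in region.counties:
        pool = sc_by_county[county]
        k = min(scenario.strata_per_county, len(pool))
        surveyed.extend(sorted(rng.choice(pool, size=k, replace=False)))

    children_rows = []
    calendar_rows = []
    for sid in surveyed:
        county = region.subcounty_to_county[sid]
        for month in scenario.survey_months:
            cell = surface.cell(sid, month)  # raises if not covered
            stratum = f"{sid}|{month}"
            calendar_rows.append(
                {
                    "stratum_id": stratum,
                    "survey_id": f"SV-{month}",
                    "subcounty": sid,
                    "county": county,
                    "survey_month": month,
                    "n_clusters": scenario.clusters_per_stratum,
                }
            )
            for c in range(scenario.clusters_per_stratum):
                u = rng.normal(0.0, scenario.cluster_sd) if scenario.cluster_sd > 0 else 0.0
                p_cl = float(expit(logit(np.clip(cell["p_gam"], 1e-9, 1 - 1e-9)) + u))
                mu_cl = -2.0 - norm.ppf(p_cl)
                for k in range(scenario.children_per_cluster):
                    rec = _draw_child(rng, ref, scenario, mu_cl, cell)
                    rec.update(
                        {
                            "survey_id": f"SV-{month}",
                            "stratum_id": stratum,
                            "cluster": c + 1,
                            "child_id": f"{stratum}|c{c + 1}|k{k + 1}",
                            "subcounty": sid,
                            "survey_month": month,
                        }
                    )
                    children_rows.append(rec)
    children = pd.DataFrame(children_rows)
    children = _corrupt(children, scenario, rng)
    cols = [
        "survey_id", "stratum_id", "cluster", "child_id", "subcounty",
        "survey_month", "age_value", "age_unit", "sex", "weight", "height",
        "oedema", "muac", "true_whz", "true_muacz",
    ]
    return children[cols], pd.DataFrame(calendar_rows)


def _draw_child(rng, ref, scenario, mu_cluster, cell) -> dict:
    sex = "male" if rng.uniform() < 0.5 else "female"
    age = rng.uniform(6.0, 59.99)
    if rng.uniform() < 0.2:  # a share of surveys report age in days
        age_value = float(np.round(age * DAYS_PER_MONTH))
        age_unit = "days"
    else:
        age_value = float(np.round(age, 1))
        age_unit = "months"
    age_months = age_value / DAYS_PER_MONTH if age_unit == "days" else age_value

    height = 67.0 + 1.05 * (age_months - 6.0) - 0.004 * (age_months - 6.0) ** 2
    height = float(np.clip(np.round(height + rng.normal(0, 2.5), 1), 50.0, 125.0))

    whz = float(rng.normal(mu_cluster, 1.0))
    Lw, Mw, Sw = ref.lookup("wfh", sex, height)
    weight = float(lms_inverse(whz, Lw, Mw, Sw))
    if scenario.round_weight:
        weight = round(weight, 1)

    muacz = float(
        cell["mean_muacz"]
        + 0.6 * (whz - cell["mean_whz"])
        + 0.8 * rng.standard_normal()
    )
    La, Ma, Sa = ref.lookup("mfa", sex, age_months)
    muac_cm = round(float(lms_inverse(muacz, La, Ma, Sa)), 1)
    if rng.uniform() < scenario.muac_mm_fraction:
        muac = float(np.round(muac_cm * 10.0))  # reported in mm
    else:
        muac = muac_cm

    oedema = "yes" if (whz < -3 and rng.uniform() < scenario.oedema_rate) else "no"
    return {
        "age_value": age_value,
        "age_unit": age_unit,
        "sex": sex,
        "weight": weight,
        "height": height,
        "oedema": oedema,
        "muac": muac,
        "true_whz": whz,
        "true_muacz": muacz,
    }


def _corrupt(children: pd.DataFrame, scenario: ScenarioConfig, rng) -> pd.DataFrame:
    if scenario.corruption_fraction <= 0 or children.empty:
        return children
    out = children.copy()
    hit = rng.uniform(size=len(out)) < scenario.corruption_fraction
    modes = list(scenario.corruption_modes)
    for i in np.flatnonzero(hit):
        mode = modes[rng.integers(len(modes))]
        if mode == "missing_field":
            col = ("weight", "height", "muac", "sex")[rng.integers(4)]
            out.iat[i, out.columns.get_loc(col)] = np.nan
        elif mode == "age_range":
            out.iat[i, out.columns.get_loc("age_value")] = float(rng.uniform(61, 80))
            out.iat[i, out.columns.get_loc("age_unit")] = "months"
        elif mode == "implausible":
            out.iat[i, out.columns.get_loc("weight")] = (
                float(out.iat[i, out.columns.get_loc("weight")]) * 2.0
            )
        elif mode == "unknown_subcounty":
            out.iat[i, out.columns.get_loc("subcounty")] = np.nan
    return out


# ---------------------------------------------------------------------------
# Direct simulation helper (parameter-recovery studies)
# ---------------------------------------------------------------------------

def simulate_logistic_table(
    beta: Mapping[str, float],
    n: int,
    seed: int,
    n_noise: int = 0,
    stratum_count: int = 1,
) -> pd.DataFrame:
    """Child rows with iid standard-normal predictors and a known logistic link.

    ``beta`` holds ``intercept`` plus named true coefficients; ``n_noise``
    extra standard-normal columns (``noise1`` ...) carry zero true effect.
    Rows are split evenly into ``stratum_count`` strata (column
    ``stratum_id``).  Outcome column: ``y`` (0/1).
    """
    rng = np.random.default_rng(seed)
    cols = {}
    lp = np.full(n, float(beta.get("intercept", 0.0)))
    for name, coef in beta.items():
        if name == "intercept":
            continue
        x = rng.standard_normal(n)
        cols[name] = x
        lp += float(coef) * x
    for j in range(n_noise):
        cols[f"noise{j + 1}"] = rng.standard_normal(n)
    y = (rng.uniform(size=n) < expit(lp)).astype(int)
    df = pd.DataFrame(cols)
    df["y"] = y
    df["stratum_id"] = [f"st{(i * stratum_count) // n + 1}" for i in range(n)]
    return df


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(
    outdir,
    region: RegionSpec,
    scenario: ScenarioConfig,
    predictors_long: pd.DataFrame,
    population_annual: pd.DataFrame,
    children: pd.DataFrame,
    calendar: pd.DataFrame,
    ref: LMSReference,
) -> dict:
    """Write the synthetic study as delimited text + GeoJSON + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region.subcounties.to_csv(outdir / "geography.csv", index=False)
    predictors_long.to_csv(outdir / "predictors.csv", index=False)
    population_annual.to_csv(outdir / "population.csv", index=False)
    children.to_csv(outdir / "children.csv", index=False)
    calendar.to_csv(outdir / "survey_calendar.csv", index=False)
    ref.to_csv(outdir / "lms_reference.csv")

    def _fc(df, id_col):
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point",
                                 "coordinates": [float(r["lon"]), float(r["lat"])]},
                    "properties": {id_col: str(r[id_col])},
                }
                for _, r in df.iterrows()
            ],
        }

    (outdir / "centroids.geojson").write_text(
        json.dumps(_fc(region.subcounties, "subcounty"))
    )
    (outdir / "markets.geojson").write_text(json.dumps(_fc(region.markets, "market_id")))
    manifest = {
        "seed": scenario.seed,
        "beta": dict(scenario.beta),
        "period": [scenario.period_start, scenario.period_end],
        "drought": [scenario.drought_start, scenario.drought_end],
        "n_subcounties": int(len(region.subcounties)),
        "n_children": int(len(children)),
        "n_strata": int(calendar["stratum_id"].nunique()),
    }
    (outdir / "scenario_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
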