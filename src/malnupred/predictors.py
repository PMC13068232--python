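"""Predictor engineering: transforms raw monthly series into model-ready features.

Covers the standardized precipitation index (SPI), right-aligned rolling
means, price deflation and smoothing, market-to-subcounty attribution by
centroid distance, per-capita rates, monthly interpolation of annual
population totals, quintile encoding of skewed predictors, and the join of
per-child records to their sub-county-month (or county-month) predictor
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "month_range",
    "to_period",
    "compute_spi",
    "rolling_mean",
    "deflate_price",
    "rebase_index",
    "smooth_price",
    "haversine_km",
    "nearest_market",
    "per_capita_rate",
    "interpolate_population",
    "QuintileEncoder",
    "quintile_encode",
    "link_children",
]

EARTH_RADIUS_KM = 6371.0088


def to_period(month) -> pd.Period:
    """Coerce a month given as str/Timestamp/Period to a monthly Period."""
    return pd.Period(month, freq="M")


def month_range(start, end) -> pd.PeriodIndex:
    """Inclusive monthly PeriodIndex from ``start`` to ``end``."""
    return pd.period_range(to_period(start), to_period(end), freq="M")


# ---------------------------------------------------------------------------
# Standardized precipitation index
# ---------------------------------------------------------------------------

def compute_spi(
    precip: pd.Series,
    reference_period: tuple | None = None,
    accumulation: int = 1,
    min_reference: int = 20,
) -> pd.Series:
    """Standardized precipitation index of a monthly precipitation series.

    ``precip`` is indexed by monthly Period (or coercible).  Totals are
    accumulated over ``accumulation`` months (right-aligned; default 1, i.e.
    monthly totals).  For each calendar month a gamma distribution is fitted
    by maximum likelihood to the strictly positive accumulated totals whose
    month falls inside ``reference_period`` (default: the whole series), with
    a zero-inflation weight ``q`` equal to the observed fraction of zeros.
    The SPI of an accumulated total ``x`` is then

        Phi^-1(q/2)                 if x == 0
        Phi^-1(q + (1-q) * G(x))    otherwise,

    where ``G`` is the fitted gamma CDF and ``Phi^-1`` the standard normal
    quantile.  Calendar months with fewer than ``min_reference`` reference
    values raise; calendar months whose reference values are all zero are
    unfittable and return NaN for every month of that calendar month.
    """
    s = precip.copy()
    s.index = pd.PeriodIndex(s.index, freq="M")
    s = s.sort_index()
    acc = s.rolling(accumulation, min_periods=accumulation).sum() if accumulation > 1 else s

    if reference_period is None:
        ref_mask = pd.Series(True, index=acc.index)
    else:
        start, end = to_period(reference_period[0]), to_period(reference_period[1])
        ref_mask = (acc.index >= start) & (acc.index <= end)
        ref_mask = pd.Series(ref_mask, index=acc.index)

    out = pd.Series(np.nan, index=acc.index, dtype=float)
    months = acc.index.month
    for cal_month in range(1, 13):
        sel = months == cal_month
        if not sel.any():
            continue
        ref = acc[sel & ref_mask.to_numpy()].dropna()
        if len(ref) < min_reference:
            raise ValueError(
                f"calendar month {cal_month}: only {len(ref)} reference values "
                f"(< {min_reference})"
            )
        q = float((ref == 0).mean())
        pos = ref[ref > 0].to_numpy(dtype=float)
        vals = acc[sel]
        if len(pos) == 0:
            # all-zero calendar month: gamma unfittable, flagged missing
            continue
        # MLE gamma fit with location pinned at zero (method-of-moments start
        # is scipy's internal default behaviour for the remaining parameters)
        shape, _, scale = stats.gamma.fit(pos, floc=0)
        cdf = np.where(
            vals.to_numpy(dtype=float) == 0,
            q / 2.0,
            q + (1 - q) * stats.gamma.cdf(vals.to_numpy(dtype=float), shape, scale=scale),
        )
        cdf = np.clip(cdf, 1e-9, 1 - 1e-9)
        res = stats.norm.ppf(cdf)
        res[~np.isfinite(vals.to_numpy(dtype=float))] = np.nan
        out[sel] = res
    return out


# ---------------------------------------------------------------------------
# Rolling means, prices, distances, rates, population
# ---------------------------------------------------------------------------

def rolling_mean(series: pd.Series, window: int) -> pd.Series:
    """Right-aligned rolling mean over the previous ``window`` months.

    The value at month t is the mean of available (non-missing) values in
    (t-window, t], so isolated missing months are absorbed; the result is
    missing only where every value in the window is missing.  The index is
    expanded to a complete monthly grid first so that gaps count as missing
    months rather than silently shrinking the window.
    """
    s = series.copy()
    s.index = pd.PeriodIndex(s.index, freq="M")
    s = s.sort_index()
    full = pd.period_range(s.index[0], s.index[-1], freq="M")
    s = s.reindex(full)
    return s.rolling(window, min_periods=1).mean()


def rebase_index(index_by_year: Mapping[int, float], base_year: int = 2015) -> dict:
    """Rebase an annual deflator index so that ``base_year`` = 100."""
    base = index_by_year[base_year]
    if base <= 0:
        raise ValueError("base-year index must be positive")
    return {int(y): 100.0 * v / base for y, v in index_by_year.items()}


def deflate_price(
    nominal: pd.Series,
    index_by_year: Mapping[int, float],
    base_year: int = 2015,
) -> pd.Series:
    """Deflate nominal prices to constant (base-year) terms.

    ``nominal`` is indexed by monthly Period; the annual index is applied by
    the calendar year of each observation after rebasing so ``base_year`` =
    100: ``real = nominal * 100 / index[year]``.  A missing index year raises.
    """
    s = nominal.copy()
    s.index = pd.PeriodIndex(s.index, freq="M")
    idx = rebase_index(index_by_year, base_year)
    years = s.index.year
    missing = sorted({int(y) for y in np.unique(years)} - set(idx))
    if missing:
        raise KeyError(f"deflator index missing years: {missing}")
    denom = np.array([idx[int(y)] for y in years], dtype=float)
    if np.any(denom <= 0):
        raise ValueError("deflator index values must be positive")
    return s * 100.0 / denom


def smooth_price(values: pd.Series) -> pd.Series:
    """Moderate outlier attenuation: centred running median, window 3.

    Endpoints are passed through unchanged; series shorter than 3 return
    unchanged.
    """
    v = values.to_numpy(dtype=float)
    if len(v) < 3:
        return values.copy()
    out = v.copy()
    out[1:-1] = np.median(np.column_stack([v[:-2], v[1:-1], v[2:]]), axis=1)
    return pd.Series(out, index=values.index)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def nearest_market(centroid: tuple[float, float], markets: pd.DataFrame) -> str:
    """Market id minimising haversine distance to a sub-county centroid.

    ``markets`` has columns (market_id, lat, lon).  Ties break by market id
    order (ascending).
    """
    if markets.empty:
        raise ValueError("at least one market required")
    lat, lon = centroid
    d = haversine_km(lat, lon, markets["lat"].to_numpy(), markets["lon"].to_numpy())
    order = markets.assign(_d=d).sort_values(["_d", "market_id"])
    return str(order.iloc[0]["market_id"])


def per_capita_rate(counts: pd.Series, population: pd.Series, scale: float = 1000.0) -> pd.Series:
    """Event rate per ``scale`` persons: ``count / population * scale``.

    Both series are indexed by monthly Period; every count month must have a
    positive population value.
    """
    c = counts.copy()
    c.index = pd.PeriodIndex(c.index, freq="M")
    p = population.copy()
    p.index = pd.PeriodIndex(p.index, freq="M")
    pop = p.reindex(c.index)
    if pop.isna().any():
        missing = list(c.index[pop.isna()][:3])
        raise KeyError(f"population missing for months {missing}")
    if (pop <= 0).any():
        raise ValueError("population must be positive")
    return c / pop * scale


def interpolate_population(annual: Sequence[tuple[int, float]]) -> pd.Series:
    """Monthly population from annual totals, anchored at mid-year (July).

    Linear interpolation between anchors, constant extrapolation beyond them.
    Returns a Series indexed from January of the first anchor year to
    December of the last.
    """
    annual = sorted(annual)
    if len(annual) < 2:
        raise ValueError("need at least two annual values")
    anchors = [pd.Period(f"{int(y)}-07", freq="M") for y, _ in annual]
    vals = np.array([v for _, v in annual], dtype=float)
    grid = pd.period_range(f"{annual[0][0]}-01", f"{annual[-1][0]}-12", freq="M")
    x = np.array([p.ordinal for p in grid], dtype=float)
    xa = np.array([p.ordinal for p in anchors], dtype=float)
    return pd.Series(np.interp(x, xa, vals), index=grid)


# ---------------------------------------------------------------------------
# Quintile encoding
# ---------------------------------------------------------------------------

@dataclass
class QuintileEncoder:
    """Quintile (plus optional zero-category) encoder for skewed predictors.

    Fitted on training values: if the fraction of zeros is at least
    ``zero_category_threshold`` the zeros form category 0 and quintile
    cut-points are computed on the positive values only (categories 1-5);
    otherwise quintiles are computed on all values (categories 1-5, no zero
    category).  Stored cut-points are reused out of sample, with values
    beyond the training range clamped to the extreme categories.  When the
    positive values have too few distinct quantiles, duplicate cut-points
    collapse and fewer categories result (recorded in ``n_categories``).
    """

    zero_category_threshold: float = 0.10
    n_quantile_bins: int = 5
    has_zero_category: bool = field(default=False, init=False)
    cutpoints_: np.ndarray = field(default=None, init=False, repr=False)
    n_categories: int = field(default=0, init=False)

    def fit(self, values) -> "QuintileEncoder":
        v = pd.Series(values).dropna().to_numpy(dtype=float)
        if len(v) < 10:
            raise ValueError("need at least 10 non-missing values to fit")
        zero_frac = float((v == 0).mean())
        self.has_zero_category = zero_frac >= self.zero_category_threshold
        base = v[v > 0] if self.has_zero_category else v
        qs = np.linspace(0, 1, self.n_quantile_bins + 1)[1:-1]
        cuts = np.unique(np.quantile(base, qs)) if len(base) else np.array([])
        self.cutpoints_ = cuts
        self.n_categories = (1 if self.has_zero_category else 0) + len(cuts) + 1
        return self

    def transform(self, values) -> np.ndarray:
        if self.cutpoints_ is None:
            raise RuntimeError("encoder not fitted")
        v = np.asarray(pd.Series(values), dtype=float)
        # np.searchsorted clamps out-of-range values into the extreme bins
        cat = np.searchsorted(self.cutpoints_, v, side="right") + 1
        if self.has_zero_category:
            cat = np.where(v == 0, 0, cat)
        out = cat.astype(float)
        out[~np.isfinite(v)] = np.nan
        return out

    def fit_transform(self, values) -> np.ndarray:
        return self.fit(values).transform(values)


def quintile_encode(values, zero_category_threshold: float = 0.10):
    """Fit-and-apply quintile encoding; returns (codes, fitted encoder)."""
    enc = QuintileEncoder(zero_category_threshold=zero_category_threshold)
    return enc.fit_transform(values), enc


# ---------------------------------------------------------------------------
# Child-to-predictor linkage
# ---------------------------------------------------------------------------

def link_children(
    children: pd.DataFrame,
    subcounty_features: pd.DataFrame,
    county_features: pd.DataFrame | None,
    subcounty_to_county: Mapping[str, str],
) -> pd.DataFrame:
    """Join eligible child rows to concurrent predictor values.

    ``subcounty_features`` has one row per (subcounty, month) with predictor
    columns; ``county_features`` (optional) one row per (county, month) whose
    columns broadcast to all member sub-counties.  Children carry
    ``subcounty`` and ``survey_month`` columns.  The result preserves the row
    count of ``children``; rows with any missing joined predictor are flagged
    in a boolean ``complete_predictors`` column rather than dropped (the
    fold-coverage logic consumes the flag).  Children in a sub-county absent
    from the geography mapping raise.
    """
    ch = children.copy()
    unknown = set(ch["subcounty"].dropna().astype(str)) - set(subcounty_to_county)
    if unknown:
        raise KeyError(f"children in unknown sub-counties: {sorted(unknown)[:5]}")
    ch["_month"] = pd.PeriodIndex(ch["survey_month"], freq="M")
    ch["_county"] = ch["subcounty"].astype(str).map(subcounty_to_county)

    sf = subcounty_features.copy()
    sf["_month"] = pd.PeriodIndex(sf["month"], freq="M")
    sf = sf.drop(columns=["month"])
    feature_cols = [c for c in sf.columns if c not in ("subcounty", "_month")]
    merged = ch.merge(
        sf, how="left", left_on=["subcounty", "_month"], right_on=["subcounty", "_month"]
    )

    if county_features is not None:
        cf = county_features.copy()
        cf["_month"] = pd.PeriodIndex(cf["month"], freq="M")
        cf = cf.drop(columns=["month"])
        cfeat = [c for c in cf.columns if c not in ("county", "_month")]
        merged = merged.merge(
            cf, how="left", left_on=["_county", "_month"], right_on=["county", "_month"],
            suffixes=("", "_countytbl"),
        )
        if "county_countytbl" in merged.columns:
            merged = merged.drop(columns=["county_countytbl"])
        elif "county" in merged.columns and "county" not in ch.columns:
            merged = merged.drop(columns=["county"])
        feature_cols = feature_cols + cfeat

    merged["complete_predictors"] = merged[feature_cols].notna().all(axis=1)
    merged = merged.drop(columns=["_month"]).rename(columns={"_county": "county_id"})
    if len(merged) != len(children):
        raise AssertionError("linkage changed the row count")
    return merged
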