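"""Child-level outcome models: GLM/GAM-style fits and random forests.

Binary outcomes (GAM, SAM) are modelled as binomial with a logit link and
fitted by iteratively reweighted least squares; continuous outcomes (mean
WHZ, MUACZ at the child level) are Gaussian with an identity link.  Smooth
terms are fixed-degree-of-freedom cubic B-spline bases with knots at training
quantiles, which keeps every candidate model AIC-comparable and fully
deterministic.  Predictors are screened univariately by AIC (choosing between
3- and 6-month rolling windows per predictor), pairs of highly rank-correlated
predictors are blocked, and multivariable specifications are grown by forward
selection in univariate-AIC order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.linalg import qr as scipy_qr
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "CoverageError",
    "Term",
    "ModelSpec",
    "ForestSpec",
    "SplineBasis",
    "spline_basis",
    "DesignBuilder",
    "FittedModel",
    "fit_glm",
    "ForestModel",
    "fit_forest",
    "univariate_screen",
    "correlation_screen",
    "forward_select",
    "predict_stratum",
]

BINOMIAL = "binomial"
GAUSSIAN = "gaussian"


class CoverageError(ValueError):
    """Prediction rows not covered by the trained model (missing predictor
    values or categorical levels unseen in training)."""


@dataclass(frozen=True)
class Term:
    """One model term: a predictor column plus its functional form."""

    name: str
    form: str = "linear"  # "linear" | "smooth"
    df: int = 4  # basis dimension for smooth terms
    encoding: str = "continuous"  # "continuous" | "categorical"


@dataclass
class ModelSpec:
    """Declarative model description: outcome, family and ordered term list."""

    outcome: str
    family: str  # "binomial" | "gaussian"
    terms: list[Term] = field(default_factory=list)

    def __post_init__(self):
        if self.family not in (BINOMIAL, GAUSSIAN):
            raise ValueError(f"unknown family {self.family!r}")
        names = [t.name for t in self.terms]
        if len(names) != len(set(names)):
            raise ValueError("a predictor may appear at most once")

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "terms": [asdict(t) for t in self.terms],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(d["outcome"], d["family"], [Term(**t) for t in d["terms"]])


@dataclass
class ForestSpec:
    """Random-forest configuration: ensemble size, per-node candidate
    variables, task type and seed."""

    n_trees: int = 1000
    max_split_vars: int = 5
    task: str = "classification"  # "classification" | "regression"
    seed: int = 0
    bootstrap: bool = True  # False grows each tree on the full sample

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")


# ---------------------------------------------------------------------------
# Spline basis
# ---------------------------------------------------------------------------

class SplineBasis:
    """Cubic B-spline basis with ``df`` columns and knots at training quantiles.

    The raw cubic basis has df+1 functions (a partition of unity); the first
    is dropped so the span excludes the constant already carried by the model
    intercept.  Stored knots are reused out of sample; x values beyond the
    training boundaries are clamped to the boundary, so extrapolation is
    constant in the basis.
    """

    ORDER = 3  # cubic

    def __init__(self, df: int):
        if df < 3:
            raise ValueError("df must be >= 3")
        self.df = df
        self.knots_: np.ndarray | None = None
        self.bounds_: tuple[float, float] | None = None

    def fit(self, x) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if len(np.unique(x)) < self.df + 1:
            raise ValueError(
                f"need at least df+1={self.df + 1} distinct values, got {len(np.unique(x))}"
            )
        n_interior = self.df + 1 - (self.ORDER + 1)
        lo, hi = float(np.min(x)), float(np.max(x))
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
        else:
            interior = np.array([])
        t = np.concatenate([[lo] * (self.ORDER + 1), interior, [hi] * (self.ORDER + 1)])
        self.knots_ = t
        self.bounds_ = (lo, hi)
        return self

    def transform(self, x) -> np.ndarray:
        if self.knots_ is None:
            raise RuntimeError("basis not fitted")
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.bounds_[0], self.bounds_[1])
        dm = BSpline.design_matrix(xc, self.knots_, self.ORDER).toarray()
        return dm[:, 1:]  # drop first column for identifiability

    def fit_transform(self, x) -> np.ndarray:
        return self.fit(x).transform(x)


def spline_basis(x, df: int) -> np.ndarray:
    """Convenience: fit a cubic B-spline basis on ``x`` and return its columns."""
    return SplineBasis(df).fit_transform(x)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

class DesignBuilder:
    """Builds (and re-applies) the design matrix for a ModelSpec.

    Fitting records, per term, the artefacts needed to reproduce columns out
    of sample: spline knots for smooth terms and the level registry for
    categorical terms (reference-coded against the first training level).
    Out-of-sample rows carrying an unseen categorical level, or missing any
    required predictor, raise :class:`CoverageError`.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.splines_: dict[str, SplineBasis] = {}
        self.levels_: dict[str, list] = {}
        self.columns_: list[str] = []

    def fit(self, table: pd.DataFrame) -> "DesignBuilder":
        for term in self.spec.terms:
            if term.name not in table.columns:
                raise KeyError(f"predictor column {term.name!r} absent from table")
            col = table[term.name]
            if col.isna().any():
                raise ValueError(f"missing values in training predictor {term.name!r}")
            if term.encoding == "categorical":
                self.levels_[term.name] = sorted(pd.unique(col))
            elif term.form == "smooth":
                self.splines_[term.name] = SplineBasis(term.df).fit(
                    col.to_numpy(dtype=float)
                )
        self._set_columns(table)
        return self

    def _set_columns(self, table: pd.DataFrame) -> None:
        cols = ["intercept"]
        for term in self.spec.terms:
            if term.encoding == "categorical":
                cols += [f"{term.name}[{lv}]" for lv in self.levels_[term.name][1:]]
            elif term.form == "smooth":
                cols += [f"{term.name}.s{j + 1}" for j in range(term.df)]
            else:
                cols.append(term.name)
        self.columns_ = cols

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(table), 1))]
        for term in self.spec.terms:
            if term.name not in table.columns:
                raise CoverageError(f"missing predictor: {term.name}")
            col = table[term.name]
            if col.isna().any():
                raise CoverageError(f"missing predictor values: {term.name}")
            if term.encoding == "categorical":
                levels = self.levels_[term.name]
                unseen = set(pd.unique(col)) - set(levels)
                if unseen:
                    raise CoverageError(
                        f"unseen level(s) for {term.name}: {sorted(unseen)}"
                    )
                block = np.column_stack(
                    [(col == lv).to_numpy(dtype=float) for lv in levels[1:]]
                ) if len(levels) > 1 else np.empty((len(table), 0))
                blocks.append(block)
            elif term.form == "smooth":
                blocks.append(self.splines_[term.name].transform(col.to_numpy(dtype=float)))
            else:
                blocks.append(col.to_numpy(dtype=float)[:, None])
        return np.hstack(blocks)


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted GLM: spec, design artefacts, coefficients and fit statistics.

    AIC is -2*loglik + 2*k where k counts every estimated parameter: the
    regression coefficients, plus the residual variance for Gaussian models
    (whose log-likelihood is evaluated at the maximum-likelihood variance
    RSS/n).
    """

    spec: ModelSpec
    design: DesignBuilder
    params: pd.Series
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    aliased: tuple = ()  # columns dropped as linear combinations of earlier ones

    @property
    def required_columns(self) -> list[str]:
        return [t.name for t in self.spec.terms]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Per-child predicted probability (binomial) or mean (Gaussian)."""
        X = self.design.transform(table)
        eta = X @ self.params.to_numpy()
        if self.spec.family == BINOMIAL:
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "levels": self.design.levels_,
            "spline_knots": {
                k: list(map(float, v.knots_)) for k, v in self.design.splines_.items()
            },
        }


def _gaussian_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    n = len(y)
    sigma2 = float(np.sum((y - mu) ** 2) / n)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def _binomial_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_glm(table: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit a GLM to child-level rows.

    Binomial fits use iteratively reweighted least squares (relative
    convergence tolerance 1e-8, at most 100 iterations); Gaussian fits reduce
    to ordinary least squares.  Rows must be complete for every spec term and
    must outnumber the parameters.  Perfect separation or non-convergence is
    reported via ``converged=False`` with coefficients at the last iterate.
    """
    design = DesignBuilder(spec).fit(table)
    X = design.transform(table)
    y = pd.to_numeric(table[spec.outcome]).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values")
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")

    # drop (near-)aliased columns via pivoted QR, as R's glm does: without
    # this, a fold refit whose held-out stratum carried the only independent
    # variation of a column yields a singular design, enormous coefficients
    # and explosive out-of-sample predictions
    keep = np.arange(X.shape[1])
    aliased: tuple = ()
    R, piv = scipy_qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > diag[0] * 1e-10)) if diag[0] > 0 else 0
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        aliased = tuple(design.columns_[j] for j in sorted(piv[rank:]))
        X = X[:, keep]

    fam = sm.families.Binomial() if spec.family == BINOMIAL else sm.families.Gaussian()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam).fit(maxiter=100, tol=1e-8)
            converged = bool(getattr(res, "converged", True))
            beta_fit = np.asarray(res.params, dtype=float)
        except Exception:
            beta_fit = np.linalg.lstsq(X, y, rcond=None)[0]
            converged = False
    beta = np.zeros(len(design.columns_))
    beta[keep] = beta_fit
    params = pd.Series(beta, index=design.columns_)

    eta = X @ beta_fit
    if spec.family == BINOMIAL:
        llf = _binomial_loglik(y, 1.0 / (1.0 + np.exp(-eta)))
        k = X.shape[1]
    else:
        llf = _gaussian_loglik(y, eta)
        k = X.shape[1] + 1  # + residual variance
    aic = -2.0 * llf + 2.0 * k
    return FittedModel(spec, design, params, llf, aic, converged, len(y), aliased)


# ---------------------------------------------------------------------------
# Random forests
# ---------------------------------------------------------------------------

@dataclass
class ForestModel:
    """A fitted random forest plus the registries needed for safe prediction."""

    spec: ForestSpec
    outcome: str
    predictors: list[str]
    categorical_levels: dict[str, list]
    estimator: object

    @property
    def required_columns(self) -> list[str]:
        return list(self.predictors)

    def _encode(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.predictors:
            if name not in table.columns:
                raise CoverageError(f"missing predictor: {name}")
            col = table[name]
            if col.isna().any():
                raise CoverageError(f"missing predictor values: {name}")
            if name in self.categorical_levels:
                levels = self.categorical_levels[name]
                codes = pd.Categorical(col, categories=levels).codes
                if (codes < 0).any():
                    unseen = sorted(set(pd.unique(col)) - set(levels))
                    raise CoverageError(f"unseen level(s) for {name}: {unseen}")
                cols.append(codes.astype(float))
            else:
                cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Per-child class-1 probability (classification) or mean (regression)."""
        X = self._encode(table)
        if self.spec.task == "classification":
            proba = self.estimator.predict_proba(X)
            classes = list(self.estimator.classes_)
            if 1 in classes:
                return proba[:, classes.index(1)]
            return np.zeros(len(X))
        return self.estimator.predict(X)


def fit_forest(
    table: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    spec: ForestSpec,
    categorical: Iterable[str] = (),
) -> ForestModel:
    """Grow a random forest on child-level rows.

    Each of ``spec.n_trees`` trees is grown on a bootstrap resample; at each
    node at most ``spec.max_split_vars`` randomly chosen candidate variables
    are considered.  Binary predictions average per-tree class-1 leaf
    proportions; continuous predictions average per-tree means.  Categorical
    predictors are integer-coded against a training level registry, and
    prediction rows with unseen levels raise :class:`CoverageError`.
    """
    predictors = list(predictors)
    cat_levels = {
        name: sorted(pd.unique(table[name])) for name in categorical if name in predictors
    }
    model = ForestModel(spec, outcome, predictors, cat_levels, None)
    X = model._encode(table)
    y = pd.to_numeric(table[outcome]).to_numpy()
    max_feat = min(spec.max_split_vars, len(predictors))
    common = dict(
        n_estimators=spec.n_trees,
        max_features=max_feat,
        random_state=spec.seed,
        bootstrap=spec.bootstrap,
        n_jobs=1,
    )
    if spec.task == "classification":
        est = RandomForestClassifier(**common)
        est.fit(X, y.astype(int))
    else:
        est = RandomForestRegressor(**common)
        est.fit(X, y.astype(float))
    model.estimator = est
    return model


# ---------------------------------------------------------------------------
# Screening and selection
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Univariate-AIC screening output.

    ``table`` has one row per retained predictor with its chosen variant
    column and AIC, ranked ascending; ``variants`` records the AIC of every
    (predictor, variant) pair tried; ``excluded`` lists zero-variance
    predictors that were dropped.
    """

    table: pd.DataFrame
    variants: pd.DataFrame
    excluded: list

    @property
    def ranked_columns(self) -> list[str]:
        return list(self.table["column"])


def _term_for(column: str, categorical: set, form: str = "linear", df: int = 4) -> Term:
    if column in categorical:
        return Term(column, form="linear", encoding="categorical")
    return Term(column, form=form, df=df, encoding="continuous")


def univariate_screen(
    table: pd.DataFrame,
    outcome: str,
    family: str,
    candidates: Mapping[str, Sequence[str]],
    categorical: Iterable[str] = (),
) -> ScreeningResult:
    """Rank predictors by single-predictor model AIC.

    ``candidates`` maps a predictor name to its alternative columns (e.g. the
    3- and 6-month rolling-mean variants); one model is fitted per column and
    the lower-AIC variant is chosen per predictor.  Predictors are then
    ranked by chosen-variant AIC ascending, ties broken alphabetically by
    predictor name.  Zero-variance columns are excluded and recorded.
    """
    categorical = set(categorical)
    variant_rows, chosen_rows, excluded = [], [], []
    for pred in sorted(candidates):
        best = None
        for colname in candidates[pred]:
            col = table[colname]
            if col.nunique(dropna=True) < 2:
                excluded.append(colname)
                continue
            spec = ModelSpec(outcome, family, [_term_for(colname, categorical)])
            fitted = fit_glm(table, spec)
            variant_rows.append(
                {"predictor": pred, "column": colname, "aic": fitted.aic}
            )
            if best is None or fitted.aic < best["aic"]:
                best = {"predictor": pred, "column": colname, "aic": fitted.aic}
        if best is not None:
            chosen_rows.append(best)
    chosen = pd.DataFrame(chosen_rows)
    if not chosen.empty:
        chosen = chosen.sort_values(["aic", "predictor"]).reset_index(drop=True)
        chosen["rank"] = np.arange(1, len(chosen) + 1)
    return ScreeningResult(chosen, pd.DataFrame(variant_rows), excluded)


def correlation_screen(
    columns: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, set]:
    """Pairwise Spearman correlations and the set of blocked pairs.

    Correlations use complete pairs; a pair is blocked when |rho| >=
    ``threshold`` (default 0.8).  Returns (correlation matrix, set of
    frozenset pairs).  Categorical codes participate via their numeric codes.
    """
    if columns.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    num = columns.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    corr = num.corr(method="spearman")
    blocked = set()
    names = list(corr.columns)
    for i, a in enumerate(names):
        for b in names[i:]:
            rho = corr.loc[a, b]
            if pd.notna(rho) and abs(rho) >= threshold:
                blocked.add(frozenset((a, b)))
    return corr, blocked


def forward_select(
    screening: ScreeningResult,
    blocked_pairs: set,
    table: pd.DataFrame,
    outcome: str,
    family: str,
    categorical: Iterable[str] = (),
    smooth_dfs: Sequence[int] = (4, 6),
    smoothable: Iterable[str] | None = None,
    max_params: int | None = None,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Grow a multivariable spec by forward selection in univariate-AIC order.

    Predictors are tried from best to worst univariate AIC; a candidate
    blocked against an already-included predictor is skipped.  For continuous
    predictors both the linear form and cubic-spline smooth forms (df drawn
    from ``smooth_dfs``) are tried and the lowest-AIC form kept; the
    candidate is retained only if the model AIC strictly decreases.  Returns
    the selected spec and a full decision trace.

    ``max_params`` caps the design-matrix width (intercept included).  With
    predictors that vary only at the stratum-month level, child-level AIC
    keeps rewarding terms long after the model has begun interpolating the
    stratum cell means; callers should budget parameters against the number
    of distinct cells, not the number of children.
    """
    categorical = set(categorical)
    smoothable = set(smoothable) if smoothable is not None else None
    current_terms: list[Term] = []
    base = fit_glm(table, ModelSpec(outcome, family, []))
    current_aic = base.aic
    trace = []
    for _, row in screening.table.iterrows():
        colname = row["column"]
        clash = [
            t.name for t in current_terms if frozenset((t.name, colname)) in blocked_pairs
        ]
        if clash:
            trace.append(
                {"column": colname, "action": "skipped_blocked",
                 "against": ",".join(clash), "aic": np.nan}
            )
            continue
        forms: list[Term] = [_term_for(colname, categorical)]
        if colname not in categorical and (smoothable is None or colname in smoothable):
            # a smooth needs adequate covariate support: with predictors that
            # vary only at the stratum-month level, a basis with df close to
            # the number of distinct values interpolates the cell means and
            # predicts erratically out of sample
            distinct = int(table[colname].nunique(dropna=True))
            forms += [
                Term(colname, form="smooth", df=d)
                for d in smooth_dfs
                if distinct >= 4 * d
            ]
        best_term, best_aic = None, np.inf
        any_within_budget = False
        for cand in forms:
            try:
                fitted = fit_glm(
                    table, ModelSpec(outcome, family, current_terms + [cand])
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if max_params is not None and len(fitted.params) > max_params:
                continue
            any_within_budget = True
            if fitted.aic < best_aic:
                best_term, best_aic = cand, fitted.aic
        if max_params is not None and not any_within_budget:
            trace.append(
                {"column": colname, "action": "skipped_max_params",
                 "against": "", "aic": np.nan}
            )
            continue
        if best_term is not None and best_aic < current_aic:
            current_terms.append(best_term)
            current_aic = best_aic
            trace.append(
                {"column": colname, "action": f"added_{best_term.form}",
                 "against": "", "aic": best_aic}
            )
        else:
            trace.append(
                {"column": colname, "action": "rejected", "against": "",
                 "aic": best_aic if np.isfinite(best_aic) else np.nan}
            )
    return ModelSpec(outcome, family, current_terms), pd.DataFrame(trace)


def predict_stratum(model, rows: pd.DataFrame) -> float:
    """Stratum-level prediction: mean of per-child model predictions.

    Works for any model exposing ``predict(table) -> array``; raises
    :class:`CoverageError` when the rows are not covered by the trained model.
    """
    if len(rows) == 0:
        raise ValueError("empty stratum")
    return float(np.mean(model.predict(rows)))
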