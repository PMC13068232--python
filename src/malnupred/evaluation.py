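"""Stratum-fold leave-one-out cross-validation and the performance metric suite.

Each fold holds out one entire survey stratum; the model is refitted on the
remaining strata and predicts the held-out stratum's outcome (mean of
per-child predictions), which is compared with the stratum's observed
estimate.  Folds whose rows are not covered by the trained model — a missing
predictor series or a categorical level unseen in training — are excluded
with a recorded reason, reducing the metric denominators, as happens with
real survey strata whose predictor coverage is incomplete.

Metrics: signed mean bias (predicted - observed), mean absolute error,
within-bound proportions at configurable error bounds, and sensitivity at
crisis thresholds (the proportion of observed-beyond-threshold folds that the
model also predicts beyond the threshold; direction '>=' for prevalences,
'<=' for Z-score means).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import CoverageError, FittedModel, predict_stratum

__all__ = [
    "FoldResult",
    "MetricReport",
    "derive_fold_seed",
    "make_folds",
    "fold_coverage_check",
    "run_loocv",
    "compute_metrics",
    "diagnostics",
    "plot_predictions",
]


@dataclass
class FoldResult:
    """Held-out prediction vs observation for one survey stratum."""

    stratum_id: str
    outcome: str
    n_children: int
    predicted: float | None
    observed: float | None
    evaluable: bool
    reason: str = ""


@dataclass
class MetricReport:
    """Aggregate out-of-sample performance over evaluable folds."""

    outcome: str
    bias: float
    relative_bias: float
    mae: float
    within_bounds: dict  # bound -> (numerator, denominator)
    sensitivity: dict  # threshold -> (numerator, denominator) or None
    n_evaluable: int
    n_excluded: int
    exclusion_reasons: dict

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "bias": self.bias,
            "relative_bias": self.relative_bias,
            "mae": self.mae,
            "within_bounds": {
                str(b): {"num": n, "den": d} for b, (n, d) in self.within_bounds.items()
            },
            "sensitivity": {
                str(t): (None if v is None else {"num": v[0], "den": v[1]})
                for t, v in self.sensitivity.items()
            },
            "n_evaluable": self.n_evaluable,
            "n_excluded": self.n_excluded,
            "exclusion_reasons": dict(self.exclusion_reasons),
        }


def derive_fold_seed(master_seed: int, fold_id: str) -> int:
    """Stable per-fold seed from (master seed, fold id); < 2**31.

    Hash-derived so that fold execution order or parallelisation cannot
    change any fold's randomness.
    """
    h = hashlib.sha256(f"{master_seed}:{fold_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def make_folds(strata_ids: Sequence) -> list:
    """One leave-one-out fold per survey stratum (>= 2 strata required)."""
    ids = list(dict.fromkeys(strata_ids))  # preserve order, unique
    if len(ids) < 2:
        raise ValueError("need at least two strata for LOOCV")
    return ids


def fold_coverage_check(test_rows: pd.DataFrame, model) -> tuple[bool, str]:
    """Is the held-out stratum covered by the trained model?

    Non-evaluable when a required predictor is missing (column absent or NaN
    in the fold rows) or a categorical value is absent from the model's
    training registry.  Checked by attempting the model's own design
    transform, so the check and the prediction path cannot drift apart.
    """
    try:
        model.predict(test_rows)
    except CoverageError as e:
        return False, str(e)
    return True, ""


def run_loocv(
    builder: Callable[[pd.DataFrame, int], object],
    table: pd.DataFrame,
    outcome: str,
    stratum_col: str = "stratum_id",
    master_seed: int = 0,
) -> list[FoldResult]:
    """Stratum-fold LOOCV for any model builder.

    ``builder(train_rows, seed) -> model`` must return an object with a
    ``predict(rows) -> array`` method.  For each stratum: the model is fitted
    on all other strata's children, coverage-checked on the held-out rows,
    and its mean per-child prediction is paired with the stratum's observed
    child-level mean of ``outcome``.  Builder failures mark the fold
    non-evaluable with reason "fit failure" rather than aborting the run.
    """
    folds = make_folds(table[stratum_col])
    results: list[FoldResult] = []
    for fid in folds:
        test = table[table[stratum_col] == fid]
        train = table[table[stratum_col] != fid]
        observed = float(pd.to_numeric(test[outcome]).mean())
        seed = derive_fold_seed(master_seed, str(fid))
        try:
            model = builder(train, seed)
        except Exception as e:  # noqa: BLE001 - any builder failure is a fold outcome
            results.append(
                FoldResult(str(fid), outcome, len(test), None, None, False,
                           f"fit failure: {e}")
            )
            continue
        ok, reason = fold_coverage_check(test, model)
        if not ok:
            results.append(
                FoldResult(str(fid), outcome, len(test), None, None, False, reason)
            )
            continue
        pred = predict_stratum(model, test)
        results.append(
            FoldResult(str(fid), outcome, len(test), pred, observed, True)
        )
    return results


def compute_metrics(
    folds: Sequence[FoldResult],
    bounds: Sequence[float],
    thresholds: Sequence[float],
    threshold_direction: str = "ge",
) -> MetricReport:
    """Aggregate the metric suite over evaluable folds, all equally weighted.

    * bias = mean(predicted - observed); the relative variant divides by the
      mean prediction.
    * MAE = mean |predicted - observed|.
    * within-bound proportion at bound b = #{|predicted - observed| <= b} /
      n evaluable folds.
    * sensitivity at threshold T = #{observed beyond T and predicted beyond T}
      / #{observed beyond T}, with "beyond" meaning >= T when
      ``threshold_direction`` is "ge" (prevalences) and <= T when "le"
      (Z-score means).  An empty denominator yields None (undefined), not 0.
    """
    if threshold_direction not in ("ge", "le"):
        raise ValueError("threshold_direction must be 'ge' or 'le'")
    ev = [f for f in folds if f.evaluable]
    if not ev:
        raise ValueError("no evaluable folds")
    pred = np.array([f.predicted for f in ev], dtype=float)
    obs = np.array([f.observed for f in ev], dtype=float)
    diff = pred - obs
    bias = float(np.mean(diff))
    mean_pred = float(np.mean(pred))
    rel_bias = bias / mean_pred if mean_pred != 0 else float("nan")
    mae = float(np.mean(np.abs(diff)))

    within = {
        float(b): (int(np.sum(np.abs(diff) <= b)), len(ev)) for b in bounds
    }
    beyond = (lambda x, t: x >= t) if threshold_direction == "ge" else (lambda x, t: x <= t)
    sens: dict = {}
    for t in thresholds:
        obs_beyond = beyond(obs, t)
        den = int(np.sum(obs_beyond))
        if den == 0:
            sens[float(t)] = None
        else:
            num = int(np.sum(obs_beyond & beyond(pred, t)))
            sens[float(t)] = (num, den)

    excluded = [f for f in folds if not f.evaluable]
    reasons: dict = {}
    for f in excluded:
        key = f.reason.split(":")[0] if f.reason else "unknown"
        reasons[key] = reasons.get(key, 0) + 1
    outcome = ev[0].outcome
    return MetricReport(
        outcome, bias, rel_bias, mae, within, sens, len(ev), len(excluded), reasons
    )


def diagnostics(model: FittedModel, table: pd.DataFrame,
                max_normality_n: int = 500, seed: int = 0) -> dict:
    """Model diagnostics: multicollinearity and (Gaussian) residual normality.

    Variance inflation factors are computed per non-intercept design column
    (flagged at VIF > 10, with exactly collinear columns reported as
    infinite); Gaussian models additionally report residual skewness, excess
    kurtosis and a Shapiro-Wilk statistic on a subsample capped at
    ``max_normality_n``.
    """
    if not model.converged:
        raise ValueError("diagnostics require a converged model")
    X = model.design.transform(table)
    names = model.design.columns_
    vifs = {}
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, _, _, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        tss = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        rss = float(np.sum(resid**2))
        if tss == 0:
            vifs[names[j]] = float("inf")
        else:
            r2 = max(0.0, 1.0 - rss / tss)
            vifs[names[j]] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    report = {
        "vif": vifs,
        "vif_flagged": sorted(k for k, v in vifs.items() if v > 10),
    }
    if model.spec.family == "gaussian":
        y = pd.to_numeric(table[model.spec.outcome]).to_numpy(dtype=float)
        resid = y - model.predict(table)
        rng = np.random.default_rng(seed)
        sample = (
            rng.choice(resid, size=max_normality_n, replace=False)
            if len(resid) > max_normality_n
            else resid
        )
        w, p = stats.shapiro(sample)
        report["residual_skewness"] = float(stats.skew(resid))
        report["residual_excess_kurtosis"] = float(stats.kurtosis(resid))
        report["shapiro_w"] = float(w)
        report["shapiro_p"] = float(p)
        report["normality_flagged"] = bool(p < 0.01)
    return report


def plot_predictions(
    folds: Sequence[FoldResult],
    bounds: Sequence[float],
    thresholds: Sequence[float],
    title: str = "",
    ax=None,
):
    """Predicted-vs-observed panel: 45-degree line, shaded error bounds and
    threshold lines, dot area proportional to the stratum's child count."""
    import matplotlib.pyplot as plt

    ev = [f for f in folds if f.evaluable]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    obs = np.array([f.observed for f in ev])
    pred = np.array([f.predicted for f in ev])
    n = np.array([f.n_children for f in ev], dtype=float)
    lo = min(obs.min(), pred.min())
    hi = max(obs.max(), pred.max())
    pad = 0.05 * (hi - lo) if hi > lo else 0.05
    lo, hi = lo - pad, hi + pad
    line = np.linspace(lo, hi, 2)
    for b in sorted(bounds, reverse=True):
        ax.fill_between(line, line - b, line + b, alpha=0.15, color="grey")
    ax.plot(line, line, color="black", lw=1)
    for t in thresholds:
        ax.axvline(t, color="firebrick", ls=":", lw=0.8)
        ax.axhline(t, color="firebrick", ls=":", lw=0.8)
    ax.scatter(obs, pred, s=10 + 90 * n / n.max(), alpha=0.7, edgecolor="k", lw=0.3)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel("observed")
    ax.set_ylabel("predicted")
    if title:
        ax.set_title(title)
    return ax
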