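"""End-to-end orchestration: simulate -> clean -> features -> screen -> select
-> crossval -> report.

Each stage reads its inputs from, and writes its outputs to, the run's output
directory, so stages are idempotent and a run can resume from written
intermediates.  A manifest recording the configuration hash, per-stage row
counts and seeds is written at the end of a full run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import anthropometry as anth
from . import evaluation as ev
from . import modeling as mdl
from . import predictors as pred
from . import synthetic_data as syn

__all__ = [
    "RunConfig",
    "OUTCOMES",
    "DEFAULT_BOUNDS",
    "DEFAULT_THRESHOLDS",
    "build_features",
    "validate_inputs",
    "run_all",
    "stage_simulate",
    "stage_clean",
    "stage_features",
    "stage_screen",
    "stage_select",
    "stage_crossval",
    "stage_report",
]

#: outcome name -> (analysis-table column, GLM family, threshold direction)
OUTCOMES = {
    "gam": ("gam", mdl.BINOMIAL, "ge"),
    "sam": ("sam", mdl.BINOMIAL, "ge"),
    "whz": ("whz", mdl.GAUSSIAN, "le"),
    "muacz": ("muacz", mdl.GAUSSIAN, "le"),
}

#: default error bounds per outcome (outcome units)
DEFAULT_BOUNDS = {
    "gam": (0.02, 0.05),
    "sam": (0.01, 0.02),
    "whz": (0.10, 0.25),
    "muacz": (0.10, 0.25),
}

#: default crisis thresholds per outcome ('>=' for prevalences, '<=' for Z means)
DEFAULT_THRESHOLDS = {
    "gam": (0.15, 0.20),
    "sam": (0.02, 0.05),
    "whz": (-1.0, -1.25),
    "muacz": (-1.0, -1.25),
}

#: time-varying engineered predictors that receive 3- and 6-month rolling means
TIME_VARYING = (
    "spi",
    "ndvi",
    "price_real",
    "mam_rate",
    "sam_rate",
    "insecurity_rate",
    "cholera_rate",
    "measles_rate",
    "mmr1_rate",
    "penta3_rate",
)
STATIC = ("safe_births", "literacy", "school_attendance")


@dataclass
class RunConfig:
    """Declarative configuration of a full run (see docs/methods.md)."""

    outdir: str = "run_output"
    seed: int = 0
    # synthetic study size
    n_counties: int = 3
    subcounties_per_county: int = 3
    scenario: dict = field(default_factory=dict)  # ScenarioConfig overrides
    # analysis settings
    outcomes: tuple = ("gam", "sam", "whz", "muacz")
    correlation_threshold: float = 0.8
    smooth_dfs: tuple = (4, 6)
    forest_trees: int = 1000
    forest_max_split: int = 5
    bounds: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    rate_scale: float = 1000.0
    epidemic_rate_scale: float = 100000.0
    zero_category_threshold: float = 0.10

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def scenario_config(self) -> syn.ScenarioConfig:
        return syn.ScenarioConfig(**{"seed": self.seed, **self.scenario})

    def bounds_for(self, outcome: str):
        return tuple(self.bounds.get(outcome, DEFAULT_BOUNDS[outcome]))

    def thresholds_for(self, outcome: str):
        return tuple(self.thresholds.get(outcome, DEFAULT_THRESHOLDS[outcome]))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def path(self) -> Path:
        return Path(self.outdir)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

CHILD_SCHEMA = ("cluster", "child_id", "age_value", "age_unit", "sex", "weight",
                "height", "oedema", "muac", "subcounty", "survey_month", "stratum_id")
PREDICTOR_SCHEMA = ("predictor", "unit_level", "unit_id", "month", "value")
POPULATION_SCHEMA = ("subcounty", "year", "population")


@dataclass
class ValidationReport:
    hard_failures: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.hard_failures


def validate_inputs(data_dir) -> ValidationReport:
    """Schema checks on an input bundle: hard failures vs warnings.

    Missing minimal child variables or predictor columns are hard failures;
    monthly gaps in predictor series are warnings (rolling means tolerate
    minor missingness).
    """
    data_dir = Path(data_dir)
    rep = ValidationReport()
    for fname, schema in (
        ("children.csv", CHILD_SCHEMA),
        ("predictors.csv", PREDICTOR_SCHEMA),
        ("population.csv", POPULATION_SCHEMA),
    ):
        path = data_dir / fname
        if not path.exists():
            rep.hard_failures.append(f"{fname}: file missing")
            continue
        try:
            df = pd.read_csv(path, nrows=500000)
        except Exception as e:  # unreadable file
            rep.hard_failures.append(f"{fname}: unreadable ({e})")
            continue
        missing = set(schema) - set(df.columns)
        if missing:
            rep.hard_failures.append(f"{fname}: missing columns {sorted(missing)}")
            continue
        if fname == "predictors.csv":
            for (name, unit), grp in df.groupby(["predictor", "unit_id"]):
                months = pd.PeriodIndex(grp["month"], freq="M").sort_values()
                if len(months) > 1:
                    span = (months[-1] - months[0]).n + 1
                    if span != len(months):
                        rep.warnings.append(
                            f"predictor {name}/{unit}: {span - len(months)} month gap(s)"
                        )
                        break
    return rep


# ---------------------------------------------------------------------------
# Feature engineering
# ---------------------------------------------------------------------------

def build_features(
    predictors_long: pd.DataFrame,
    population_annual: pd.DataFrame,
    geography: pd.DataFrame,
    deflator: Mapping[int, float],
    study_months: pd.PeriodIndex,
    rate_scale: float = 1000.0,
    epidemic_rate_scale: float = 100000.0,
    zero_category_threshold: float = 0.10,
) -> dict:
    """Transform raw long-format series into the model-ready feature tables.

    Returns a dict with wide ``subcounty`` and ``county`` feature tables (one
    row per unit-month with ``<name>__roll3`` / ``__roll6`` columns for
    time-varying predictors), the candidate map for screening, the set of
    categorical columns, the fitted quintile encoders, and a transform audit
    log.
    """
    sc2c = dict(zip(geography["subcounty"], geography["county"]))
    audit = []

    pop_monthly = {}
    for sid, grp in population_annual.groupby("subcounty"):
        pop_monthly[sid] = pred.interpolate_population(
            list(zip(grp["year"], grp["population"]))
        )
    county_pop = {}
    for county in sorted(set(sc2c.values())):
        members = [s for s, c in sc2c.items() if c == county]
        county_pop[county] = sum(pop_monthly[s] for s in members)

    def series_of(name, unit):
        sub = predictors_long[
            (predictors_long["predictor"] == name)
            & (predictors_long["unit_id"] == unit)
        ]
        s = pd.Series(
            sub["value"].to_numpy(dtype=float),
            index=pd.PeriodIndex(sub["month"], freq="M"),
        ).sort_index()
        return s

    sub_units = sorted(geography["subcounty"])
    county_units = sorted(set(sc2c.values()))

    raw: dict[tuple[str, str], pd.Series] = {}
    for sid in sub_units:
        rain = series_of("rainfall", sid)
        raw[("spi", sid)] = pred.compute_spi(rain, accumulation=1)
        audit.append(f"spi/{sid}: gamma-fit SPI on {len(rain)} months of rainfall")
        raw[("ndvi", sid)] = series_of("ndvi", sid)
        price = series_of("price", sid)
        real = pred.deflate_price(price, deflator)
        raw[("price_real", sid)] = pred.smooth_price(real)
        audit.append(f"price_real/{sid}: deflated to 2015 KES, running-median smoothed")
        pop = pop_monthly[sid]
        raw[("mam_rate", sid)] = pred.per_capita_rate(
            series_of("mam_admissions", sid), pop, rate_scale)
        raw[("sam_rate", sid)] = pred.per_capita_rate(
            series_of("sam_admissions", sid), pop, rate_scale)
        raw[("insecurity_rate", sid)] = pred.per_capita_rate(
            series_of("insecurity_events", sid), pop, rate_scale)
        raw[("safe_births", sid)] = series_of("safe_births", sid)
        raw[("literacy", sid)] = series_of("literacy", sid)
    for county in county_units:
        cpop = county_pop[county]
        raw[("cholera_rate", county)] = pred.per_capita_rate(
            series_of("cholera_cases", county), cpop, epidemic_rate_scale)
        raw[("measles_rate", county)] = pred.per_capita_rate(
            series_of("measles_cases", county), cpop, epidemic_rate_scale)
        raw[("mmr1_rate", county)] = pred.per_capita_rate(
            series_of("mmr1_doses", county), cpop, rate_scale)
        raw[("penta3_rate", county)] = pred.per_capita_rate(
            series_of("penta3_doses", county), cpop, rate_scale)
        raw[("school_attendance", county)] = series_of("school_attendance", county)

    def assemble(units, names, unit_col):
        frames = []
        for unit in units:
            cols = {unit_col: unit}
            df = pd.DataFrame(index=study_months)
            for name in names:
                s = raw[(name, unit)]
                if name in TIME_VARYING:
                    for w in (3, 6):
                        df[f"{name}__roll{w}"] = pred.rolling_mean(s, w).reindex(
                            study_months
                        )
                else:
                    df[name] = s.reindex(study_months)
            df.insert(0, unit_col, unit)
            df.insert(1, "month", [str(m) for m in study_months])
            frames.append(df.reset_index(drop=True))
        return pd.concat(frames, ignore_index=True)

    sub_names = ("spi", "ndvi", "price_real", "mam_rate", "sam_rate",
                 "insecurity_rate", "safe_births", "literacy")
    cty_names = ("cholera_rate", "measles_rate", "mmr1_rate", "penta3_rate",
                 "school_attendance")
    sub_feat = assemble(sub_units, sub_names, "subcounty")
    cty_feat = assemble(county_units, cty_names, "county")

    # quintile-encode the zero-heavy epidemic rates (zero category + quintiles)
    encoders = {}
    categorical = []
    for base in ("cholera_rate", "measles_rate"):
        for w in (3, 6):
            col = f"{base}__roll{w}"
            enc = pred.QuintileEncoder(zero_category_threshold=zero_category_threshold)
            cty_feat[f"{base}_cat__roll{w}"] = enc.fit_transform(cty_feat[col])
            encoders[f"{base}_cat__roll{w}"] = enc
            categorical.append(f"{base}_cat__roll{w}")
            audit.append(
                f"{base}_cat__roll{w}: quintile-encoded, {enc.n_categories} categories"
                f"{' incl. zero' if enc.has_zero_category else ''}"
            )

    candidates = {}
    for name in ("spi", "ndvi", "price_real", "mam_rate", "sam_rate",
                 "insecurity_rate", "mmr1_rate", "penta3_rate"):
        candidates[name] = [f"{name}__roll3", f"{name}__roll6"]
    for base in ("cholera_rate", "measles_rate"):
        candidates[f"{base}_cat"] = [f"{base}_cat__roll3", f"{base}_cat__roll6"]
    for name in STATIC:
        candidates[name] = [name]

    return {
        "subcounty": sub_feat,
        "county": cty_feat,
        "candidates": candidates,
        "categorical": categorical,
        "encoders": encoders,
        "audit": audit,
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _datadir(cfg: RunConfig) -> Path:
    return cfg.path / "data"


def stage_simulate(cfg: RunConfig) -> dict:
    """Generate and write the synthetic study bundle."""
    scenario = cfg.scenario_config()
    region = syn.generate_geography(cfg.n_counties, cfg.subcounties_per_county, cfg.seed)
    ref = syn.synthetic_lms_reference()
    predictors_long = syn.generate_predictors(region, scenario)
    population = syn.generate_population(region, scenario)
    surface = syn.build_true_surface(region, predictors_long, scenario)
    children, calendar = syn.generate_surveys(region, surface, scenario, ref)
    manifest = syn.write_bundle(
        _datadir(cfg), region, scenario, predictors_long, population, children,
        calendar, ref,
    )
    deflator = syn.synthetic_deflator(scenario)
    (_datadir(cfg) / "deflator.json").write_text(json.dumps(deflator))
    surface.table.reset_index().to_csv(_datadir(cfg) / "true_surface.csv", index=False)
    return {"stage": "simulate", **manifest}


def stage_clean(cfg: RunConfig) -> dict:
    """Score and clean the child table; write cleaned records and attrition."""
    d = _datadir(cfg)
    children = pd.read_csv(d / "children.csv")
    ref = anth.LMSReference.read_csv(d / "lms_reference.csv")
    geo = pd.read_csv(d / "geography.csv")
    clean = anth.clean_table(children, ref, known_subcounties=geo["subcounty"])
    clean.to_csv(cfg.path / "cleaned.csv", index=False)
    attr = anth.attrition_summary(clean)
    attr.to_csv(cfg.path / "attrition.csv", index=False)
    n_elig = int((clean["exclusion"] == anth.EXCLUSION_NONE).sum())
    return {
        "stage": "clean",
        "records_in": int(len(children)),
        "eligible": n_elig,
        "excluded": int(len(children) - n_elig),
    }


def stage_features(cfg: RunConfig) -> dict:
    """Engineer predictors and link eligible children to them."""
    d = _datadir(cfg)
    scenario = cfg.scenario_config()
    predictors_long = pd.read_csv(d / "predictors.csv")
    population = pd.read_csv(d / "population.csv")
    geo = pd.read_csv(d / "geography.csv")
    deflator = {int(k): v for k, v in json.loads((d / "deflator.json").read_text()).items()}
    feats = build_features(
        predictors_long, population, geo, deflator, scenario.months(),
        rate_scale=cfg.rate_scale, epidemic_rate_scale=cfg.epidemic_rate_scale,
        zero_category_threshold=cfg.zero_category_threshold,
    )
    clean = pd.read_csv(cfg.path / "cleaned.csv")
    eligible = clean[clean["exclusion"] == anth.EXCLUSION_NONE].copy()
    for col in ("gam", "sam"):
        eligible[col] = eligible[col].astype(bool).astype(int)
    analysis = pred.link_children(
        eligible, feats["subcounty"], feats["county"],
        dict(zip(geo["subcounty"], geo["county"])),
    )
    analysis.to_csv(cfg.path / "analysis.csv", index=False)
    meta = {
        "candidates": feats["candidates"],
        "categorical": feats["categorical"],
        "audit": feats["audit"],
    }
    (cfg.path / "features_meta.json").write_text(json.dumps(meta, indent=2))
    return {
        "stage": "features",
        "rows": int(len(analysis)),
        "complete_rows": int(analysis["complete_predictors"].sum()),
    }


def _load_analysis(cfg: RunConfig):
    analysis = pd.read_csv(cfg.path / "analysis.csv")
    meta = json.loads((cfg.path / "features_meta.json").read_text())
    return analysis, meta


def stage_screen(cfg: RunConfig) -> dict:
    """Univariate AIC screening per outcome, choosing rolling windows."""
    analysis, meta = _load_analysis(cfg)
    complete = analysis[analysis["complete_predictors"]]
    counts = {}
    for outcome in cfg.outcomes:
        col, family, _ = OUTCOMES[outcome]
        scr = mdl.univariate_screen(
            complete, col, family, meta["candidates"], categorical=meta["categorical"]
        )
        scr.table.to_csv(cfg.path / f"screening_{outcome}.csv", index=False)
        scr.variants.to_csv(cfg.path / f"screening_{outcome}_variants.csv", index=False)
        counts[outcome] = int(len(scr.table))
    return {"stage": "screen", "ranked": counts}


def stage_select(cfg: RunConfig) -> dict:
    """Correlation blocking + forward selection per outcome."""
    analysis, meta = _load_analysis(cfg)
    complete = analysis[analysis["complete_predictors"]]
    selected = {}
    for outcome in cfg.outcomes:
        col, family, _ = OUTCOMES[outcome]
        table = pd.read_csv(cfg.path / f"screening_{outcome}.csv")
        scr = mdl.ScreeningResult(table, pd.DataFrame(), [])
        _, blocked = mdl.correlation_screen(
            complete[scr.ranked_columns], threshold=cfg.correlation_threshold
        )
        # budget parameters against stratum cells, not children: predictors
        # only vary at the stratum-month level
        n_cells = int(complete["stratum_id"].nunique())
        spec, trace = mdl.forward_select(
            scr, blocked, complete, col, family,
            categorical=meta["categorical"], smooth_dfs=cfg.smooth_dfs,
            max_params=max(4, n_cells // 3),
        )
        (cfg.path / f"model_spec_{outcome}.json").write_text(
            json.dumps(spec.to_dict(), indent=2)
        )
        trace.to_csv(cfg.path / f"selection_trace_{outcome}.csv", index=False)
        selected[outcome] = [t.name for t in spec.terms]
    return {"stage": "select", "selected": selected}


def _glm_builder(spec: mdl.ModelSpec):
    def build(train: pd.DataFrame, seed: int):
        train = train[train["complete_predictors"]]
        return mdl.fit_glm(train, spec)

    return build


def _forest_builder(outcome_col: str, columns: list, categorical: list,
                    cfg: RunConfig, task: str):
    def build(train: pd.DataFrame, seed: int):
        train = train[train["complete_predictors"]]
        fspec = mdl.ForestSpec(
            n_trees=cfg.forest_trees, max_split_vars=cfg.forest_max_split,
            task=task, seed=seed,
        )
        cats = [c for c in columns if c in categorical]
        return mdl.fit_forest(train, outcome_col, columns, fspec, categorical=cats)

    return build


def stage_crossval(cfg: RunConfig) -> dict:
    """Stratum-fold LOOCV for the selected GLM and a random forest, per outcome."""
    analysis, meta = _load_analysis(cfg)
    report = {}
    for outcome in cfg.outcomes:
        col, family, direction = OUTCOMES[outcome]
        spec = mdl.ModelSpec.from_dict(
            json.loads((cfg.path / f"model_spec_{outcome}.json").read_text())
        )
        screening = pd.read_csv(cfg.path / f"screening_{outcome}.csv")
        forest_cols = list(screening["column"])
        task = "classification" if family == mdl.BINOMIAL else "regression"
        builders = {
            "glm": _glm_builder(spec),
            "forest": _forest_builder(col, forest_cols, meta["categorical"], cfg, task),
        }
        report[outcome] = {}
        for label, builder in builders.items():
            folds = ev.run_loocv(builder, analysis, col, master_seed=cfg.seed)
            pd.DataFrame([vars(f) for f in folds]).to_csv(
                cfg.path / f"folds_{outcome}_{label}.csv", index=False
            )
            metrics = ev.compute_metrics(
                folds, cfg.bounds_for(outcome), cfg.thresholds_for(outcome),
                threshold_direction=direction,
            )
            report[outcome][label] = metrics.to_dict()
    (cfg.path / "metrics.json").write_text(json.dumps(report, indent=2))
    return {"stage": "crossval", "outcomes": list(report)}


def stage_report(cfg: RunConfig, make_plots: bool = True) -> dict:
    """Bundle metrics side by side, render panels, write the run manifest."""
    metrics = json.loads((cfg.path / "metrics.json").read_text())
    rows = []
    for outcome, by_model in metrics.items():
        for label, m in by_model.items():
            rows.append(
                {
                    "outcome": outcome,
                    "model": label,
                    "bias": m["bias"],
                    "mae": m["mae"],
                    "n_evaluable": m["n_evaluable"],
                    "n_excluded": m["n_excluded"],
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(cfg.path / "performance_summary.csv", index=False)
    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for outcome in cfg.outcomes:
            for label in ("glm", "forest"):
                fpath = cfg.path / f"folds_{outcome}_{label}.csv"
                if not fpath.exists():
                    continue
                df = pd.read_csv(fpath)
                folds = [ev.FoldResult(**r) for r in df.to_dict("records")]
                if not any(f.evaluable for f in folds):
                    continue
                ax = ev.plot_predictions(
                    folds, cfg.bounds_for(outcome), cfg.thresholds_for(outcome),
                    title=f"{outcome} ({label})",
                )
                ax.figure.savefig(cfg.path / f"pred_vs_obs_{outcome}_{label}.png",
                                  dpi=100)
                plt.close(ax.figure)
    return {"stage": "report", "rows": int(len(summary))}


STAGES = (
    stage_simulate,
    stage_clean,
    stage_features,
    stage_screen,
    stage_select,
    stage_crossval,
    stage_report,
)


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages in order and write the run manifest.

    Any stage failure aborts with the failing stage named; outputs written by
    earlier stages are preserved on disk.
    """
    cfg.path.mkdir(parents=True, exist_ok=True)
    stage_logs = []
    for stage in STAGES:
        try:
            stage_logs.append(stage(cfg))
        except Exception as e:
            raise RuntimeError(f"stage {stage.__name__} failed: {e}") from e
    manifest = {
        "config_hash": cfg.hash(),
        "version": _version(),
        "seed": cfg.seed,
        "stages": stage_logs,
        "outputs": sorted(p.name for p in cfg.path.iterdir() if p.is_file()),
    }
    tmp = cfg.path / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(cfg.path / "manifest.json")  # atomic finalisation
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
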