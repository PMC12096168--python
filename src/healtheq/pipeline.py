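"""Five-stage analysis pipeline behind one configuration object:

  1. data      — load a survey file or simulate one; clean; derive
                 within-province income quintiles;
  2. univariate — chi-square screen of every candidate factor (factors
                 failing the screen are excluded from the forest stage);
  3. importance — bagged-tree OOB permutation importance (optional
                 randomized hyperparameter search first);
  4. selection — L1-penalized logistic path over the screened factors'
                 dummies with k-fold CV (the forest ranks importance but
                 does not gate the selection, matching the published flow
                 in which every screened factor enters the penalized model);
  5. model + equity — unpenalized logit on the selected factors, odds
                 ratios, average marginal effects, concentration index
                 and Wagstaff decomposition over household-income ranks.

Every stage is a pure function of (input data, config, seed); a fixed
seed gives byte-identical report JSONs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import codebook as cb
from .data_model import (CleaningRules, SurveyTable, assign_income_quintiles,
                         clean, dummy_encode, load_survey)
from .equity import concentration_index, fractional_rank, wagstaff_decompose
from .lasso_select import cv_select, selected_factors
from .logit_model import fit_logit, odds_ratio_table
from .rf_importance import ForestConfig, fit_forest, oob_importance, random_search
from .synthetic import GeneratorConfig, generate
from .univariate import chi2_screen, summary_frame

log = logging.getLogger("healtheq")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "validate_report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full pipeline configuration; ``seed`` feeds every stochastic stage."""

    input_path: str | None = None
    simulate: GeneratorConfig | None = None
    factors: list[str] = field(default_factory=lambda: list(cb.FACTORS))
    chi2_alpha: float = 0.05
    forest: ForestConfig = field(default_factory=lambda: ForestConfig(
        n_estimators=100, max_depth=10))
    search_iters: int = 0          # 0 = use `forest` as-is, no search
    search_folds: int = 5
    lasso_folds: int = 10
    lasso_n_lambdas: int = 50
    lasso_rule: str = "min"        # "min" | "1se"
    rank_income: str = "household"  # income variable feeding the equity ranks
    cleaning: CleaningRules = field(default_factory=CleaningRules)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.input_path is None and self.simulate is None:
            self.simulate = GeneratorConfig(n=20_000, seed=self.seed,
                                            income_education_shift=0.25)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = GeneratorConfig(**d["simulate"])
        if d.get("forest") is not None and not isinstance(d["forest"], ForestConfig):
            d["forest"] = ForestConfig(**d["forest"])
        if d.get("cleaning") is not None and not isinstance(d["cleaning"], CleaningRules):
            d["cleaning"] = CleaningRules(**d["cleaning"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ReportBundle:
    """All stage outputs plus the machine-readable report dictionary."""

    table: SurveyTable
    univariate: object
    screen_kept: list[str]
    importance: object
    search: object
    cv: object
    selected: list[str]
    fit: object
    or_table: object
    decomposition: object
    concentration: object
    report: dict
    timings: dict[str, float]


def _report_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the five stages in order and assemble the report bundle.

    On a stage failure, artifacts of completed stages are still written
    (when ``cfg.outdir`` is set) and a :class:`StageError` naming the
    stage is raised.
    """
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    # outdir is where the run lands, not what it computes: keep it out of
    # the report so identical seeds give byte-identical reports
    cfg_dict = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    report: dict = {"seed": cfg.seed, "config": cfg_dict}
    artifacts: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as e:  # persist partial outputs, then abort
                if outdir:
                    _write_artifacts(outdir, artifacts, report)
                log.error("stage %s failed: %s", name, e)
                raise StageError(name, e) from e
            timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, timings[name])
            return out
        return deco

    # -- stage 1: data -----------------------------------------------------
    def _data():
        if cfg.input_path:
            t = load_survey(cfg.input_path)
        else:
            t, truth = generate(cfg.simulate)
            report["generator_beta0"] = truth.beta0
        t, cleaning_report = clean(t, cfg.cleaning)
        t = assign_income_quintiles(t)
        report["n"] = t.n
        report["cleaning"] = cleaning_report
        report["outcome_rate"] = float(t.df[cb.OUTCOME].mean())
        return t
    table = stage("data")(_data)

    # -- stage 2: univariate screen ---------------------------------------
    def _univariate():
        kept, frame = chi2_screen(table, cfg.factors, cfg.chi2_alpha)
        artifacts["univariate"] = summary_frame(table, cfg.factors)
        report["chi2_screen"] = {
            r["factor"]: {"statistic": r["statistic"], "df": int(r["df"]),
                          "p": r["p_value"], "kept": bool(r["kept"])}
            for r in frame.to_dict("records")}
        report["screen_kept"] = kept
        return kept, frame
    screen_kept, uni_frame = stage("univariate")(_univariate)

    # -- stage 3: forest importance ---------------------------------------
    def _importance():
        Xint = table.df[screen_kept]
        y = table.df[cb.OUTCOME].to_numpy()
        search = None
        fcfg = cfg.forest
        if cfg.search_iters > 0:
            search = random_search(Xint, y, n_iter=cfg.search_iters,
                                   k_folds=cfg.search_folds, seed=cfg.seed)
            fcfg = dataclasses.replace(
                search.best_config, mode=cfg.forest.mode, seed=cfg.seed)
            report["search_best_score"] = search.best_score
        forest = fit_forest(Xint, y, dataclasses.replace(fcfg, seed=cfg.seed))
        imp = oob_importance(forest, Xint, y, seed=cfg.seed)
        artifacts["importance"] = imp.frame()
        report["importance_ranking"] = imp.ranking
        report["oob_store"] = imp.oob_store
        return imp, search
    importance, search = stage("importance")(_importance)

    # -- stage 4: penalized selection --------------------------------------
    def _select():
        X = dummy_encode(table, screen_kept,
                         {f: cb.REFERENCE_LEVELS[f] for f in screen_kept})
        y = table.df[cb.OUTCOME].to_numpy()
        cv = cv_select(X, y, k=cfg.lasso_folds, seed=cfg.seed,
                       n_lambdas=cfg.lasso_n_lambdas)
        lam = cv.lambda_min if cfg.lasso_rule == "min" else cv.lambda_1se
        sel = selected_factors(cv.path, lam, X.factor_of_column)
        artifacts["cv_curve"] = _cv_frame(cv)
        report["lambda_min"] = cv.lambda_min
        report["lambda_1se"] = cv.lambda_1se
        report["selected_factors"] = sel
        return cv, sel
    cv, selected = stage("select")(_select)

    # -- stage 5: logit + equity -------------------------------------------
    def _model_equity():
        model_factors = [f for f in cb.MODEL_FACTORS if f in selected]
        model_factors += [f for f in selected if f not in model_factors]
        X = dummy_encode(table, model_factors,
                         {f: cb.REFERENCE_LEVELS[f] for f in model_factors})
        y = table.df[cb.OUTCOME].to_numpy()
        fit = fit_logit(X, y)
        ortab = odds_ratio_table(fit, X)
        artifacts["odds_ratios"] = ortab
        ranks = fractional_rank(table.df[cb.INCOME_RAW].to_numpy())
        conc = concentration_index(y.astype(float), ranks)
        decomp = wagstaff_decompose(fit, X, ranks, y)
        artifacts["decomposition"] = decomp.table
        report["logit"] = {name: {"beta": float(b), "se": float(s),
                                  "or": float(o), "p": float(p)}
                           for name, b, s, o, p in zip(
                               fit.column_names, fit.beta, fit.se,
                               fit.or_, fit.pvalues)}
        report["concentration_index"] = conc.ci
        report["outcome_mean"] = conc.mu
        report["direction"] = conc.direction
        report["residual_term"] = decomp.residual_term
        report["decomposition_identity_gap"] = float(
            decomp.total_ci - (decomp.explained() + decomp.residual_term))
        return fit, ortab, conc, decomp
    fit, ortab, conc, decomp = stage("model_equity")(_model_equity)

    if outdir:
        _write_artifacts(outdir, artifacts, report)
        with open(outdir / "run.log", "w") as fh:
            fh.write(f"seed={cfg.seed}\n")
            import sklearn, statsmodels, scipy, numpy as _np
            fh.write(f"versions: numpy={_np.__version__} scipy={scipy.__version__} "
                     f"sklearn={sklearn.__version__} statsmodels={statsmodels.__version__}\n")
            for k, v in timings.items():
                fh.write(f"stage {k}: {v:.3f}s\n")

    return ReportBundle(table=table, univariate=uni_frame,
                        screen_kept=screen_kept, importance=importance,
                        search=search, cv=cv, selected=selected, fit=fit,
                        or_table=ortab, decomposition=decomp,
                        concentration=conc, report=report, timings=timings)


def _cv_frame(cv):
    import pandas as pd
    return pd.DataFrame({"lambda": cv.lambdas, "cv_mean": cv.cv_mean,
                         "cv_se": cv.cv_se})


def _write_artifacts(outdir: Path, artifacts: dict, report: dict) -> None:
    for name, frame in artifacts.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        fh.write(_report_json(report))


# -- report schema ----------------------------------------------------------

_TYPES = {"int": int, "float": float, "str": str, "list": list, "dict": dict}


def _load_schema() -> dict:
    from importlib import resources
    with resources.files("healtheq").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Check the report dictionary against the shipped report_schema.json."""
    schema = _load_schema()
    required = set(schema["required"])
    props = schema["properties"]
    for key in required:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for key, value in report.items():
        if key not in props:
            raise ValueError(f"unknown report key {key!r}")
        expected = _TYPES[props[key]["type"]]
        if not isinstance(value, expected):
            raise ValueError(f"report key {key!r} has type "
                             f"{type(value).__name__}, expected {expected.__name__}")
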