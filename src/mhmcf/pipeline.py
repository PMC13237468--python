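"""End-to-end orchestration: simulate/load -> prepare -> estimate -> report.

``run_all`` executes the whole analysis and writes CSV report tables
(probit marginal effects, count-model IRR table), a machine-readable
``results.json`` (stable, versioned schema) and a JSON-lines log to the
output directory.  Reruns with an identical configuration produce an
identical ``results.json``.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_REFERENCE_LEVELS, RunConfig
from .design import ModelRoles
from .diagnostics import run_diagnostics
from .outcomes import BootstrapConfig, endogeneity_test, fit_cf_2sri, fit_poisson
from .placebo import run_placebo, run_subsample
from .prep import prepare_table
from .probit import marginal_effects
from .synthetic import simulate, split_visible

__all__ = ["default_roles", "summarize", "run_all", "RESULTS_SCHEMA_VERSION"]

RESULTS_SCHEMA_VERSION = 1

logger = logging.getLogger("mhmcf")

DEFAULT_EXOGENOUS = [
    "age_c", "education", "residence", "wealth", "media_any",
    "no_contraception", "nicotine_or_alcohol", "head_female", "head_age_c",
    "head_education", "region", "ethnicity",
]


def default_roles(outcome: str = "ceb") -> ModelRoles:
    """Canonical role declaration: WASH dummies instrument the MHM probit."""
    return ModelRoles(
        outcome=outcome,
        endogenous="mhm",
        excluded_instruments=["wash"],
        exogenous=list(DEFAULT_EXOGENOUS),
        reference_levels=dict(DEFAULT_REFERENCE_LEVELS),
    )


def _shares(series: pd.Series) -> dict[str, float]:
    if len(series) == 0:
        return {}
    return {str(k): float(v)
            for k, v in series.value_counts(normalize=True).sort_index().items()}


def summarize(table: pd.DataFrame, outcome: str = "ceb") -> dict:
    """Descriptive report: MHM/WASH/wealth/education shares, residence
    cross-tabs and the outcome mean."""
    report: dict = {"n": int(len(table))}
    if len(table) == 0:
        return report
    if "mhm" in table:
        mhm = table["mhm"].astype(float)
        report["mhm_share"] = float(mhm.mean(skipna=True))
        if "residence" in table:
            report["mhm_share_by_residence"] = {
                str(k): float(v) for k, v in
                mhm.groupby(table["residence"]).mean().sort_index().items()}
    for col in ("wash", "wealth", "education", "residence"):
        if col in table:
            report[f"{col}_shares"] = _shares(table[col])
    if outcome in table:
        report[f"{outcome}_mean"] = float(table[outcome].mean())
    return report


def _setup_logging(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter(
        '{"t": "%(asctime)s", "stage": "%(name)s", '
        '"level": "%(levelname)s", "msg": "%(message)s"}'))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               for h in logger.handlers if h is not handler):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(handler.formatter)
        logger.addHandler(stream)
    return handler


def _series_block(fit) -> dict:
    se = fit.se("auto")
    return {
        "family": fit.family,
        "coefficients": {k: float(v) for k, v in fit.coefs.items()},
        "se": {k: float(v) for k, v in se.items()},
        "irr_pct": {k: float(v) for k, v in
                    fit.irr_table()["irr_pct"].items()},
        "n": fit.n,
        "n_boot": fit.n_boot,
        "nb_alpha": fit.nb_alpha,
    }


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(run_dir)
    t0 = time.time()
    results: dict = {"schema_version": RESULTS_SCHEMA_VERSION,
                     "seeds": {"bootstrap": config.bootstrap_seed}}
    try:
        if config.simulate is not None:
            logger.info("simulating n=%d seed=%d",
                        config.simulate.n_individuals, config.simulate.seed)
            results["seeds"]["simulation"] = config.simulate.seed
            table = simulate(config.simulate)
            table, _truth = split_visible(table)
        else:
            logger.info("loading %s", config.input_path)
            table = pd.read_csv(config.input_path)
            if config.column_mapping:
                table = table.rename(columns={
                    v: k for k, v in config.column_mapping.items()})

        prepared, audit, imp_report, n_listwise = prepare_table(
            table, policy=config.imputation_policy,
            seed=config.bootstrap_seed)
        logger.info("prepared: %d rows, %d imputed, %d listwise-dropped",
                    len(prepared), imp_report.n_imputed, n_listwise)
        results["prepare"] = {
            "n_rows": int(len(prepared)),
            "filter_dropped": audit.dropped,
            "n_listwise_dropped": n_listwise,
            "imputation": {"n_imputed": imp_report.n_imputed,
                           "policy": imp_report.policy,
                           "coefficients": {k: float(v) for k, v in
                                            imp_report.coefficients.items()}},
        }

        roles = default_roles()
        results["summary"] = summarize(prepared)

        first, resid, count = fit_cf_2sri(
            prepared, roles, family="poisson",
            bootstrap=BootstrapConfig(reps=config.bootstrap_reps,
                                      seed=config.bootstrap_seed))
        ame = marginal_effects(first, prepared, roles)
        ame.to_frame().round(6).to_csv(run_dir / "first_stage_effects.csv")
        count.irr_table().round(
            {"coefficient": 3, "ci_low": 3, "ci_high": 3, "irr_pct": 1}
        ).to_csv(run_dir / "second_stage_irr.csv")
        naive = fit_poisson(prepared, roles)
        results["first_stage"] = {
            "loglik": first.loglik,
            "coefficients": {k: float(v) for k, v in first.alpha_hat.items()},
            "wash_effects": {k: float(v) for k, v in
                             ame.to_frame()["effect"].items()
                             if k.startswith("wash[")},
        }
        results["second_stage"] = {"cf_2sri": _series_block(count),
                                   "naive_poisson": _series_block(naive)}

        z, p = endogeneity_test(count)
        diag = run_diagnostics(prepared, roles, endogeneity=(z, p))
        results["diagnostics"] = diag.to_dict()
        (run_dir / "diagnostics.json").write_text(
            json.dumps(diag.to_dict(), indent=2))

        if "live_births" in prepared.columns:
            _, _, nb = fit_cf_2sri(prepared, roles, family="negbin2",
                                   outcome="live_births")
            results["sensitivity_negbin"] = _series_block(nb)
        else:
            logger.warning("no live_births column; NB sensitivity skipped")

        placebo = run_placebo(prepared, roles, config.placebo_outcome,
                              config.significance_level)
        results["placebo"] = placebo.summary()

        results["subsamples"] = {}
        for name, spec in config.subsamples.items():
            try:
                sub = run_subsample(prepared, roles, spec, name=name)
                results["subsamples"][name] = {
                    "n": sub.n,
                    "gamma": float(sub.count_fit.coefs[roles.endogenous]),
                    "diagnostics": sub.diagnostics.to_dict(),
                }
            except ValueError as exc:
                logger.warning("subsample %s skipped: %s", name, exc)
                results["subsamples"][name] = {"skipped": str(exc)}

        (run_dir / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True))
        logger.info("run complete in %.1fs", time.time() - t0)
        return run_dir
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
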