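"""Falsification (placebo) harness and subsample runners.

The placebo test reruns the full identification machinery with an outcome
that cannot plausibly be caused by the exposure (household-head age): a
CF-OLS with the generalized residual, an IV-2SLS, and the instrument
diagnostics.  A null MHM coefficient and a non-significant residual term
support the exclusion restriction.  The subsample runner re-estimates the
pipeline on filtered rows (e.g. rural residents, ages 15-29) without
mutating the parent table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cf import GeneralizedResiduals, generalized_residual
from .design import ModelRoles
from .diagnostics import DiagnosticsReport, TwoSLSFit, linear_iv_fit, run_diagnostics
from .outcomes import (BootstrapConfig, CountFit, RESIDUAL_COLUMN,
                       endogeneity_test, fit_cf_2sri, fit_ols)
from .probit import ProbitFit, fit_probit

__all__ = ["PlaceboResult", "run_placebo", "SubsampleResult", "run_subsample"]


@dataclass
class PlaceboResult:
    cf_ols: CountFit
    iv_2sls: TwoSLSFit
    diagnostics: DiagnosticsReport
    first_stage: ProbitFit
    endogeneity_ruled_out: bool
    exclusion_supported: bool
    significance_level: float

    def summary(self) -> dict:
        mhm = self.cf_ols.coefs.index[-2]
        return {
            "cf_ols_mhm": float(self.cf_ols.coefs.iloc[-2]),
            "cf_ols_residual": float(self.cf_ols.coefs[RESIDUAL_COLUMN]),
            "iv_2sls_mhm": self.iv_2sls.coef(mhm),
            "endogeneity_ruled_out": self.endogeneity_ruled_out,
            "exclusion_supported": self.exclusion_supported,
            "diagnostics": self.diagnostics.to_dict(),
        }


def run_placebo(table: pd.DataFrame, roles: ModelRoles,
                placebo_outcome: str,
                significance_level: float = 0.05) -> PlaceboResult:
    """CF-OLS and IV-2SLS with a placebo outcome plus full diagnostics.

    The first stage is the identical probit as the main pipeline (the
    outcome swap cannot touch it).  Verdict flags are pure functions of
    the stored statistics at ``significance_level``.
    """
    if placebo_outcome == roles.outcome:
        raise ValueError("placebo outcome must differ from the true outcome")
    values = table[placebo_outcome].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        raise ValueError("placebo outcome is constant; nothing to falsify")

    # Columns that are (affine transforms of) the placebo outcome must
    # leave BOTH stages: in the outcome equation they would be a tautology,
    # and in the selection index even a noise-level estimated coefficient
    # on the placebo variable makes the generalized residual mechanically
    # invertible for it, manufacturing spurious significance.
    exogenous = []
    for col in roles.exogenous:
        series = table[col]
        if pd.api.types.is_numeric_dtype(series):
            x = series.to_numpy(dtype=float)
            if np.std(x) > 0 and abs(np.corrcoef(x, values)[0, 1]) > 0.9999:
                continue
        exogenous.append(col)
    roles = ModelRoles(
        outcome=roles.outcome, endogenous=roles.endogenous,
        excluded_instruments=list(roles.excluded_instruments),
        exogenous=exogenous,
        reference_levels=dict(roles.reference_levels))

    first = fit_probit(table, roles)
    resid = generalized_residual(
        table[roles.endogenous].to_numpy(dtype=float), first.linear_index,
        source_fit=first)
    cf = fit_ols(table, roles, m_hat=resid.m_hat,
                 outcome=placebo_outcome)
    z, p_resid = endogeneity_test(cf)
    iv = linear_iv_fit(table, roles, outcome=placebo_outcome)
    diag = run_diagnostics(table, roles, outcome=placebo_outcome,
                           endogeneity=(z, p_resid))

    mhm_coef = cf.coefs[roles.endogenous]
    mhm_se = float(np.sqrt(cf.vcov_naive.loc[roles.endogenous,
                                             roles.endogenous]))
    crit = norm.ppf(1 - significance_level / 2)
    return PlaceboResult(
        cf_ols=cf, iv_2sls=iv, diagnostics=diag, first_stage=first,
        endogeneity_ruled_out=bool(p_resid >= significance_level),
        exclusion_supported=bool(abs(mhm_coef / mhm_se) < crit),
        significance_level=significance_level)


@dataclass
class SubsampleResult:
    name: str
    n: int
    first_stage: ProbitFit
    residuals: GeneralizedResiduals
    count_fit: CountFit
    diagnostics: DiagnosticsReport


def run_subsample(table: pd.DataFrame, roles: ModelRoles, filter_spec: str,
                  name: str = "subsample", family: str = "poisson",
                  bootstrap: BootstrapConfig | None = None,
                  min_rows: int = 500) -> SubsampleResult:
    """Re-run the CF-2SRI pipeline and diagnostics on a row subset.

    ``filter_spec`` is a ``DataFrame.query`` expression.  Requires at
    least ``min_rows`` rows and both exposure classes; the parent table is
    never modified.
    """
    sub = table.query(filter_spec).copy()
    if len(sub) == 0:
        raise ValueError(f"filter {filter_spec!r} matches no rows")
    if len(sub) < min_rows:
        raise ValueError(
            f"subsample {name!r} has {len(sub)} rows < minimum {min_rows}")
    classes = set(np.unique(sub[roles.endogenous].astype(float)))
    if classes != {0.0, 1.0}:
        raise ValueError(f"subsample {name!r} lacks both exposure classes")
    # a covariate can collapse to a single level inside a subsample (e.g.
    # residence in the rural stratum); it is then absorbed by the intercept
    kept = [c for c in roles.exogenous if sub[c].nunique() > 1]
    if kept != list(roles.exogenous):
        roles = ModelRoles(
            outcome=roles.outcome, endogenous=roles.endogenous,
            excluded_instruments=list(roles.excluded_instruments),
            exogenous=kept, reference_levels=dict(roles.reference_levels))
    first, resid, count = fit_cf_2sri(sub, roles, family=family,
                                      bootstrap=bootstrap)
    diag = run_diagnostics(sub, roles, endogeneity=endogeneity_test(count))
    return SubsampleResult(name=name, n=len(sub), first_stage=first,
                           residuals=resid, count_fit=count, diagnostics=diag)
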