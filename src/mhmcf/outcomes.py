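"""Second-stage estimators: Poisson 2SRI, NB2 sensitivity, OLS placebo.

The headline estimator is two-stage residual inclusion: the probit
generalized residual enters the count regression as an extra regressor,
absorbing the endogeneity of the binary exposure.  Because the residual is
a generated regressor, the default inference is a nonparametric pairs
bootstrap that re-runs BOTH stages per replicate; the model-based
covariance is also kept (it is valid for testing the residual coefficient
under the null of exogeneity, and understates uncertainty otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .cf import GeneralizedResiduals, generalized_residual
from .design import ModelRoles, build_design
from .probit import ProbitFit, fit_probit

__all__ = ["CountFit", "fit_poisson", "fit_negbin", "fit_ols", "fit_cf_2sri",
           "irr_percent", "endogeneity_test", "BootstrapConfig"]

logger = logging.getLogger("mhmcf")

RESIDUAL_COLUMN = "m_hat"


def irr_percent(coef: float) -> float:
    """Percentage change implied by a log-link coefficient: (e^b - 1)*100."""
    return float((np.exp(coef) - 1.0) * 100.0)


@dataclass
class BootstrapConfig:
    reps: int = 500
    seed: int = 12345
    max_failure_rate: float = 0.10


@dataclass
class CountFit:
    """Second-stage estimate over (X1, exposure, generalized residual)."""

    coefs: pd.Series
    vcov_naive: pd.DataFrame
    family: str                       # poisson | negbin2 | ols
    loglik: float
    n: int
    nb_alpha: float | None = None
    equidispersion_lr: float | None = None
    equidispersion_p: float | None = None
    vcov_bootstrap: pd.DataFrame | None = None
    boot_percentile_ci: pd.DataFrame | None = None
    n_boot: int = 0
    n_boot_failed: int = 0
    fitted_mean: np.ndarray | None = None

    def se(self, which: str = "auto") -> pd.Series:
        if which == "bootstrap" or (which == "auto"
                                    and self.vcov_bootstrap is not None):
            return pd.Series(np.sqrt(np.diag(self.vcov_bootstrap)),
                             index=self.coefs.index)
        return pd.Series(np.sqrt(np.diag(self.vcov_naive)),
                         index=self.coefs.index)

    def irr_table(self, level: float = 0.95,
                  which_se: str = "auto") -> pd.DataFrame:
        """Table-style report: coefficient, CI, percentage-change IRR."""
        se = self.se(which_se)
        z = norm.ppf(0.5 + level / 2)
        lo, hi = self.coefs - z * se, self.coefs + z * se
        return pd.DataFrame({
            "coefficient": self.coefs,
            "ci_low": lo,
            "ci_high": hi,
            "irr_pct": [irr_percent(c) for c in self.coefs],
            "family": self.family,
        })


def _count_design(table: pd.DataFrame, roles: ModelRoles,
                  m_hat: np.ndarray | None):
    info = build_design(table, roles.outcome_columns(),
                        roles.reference_levels, require_full_rank=True)
    x = info.matrix.copy()
    x[roles.endogenous] = table[roles.endogenous].to_numpy(dtype=float)
    if m_hat is not None:
        x[RESIDUAL_COLUMN] = np.asarray(m_hat, dtype=float)
    return x


def _check_count_outcome(y: np.ndarray, family: str) -> None:
    if family in ("poisson", "negbin2"):
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError(f"{family} outcome must be non-negative integers")


def fit_poisson(table: pd.DataFrame, roles: ModelRoles,
                m_hat: np.ndarray | None = None,
                outcome: str | None = None) -> CountFit:
    """Poisson MLE with log link over (X1, exposure[, residual])."""
    outcome = outcome or roles.outcome
    y = table[outcome].to_numpy(dtype=float)
    _check_count_outcome(y, "poisson")
    x = _count_design(table, roles, m_hat)
    res = sm.GLM(y, x.to_numpy(), family=sm.families.Poisson()).fit(
        tol=1e-12, maxiter=200)
    names = list(x.columns)
    mu = np.asarray(res.mu)
    return CountFit(
        coefs=pd.Series(np.asarray(res.params), index=names),
        vcov_naive=pd.DataFrame(np.asarray(res.cov_params()),
                                index=names, columns=names),
        family="poisson", loglik=float(res.llf), n=len(y), fitted_mean=mu)


def fit_negbin(table: pd.DataFrame, roles: ModelRoles,
               m_hat: np.ndarray | None = None,
               outcome: str | None = None) -> CountFit:
    """NB2 MLE (variance mu + alpha*mu^2) with a boundary-corrected
    equidispersion check against the nested Poisson."""
    outcome = outcome or roles.outcome
    y = table[outcome].to_numpy(dtype=float)
    _check_count_outcome(y, "negbin2")
    x = _count_design(table, roles, m_hat)
    pois = fit_poisson(table, roles, m_hat=m_hat, outcome=outcome)
    model = sm.NegativeBinomial(y, x.to_numpy(), loglike_method="nb2")
    start = np.append(pois.coefs.to_numpy(), 0.05)
    with np.errstate(all="ignore"):
        res = model.fit(start_params=start, method="bfgs", maxiter=500,
                        disp=0)
    names = list(x.columns)
    params = np.asarray(res.params)
    nb_alpha = max(float(params[-1]), 0.0)
    lr = max(2.0 * (float(res.llf) - pois.loglik), 0.0)
    # alpha = 0 sits on the parameter boundary: the LR null distribution is
    # an equal mixture of chi2(0) and chi2(1)
    p = 0.5 * float(chi2.sf(lr, 1)) if lr > 0 else 1.0
    try:
        vcov = np.asarray(res.cov_params())[:len(names), :len(names)]
    except (ValueError, np.linalg.LinAlgError):
        # alpha on the zero boundary makes the NB hessian singular; the
        # beta block then coincides with the nested Poisson covariance
        logger.warning("NB2 hessian singular at the boundary; using the "
                       "Poisson covariance for the mean parameters")
        vcov = pois.vcov_naive.to_numpy()
    return CountFit(
        coefs=pd.Series(params[:len(names)], index=names),
        vcov_naive=pd.DataFrame(vcov, index=names, columns=names),
        family="negbin2", loglik=float(res.llf), n=len(y),
        nb_alpha=nb_alpha, equidispersion_lr=lr, equidispersion_p=p,
        fitted_mean=np.exp(x.to_numpy() @ params[:len(names)]))


def fit_ols(table: pd.DataFrame, roles: ModelRoles,
            m_hat: np.ndarray | None = None,
            outcome: str | None = None) -> CountFit:
    """Least squares with heteroskedasticity-robust (HC1) covariance;
    the placebo harness's workhorse."""
    outcome = outcome or roles.outcome
    y = table[outcome].to_numpy(dtype=float)
    x = _count_design(table, roles, m_hat)
    res = sm.OLS(y, x.to_numpy()).fit(cov_type="HC1")
    names = list(x.columns)
    return CountFit(
        coefs=pd.Series(np.asarray(res.params), index=names),
        vcov_naive=pd.DataFrame(np.asarray(res.cov_params()),
                                index=names, columns=names),
        family="ols", loglik=float(res.llf), n=len(y),
        fitted_mean=np.asarray(res.fittedvalues))


_FITTERS = {"poisson": fit_poisson, "negbin2": fit_negbin, "ols": fit_ols}


def _single_pass(table: pd.DataFrame, roles: ModelRoles, family: str,
                 outcome: str | None):
    first = fit_probit(table, roles)
    resid = generalized_residual(table[roles.endogenous].to_numpy(dtype=float),
                                 first.linear_index, source_fit=first)
    count = _FITTERS[family](table, roles, m_hat=resid.m_hat, outcome=outcome)
    return first, resid, count


def fit_cf_2sri(table: pd.DataFrame, roles: ModelRoles,
                family: str = "poisson",
                bootstrap: BootstrapConfig | None = None,
                outcome: str | None = None
                ) -> tuple[ProbitFit, GeneralizedResiduals, CountFit]:
    """Two-stage residual inclusion: probit -> generalized residual ->
    count model including the residual.

    With a :class:`BootstrapConfig`, pairs-bootstraps rows with
    replacement, re-running both stages per replicate; the replicate
    coefficient spread gives ``vcov_bootstrap`` and percentile CIs.  A
    failure rate above ``max_failure_rate`` aborts.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}")
    first, resid, count = _single_pass(table, roles, family, outcome)

    if bootstrap is not None and bootstrap.reps > 0:
        rng = np.random.default_rng(bootstrap.seed)
        n = len(table)
        draws: list[pd.Series] = []
        failed = 0
        for _ in range(bootstrap.reps):
            idx = rng.integers(0, n, n)
            sub = table.iloc[idx].reset_index(drop=True)
            try:
                _, _, rep = _single_pass(sub, roles, family, outcome)
                draws.append(rep.coefs)
            except Exception as exc:  # noqa: BLE001 - replicate-level guard
                failed += 1
                logger.warning("bootstrap replicate failed: %s", exc)
        if failed > bootstrap.max_failure_rate * bootstrap.reps:
            raise RuntimeError(
                f"{failed}/{bootstrap.reps} bootstrap replicates failed")
        mat = pd.DataFrame(draws).reindex(columns=count.coefs.index)
        bad = mat.isna().any(axis=1)
        if bad.any():
            failed += int(bad.sum())
            mat = mat.loc[~bad]
        count.vcov_bootstrap = pd.DataFrame(
            np.cov(mat.to_numpy(), rowvar=False),
            index=count.coefs.index, columns=count.coefs.index)
        count.boot_percentile_ci = pd.DataFrame({
            "ci_low": mat.quantile(0.025),
            "ci_high": mat.quantile(0.975)})
        count.n_boot = len(mat)
        count.n_boot_failed = failed
    return first, resid, count


def endogeneity_test(count: CountFit) -> tuple[float, float]:
    """z-test on the generalized-residual coefficient.

    Uses the model-based covariance, which is valid under the null of
    exogeneity (residual coefficient zero); a rejection indicates the
    exposure is endogenous.
    """
    if RESIDUAL_COLUMN not in count.coefs.index:
        raise ValueError("fit does not include the generalized residual")
    delta = float(count.coefs[RESIDUAL_COLUMN])
    se = float(np.sqrt(count.vcov_naive.loc[RESIDUAL_COLUMN,
                                            RESIDUAL_COLUMN]))
    z = delta / se
    return z, float(2.0 * norm.sf(abs(z)))
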