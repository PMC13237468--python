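"""Linear-IV auxiliary diagnostics: identification, weak instruments,
over-identification, endogeneity.

The headline estimator is a count model, but the standard instrument
diagnostics are defined for the linear IV regression, so they are computed
on a 2SLS of the outcome on the endogenous exposure with the WASH dummies
as excluded instruments — the conventional reporting companion to a
control-function count second stage.  All statistics partial exogenous
controls out first (Frisch–Waugh) and use heteroskedasticity-robust
covariances with an (n - k) small-sample adjustment.

With a single endogenous regressor the Kleibergen–Paap rank statistics
reduce to quadratic forms in the first-stage reduced-form coefficients on
the partialled instruments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .design import ModelRoles, build_design

__all__ = ["DiagnosticsReport", "TwoSLSFit", "linear_iv_fit", "kp_rk_lm",
           "kp_rk_wald_f", "cragg_donald_f", "hansen_j", "chi2_upper_tail",
           "stock_yogo_10pct_bias", "run_diagnostics"]

#: 10% maximal IV relative-bias critical values for one endogenous
#: regressor, by number of excluded instruments (Stock & Yogo, 2005).
_STOCK_YOGO_10PCT_BIAS = {3: 9.08, 4: 10.27, 5: 10.83, 6: 11.12,
                          7: 11.29, 8: 11.39, 9: 11.46, 10: 11.49}


def chi2_upper_tail(statistic: float, df: int) -> float:
    """Upper-tail (survival) probability of the chi-square distribution."""
    if df <= 0 or int(df) != df:
        raise ValueError("df must be a positive integer")
    if statistic < 0:
        raise ValueError("statistic must be non-negative")
    return float(chi2.sf(statistic, df))


def stock_yogo_10pct_bias(n_endogenous: int, n_instruments: int) -> float:
    """Tabulated weak-instrument critical value (10% maximal relative bias)."""
    if n_endogenous != 1:
        raise KeyError("tabulated only for one endogenous regressor")
    try:
        return _STOCK_YOGO_10PCT_BIAS[n_instruments]
    except KeyError:
        raise KeyError(
            f"no tabulated 10%-bias value for {n_instruments} instruments "
            f"(available: {sorted(_STOCK_YOGO_10PCT_BIAS)})") from None


def _partial_out(target: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Residuals of regressing ``target`` (vector or matrix) on ``controls``."""
    coef, *_ = np.linalg.lstsq(controls, target, rcond=None)
    return target - controls @ coef


def _matrices(table: pd.DataFrame, roles: ModelRoles):
    """(y, d, Z, X) with X including the intercept."""
    y = table[roles.outcome].to_numpy(dtype=float)
    d = table[roles.endogenous].to_numpy(dtype=float)
    z_info = build_design(table, roles.excluded_instruments,
                          roles.reference_levels, add_intercept=False)
    x_info = build_design(table, roles.exogenous, roles.reference_levels,
                          add_intercept=True)
    return y, d, z_info.matrix, x_info.matrix


@dataclass
class TwoSLSFit:
    params: pd.Series
    vcov: pd.DataFrame
    first_stage_pi: pd.Series      # reduced-form coefs on partialled Z
    residuals: np.ndarray
    n: int
    n_instruments: int

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def se(self, name: str) -> float:
        return float(np.sqrt(self.vcov.loc[name, name]))


def linear_iv_fit(table: pd.DataFrame, roles: ModelRoles,
                  outcome: str | None = None) -> TwoSLSFit:
    """Two-stage least squares with HC-robust covariance.

    Regressors are (exogenous controls, endogenous exposure); instruments
    are (exogenous controls, excluded WASH dummies).
    """
    y, d, z_df, x_df = _matrices(table, roles)
    if outcome is not None:
        y = table[outcome].to_numpy(dtype=float)
    z, x = z_df.to_numpy(), x_df.to_numpy()
    n = len(y)
    regressors = np.column_stack([x, d])
    names = list(x_df.columns) + [roles.endogenous]
    instruments = np.column_stack([x, z])
    k = regressors.shape[1]
    if instruments.shape[1] < k:
        raise ValueError("under-identified: fewer instruments than regressors")

    qz = np.linalg.qr(instruments)[0]
    fitted = qz @ (qz.T @ regressors)
    xtx = fitted.T @ fitted
    beta = np.linalg.solve(xtx, fitted.T @ y)
    resid = y - regressors @ beta
    meat = (fitted * (resid ** 2)[:, None]).T @ fitted
    bread = np.linalg.inv(xtx)
    vcov = bread @ meat @ bread * n / (n - k)

    zp = _partial_out(z, x)
    dp = _partial_out(d, x)
    pi, *_ = np.linalg.lstsq(zp, dp, rcond=None)
    return TwoSLSFit(
        params=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        first_stage_pi=pd.Series(pi, index=z_df.columns),
        residuals=resid, n=n, n_instruments=z.shape[1])


def kp_rk_lm(table: pd.DataFrame, roles: ModelRoles
             ) -> tuple[float, int, float]:
    """Robust rank LM under-identification test (one endogenous regressor).

    Tests that the reduced-form coefficient vector on the partialled
    instruments is zero: LM = n * gbar' S^{-1} gbar with moments
    g_i = z_perp_i * d_perp_i and S their robust covariance under the
    null.  df = L, p from the chi-square upper tail.  Under i.i.d.
    homoskedasticity this approaches the Anderson canonical-correlation LM.
    """
    _, d, z_df, x_df = _matrices(table, roles)
    z, x = z_df.to_numpy(), x_df.to_numpy()
    n, L = z.shape
    if n <= x.shape[1] + L:
        raise ValueError("fewer rows than parameters")
    zp = _partial_out(z, x)
    dp = _partial_out(d, x)
    g = zp * dp[:, None]
    gbar = g.mean(axis=0)
    s = g.T @ g / n
    stat = float(n * gbar @ np.linalg.solve(s, gbar))
    return stat, L, chi2_upper_tail(stat, L)


def _first_stage_pieces(table: pd.DataFrame, roles: ModelRoles):
    _, d, z_df, x_df = _matrices(table, roles)
    z, x = z_df.to_numpy(), x_df.to_numpy()
    zp = _partial_out(z, x)
    dp = _partial_out(d, x)
    pi, *_ = np.linalg.lstsq(zp, dp, rcond=None)
    e = dp - zp @ pi
    k_total = z.shape[1] + x.shape[1]
    return zp, dp, pi, e, k_total


def kp_rk_wald_f(table: pd.DataFrame, roles: ModelRoles) -> float:
    """Robust rank Wald statistic on an F scale (divide by L, n-k adjusted).

    Equals the robust first-stage F on the excluded instruments for one
    endogenous regressor, and approaches the classical first-stage F under
    homoskedasticity.
    """
    zp, dp, pi, e, k_total = _first_stage_pieces(table, roles)
    n, L = zp.shape
    ztz_inv = np.linalg.inv(zp.T @ zp)
    meat = (zp * (e ** 2)[:, None]).T @ zp
    v = ztz_inv @ meat @ ztz_inv * n / (n - k_total)
    wald = float(pi @ np.linalg.solve(v, pi))
    return wald / L


def cragg_donald_f(table: pd.DataFrame, roles: ModelRoles) -> float:
    """Classical (non-robust) first-stage F on the excluded instruments."""
    zp, dp, pi, e, k_total = _first_stage_pieces(table, roles)
    n, L = zp.shape
    sigma2 = float(e @ e) / (n - k_total)
    v = sigma2 * np.linalg.inv(zp.T @ zp)
    return float(pi @ np.linalg.solve(v, pi)) / L


def hansen_j(table: pd.DataFrame, roles: ModelRoles,
             outcome: str | None = None,
             homoskedastic: bool = False):
    """Two-step efficient-GMM over-identification test.

    df = L - 1 for one endogenous regressor.  Just-identified models
    return (0.0, 0, None).  ``homoskedastic=True`` forces the classical
    weighting, collapsing the statistic to the Sargan form.
    """
    y, d, z_df, x_df = _matrices(table, roles)
    if outcome is not None:
        y = table[outcome].to_numpy(dtype=float)
    z, x = z_df.to_numpy(), x_df.to_numpy()
    n, L = z.shape
    df = L - 1
    q = np.column_stack([x, z])
    r = np.column_stack([x, d])
    if df == 0:
        return 0.0, 0, None
    # step 1: 2SLS residuals
    qq = np.linalg.qr(q)[0]
    r_hat = qq @ (qq.T @ r)
    beta1 = np.linalg.solve(r_hat.T @ r_hat, r_hat.T @ y)
    u1 = y - r @ beta1
    if homoskedastic:
        s = (q.T @ q) * float(u1 @ u1) / n / n
    else:
        qu = q * u1[:, None]
        s = qu.T @ qu / n
    w = np.linalg.inv(s)
    # step 2: efficient GMM and its J
    a = r.T @ q @ w @ q.T @ r
    b = r.T @ q @ w @ q.T @ y
    beta2 = np.linalg.solve(a, b)
    u2 = y - r @ beta2
    gbar = q.T @ u2 / n
    stat = float(n * gbar @ w @ gbar)
    return stat, df, chi2_upper_tail(stat, df)


@dataclass
class DiagnosticsReport:
    kp_lm_stat: float
    kp_lm_df: int
    kp_lm_p: float
    kp_wald_f: float
    cragg_donald_f: float
    hansen_j_stat: float
    hansen_j_df: int
    hansen_j_p: float | None
    stock_yogo_10pct_bias: float | None
    endogeneity_z: float | None = None
    endogeneity_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "kp_rk_lm": {"statistic": self.kp_lm_stat, "df": self.kp_lm_df,
                         "p": self.kp_lm_p},
            "kp_rk_wald_f": self.kp_wald_f,
            "cragg_donald_f": self.cragg_donald_f,
            "hansen_j": {"statistic": self.hansen_j_stat,
                         "df": self.hansen_j_df, "p": self.hansen_j_p},
            "stock_yogo_10pct_bias": self.stock_yogo_10pct_bias,
            "endogeneity": {"z": self.endogeneity_z,
                            "p": self.endogeneity_p},
        }


def run_diagnostics(table: pd.DataFrame, roles: ModelRoles,
                    outcome: str | None = None,
                    endogeneity: tuple[float, float] | None = None
                    ) -> DiagnosticsReport:
    """Assemble the full diagnostics block for one dataset."""
    lm_stat, lm_df, lm_p = kp_rk_lm(table, roles)
    j_stat, j_df, j_p = hansen_j(table, roles, outcome=outcome)
    try:
        sy = stock_yogo_10pct_bias(1, lm_df)
    except KeyError:
        sy = None
    z_p = endogeneity or (None, None)
    return DiagnosticsReport(
        kp_lm_stat=lm_stat, kp_lm_df=lm_df, kp_lm_p=lm_p,
        kp_wald_f=kp_rk_wald_f(table, roles),
        cragg_donald_f=cragg_donald_f(table, roles),
        hansen_j_stat=j_stat, hansen_j_df=j_df, hansen_j_p=j_p,
        stock_yogo_10pct_bias=sy,
        endogeneity_z=z_p[0], endogeneity_p=z_p[1])
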