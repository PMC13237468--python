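"""First-stage probit MLE and Table-4-style average marginal effects."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .design import DesignError, DesignInfo, ModelRoles, build_design, dummy_name

__all__ = ["ProbitFit", "fit_probit", "marginal_effects", "predict_index",
           "MarginalEffectsTable"]


class SeparationError(RuntimeError):
    """Perfect separation: the probit MLE does not exist."""


@dataclass
class ProbitFit:
    """First-stage probit estimate.

    ``vcov`` is the robust (sandwich) covariance used for reporting;
    ``vcov_obs_info`` the observed-information covariance used by the
    delta method for marginal effects.
    """

    alpha_hat: pd.Series
    vcov: pd.DataFrame
    vcov_obs_info: pd.DataFrame
    linear_index: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    design_info: DesignInfo
    reference_levels: dict[str, str]
    response: str

    @property
    def columns(self) -> list[str]:
        return list(self.alpha_hat.index)


def fit_probit(table: pd.DataFrame, roles: ModelRoles,
               response: str | None = None) -> ProbitFit:
    """Maximum-likelihood probit of the endogenous indicator on W + X1.

    Newton iterations from a zero start with tolerance 1e-10; convergence
    failure is flagged, never silent.  Rank-deficient designs and perfect
    separation raise with the offending columns / advice.
    """
    response = response or roles.endogenous
    y = table[response].astype(float)
    if y.isna().any():
        raise ValueError(f"response {response!r} has missing values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"response {response!r} is not binary 0/1")
    info = build_design(table, roles.selection_columns(),
                        roles.reference_levels, require_full_rank=True)
    x = info.matrix

    model = sm.Probit(y.to_numpy(), x.to_numpy())
    with np.errstate(all="ignore"):
        res = model.fit(method="newton", tol=1e-10, maxiter=100, disp=0,
                        warn_convergence=False)
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        raise SeparationError(
            "probit coefficients diverged (perfect separation likely); "
            "consider a penalized fit or dropping the separating column")

    score_obs = model.score_obs(params)
    hessian = model.hessian(params)
    obs_info = np.linalg.inv(-hessian)
    sandwich = obs_info @ (score_obs.T @ score_obs) @ obs_info
    names = list(x.columns)
    return ProbitFit(
        alpha_hat=pd.Series(params, index=names),
        vcov=pd.DataFrame(sandwich, index=names, columns=names),
        vcov_obs_info=pd.DataFrame(obs_info, index=names, columns=names),
        linear_index=np.asarray(x.to_numpy() @ params),
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", False)),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        design_info=info,
        reference_levels=dict(roles.reference_levels),
        response=response,
    )


def design_matrix_for(fit: ProbitFit, table: pd.DataFrame) -> np.ndarray:
    """Rebuild the fitted design on a new table, column-for-column.

    Categorical dummies come from the levels stored at fit time; a level
    never seen in fitting raises.
    """
    info = fit.design_info
    cols: dict[str, np.ndarray] = {"const": np.ones(len(table))}
    for source, names in info.term_columns.items():
        if source in info.categorical_levels:
            levels = info.categorical_levels[source]
            extra = set(pd.unique(table[source].dropna())) - set(levels)
            if extra:
                raise DesignError(
                    f"unseen level(s) {sorted(map(str, extra))} in {source!r}")
            for lv in levels[1:]:
                cols[dummy_name(source, lv)] = (
                    table[source] == lv).to_numpy(dtype=float)
        else:
            cols[source] = table[source].to_numpy(dtype=float)
    matrix = pd.DataFrame(cols, index=table.index)
    return matrix[fit.columns].to_numpy()


def predict_index(fit: ProbitFit, table: pd.DataFrame) -> np.ndarray:
    """Linear index x'a per row of ``table``; Phi of it is the predicted
    probability."""
    return design_matrix_for(fit, table) @ fit.alpha_hat.to_numpy()


@dataclass
class MarginalEffectsTable:
    """Average marginal effects in probability points.

    ``kind`` is ``continuous-AME`` (mean of phi(x'a)*a_j) or
    ``discrete-from-base`` (mean discrete change in Phi from the reference
    level of the factor).
    """

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _effects_at(alpha: np.ndarray, fit: ProbitFit, x: np.ndarray,
                table: pd.DataFrame, rows: list[tuple[str, str, str]]
                ) -> np.ndarray:
    idx = x @ alpha
    out = np.empty(len(rows))
    coef = pd.Series(alpha, index=fit.columns)
    col_pos = {c: j for j, c in enumerate(fit.columns)}
    phi_bar = float(np.mean(norm.pdf(idx)))
    for i, (kind, source, design_col) in enumerate(rows):
        if kind == "continuous-AME":
            out[i] = phi_bar * coef[design_col]
        else:
            levels = fit.design_info.categorical_levels[source]
            base_idx = idx.copy()
            # zero out the factor's own dummies -> base level
            for lv in levels[1:]:
                j = col_pos[dummy_name(source, lv)]
                base_idx -= x[:, j] * alpha[j]
            lev_idx = base_idx + coef[design_col]
            out[i] = float(np.mean(norm.cdf(lev_idx) - norm.cdf(base_idx)))
    return out


def marginal_effects(fit: ProbitFit, table: pd.DataFrame,
                     roles: ModelRoles, level: float = 0.95
                     ) -> MarginalEffectsTable:
    """Average marginal effects with delta-method standard errors.

    Continuous covariates get the classic AME; factor levels get the
    average discrete change in probability from the declared base level,
    matching the reporting convention of probit marginal-effects tables.
    """
    if not fit.converged:
        raise RuntimeError("marginal effects require a converged fit")
    x = design_matrix_for(fit, table)
    rows: list[tuple[str, str, str]] = []
    for source, names in fit.design_info.term_columns.items():
        if source in fit.design_info.categorical_levels:
            rows.extend(("discrete-from-base", source, nm) for nm in names)
        else:
            rows.extend(("continuous-AME", source, nm) for nm in names)

    alpha = fit.alpha_hat.to_numpy()
    effects = _effects_at(alpha, fit, x, table, rows)

    # delta method: numerical Jacobian of the effect vector in alpha
    k = len(alpha)
    jac = np.empty((len(rows), k))
    for j in range(k):
        h = 1e-6 * (1.0 + abs(alpha[j]))
        ap, am = alpha.copy(), alpha.copy()
        ap[j] += h
        am[j] -= h
        jac[:, j] = (_effects_at(ap, fit, x, table, rows)
                     - _effects_at(am, fit, x, table, rows)) / (2 * h)
    cov = jac @ fit.vcov_obs_info.to_numpy() @ jac.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = norm.ppf(0.5 + level / 2)
    frame = pd.DataFrame({
        "term": [r[2] for r in rows],
        "effect": effects,
        "se": se,
        "ci_low": effects - z * se,
        "ci_high": effects + z * se,
        "kind": [r[0] for r in rows],
    }).set_index("term")
    return MarginalEffectsTable(table=frame)
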