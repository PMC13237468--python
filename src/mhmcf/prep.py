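"""Variable construction, eligibility filtering and MHM imputation.

Turns raw questionnaire fields into analysis variables: the binary MHM
indicator from the three menstrual-hygiene items, the three-category wealth
recode, the five-category WASH availability variable, then applies the
eligibility filters (ever-married, aged 15-49, no hysterectomy, not
menopausal) and regression-imputes missing MHM from water availability and
wealth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["construct_mhm", "apply_filters", "recode_wealth",
           "construct_wash_category", "impute_mhm", "prepare_table",
           "FilterAudit", "ImputationReport", "PrepError"]


class PrepError(ValueError):
    """Raised on unrecognized codes or impossible preparation requests."""


_YES = {"yes", "y", "1", 1, True}
_NO = {"no", "n", "0", 0, False}
_MISSING = {"missing", "", None}

FILTER_ORDER = ["marital", "hysterectomy", "menopause", "age"]

WEALTH_RECODE = {"richest": "rich", "rich": "rich", "middle": "middle",
                 "poor": "poor", "poorest": "poor"}
#: Numeric codes of the three-category recode (rich=0, middle=1, poor=2).
WEALTH_CODES = {"rich": 0, "middle": 1, "poor": 2}


def _answer(value, row_index) -> float:
    if isinstance(value, float) and np.isnan(value):
        return np.nan
    if isinstance(value, str):
        value = value.strip().lower()
    if value in _YES:
        return 1.0
    if value in _NO:
        return 0.0
    if value in _MISSING or value is pd.NA:
        return np.nan
    raise PrepError(f"unrecognized answer code {value!r} at row {row_index}")


def construct_mhm(q_privacy, q_materials, q_reuse):
    """Binary MHM indicator: 1 iff all three items are 'yes'.

    Accepts scalars or aligned Series; returns float (NaN = missing).  A
    missing answer on any item propagates to a missing indicator.
    """
    scalar = np.isscalar(q_privacy) or q_privacy is None
    if scalar:
        vals = [_answer(q_privacy, 0), _answer(q_materials, 0), _answer(q_reuse, 0)]
        if any(np.isnan(v) for v in vals):
            return np.nan
        return float(all(v == 1.0 for v in vals))
    frames = []
    for series in (q_privacy, q_materials, q_reuse):
        series = pd.Series(series)
        frames.append(series.reset_index(drop=True).map(
            lambda v, _idx=series.index: np.nan if _is_missing(v) else _strict(v)))
    stacked = pd.concat(frames, axis=1)
    out = (stacked == 1.0).all(axis=1).astype(float)
    out[stacked.isna().any(axis=1)] = np.nan
    return out


def _is_missing(value) -> bool:
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str):
        value = value.strip().lower()
    return value in _MISSING or value is pd.NA


def _strict(value) -> float:
    if isinstance(value, str):
        value = value.strip().lower()
    if value in _YES:
        return 1.0
    if value in _NO:
        return 0.0
    raise PrepError(f"unrecognized answer code {value!r}")


@dataclass
class FilterAudit:
    """Rows dropped per eligibility rule, in application order."""

    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())

    def is_empty(self) -> bool:
        return self.total_dropped == 0


def apply_filters(table: pd.DataFrame,
                  age_bounds: tuple[int, int] = (15, 49)
                  ) -> tuple[pd.DataFrame, FilterAudit]:
    """Retain ever-married women aged 15-49 without hysterectomy/menopause.

    Filters run in the fixed order marital -> hysterectomy -> menopause ->
    age so the per-rule drop counts are reproducible.  Idempotent.
    """
    audit = FilterAudit()
    out = table
    for rule in FILTER_ORDER:
        if rule == "marital":
            keep = out["marital_status"].astype(str).str.lower().isin(
                {"married", "ever-married", "ever_married", "widowed",
                 "divorced", "separated"})
        elif rule == "hysterectomy":
            keep = ~out["hysterectomy"].astype(float).fillna(0).astype(bool)
        elif rule == "menopause":
            keep = ~out["menopause"].astype(float).fillna(0).astype(bool)
        else:
            keep = out["age"].between(age_bounds[0], age_bounds[1])
        n_drop = int((~keep).sum())
        if n_drop:
            audit.dropped[rule] = n_drop
        out = out.loc[keep]
    return out.copy(), audit


def recode_wealth(quintile):
    """Five-quintile wealth to the three analysis categories.

    rich & richest -> 'rich' (code 0); middle -> 'middle' (code 1);
    poor & poorest -> 'poor' (code 2).
    """
    if isinstance(quintile, (pd.Series, np.ndarray, list)):
        series = pd.Series(quintile).astype(str).str.strip().str.lower()
        unknown = set(series.unique()) - set(WEALTH_RECODE)
        if unknown:
            raise PrepError(f"unknown wealth quintile level(s) {sorted(unknown)}")
        return series.map(WEALTH_RECODE)
    key = str(quintile).strip().lower()
    if key not in WEALTH_RECODE:
        raise PrepError(f"unknown wealth quintile level {quintile!r}")
    return WEALTH_RECODE[key]


def construct_wash_category(water_available_dwelling, water_elsewhere,
                            handwash_place, hand_cleanser):
    """Five-category WASH availability variable.

    Categories: 'none' (no water, no handwashing place, no cleanser),
    'dwelling+wash' (water in dwelling/yard/plot with a handwashing place
    and/or cleanser), 'dwelling-only', 'elsewhere+wash', 'elsewhere-only'.
    Water reported both at the dwelling and elsewhere, or wash facilities
    without any water source, are contradictory inputs.
    """
    wd = np.asarray(water_available_dwelling, dtype=float)
    we = np.asarray(water_elsewhere, dtype=float)
    hw = np.asarray(handwash_place, dtype=float)
    hc = np.asarray(hand_cleanser, dtype=float)
    scalar = wd.ndim == 0
    wd, we, hw, hc = np.atleast_1d(wd, we, hw, hc)
    if np.any((wd == 1) & (we == 1)):
        raise PrepError("contradictory WASH inputs: water reported both at "
                        "the dwelling and elsewhere")
    wash_any = (hw == 1) | (hc == 1)
    if np.any((wd == 0) & (we == 0) & wash_any):
        raise PrepError("contradictory WASH inputs: handwashing facilities "
                        "without any water source")
    out = np.where(wd == 1, np.where(wash_any, "dwelling+wash", "dwelling-only"),
          np.where(we == 1, np.where(wash_any, "elsewhere+wash", "elsewhere-only"),
                   "none")).astype(object)
    return out[0] if scalar else pd.Series(out)


@dataclass
class ImputationReport:
    n_imputed: int
    coefficients: dict[str, float]
    policy: str
    penalized: bool = False


def _probit_loglik(alpha, x, y):
    idx = x @ alpha
    return -np.sum(y * norm.logcdf(idx) + (1 - y) * norm.logcdf(-idx))


def _fit_imputation_probit(x: np.ndarray, y: np.ndarray,
                           ridge: float = 0.0) -> np.ndarray:
    def objective(a):
        return _probit_loglik(a, x, y) + ridge * np.sum(a ** 2)

    res = minimize(objective, np.zeros(x.shape[1]), method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    return res.x


def impute_mhm(table: pd.DataFrame, policy: str = "deterministic",
               seed: int = 0) -> tuple[pd.DataFrame, ImputationReport]:
    """Regression-impute missing MHM from water availability and wealth.

    A probit of observed MHM on the dwelling-water indicator and the wealth
    dummies supplies predicted probabilities; under the default
    deterministic policy a missing MHM becomes 1[p >= 0.5], under the
    stochastic policy a Bernoulli(p) draw.  Perfect separation triggers a
    ridge-penalized fallback with a logged warning.
    """
    if policy not in ("deterministic", "stochastic"):
        raise PrepError(f"unknown imputation policy {policy!r}")
    out = table.copy()
    mhm = out["mhm"].astype(float)
    observed = mhm.notna()
    if not observed.any():
        raise PrepError("cannot impute: all MHM values are missing")
    missing = ~observed
    names = ["const", "water_available_dwelling",
             "wealth[middle]", "wealth[poor]"]
    x_all = np.column_stack([
        np.ones(len(out)),
        out["water_available_dwelling"].to_numpy(dtype=float),
        (out["wealth"] == "middle").to_numpy(dtype=float),
        (out["wealth"] == "poor").to_numpy(dtype=float),
    ])
    x_obs = x_all[observed.to_numpy()]
    y_obs = mhm[observed].to_numpy()
    penalized = False
    alpha = _fit_imputation_probit(x_obs, y_obs)
    idx = x_obs @ alpha
    separated = (y_obs.min() < y_obs.max()
                 and idx[y_obs == 1].min() > idx[y_obs == 0].max()
                 and np.ptp(idx) > 4.0)
    if not np.all(np.isfinite(alpha)) or separated:
        warnings.warn("perfect separation in the MHM imputation probit; "
                      "falling back to a ridge-penalized fit")
        penalized = True
        alpha = _fit_imputation_probit(x_obs, y_obs, ridge=1e-3)
    report = ImputationReport(
        n_imputed=int(missing.sum()),
        coefficients=dict(zip(names, np.round(alpha, 6))),
        policy=policy, penalized=penalized)
    if report.n_imputed == 0:
        return out, report
    p_miss = norm.cdf(x_all[missing.to_numpy()] @ alpha)
    if policy == "deterministic":
        filled = (p_miss >= 0.5).astype(float)
    else:
        rng = np.random.default_rng(seed)
        filled = (rng.random(len(p_miss)) < p_miss).astype(float)
    out.loc[missing, "mhm"] = filled
    out["mhm_imputed"] = missing.astype(int)
    return out, report


def prepare_table(table: pd.DataFrame, policy: str = "deterministic",
                  seed: int = 0):
    """Filter, derive any absent analysis variables, and impute missing MHM.

    Returns ``(prepared_table, filter_audit, imputation_report,
    n_listwise_dropped)``.  Rows missing any non-MHM analysis variable are
    listwise-deleted with an audit count.
    """
    out = table.copy()
    if "mhm" not in out.columns:
        out["mhm"] = construct_mhm(out["q_privacy"], out["q_materials"],
                                   out["q_reuse"]).to_numpy()
    if "wealth" not in out.columns:
        out["wealth"] = recode_wealth(out["wealth_quintile"]).to_numpy()
    if "wash" not in out.columns:
        out["wash"] = construct_wash_category(
            out["water_available_dwelling"], out["water_elsewhere"],
            out["handwash_place"], out["hand_cleanser"]).to_numpy()
    if "age_c" not in out.columns:
        out["age_c"] = out["age"] - 32
    if "head_age_c" not in out.columns:
        out["head_age_c"] = out["head_age"] - 45
    out, audit = apply_filters(out)
    non_mhm = [c for c in out.columns if c not in ("mhm", "q_materials",
                                                   "q_privacy", "q_reuse")]
    complete = out[non_mhm].notna().all(axis=1)
    n_listwise = int((~complete).sum())
    out = out.loc[complete]
    out, report = impute_mhm(out, policy=policy, seed=seed)
    out["mhm"] = out["mhm"].astype(int)
    return out, audit, report, n_listwise
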