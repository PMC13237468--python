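"""Synthetic MICS-style survey microdata with known endogeneity structure.

The generator emulates a cross-sectional women's-questionnaire extract:
one row per ever-married woman aged 15-49, with socio-demographics, WASH
facility indicators, the three menstrual-hygiene questionnaire items, and
fertility counts.  Menstrual hygiene management (MHM) is selected through a
probit latent index sharing a standard-normal error ``eps`` with the count
outcome, whose Poisson log-mean carries ``delta * eps`` — the endogeneity
that the control-function stages are built to remove.  A closed-form
conditional-mean oracle provides ground truth for validation.

Randomness is split into independent per-stage streams (covariates /
selection / outcome / missingness), so regenerating one stage never
perturbs the others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ConfigError, SimulationConfig

__all__ = [
    "generate_covariates", "generate_selection", "generate_outcome",
    "apply_missingness", "oracle_conditional_mean", "simulate",
    "split_visible", "write_csv", "HIDDEN_COLUMNS",
]

#: Ground-truth columns excluded from any export consumed by estimation.
HIDDEN_COLUMNS = ["latent_epsilon", "sel_index", "out_index", "true_mean"]

_STAGE_COVARIATES = 0
_STAGE_SELECTION = 1
_STAGE_OUTCOME = 2
_STAGE_MISSINGNESS = 3


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stage]))


def _draw_categorical(u: np.ndarray, probs: dict[str, float]) -> np.ndarray:
    levels = np.array(list(probs.keys()), dtype=object)
    cum = np.cumsum(list(probs.values()))
    cum[-1] = 1.0
    idx = np.searchsorted(cum, u, side="right")
    return levels[np.clip(idx, 0, len(levels) - 1)]


def _uniforms(rng: np.random.Generator, n: int, rho: float,
              factor: np.ndarray | None) -> np.ndarray:
    """Marginally-uniform draws, optionally tied through a Gaussian factor."""
    if factor is None or rho == 0.0:
        return rng.random(n)
    z = rho * factor + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return norm.cdf(z)


def generate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw the covariate table (everything upstream of MHM and fertility)."""
    n = config.n_individuals
    rng = _stage_rng(config, _STAGE_COVARIATES)
    probs = config.category_probabilities
    rho = config.copula_rho
    factor = rng.standard_normal(n) if rho != 0.0 else None

    cols: dict[str, np.ndarray] = {"woman_id": np.arange(1, n + 1)}

    lo, hi = config.age_range
    cols["age"] = lo + np.floor(_uniforms(rng, n, rho, factor) * (hi - lo + 1)).astype(int)
    hlo, hhi = config.head_age_range
    cols["head_age"] = hlo + np.floor(
        _uniforms(rng, n, rho, factor) * (hhi - hlo + 1)).astype(int)

    for name in ("education", "residence", "region", "ethnicity",
                 "head_education", "wash"):
        cols[name] = _draw_categorical(_uniforms(rng, n, rho, factor), probs[name])

    # Wealth is sampled at quintile granularity consistent with the
    # three-category analysis recode (rich & richest / middle / poor & poorest).
    w3 = _draw_categorical(_uniforms(rng, n, rho, factor), probs["wealth"])
    half = rng.random(n) < 0.5
    quintile = np.where(w3 == "rich", np.where(half, "richest", "rich"),
               np.where(w3 == "poor", np.where(half, "poorest", "poor"), "middle"))
    cols["wealth_quintile"] = quintile.astype(object)
    cols["wealth"] = w3

    for name in ("media_any", "no_contraception", "nicotine_or_alcohol",
                 "head_female"):
        cols[name] = (_uniforms(rng, n, rho, factor)
                      < config.binary_rate(name)).astype(int)

    table = pd.DataFrame(cols)
    table["age_c"] = table["age"] - 32
    table["head_age_c"] = table["head_age"] - 45
    table["head_sex"] = np.where(table["head_female"] == 1, "female", "male")

    # Raw WASH facility indicators consistent with the 5-category variable.
    wash = table["wash"].to_numpy()
    at_dwelling = np.isin(wash, ["dwelling+wash", "dwelling-only"]).astype(int)
    elsewhere = np.isin(wash, ["elsewhere+wash", "elsewhere-only"]).astype(int)
    has_wash = np.isin(wash, ["dwelling+wash", "elsewhere+wash"])
    split = rng.random(n)
    table["water_available_dwelling"] = at_dwelling
    table["water_elsewhere"] = elsewhere
    # wash facilities mean a handwashing place and/or a hand cleanser
    table["handwash_place"] = (has_wash & (split < 0.8)).astype(int)
    table["hand_cleanser"] = (has_wash & ((split >= 0.8) | (rng.random(n) < 0.6))).astype(int)

    # The sampling frame is the analysis population, so the eligibility
    # filters are no-ops on simulated data.
    table["marital_status"] = "married"
    table["hysterectomy"] = 0
    table["menopause"] = 0
    return table


def _linear_index(table: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Evaluate sum(coef * column) where keys are ``const``, numeric column
    names, or ``column[level]`` indicator terms."""
    idx = np.zeros(len(table))
    for key, coef in coefs.items():
        if coef == 0.0:
            continue
        if key == "const":
            idx += coef
        elif key.endswith("]") and "[" in key:
            col, level = key[:-1].split("[", 1)
            if col not in table.columns:
                raise ConfigError(f"unknown covariate {col!r} in coefficient {key!r}")
            idx += coef * (table[col] == level).to_numpy(dtype=float)
        elif key in table.columns:
            idx += coef * table[key].to_numpy(dtype=float)
        else:
            raise ConfigError(f"unknown covariate name {key!r}")
    return idx


def generate_selection(table: pd.DataFrame,
                       config: SimulationConfig) -> pd.DataFrame:
    """Add the latent error, the MHM indicator and the questionnaire items.

    MHM = 1 exactly when ``sel_index + eps >= 0`` with eps ~ N(0,1).  The
    three yes/no items are emitted consistently with the indicator: an
    all-yes pattern if and only if MHM = 1.
    """
    rng = _stage_rng(config, _STAGE_SELECTION)
    out = table.copy()
    sel_index = _linear_index(out, config.sel_coefs)
    eps = rng.standard_normal(len(out))
    mhm = (sel_index + eps >= 0).astype(int)
    out["sel_index"] = sel_index
    out["latent_epsilon"] = eps
    out["mhm"] = mhm.astype(float)

    yes = rng.random((len(out), 3)) < 0.7
    all_yes = yes.all(axis=1)
    forced_no = rng.integers(0, 3, size=len(out))
    rows = np.flatnonzero(all_yes & (mhm == 0))
    yes[rows, forced_no[rows]] = False
    yes[mhm == 1] = True
    for j, name in enumerate(["q_privacy", "q_materials", "q_reuse"]):
        out[name] = np.where(yes[:, j], "yes", "no")
    return out


def generate_outcome(table: pd.DataFrame,
                     config: SimulationConfig) -> pd.DataFrame:
    """Draw fertility counts: Poisson with log-mean x1'b + gamma*MHM + delta*eps."""
    if "latent_epsilon" not in table.columns:
        raise ConfigError("selection must be generated before the outcome")
    rng = _stage_rng(config, _STAGE_OUTCOME)
    out = table.copy()
    x1 = _linear_index(out, config.out_coefs)
    log_mean = (x1 + config.gamma * out["mhm"].to_numpy()
                + config.delta * out["latent_epsilon"].to_numpy())
    worst = float(np.max(log_mean))
    if worst > config.max_log_mean:
        raise ConfigError(
            f"maximum log-mean {worst:.2f} exceeds the overflow guard "
            f"{config.max_log_mean}; rescale out_coefs/gamma/delta")
    mean = np.exp(log_mean)
    out["out_index"] = x1
    out["true_mean"] = mean
    out["ceb"] = rng.poisson(mean)
    # independent re-draw from the same conditional mean: the alternative
    # fertility count used for sensitivity analysis
    out["live_births"] = rng.poisson(mean)
    return out


def apply_missingness(table: pd.DataFrame,
                      config: SimulationConfig) -> pd.DataFrame:
    """Set MHM missing completely at random at ``missing_rate``."""
    rng = _stage_rng(config, _STAGE_MISSINGNESS)
    out = table.copy()
    mask = rng.random(len(out)) < config.missing_rate
    out["mhm_missing"] = mask.astype(int)
    out.loc[mask, "mhm"] = np.nan
    out.loc[mask, "q_materials"] = "missing"
    return out


def oracle_conditional_mean(x_index, mhm, beta_part, gamma: float,
                            delta: float):
    """Exact E[CEB | X, MHM] under the generating model.

    With eps ~ N(0,1), MHM = 1[x_index + eps >= 0] and Poisson log-mean
    beta_part + gamma*MHM + delta*eps, truncated-normal moment algebra gives

        E[CEB | MHM=1] = exp(beta_part + gamma + delta^2/2)
                         * Phi(x_index + delta) / Phi(x_index)
        E[CEB | MHM=0] = exp(beta_part + delta^2/2)
                         * Phi(-x_index - delta) / Phi(-x_index)

    computed via log-CDF differences for numerical stability.
    """
    x_index = np.asarray(x_index, dtype=float)
    mhm = np.asarray(mhm)
    beta_part = np.asarray(beta_part, dtype=float)
    sign = np.where(mhm == 1, 1.0, -1.0)
    log_ratio = norm.logcdf(sign * (x_index + delta)) - norm.logcdf(sign * x_index)
    value = np.exp(beta_part + gamma * (mhm == 1) + 0.5 * delta ** 2 + log_ratio)
    return value if value.ndim else float(value)


def simulate(config: SimulationConfig) -> pd.DataFrame:
    """Run all four generation stages; returns the table with hidden columns."""
    table = generate_covariates(config)
    table = generate_selection(table, config)
    table = generate_outcome(table, config)
    table = apply_missingness(table, config)
    return table


def split_visible(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate the estimation-facing table from the ground-truth sidecar."""
    hidden = [c for c in HIDDEN_COLUMNS if c in table.columns]
    return table.drop(columns=hidden), table[["woman_id", *hidden]].copy()


def write_csv(table: pd.DataFrame, path) -> None:
    """Write the visible table to ``path`` and truth columns to a sidecar
    ``<path minus .csv>.truth.csv``."""
    visible, truth = split_visible(table)
    path = str(path)
    visible.to_csv(path, index=False)
    stem = path[:-4] if path.endswith(".csv") else path
    truth.to_csv(stem + ".truth.csv", index=False)
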