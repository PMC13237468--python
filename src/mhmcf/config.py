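"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "RunConfig", "ConfigError",
           "default_simulation_config", "load_run_config"]


class ConfigError(ValueError):
    """Invalid configuration."""


#: Reference levels used throughout: the probit/count tables report factor
#: effects as discrete changes from these base categories.
DEFAULT_REFERENCE_LEVELS = {
    "wash": "none",
    "wealth": "rich",
    "education": "secondary+",
    "head_education": "secondary+",
    "residence": "urban",
    "region": "region_1",
    "ethnicity": "ethnic_1",
}

WASH_LEVELS = ["none", "dwelling+wash", "dwelling-only",
               "elsewhere+wash", "elsewhere-only"]

# Survey descriptive shares used as sampling defaults.  The WASH shares
# (2, 23.7, 9.5, 42, 23)% sum to 100.2% as printed and are renormalized.
_WASH_RAW = [0.02, 0.237, 0.095, 0.42, 0.23]
_WASH_PROBS = [p / sum(_WASH_RAW) for p in _WASH_RAW]


def _default_category_probabilities() -> dict[str, dict[str, float]]:
    return {
        "education": {"none": 0.29, "primary": 0.35, "secondary+": 0.36},
        "wealth": {"rich": 0.40, "middle": 0.20, "poor": 0.40},
        "wash": dict(zip(WASH_LEVELS, _WASH_PROBS)),
        "residence": {"urban": 0.40, "rural": 0.60},
        "head_education": {"none": 0.35, "primary": 0.33, "secondary+": 0.32},
        "region": {f"region_{k}": 0.2 for k in range(1, 6)},
        "ethnicity": {f"ethnic_{k}": 0.2 for k in range(1, 6)},
        "media_any": {"1": 0.78, "0": 0.22},
        "no_contraception": {"1": 0.38, "0": 0.62},
        "nicotine_or_alcohol": {"1": 0.75, "0": 0.25},
        "head_female": {"1": 0.25, "0": 0.75},
    }


def _default_sel_coefs() -> dict[str, float]:
    # Calibrated so the simulated MHM share is ~0.63 and the WASH
    # average marginal effects span roughly 0.3-0.55 probability points.
    return {
        "const": 0.0,
        "wash[dwelling+wash]": 1.45,
        "wash[dwelling-only]": 0.95,
        "wash[elsewhere+wash]": 1.30,
        "wash[elsewhere-only]": 0.90,
        "age_c": 0.012,
        "education[none]": -0.35,
        "education[primary]": -0.15,
        "wealth[middle]": -0.45,
        "wealth[poor]": -0.75,
        "residence[rural]": -0.15,
        "media_any": -0.18,
        "head_female": 0.28,
        "head_education[none]": -0.20,
        "head_education[primary]": -0.12,
        # head age is deliberately inert in both equations so that it is a
        # valid falsification outcome for the placebo harness
        "head_age_c": 0.0,
    }


def _default_out_coefs() -> dict[str, float]:
    return {
        "const": 1.08,
        "age_c": 0.05,
        "education[none]": -0.337,
        "education[primary]": -0.10,
        "wealth[middle]": -0.088,
        "wealth[poor]": -0.348,
        "no_contraception": 0.129,
        "head_female": 0.267,
        "head_education[none]": -0.108,
        "head_education[primary]": -0.055,
        "media_any": -0.030,
        "nicotine_or_alcohol": -0.028,
        "residence[rural]": 0.05,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic MICS-style survey.

    The selection equation is a probit: MHM = 1[x'a + eps >= 0] with
    eps ~ N(0,1).  The outcome is Poisson with log-mean
    x1'b + gamma*MHM + delta*eps; ``delta`` is the endogeneity loading
    E(e|eps) = delta*eps shared between the two equations.
    """

    n_individuals: int = 4989
    seed: int = 0
    category_probabilities: dict[str, dict[str, float]] = field(
        default_factory=_default_category_probabilities)
    age_range: tuple[int, int] = (15, 49)
    head_age_range: tuple[int, int] = (20, 80)
    sel_coefs: dict[str, float] = field(default_factory=_default_sel_coefs)
    out_coefs: dict[str, float] = field(default_factory=_default_out_coefs)
    gamma: float = 0.05
    delta: float = 0.3
    missing_rate: float = 0.05
    copula_rho: float = 0.0     # one-factor Gaussian copula; 0 = independent
    max_log_mean: float = 20.0  # overflow guard on the Poisson log-mean

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not (-1.0 < self.copula_rho < 1.0):
            raise ConfigError("copula_rho must lie in (-1, 1)")
        for name, probs in self.category_probabilities.items():
            vals = list(probs.values())
            if any(p < 0 for p in vals):
                raise ConfigError(f"negative probability in {name!r}")
            if not math.isclose(sum(vals), 1.0, abs_tol=1e-12):
                raise ConfigError(
                    f"probabilities for {name!r} sum to {sum(vals)!r}, not 1")
        lo, hi = self.age_range
        if not (lo < hi):
            raise ConfigError("age_range must be increasing")

    def binary_rate(self, name: str) -> float:
        return self.category_probabilities[name]["1"]


def default_simulation_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate or load, then estimate)."""

    input_path: str | None = None
    column_mapping: dict[str, str] = field(default_factory=dict)
    simulate: SimulationConfig | None = None
    bootstrap_reps: int = 500
    bootstrap_seed: int = 12345
    imputation_policy: str = "deterministic"   # or "stochastic"
    significance_level: float = 0.05
    output_dir: str = "mhmcf_run"
    subsamples: dict[str, str] = field(
        default_factory=lambda: {"young_15_29": "age <= 29",
                                 "rural": "residence == 'rural'"})
    placebo_outcome: str = "head_age"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of input_path / simulate block must be given")
        if self.imputation_policy not in ("deterministic", "stochastic"):
            raise ConfigError("imputation_policy must be "
                              "'deterministic' or 'stochastic'")
        if not (0 < self.significance_level < 1):
            raise ConfigError("significance_level must lie in (0, 1)")
        if self.bootstrap_reps < 0:
            raise ConfigError("bootstrap_reps must be >= 0")


def _as_tuple2(value) -> tuple[int, int]:
    a, b = value
    return (int(a), int(b))


def load_run_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; ``seed`` overrides the file's seeds."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulate" in raw:
        sim_raw = dict(raw.pop("simulate") or {})
        for key in ("age_range", "head_age_range"):
            if key in sim_raw:
                sim_raw[key] = _as_tuple2(sim_raw[key])
        sim = SimulationConfig(**sim_raw)
    cfg = RunConfig(simulate=sim, **raw)
    if seed is not None:
        if cfg.simulate is not None:
            cfg.simulate.seed = int(seed)
        cfg.bootstrap_seed = int(seed) + 1
    return cfg


def run_config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    return asdict(cfg)
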