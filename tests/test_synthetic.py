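"""Generator contracts: determinism, marginal calibration, the latent
selection mechanism and the closed-form conditional-mean oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from mhmcf import (SimulationConfig, apply_missingness, generate_covariates,
                   generate_outcome, generate_selection,
                   oracle_conditional_mean, simulate, split_visible)
from mhmcf.config import ConfigError

from conftest import make_complete_table


def binomial_3se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestCovariates:
    def test_identical_seed_gives_byte_identical_tables(self):
        a = simulate(SimulationConfig(seed=42))
        b = simulate(SimulationConfig(seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = simulate(SimulationConfig(seed=43))
        assert not c["ceb"].equals(a["ceb"])

    def test_single_row_is_complete(self):
        table = generate_covariates(SimulationConfig(n_individuals=1, seed=5))
        assert len(table) == 1
        assert not table.isna().any().any()

    def test_wealth_shares_match_configured_probabilities(self):
        cfg = SimulationConfig(n_individuals=10_000, seed=3)
        table = generate_covariates(cfg)
        shares = table["wealth"].value_counts(normalize=True)
        for level, p in {"rich": 0.40, "middle": 0.20, "poor": 0.40}.items():
            assert abs(shares[level] - p) < binomial_3se(p, 10_000)

    def test_invalid_probability_vector_names_variable(self):
        with pytest.raises(ConfigError, match="wealth"):
            SimulationConfig(category_probabilities={
                **SimulationConfig().category_probabilities,
                "wealth": {"rich": 0.5, "middle": 0.2, "poor": 0.2}})

    def test_age_within_bounds(self):
        table = generate_covariates(SimulationConfig(n_individuals=2000, seed=9))
        assert table["age"].between(15, 49).all()


class TestSelection:
    def test_zero_coefficients_give_half_probability(self):
        cfg = SimulationConfig(n_individuals=100_000, seed=21,
                               sel_coefs={"const": 0.0}, missing_rate=0.0)
        table = generate_selection(generate_covariates(cfg), cfg)
        assert abs(table["mhm"].mean() - 0.5) < binomial_3se(0.5, 100_000)

    def test_deep_negative_intercept_kills_selection(self):
        cfg = SimulationConfig(n_individuals=50_000, seed=22,
                               sel_coefs={"const": -10.0}, missing_rate=0.0)
        table = generate_selection(generate_covariates(cfg), cfg)
        assert table["mhm"].sum() == 0

    def test_mhm_mean_matches_probit_probability(self):
        """Empirical P(MHM=1) agrees with the mean of Phi(x'a) over rows."""
        table, cfg = make_complete_table(seed=23, n=50_000)
        expected = norm.cdf(table["sel_index"]).mean()
        se = np.sqrt(expected * (1 - expected) / len(table))
        assert abs(table["mhm"].mean() - expected) < 3 * se

    def test_mhm_equals_indicator_of_latent_sum(self):
        table, _ = make_complete_table(seed=24, n=2000)
        indicator = (table["sel_index"] + table["latent_epsilon"] >= 0)
        assert (table["mhm"] == indicator.astype(int)).all()

    def test_questionnaire_items_consistent_with_indicator(self):
        table, _ = make_complete_table(seed=25, n=2000)
        all_yes = ((table["q_privacy"] == "yes") & (table["q_materials"] == "yes")
                   & (table["q_reuse"] == "yes"))
        assert (all_yes == (table["mhm"] == 1)).all()

    def test_unknown_covariate_name_errors(self):
        cfg = SimulationConfig(sel_coefs={"const": 0.0, "no_such": 1.0})
        with pytest.raises(ConfigError, match="no_such"):
            generate_selection(generate_covariates(cfg), cfg)


class TestOutcome:
    def test_pure_poisson_mean(self):
        cfg = SimulationConfig(n_individuals=50_000, seed=31, delta=0.0,
                               gamma=0.0, out_coefs={"const": np.log(2.0)},
                               missing_rate=0.0)
        table = generate_outcome(generate_selection(
            generate_covariates(cfg), cfg), cfg)
        se = np.sqrt(2.0 / 50_000)  # Poisson variance = mean
        assert abs(table["ceb"].mean() - 2.0) < 3 * se
        assert (table["ceb"] >= 0).all()
        assert (table["ceb"] == table["ceb"].astype(int)).all()

    def test_outcome_requires_selection_first(self):
        cfg = SimulationConfig(n_individuals=100, seed=32)
        with pytest.raises(ConfigError, match="selection"):
            generate_outcome(generate_covariates(cfg), cfg)

    def test_overflow_guard_rejects_extreme_log_mean(self):
        cfg = SimulationConfig(n_individuals=100, seed=33,
                               out_coefs={"const": 25.0})
        with pytest.raises(ConfigError, match="overflow|log-mean"):
            generate_outcome(generate_selection(
                generate_covariates(cfg), cfg), cfg)

    def test_cell_means_match_oracle(self):
        """Simulated (wash, MHM) cell means agree with the closed-form
        conditional mean within 4 cell standard errors."""
        cfg = SimulationConfig(
            n_individuals=120_000, seed=34, delta=0.5, gamma=0.05,
            sel_coefs={"const": -0.3, "wash[dwelling+wash]": 1.0,
                       "wash[elsewhere+wash]": 0.6},
            out_coefs={"const": 0.7}, missing_rate=0.0)
        table = generate_outcome(generate_selection(
            generate_covariates(cfg), cfg), cfg)
        for (wash, mhm), cell in table.groupby(["wash", "mhm"]):
            if len(cell) < 1000:
                continue
            oracle = oracle_conditional_mean(
                cell["sel_index"].iloc[0], int(mhm), 0.7, 0.05, 0.5)
            tol = 4 * cell["ceb"].std() / np.sqrt(len(cell))
            assert abs(cell["ceb"].mean() - oracle) < tol, (wash, mhm)


class TestOracle:
    def test_no_endogeneity_reduces_to_plain_exponential(self):
        for mhm in (0, 1):
            assert oracle_conditional_mean(0.7, mhm, 0.2, 0.05, 0.0) == \
                pytest.approx(np.exp(0.2 + 0.05 * mhm), rel=1e-12)

    def test_direct_evaluation_and_quadrature(self):
        value = oracle_conditional_mean(0.0, 1, 0.0, 0.0, 0.3)
        assert value == pytest.approx(np.exp(0.045) * norm.cdf(0.3) / 0.5,
                                      rel=1e-12)
        integral, _ = quad(lambda e: np.exp(0.3 * e) * norm.pdf(e), 0, np.inf)
        assert value == pytest.approx(integral / 0.5, rel=1e-8)

    def test_reflection_symmetry(self):
        for z in (-1.5, -0.3, 0.0, 0.8, 2.0):
            a = oracle_conditional_mean(z, 1, 0.0, 0.0, 0.4)
            b = oracle_conditional_mean(-z, 0, 0.0, 0.0, -0.4)
            assert a == pytest.approx(b, rel=1e-12)


class TestMissingness:
    def test_missing_count_near_configured_rate(self):
        table, cfg = make_complete_table(seed=41, n=10_000)
        cfg.missing_rate = 0.05
        out = apply_missingness(table, cfg)
        assert abs(out["mhm"].isna().sum() - 500) < 3 * np.sqrt(500 * 0.95)
        assert (out.loc[out["mhm"].isna(), "mhm_missing"] == 1).all()

    def test_zero_rate_leaves_table_unchanged(self):
        table, cfg = make_complete_table(seed=42, n=500)
        cfg.missing_rate = 0.0
        out = apply_missingness(table, cfg)
        assert out["mhm"].notna().all()
        assert (out["mhm"] == table["mhm"]).all()

    def test_same_seed_same_missing_set(self):
        table, cfg = make_complete_table(seed=43, n=5000)
        cfg.missing_rate = 0.07
        a = apply_missingness(table, cfg)
        b = apply_missingness(table, cfg)
        assert (a["mhm"].isna() == b["mhm"].isna()).all()

    def test_missingness_stream_does_not_perturb_outcome(self):
        """Per-stage random streams: toggling missingness leaves every
        other generated column untouched."""
        base = simulate(SimulationConfig(seed=44))
        off = simulate(SimulationConfig(seed=44, missing_rate=0.0))
        assert (base["ceb"] == off["ceb"]).all()
        assert np.allclose(base["latent_epsilon"], off["latent_epsilon"])


class TestExport:
    def test_truth_columns_split_out(self, survey_default, tmp_path):
        visible, truth = split_visible(survey_default)
        assert {"latent_epsilon", "sel_index", "true_mean"}.isdisjoint(
            visible.columns)
        assert "latent_epsilon" in truth.columns
        from mhmcf import write_csv
        write_csv(survey_default, tmp_path / "s.csv")
        assert (tmp_path / "s.csv").exists()
        assert (tmp_path / "s.truth.csv").exists()
        loaded = pd.read_csv(tmp_path / "s.csv")
        assert "latent_epsilon" not in loaded.columns

    def test_invalid_missing_rate_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(missing_rate=1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(n_individuals=0)
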