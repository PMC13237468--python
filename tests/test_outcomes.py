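"""Second-stage estimators against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mhmcf import (BootstrapConfig, ModelRoles, endogeneity_test, fit_cf_2sri,
                   fit_negbin, fit_ols, fit_poisson, irr_percent)

from conftest import make_complete_table


def tiny_roles(exogenous=()):
    return ModelRoles(outcome="y", endogenous="d",
                      excluded_instruments=["z"], exogenous=list(exogenous))


def newton_poisson(x, y, tol=1e-12, iters=200):
    """Independent Newton solver for the Poisson score equations."""
    beta = np.zeros(x.shape[1])
    for _ in range(iters):
        mu = np.exp(x @ beta)
        score = x.T @ (y - mu)
        hess = x.T @ (mu[:, None] * x)
        step = np.linalg.solve(hess, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestPoisson:
    def test_intercept_only_closed_form(self):
        """The intercept-only Poisson MLE is exactly log(ybar)."""
        y = np.repeat([1.0, 2.0], [30, 70])  # mean 1.7
        beta = newton_poisson(np.ones((100, 1)), y)
        assert beta[0] == pytest.approx(np.log(1.7), abs=1e-10)
        # and the fitted GLM reproduces the sample mean exactly
        table = pd.DataFrame({"y": y, "d": [0, 1] * 50,
                              "z": [0, 0, 1, 1] * 25})
        fit = fit_poisson(table, tiny_roles())
        assert fit.fitted_mean.mean() == pytest.approx(1.7, rel=1e-10)

    def test_five_row_fit_matches_newton_oracle(self):
        table = pd.DataFrame({"y": [0, 1, 2, 3, 5],
                              "d": [0, 0, 1, 1, 1],
                              "z": [0, 1, 0, 1, 1]})
        fit = fit_poisson(table, tiny_roles())
        x = np.column_stack([np.ones(5), table["d"]])
        oracle = newton_poisson(x, table["y"].to_numpy(dtype=float))
        assert np.allclose(fit.coefs.to_numpy(), oracle, atol=1e-8)

    def test_gamma_consistent_under_exogeneity(self, roles):
        table, _ = make_complete_table(seed=201, n=50_000, delta=0.0,
                                       gamma=0.05)
        fit = fit_poisson(table, roles)
        se = float(np.sqrt(fit.vcov_naive.loc["mhm", "mhm"]))
        assert abs(fit.coefs["mhm"] - 0.05) < 3 * se

    def test_mean_reproduction_identity(self, roles):
        """With an intercept the Poisson score equations force the fitted
        means to reproduce the outcome total."""
        table, _ = make_complete_table(seed=202, n=4000)
        fit = fit_poisson(table, roles)
        total = table["ceb"].sum()
        assert abs(fit.fitted_mean.sum() - total) < 1e-6 * total

    def test_rejects_negative_or_fractional_outcomes(self):
        table = pd.DataFrame({"y": [0.5, 1, 2, 1], "d": [0, 1, 0, 1],
                              "z": [0, 0, 1, 1]})
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson(table, tiny_roles())


class TestNegbin:
    def test_alpha_vanishes_on_poisson_data(self, roles):
        table, _ = make_complete_table(seed=203, n=50_000, delta=0.0)
        fit = fit_negbin(table, roles)
        assert fit.nb_alpha < 0.01
        assert fit.equidispersion_p > 0.01

    def test_alpha_recovered_from_nb2_data(self):
        """NB2 mixture simulation: y | g ~ Poisson(mu*g), g ~ Gamma(1/a, a)
        gives var = mu + a*mu^2; the MLE must recover a = 0.5."""
        rng = np.random.default_rng(7)
        n = 50_000
        x = rng.binomial(1, 0.5, n)
        mu = np.exp(0.5 + 0.4 * x)
        g = rng.gamma(shape=2.0, scale=0.5, size=n)  # mean 1, var 0.5
        y = rng.poisson(mu * g)
        table = pd.DataFrame({"y": y, "d": x, "z": rng.binomial(1, 0.5, n)})
        fit = fit_negbin(table, tiny_roles())
        assert fit.nb_alpha == pytest.approx(0.5, abs=0.03)
        assert fit.equidispersion_p < 1e-6

    def test_poisson_nested_at_zero_alpha(self):
        """NB2 log-likelihood at the Poisson MLE with alpha -> 0 equals the
        Poisson log-likelihood.  Evaluated through the product form
        sum_k log(1 + alpha*k) - (y + 1/alpha) log(1 + alpha*mu)
        + y log(mu) - log(y!), which is exact for integer counts and does
        not suffer the gammaln(1/alpha) cancellation at tiny alpha."""
        from scipy.special import gammaln

        rng = np.random.default_rng(11)
        n = 2000
        x = rng.binomial(1, 0.4, n)
        y = rng.poisson(np.exp(0.3 + 0.2 * x))
        design = np.column_stack([np.ones(n), x])
        beta = newton_poisson(design, y.astype(float))
        mu = np.exp(design @ beta)
        poisson_ll = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))

        def nb2_ll(alpha):
            total = 0.0
            for yi, mi in zip(y, mu):
                total += (sum(np.log1p(alpha * k) for k in range(int(yi)))
                          - (yi + 1 / alpha) * np.log1p(alpha * mi)
                          + yi * np.log(mi) - gammaln(yi + 1))
            return total

        assert nb2_ll(1e-10) == pytest.approx(poisson_ll, abs=1e-4)
        # and the likelihood is continuous in alpha near the boundary
        assert nb2_ll(1e-8) == pytest.approx(poisson_ll, abs=1e-3)


class TestOls:
    def test_exact_linear_outcome_has_zero_rss(self):
        table = pd.DataFrame({"d": [0, 1, 0, 1, 1, 0],
                              "z": [0, 0, 1, 1, 0, 1]})
        table["y"] = 2.0 + 3.0 * table["d"]
        fit = fit_ols(table, tiny_roles())
        rss = np.sum((table["y"].to_numpy() - fit.fitted_mean) ** 2)
        assert rss < 1e-20

    def test_four_point_normal_equations(self):
        table = pd.DataFrame({"y": [1.0, 2.0, 2.5, 4.0],
                              "d": [0, 1, 0, 1], "z": [0, 0, 1, 1]})
        fit = fit_ols(table, tiny_roles())
        x = np.column_stack([np.ones(4), table["d"]])
        oracle = np.linalg.solve(x.T @ x, x.T @ table["y"].to_numpy())
        assert np.allclose(fit.coefs.to_numpy(), oracle, atol=1e-12)


class TestIrr:
    @pytest.mark.parametrize("coef,expected", [
        (0.044, 4.5), (0.0, 0.0), (-0.337, -28.6), (np.log(2), 100.0)])
    def test_percentage_transform(self, coef, expected):
        assert round(irr_percent(coef), 1) == expected

    def test_monotone(self):
        grid = np.linspace(-1, 1, 41)
        vals = [irr_percent(c) for c in grid]
        assert (np.diff(vals) > 0).all()


class TestCf2sri:
    def test_zeroed_residual_collapses_to_naive(self, roles):
        table, _ = make_complete_table(seed=204, n=3000)
        naive = fit_poisson(table, roles)
        forced = fit_poisson(table, roles, m_hat=np.zeros(len(table)))
        common = naive.coefs.index
        assert np.allclose(forced.coefs[common], naive.coefs[common],
                           atol=1e-8)
        assert abs(forced.coefs["m_hat"]) < 1e-8

    def test_bootstrap_vcov_is_seed_deterministic(self, roles):
        table, _ = make_complete_table(seed=205, n=1200)
        boot = BootstrapConfig(reps=25, seed=99)
        _, _, a = fit_cf_2sri(table, roles, bootstrap=boot)
        _, _, b = fit_cf_2sri(table, roles, bootstrap=boot)
        pd.testing.assert_frame_equal(a.vcov_bootstrap, b.vcov_bootstrap)
        assert a.n_boot == 25
        assert a.boot_percentile_ci is not None

    def test_endogeneity_test_reads_residual_term(self, roles):
        table, _ = make_complete_table(seed=206, n=5000, delta=0.5)
        _, _, count = fit_cf_2sri(table, roles)
        z, p = endogeneity_test(count)
        assert p < 0.01  # strong endogeneity is detected
        naive = fit_poisson(table, roles)
        with pytest.raises(ValueError, match="residual"):
            endogeneity_test(naive)

    def test_2sri_approximation_improves_as_delta_shrinks(self, roles):
        """The gap between the 2SRI plug-in mean and the exact conditional
        mean shrinks monotonically as the endogeneity loading |delta|
        decreases."""
        from mhmcf import oracle_conditional_mean

        gaps = []
        for delta in (0.6, 0.3, 0.1, 0.0):
            table, cfg = make_complete_table(seed=207, n=20_000, delta=delta)
            _, resid, count = fit_cf_2sri(table, roles)
            oracle = oracle_conditional_mean(
                table["sel_index"], table["mhm"], table["out_index"],
                cfg.gamma, delta)
            gaps.append(float(np.mean(np.abs(count.fitted_mean - oracle)
                                      / oracle)))
        assert all(a >= b - 0.004 for a, b in zip(gaps, gaps[1:]))
        assert gaps[0] > gaps[-1]
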