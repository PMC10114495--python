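"""Two-latent-state NB model: pmf, predicted means, moments, EM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from crispra_context import (NBFit, nb_log_pmf, predicted_mean,
                             class_moments, em_fit, simulate_nb_cells)
from crispra_context.scsim import _nb_draws

TOTAL_UMI = (np.log(10_000.0), 0.3)


def _fit(beta0=-13.49, beta_act=3.94, theta=1.0, pi=0.5):
    return NBFit(classes=["c1"], beta0={"c1": beta0},
                 beta_act={"c1": beta_act}, theta={"c1": theta},
                 pi={"c1": pi})


class TestLogPmf:
    def test_normalization(self):
        y = np.arange(0, 1001)
        total = np.exp(nb_log_pmf(y, 5.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit(self):
        """theta = 1e6 matches Poisson(5) within 1e-4 per point across the
        support carrying essentially all of the mass (the exact NB-Poisson
        gap grows like (y - mu)^2 / 2 theta in the far tail)."""
        y = np.arange(0, 20)
        nb = nb_log_pmf(y, 5.0, 1e6)
        po = stats.poisson.logpmf(y, 5.0)
        assert stats.poisson.cdf(y[-1], 5.0) > 1 - 1e-6
        assert np.abs(nb - po).max() < 1e-4

    def test_matches_extended_precision_oracle(self):
        """Direct gamma-function evaluation in 50-digit arithmetic."""
        import sympy
        y, mu, theta = 3, sympy.Rational(5, 2), sympy.Rational(17, 10)
        expr = (sympy.loggamma(y + theta) - sympy.loggamma(theta)
                - sympy.loggamma(y + 1)
                + theta * sympy.log(theta / (theta + mu))
                + y * sympy.log(mu / (theta + mu)))
        expected = float(sympy.N(expr, 50))
        got = float(nb_log_pmf(np.array([3]), 2.5, 1.7)[0])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError):
            nb_log_pmf(np.array([1.5]), 2.0, 1.0)

    def test_matches_scipy_parameterization(self):
        """Cross-check against scipy's NB with n=theta, p=theta/(theta+mu)."""
        y = np.arange(0, 30)
        for mu, theta in [(0.01, 0.5), (5.0, 2.0), (100.0, 10.0)]:
            ours = nb_log_pmf(y, mu, theta)
            ref = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
            assert np.allclose(ours, ref, atol=1e-10)


class TestPredictedMean:
    def test_worked_example_basal(self):
        assert predicted_mean(_fit(), "c1", "basal", 10_000) \
            == pytest.approx(0.014, abs=5e-4)

    def test_worked_example_active(self):
        assert predicted_mean(_fit(), "c1", "active", 10_000) \
            == pytest.approx(0.71, abs=5e-3)

    def test_identity_at_zero_coefficients(self):
        fit = _fit(beta0=0.0, beta_act=0.0)
        assert predicted_mean(fit, "c1", "basal", 1) == pytest.approx(1.0)
        assert predicted_mean(fit, "c1", "active", 1) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            predicted_mean(_fit(), "c1", "basal", 0)
        with pytest.raises(ValueError):
            predicted_mean(_fit(), "nope", "basal", 10)


class TestClassMoments:
    def test_degenerate_mixtures(self):
        mb = predicted_mean(_fit(), "c1", "basal", 10_000)
        ma = predicted_mean(_fit(), "c1", "active", 10_000)
        mean0, var0 = class_moments(_fit(pi=0.0), "c1", 10_000)
        assert mean0 == pytest.approx(mb)
        assert var0 == pytest.approx(mb + mb ** 2 / 1.0)
        mean1, _ = class_moments(_fit(pi=1.0), "c1", 10_000)
        assert mean1 == pytest.approx(ma)

    def test_monte_carlo_oracle(self):
        """Mixture mean/variance match 10^6 simulated draws within 3 se."""
        rng = np.random.default_rng(8)
        n = 1_000_000
        fit = _fit(theta=1.0, pi=0.5)
        active = rng.random(n) < 0.5
        mu = np.where(active,
                      predicted_mean(fit, "c1", "active", 10_000),
                      predicted_mean(fit, "c1", "basal", 10_000))
        draws = _nb_draws(rng, mu, np.ones(n))
        mean, var = class_moments(fit, "c1", 10_000)
        assert mean == pytest.approx(draws.mean(),
                                     abs=3 * np.sqrt(var / n))
        m4 = ((draws - draws.mean()) ** 4).mean()
        se_var = np.sqrt(max(m4 - var ** 2, 0) / n)
        assert var == pytest.approx(draws.var(), abs=3 * se_var)


class TestEMFit:
    def test_all_control_equals_single_state_nb(self):
        """With every cell anchored basal the EM reduces to a plain
        one-state NB regression (statsmodels as the independent route)."""
        cells = simulate_nb_cells({"c": -6.0}, {"c": 0.0}, {"c": 2.0},
                                  {"c": 0.0}, 0, 2_000, TOTAL_UMI, seed=3)
        fit = em_fit(cells)
        y = cells.y.to_numpy()
        X = np.ones((len(cells), 1))
        sm_fit = sm.NegativeBinomial(
            y, X, offset=np.log(cells.N.to_numpy()),
            loglike_method="nb2").fit(disp=0)
        assert fit.pi["c"] == 0.0
        assert fit.beta0["c"] == pytest.approx(sm_fit.params[0], abs=1e-4)
        assert fit.theta["c"] == pytest.approx(1 / sm_fit.params[1],
                                               rel=1e-3)

    def test_loglik_monotone_and_labels(self):
        cells = simulate_nb_cells({"c": -13.5}, {"c": 3.9}, {"c": 0.5},
                                  {"c": 0.4}, 400, 2_000, TOTAL_UMI, seed=5)
        fit = em_fit(cells)
        ll = np.array(fit.loglik_trace)
        assert np.all(np.diff(ll) >= -1e-6 * np.maximum(1, np.abs(ll[:-1])))
        # "active" is the higher-mean state by construction
        assert fit.beta_act["c"] >= 0
        r = fit.responsibilities
        assert ((r >= 0) & (r <= 1)).all()
        ctrl = cells.set_index("cell_id").is_control
        assert (r[ctrl.values] == 0).all()

    def test_responsibilities_separate_true_states(self):
        """At a well-separated point (active mean ~5.5 counts vs basal
        ~0.014) posterior responsibilities recover the latent states."""
        cells = simulate_nb_cells({"c": -13.5}, {"c": 6.0}, {"c": 2.0},
                                  {"c": 0.4}, 600, 2_000, TOTAL_UMI, seed=6)
        fit = em_fit(cells)
        truth = cells.set_index("cell_id").true_active
        on = ~cells.set_index("cell_id").is_control
        r = fit.responsibilities[on.values]
        t = truth[on.values]
        assert r[t].mean() > 0.8
        assert r[~t].mean() < 0.2

    def test_poisson_limit_matches_poisson_mixture_oracle(self):
        """With large fixed dispersion the NB-EM agrees with an
        independent two-state Poisson-mixture EM on the same data."""
        cells = simulate_nb_cells({"c": -9.0}, {"c": 2.5}, {"c": 1e6},
                                  {"c": 0.4}, 800, 800, TOTAL_UMI, seed=7)
        fit = em_fit(cells, fix_theta=1e6)

        y = cells.y.to_numpy()
        N = cells.N.to_numpy(dtype=float)
        ctrl = cells.is_control.to_numpy()
        # oracle: EM for a mixture of Poissons with offset, rates mu*N
        lam_b, lam_a, pi = y[ctrl].sum() / N[ctrl].sum() + 1e-12, None, 0.5
        lam_a = 5 * lam_b
        for _ in range(2_000):
            lb = stats.poisson.logpmf(y, lam_b * N)
            la = stats.poisson.logpmf(y, lam_a * N)
            with np.errstate(divide="ignore"):
                num = np.log(pi) + la
                den = np.logaddexp(num, np.log1p(-pi) + lb)
            r = np.exp(num - den)
            r[ctrl] = 0.0
            lam_b = ((1 - r) * y).sum() / ((1 - r) * N).sum()
            lam_a = (r * y).sum() / max((r * N).sum(), 1e-300)
            pi = r[~ctrl].mean()
        assert fit.beta0["c"] == pytest.approx(np.log(lam_b), abs=1e-3)
        assert fit.beta_act["c"] == pytest.approx(
            np.log(lam_a) - np.log(lam_b), abs=1e-3)
        assert fit.pi["c"] == pytest.approx(pi, abs=1e-3)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            em_fit(pd.DataFrame({"y": [1, 2]}))

    def test_small_class_rejected(self):
        cells = pd.DataFrame({"cell_id": ["a"], "class_label": ["c"],
                              "y": [1], "N": [100], "is_control": [False]})
        with pytest.raises(ValueError):
            em_fit(cells)
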