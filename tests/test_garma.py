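"""GARMA design, recursion, likelihood fitting and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from porpoisepam import garma


@pytest.fixture(scope="module")
def design_5000():
    ts = pd.date_range("2015-01-01", periods=5000, freq="h")
    X, names = garma.harmonic_design(ts)
    return ts, X, names


class TestHarmonicDesign:
    def test_unit_circle_values(self):
        ts = pd.to_datetime(["2015-06-01 00:00", "2015-06-01 06:00"])
        X, names = garma.harmonic_design(ts, terms=("hour",))
        assert names == ["intercept", "sin_hour", "cos_hour"]
        np.testing.assert_allclose(X[0], [1.0, 0.0, 1.0], atol=1e-12)  # t=0
        np.testing.assert_allclose(X[1], [1.0, 1.0, 0.0], atol=1e-12)  # t=6

    def test_julian_day_periodicity(self, design_5000):
        # day 365 of a 365-day year wraps onto (sin, cos) = (0, 1)
        ts = pd.to_datetime(["2015-12-31 00:00"])
        X, _ = garma.harmonic_design(ts, terms=("jday",))
        np.testing.assert_allclose(X[0, 1:], [0.0, 1.0], atol=1e-12)

    def test_sin_cos_pairs_on_unit_circle(self, design_5000):
        _, X, _ = design_5000
        np.testing.assert_allclose(X[:, 1] ** 2 + X[:, 2] ** 2, 1.0, atol=1e-12)
        np.testing.assert_allclose(X[:, 3] ** 2 + X[:, 4] ** 2, 1.0, atol=1e-12)


class TestMeanRecursion:
    def test_pure_glm_with_empty_sums(self):
        X = np.column_stack([np.ones(10), np.linspace(-1, 1, 10)])
        beta = np.array([0.5, 1.2])
        y = np.arange(10, dtype=float)
        mu = garma.garma_mean_recursion(y, X, beta)
        np.testing.assert_allclose(mu, np.exp(X @ beta), rtol=1e-12)

    def test_zero_feedback_equals_glm(self):
        X = np.column_stack([np.ones(20), np.sin(np.arange(20.0))])
        beta = np.array([0.3, 0.7])
        y = np.ones(20)
        mu0 = garma.garma_mean_recursion(y, X, beta)
        mu1 = garma.garma_mean_recursion(y, X, beta, phi=[0.0], theta=[0.0])
        np.testing.assert_allclose(mu0, mu1, rtol=1e-12)

    def test_ar1_hand_unrolled_five_steps(self):
        """Spreadsheet-style unrolling of the AR(1) recursion."""
        y = np.array([2.0, 0.0, 3.0, 1.0, 4.0])
        X = np.ones((5, 1))
        beta, phi, c = np.array([0.5]), 0.6, 0.1
        mu = garma.garma_mean_recursion(y, X, beta, phi=[phi], c=c)
        expected = []
        for t in range(5):
            eta = 0.5
            if t >= 1:
                eta += phi * (np.log(max(y[t - 1], c)) - 0.5)
            expected.append(np.exp(eta))
        np.testing.assert_allclose(mu, expected, rtol=1e-12)

    def test_ma1_matches_sequential_oracle(self):
        y = np.array([2.0, 0.0, 3.0, 1.0, 4.0])
        X = np.ones((5, 1))
        beta, theta, c = np.array([0.5]), 0.4, 0.1
        mu = garma.garma_mean_recursion(y, X, beta, theta=[theta], c=c)
        g = []
        for t in range(5):
            eta = 0.5
            if t >= 1:
                eta += theta * (np.log(max(y[t - 1], c)) - g[t - 1])
            g.append(eta)
        np.testing.assert_allclose(mu, np.exp(g), rtol=1e-12)

    def test_gap_restarts_recursion(self):
        y = np.array([5.0, 5.0, 5.0, 5.0])
        X = np.ones((4, 1))
        beta = np.array([0.2])
        seg = np.array([0, 0, 1, 1])
        mu = garma.garma_mean_recursion(y, X, beta, phi=[0.5], segment_ids=seg)
        # position 2 starts a new segment: no lag available, pure GLM value
        assert mu[2] == pytest.approx(np.exp(0.2))
        assert mu[1] != pytest.approx(np.exp(0.2))
        # its continuation inside the new segment matches the first segment's
        assert mu[3] == pytest.approx(mu[1])


class TestFitting:
    def test_glm_limit_matches_statsmodels_irls(self, design_5000):
        """With p = q = 0 the GARMA likelihood is a Poisson GLM."""
        sm = pytest.importorskip("statsmodels.api")
        _, X, _ = design_5000
        beta = np.array([0.8, 0.4, -0.3, 0.5, 0.6])
        y = garma.simulate_garma(X, beta, dist="poisson", rng=1)
        fit = garma.fit_garma(y, X, dist="poisson", n_restarts=1)
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-4)

    def test_poisson_garma_recovery_single_seed(self, design_5000):
        _, X, _ = design_5000
        beta = np.array([0.8, 0.4, -0.3, 0.5, 0.6])
        y = garma.simulate_garma(X, beta, phi=[0.3], dist="poisson", rng=5)
        fit = garma.fit_garma(y, X, dist="poisson", p=1, n_restarts=2, seed=0)
        assert fit.converged
        truth = np.append(beta, 0.3)
        assert np.all(np.abs(fit.params - truth) <= 4.0 * fit.se)

    def test_pig_sigma_recovery(self, design_5000):
        _, X, _ = design_5000
        beta = np.array([1.2, 0.3, -0.2, 0.4, 0.5])
        y = garma.simulate_garma(X, beta, dist="pig", sigma=0.5, rng=11)
        fit = garma.fit_garma(y, X, dist="pig", n_restarts=1, compute_residuals=False)
        assert fit.sigma == pytest.approx(0.5, rel=0.25)

    def test_zip_pi_recovery(self, design_5000):
        _, X, _ = design_5000
        beta = np.array([1.0, 0.2, -0.2, 0.3, 0.4])
        y = garma.simulate_garma(X, beta, dist="zip", pi=0.3, rng=13)
        fit = garma.fit_garma(y, X, dist="zip", n_restarts=1, compute_residuals=False)
        assert fit.pi == pytest.approx(0.3, abs=0.05)

    def test_aic_definition_counts_all_free_parameters(self, design_5000):
        _, X, _ = design_5000
        y = garma.simulate_garma(X, np.array([1.0, 0.2, 0.1, 0.2, 0.1]), dist="poisson", rng=3)
        fit = garma.fit_garma(y, X, dist="pig", p=1, q=1, n_restarts=1, compute_residuals=False)
        assert fit.n_params == 5 + 1 + 1 + 1
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_all_zero_series_raises(self):
        X = np.ones((100, 1))
        with pytest.raises(ValueError, match="all-zero"):
            garma.fit_garma(np.zeros(100), X)

    def test_too_few_observations_raises(self):
        X = np.ones((20, 1))
        with pytest.raises(ValueError, match="at least 50"):
            garma.fit_garma(np.ones(20), X)

    def test_hour_shift_by_full_period_leaves_fit_unchanged(self):
        ts = pd.date_range("2015-01-01", periods=600, freq="h")
        X, _ = garma.harmonic_design(ts, terms=("hour",))
        beta = np.array([1.0, 0.5, 0.3])
        y = garma.simulate_garma(X, beta, dist="poisson", rng=21)
        Xs, _ = garma.harmonic_design(ts + pd.Timedelta(hours=24), terms=("hour",))
        f1 = garma.fit_garma(y, X, n_restarts=1, compute_residuals=False)
        f2 = garma.fit_garma(y, Xs, n_restarts=1, compute_residuals=False)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)


class TestSelectionAndDiagnostics:
    def test_aic_select_minimum_and_tiebreak(self):
        def stub(aic, k):
            f = garma.GarmaFit(
                dist="poisson", p=0, q=0, beta=np.zeros(1), phi=np.empty(0),
                theta=np.empty(0), sigma=None, pi=None, mu=np.ones(1),
                loglik=0.0, aic=aic, n_params=k, converged=True, se=np.zeros(1),
            )
            return f

        fits = [stub(100.0, 6), stub(100.0, 5), stub(120.0, 2)]
        assert garma.aic_select(fits).n_params == 5
        assert garma.aic_select([fits[2]]) is fits[2]
        with pytest.raises(ValueError):
            garma.aic_select([])

    def test_acf_of_ar1_series_estimates_phi(self):
        rng = np.random.default_rng(0)
        phi = 0.6
        x = np.zeros(20_000)
        for t in range(1, len(x)):
            x[t] = phi * x[t - 1] + rng.normal()
        assert garma.acf(x, 1)[0] == pytest.approx(phi, abs=0.03)
        # PACF of an AR(1) cuts off after lag 1
        assert abs(garma.pacf(x, 3)[2]) < 0.03

    def test_acf_pacf_match_statsmodels(self):
        smt = pytest.importorskip("statsmodels.tsa.stattools")
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        np.testing.assert_allclose(garma.acf(x, 10), smt.acf(x, nlags=10)[1:], atol=1e-8)
        np.testing.assert_allclose(
            garma.pacf(x, 10), smt.pacf(x, nlags=10, method="ywm")[1:], atol=1e-6
        )

    def test_white_noise_residual_diagnostics(self, design_5000):
        """A correctly specified model leaves ~5% of ACF lags outside the band."""
        _, X, _ = design_5000
        beta = np.array([1.0, 0.3, -0.2, 0.4, 0.5])
        outside = []
        for seed in range(5):
            y = garma.simulate_garma(X, beta, dist="poisson", rng=100 + seed)
            fit = garma.fit_garma(y, X, dist="poisson", n_restarts=1, seed=seed)
            diag = garma.residual_diagnostics(fit, max_lag=40)
            assert not diag["degenerate"]
            outside.append(np.sum(np.abs(diag["acf"]) > diag["band"]))
        assert np.mean(outside) <= 3.0  # <= ~7.5% of 40 lags on average

    def test_constant_residuals_flagged(self):
        fit = garma.GarmaFit(
            dist="poisson", p=0, q=0, beta=np.zeros(1), phi=np.empty(0),
            theta=np.empty(0), sigma=None, pi=None, mu=np.ones(5),
            loglik=0.0, aic=0.0, n_params=1, converged=True, se=np.zeros(1),
            quantile_residuals=np.ones(100),
        )
        diag = garma.residual_diagnostics(fit)
        assert diag["degenerate"]
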