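"""Dispersion estimators, trend models, diagnostics and shrinkage."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dispvar import (DispersionTrend, ShrinkageConfig, SimulationSpec,
                     adjusted_profile_loglik, evaluate_trend, fit_trend,
                     gamma_loglinear_fit, genewise_phi_mle,
                     genewise_phi_mle_matrix, mom_dispersion,
                     mom_dispersion_matrix, simulate_single_group,
                     simulate_two_group, tagwise_shrink)
from dispvar.dispersion import apl_values, estimate_pi, profile_loglik
from dispvar.nbcore import design_two_group, make_offsets, nb_loglik


def _mom_reference(y):
    y = np.asarray(y, dtype=float)
    m = y.mean()
    return sum((v - m) ** 2 - m for v in y) / (len(y) * m * m)


class TestMomDispersion:
    def test_printed_formula_examples(self):
        assert mom_dispersion([5, 15]) == pytest.approx(0.15)
        # equal counts: negative (underdispersed relative to Poisson)
        assert mom_dispersion([10, 10, 10, 10]) == pytest.approx(-0.1)
        assert np.isnan(mom_dispersion([0, 0]))

    def test_matches_independent_reimplementation(self, rng):
        for _ in range(1000):
            y = rng.integers(0, 60, size=rng.integers(2, 9))
            if y.mean() == 0:
                continue
            assert mom_dispersion(y) == pytest.approx(_mom_reference(y),
                                                      rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2,
                    max_size=12))
    def test_formula_identity_for_any_counts(self, y):
        if sum(y) == 0:
            assert np.isnan(mom_dispersion(y))
        else:
            assert mom_dispersion(y) == pytest.approx(_mom_reference(y),
                                                      rel=1e-10, abs=1e-12)

    def test_matrix_agrees_with_scalar(self, rng):
        counts = rng.integers(0, 40, size=(50, 6))
        vals = mom_dispersion_matrix(counts)
        for i in range(50):
            if counts[i].mean() > 0:
                assert vals[i] == pytest.approx(mom_dispersion(counts[i]))
            else:
                assert np.isnan(vals[i])

    def test_consistency_under_nb_sampling(self, rng):
        phi, mu, n = 0.4, 100.0, 20000
        size = 1 / phi
        y = rng.negative_binomial(size, size / (size + mu), size=n)
        assert mom_dispersion(y) == pytest.approx(phi, rel=0.1)


class TestGenewiseMle:
    def test_equidispersed_data_hits_poisson_boundary(self, rng):
        y = rng.poisson(50, size=40)
        X = np.ones((40, 1))
        assert genewise_phi_mle(y, X, np.zeros(40)) == pytest.approx(0.0,
                                                                    abs=1e-4)

    def test_recovery_at_large_n(self):
        g = np.random.default_rng(5)
        phi, mu = 0.5, 100.0
        size = 1 / phi
        y = g.negative_binomial(size, size / (size + mu), size=200)
        est = genewise_phi_mle(y, np.ones((200, 1)), np.zeros(200))
        assert 0.4 < est < 0.6

    def test_within_group_permutation_invariance(self, rng):
        y = rng.negative_binomial(5, 0.1, size=8).astype(float)
        X = design_two_group([1, 1, 1, 1, 2, 2, 2, 2])
        base = genewise_phi_mle(y, X, np.zeros(8))
        yp = y.copy()
        yp[[0, 3]] = yp[[3, 0]]
        yp[[5, 6]] = yp[[6, 5]]
        assert genewise_phi_mle(yp, X, np.zeros(8)) == pytest.approx(base,
                                                                    rel=1e-4)

    def test_matrix_grid_agrees_with_scalar_optimizer(self, rng):
        counts = rng.negative_binomial(4, 0.05, size=(30, 10)).astype(float)
        X = np.ones((10, 1))
        grid_phi = genewise_phi_mle_matrix(counts, X, np.zeros(10))
        for i in range(0, 30, 7):
            ref = genewise_phi_mle(counts[i], X, np.zeros(10))
            if ref > 1e-3:
                assert np.log(grid_phi[i]) == pytest.approx(np.log(ref),
                                                            abs=0.05)


class TestAdjustedProfileLoglik:
    def test_adjustment_sign(self, rng):
        # with det(X'WX) > 1 the APL sits below the profile log-likelihood
        y = rng.poisson(100, size=6).astype(float)
        X = np.ones((6, 1))
        phi = 0.3
        apl = adjusted_profile_loglik(phi, y, X, np.zeros(6))
        prof = profile_loglik(y[None, :], X, np.zeros(6), np.array([phi]))[0]
        w = y.mean() / (1 + phi * y.mean()) * 6
        assert w > 1
        assert apl < prof

    def test_matches_explicit_determinant_two_group(self, rng):
        y = np.array([12.0, 18.0, 40.0, 52.0])
        X = design_two_group([1, 1, 2, 2])
        for phi in (0.05, 0.4):
            apl = adjusted_profile_loglik(phi, y, X, np.zeros(4))
            # brute force: cell means are the MLE; W is diagonal
            mu = np.repeat([y[:2].mean(), y[2:].mean()], 2)
            ll = nb_loglik(y, mu, phi)
            w = mu / (1 + phi * mu)
            A = X.T @ np.diag(w) @ X
            expected = ll - 0.5 * np.log(np.linalg.det(A))
            assert apl == pytest.approx(expected, abs=1e-6)

    def test_smooth_in_phi(self, rng):
        # the curve is steep at small phi but must be continuous: values
        # at intermediate points are predicted by a spline through the
        # others to high accuracy
        from scipy.interpolate import CubicSpline
        y = rng.negative_binomial(2, 0.02, size=7).astype(float)
        X = np.ones((7, 1))
        grid = np.linspace(np.log(0.01), np.log(2.0), 81)
        vals = np.array([adjusted_profile_loglik(np.exp(p), y, X, np.zeros(7))
                         for p in grid])
        assert np.all(np.isfinite(vals))
        pred = CubicSpline(grid[::2], vals[::2])(grid[1::2])
        assert np.max(np.abs(pred - vals[1::2])) < 0.01


class TestTrendFitting:
    def test_common_trend_recovers_constant(self):
        const = DispersionTrend(kind="common", alpha=np.array([-1.0]))
        cm, _ = simulate_single_group(m=800, n=7, sigma=0.0, seed=21,
                                      trend=const)
        trend = fit_trend(cm, "common")
        assert trend.alpha[0] == pytest.approx(-1.0, abs=0.1)

    def test_nbq_recovery_sigma_zero(self):
        alpha = (-1.5, -0.4, 0.05)
        cm, truth = simulate_single_group(m=2000, n=7, sigma=0.0, seed=22,
                                          trend_alpha=alpha)
        trend = fit_trend(cm, "nbq")
        dz = truth.trend.center - trend.center
        a = trend.alpha
        recentred = np.array([a[0] + a[1] * dz + a[2] * dz * dz,
                              a[1] + 2 * a[2] * dz, a[2]])
        assert np.all(np.abs(recentred - np.array(alpha))
                      <= np.array([0.15, 0.1, 0.03]))

    def test_nbq_quadratic_term_near_zero_when_absent(self):
        cm, _ = simulate_single_group(m=2000, n=7, sigma=0.0, seed=23,
                                      trend_alpha=(-2.0, -0.3, 0.0))
        trend = fit_trend(cm, "nbq")
        assert abs(trend.alpha[2]) < 0.05

    def test_smooth_trend_tracks_generative_curve(self):
        cm, truth = simulate_single_group(m=2000, n=7, sigma=0.0, seed=24)
        trend = fit_trend(cm, "smooth")
        pi = np.geomspace(np.exp(truth.trend.center - 2),
                          np.exp(truth.trend.center + 2), 25)
        err = np.log(evaluate_trend(trend, pi)) - truth.trend.log_phi(pi)
        assert np.max(np.abs(err)) < 0.35

    def test_too_few_genes_rejected(self):
        cm, _ = simulate_single_group(m=3, n=5, sigma=0.0, seed=1)
        with pytest.raises(ValueError):
            fit_trend(cm, "nbq")


class TestEvaluateTrend:
    def test_parametric_forms(self):
        common = DispersionTrend(kind="common", alpha=np.array([-1.0]))
        np.testing.assert_allclose(evaluate_trend(common, [0.1, 1.0, 10.0]),
                                   np.exp(-1.0))
        nbq0 = DispersionTrend(kind="nbq", alpha=np.zeros(3))
        np.testing.assert_allclose(evaluate_trend(nbq0, [0.5, 2.0]), 1.0)
        nbp = DispersionTrend(kind="nbp", alpha=np.array([0.0, -1.0]))
        assert evaluate_trend(nbp, np.exp(-8.0)) == pytest.approx(np.exp(8.0))

    def test_smooth_extrapolates_flat(self):
        trend = DispersionTrend(kind="smooth",
                                smooth_x=np.array([-10.0, -8.0, -6.0]),
                                smooth_y=np.array([-1.0, -2.0, -3.0]))
        assert evaluate_trend(trend, np.exp(-20.0)) == pytest.approx(np.exp(-1.0))
        assert evaluate_trend(trend, np.exp(-1.0)) == pytest.approx(np.exp(-3.0))

    def test_nonpositive_pi_rejected(self):
        common = DispersionTrend(kind="common", alpha=np.array([0.0]))
        with pytest.raises(ValueError):
            evaluate_trend(common, [0.0])


class TestGammaDiagnostic:
    def test_perfect_log_linear_fit(self):
        pi = np.geomspace(1e-6, 1e-3, 200)
        phi = np.exp(2.0 - 0.5 * np.log(pi))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef, prop = gamma_loglinear_fit(phi, pi, degree=1)
        np.testing.assert_allclose(coef, [2.0, -0.5], atol=1e-6)
        assert prop == pytest.approx(1.0, abs=1e-8)

    def test_independent_dispersion_explains_nothing(self, rng):
        pi = np.geomspace(1e-6, 1e-3, 500)
        phi = rng.lognormal(-1.0, 0.5, size=500)
        _, prop = gamma_loglinear_fit(phi, pi, degree=2)
        assert abs(prop) < 0.1

    def test_positive_mom_filter_and_minimum_size(self):
        pi = np.array([1e-4] * 5)
        phi = np.array([0.1, -0.2, 0.3, np.nan, 0.2])
        with pytest.raises(ValueError):
            gamma_loglinear_fit(phi, pi, degree=2)


@pytest.fixture(scope="module")
def shrink_setup():
    cm, _ = simulate_two_group(SimulationSpec(
        m=400, group_sizes=(5, 5), pi1=0.0, sigma=0.7, seed=9))
    X = design_two_group(cm.group)
    off = make_offsets(cm)
    trend = fit_trend(cm, "smooth", X, off)
    return cm, X, off, trend


class TestTagwiseShrinkage:
    def test_limits(self, shrink_setup):
        cm, X, off, trend = shrink_setup
        phi0 = tagwise_shrink(cm, trend, ShrinkageConfig(g0=0.0), X, off)
        gw = genewise_phi_mle_matrix(cm.counts.astype(float), X, off,
                                     use_apl=True)
        d0 = np.abs(np.log(np.maximum(phi0, 1e-8))
                    - np.log(np.maximum(gw, 1e-8)))
        assert np.median(d0) < 0.05
        phi_inf = tagwise_shrink(cm, trend, ShrinkageConfig(g0=1e6), X, off)
        pi = trend.pi_gene
        tv = evaluate_trend(trend, np.where(np.isfinite(pi) & (pi > 0), pi,
                                            np.nanmedian(pi)))
        assert np.max(np.abs(np.log(phi_inf) - np.log(tv))) < 0.02

    def test_default_prior_shrinks_toward_trend(self, shrink_setup):
        cm, X, off, trend = shrink_setup
        pi = trend.pi_gene
        tv = evaluate_trend(trend, np.where(np.isfinite(pi) & (pi > 0), pi,
                                            np.nanmedian(pi)))
        d = {}
        for g0 in (0.0, 10.0):
            phi = tagwise_shrink(cm, trend, ShrinkageConfig(g0=g0), X, off)
            d[g0] = np.abs(np.log(np.maximum(phi, 1e-8)) - np.log(tv)).mean()
        assert d[10.0] < d[0.0]

    def test_monotone_in_prior_weight(self, shrink_setup):
        cm, X, off, trend = shrink_setup
        pi = trend.pi_gene
        lt = np.log(evaluate_trend(trend, np.where(
            np.isfinite(pi) & (pi > 0), pi, np.nanmedian(pi))))
        weights = [0.0, 1.0, 10.0, 100.0, 1e6]
        logphi = [np.log(np.maximum(tagwise_shrink(
            cm, trend, ShrinkageConfig(g0=g0), X, off), 1e-12))
            for g0 in weights]
        # distance to the trend shrinks monotonically (0.01 slack for the
        # log-phi grid resolution of the optimizer)
        for i in range(100):
            dist = [abs(lp[i] - lt[i]) for lp in logphi]
            assert all(dist[j + 1] <= dist[j] + 0.01 for j in range(4))

    def test_negative_prior_weight_rejected(self):
        with pytest.raises(ValueError):
            ShrinkageConfig(g0=-1.0)


class TestEstimatePi:
    def test_matches_sample_relative_frequency_single_group(self, rng):
        counts = rng.poisson(200, size=(40, 5))
        from dispvar import CountMatrix
        cm = CountMatrix(counts=counts, lib_size=np.full(5, 1e6))
        pi, _ = estimate_pi(cm)
        np.testing.assert_allclose(pi, counts.mean(axis=1) / 1e6, rtol=1e-6)
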