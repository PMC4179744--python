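"""Experiment-1 model families: fitting, predictive distributions, NLL."""

import numpy as np
import pytest
from scipy import stats

from funclearn.functions import EXP1_FUNCTIONS
from funclearn.models import (
    ExtrapolationHeuristic,
    InterpolationHeuristic,
    PolynomialRegression,
    SquaredExponentialGP,
)
from funclearn.models import test_nll as nll_of


class TestPolynomialRegression:
    def test_noiseless_quadratic_recovery(self):
        f2 = EXP1_FUNCTIONS["quadratic"]  # -0.1 x^2 + 0.5 x + 1700
        x = np.linspace(-100, 100, 30)
        model = PolynomialRegression(2).fit(x, f2(x))
        np.testing.assert_allclose(model.coef_, [1700.0, 0.5, -0.1], rtol=1e-8)
        assert model.residual_sd_ == pytest.approx(0.0, abs=1e-8)

    def test_degree_zero_is_mean(self, rng):
        y = rng.normal(100, 5, 20)
        model = PolynomialRegression(0).fit(np.zeros(20) + rng.uniform(-1, 1, 20), y)
        assert model.coef_[0] == pytest.approx(y.mean())

    def test_hand_ols_five_points(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([9.0, 7.0, 5.0, 3.0, 1.0])
        model = PolynomialRegression(1).fit(x, y)
        assert model.coef_[0] == pytest.approx(5.0)
        assert model.coef_[1] == pytest.approx(-2.0)
        assert model.residual_sd_ == pytest.approx(0.0, abs=1e-12)

    def test_variance_propagation_linear(self):
        # var at x* = A + B x*^2 + 2 x* C + residual^2
        model = PolynomialRegression(1).fit(
            np.array([-2.0, -1.0, 1.0, 2.0]), np.array([1.0, 2.0, 2.5, 4.0])
        )
        A_, B_ = model.coef_covariance_[0, 0], model.coef_covariance_[1, 1]
        C_ = model.coef_covariance_[0, 1]
        r2 = model.residual_sd_**2
        _, sd0 = model.predict(np.array([0.0]), return_std=True)
        assert sd0[0] ** 2 == pytest.approx(A_ + r2)
        _, sd1 = model.predict(np.array([1.0]), return_std=True)
        assert sd1[0] ** 2 == pytest.approx(A_ + B_ + 2 * C_ + r2)

    def test_variance_vs_parametric_bootstrap(self, rng):
        # degree-2 propagation term vs 1e5 draws from N(theta_hat, Sigma)
        x = rng.uniform(-50, 50, 40)
        y = 1700 + 0.5 * x - 0.1 * x**2 + rng.normal(0, 20, 40)
        model = PolynomialRegression(2).fit(x, y)
        draws = rng.multivariate_normal(model.coef_, model.coef_covariance_, size=100_000)
        for xs in (-30.0, 0.0, 45.0):
            v = np.array([1.0, xs, xs**2])
            boot_var = np.var(draws @ v)
            _, sd = model.predict(np.array([xs]), return_std=True)
            prop_var = sd[0] ** 2 - model.residual_sd_**2
            assert prop_var == pytest.approx(boot_var, rel=0.02)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            PolynomialRegression(2).fit([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            PolynomialRegression(1).fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


REGIONS2 = ((-60.0, -10.0), (10.0, 60.0))
REGIONS3 = ((-100.0, -60.0), (-20.0, 20.0), (60.0, 100.0))


def _segment_data(fn, regions, n_per=15, noise=0.0, seed=0):
    r = np.random.default_rng(seed)
    xs, ys = [], []
    for lo, hi in regions:
        x = np.linspace(lo, hi, n_per)
        xs.append(x)
        ys.append(fn(x) + (r.normal(0, noise, n_per) if noise else 0.0))
    return np.concatenate(xs), np.concatenate(ys)


class TestInterpolationHeuristic:
    def test_global_line_recovered(self):
        line = lambda x: 3.0 * x + 10.0
        x, y = _segment_data(line, REGIONS2)
        m = InterpolationHeuristic(REGIONS2).fit(x, y)
        for seg in m.segments_:
            np.testing.assert_allclose(seg.coef, [10.0, 3.0], atol=1e-9)
        # gap prediction continues the line (interpolating identical edges)
        mean = m.predict(np.array([0.0]))
        assert mean[0] == pytest.approx(10.0)

    def test_segment_slopes_match_quadratic_mean_slope(self):
        f2 = EXP1_FUNCTIONS["quadratic"]
        x, y = _segment_data(f2, REGIONS3, n_per=21)
        m = InterpolationHeuristic(REGIONS3).fit(x, y)
        for seg, (lo, hi) in zip(m.segments_, REGIONS3):
            # on symmetric noiseless samples the OLS slope equals the
            # quadratic's mean slope over the region, c1 + c2 (lo + hi)
            expected = 0.5 + (-0.1) * (lo + hi)
            assert seg.coef[1] == pytest.approx(expected, rel=1e-9)

    def test_edge_continuity_and_midpoint_variance(self, rng):
        x, y = _segment_data(lambda x: 2 * x + 5, REGIONS2, noise=3.0, seed=4)
        m = InterpolationHeuristic(REGIONS2).fit(x, y)
        left, right = m.segments_
        # continuity at region edge
        edge_mean = m.predict(np.array([left.hi]))[0]
        assert edge_mean == pytest.approx(left.value(left.hi))
        # midpoint: var = (varL + varR)/4 + weighted residual variance
        mid = (left.hi + right.lo) / 2
        _, sd = m.predict(np.array([mid]), return_std=True)
        expected = (
            0.25 * left.param_var(left.hi)
            + 0.25 * right.param_var(right.lo)
            + 0.5 * (left.residual_sd**2 + right.residual_sd**2)
        )
        assert sd[0] ** 2 == pytest.approx(expected)

    def test_flat_flanks(self, rng):
        x, y = _segment_data(lambda x: 2 * x + 5, REGIONS2, noise=3.0, seed=5)
        m = InterpolationHeuristic(REGIONS2).fit(x, y)
        means = m.predict(np.array([70.0, 85.0, 100.0]))
        assert np.ptp(means) == pytest.approx(0.0, abs=1e-12)
        assert means[0] == pytest.approx(m.segments_[-1].value(60.0))

    def test_single_region_degenerates_to_line_fit(self, rng):
        x = np.linspace(-50, 50, 20)
        y = 4 * x + 1 + rng.normal(0, 2, 20)
        heur = InterpolationHeuristic(((-50.0, 50.0),)).fit(x, y)
        poly = PolynomialRegression(1).fit(x, y)
        np.testing.assert_allclose(heur.segments_[0].coef, poly.coef_)
        m1, s1 = heur.predict(np.array([12.0]), return_std=True)
        m2, s2 = poly.predict(np.array([12.0]), return_std=True)
        assert m1[0] == pytest.approx(m2[0])
        assert s1[0] == pytest.approx(s2[0])

    def test_too_few_trials_per_region(self):
        with pytest.raises(ValueError):
            InterpolationHeuristic(REGIONS2).fit([-50.0, -40.0, 20.0, 30.0, 40.0], [1.0] * 5)


class TestExtrapolationHeuristic:
    def test_global_line_extrapolated_everywhere(self):
        line = lambda x: -2.0 * x + 100.0
        x, y = _segment_data(line, REGIONS2)
        m = ExtrapolationHeuristic(REGIONS2).fit(x, y)
        for xs in (-95.0, 0.0, 80.0):
            assert m.predict(np.array([xs]))[0] == pytest.approx(line(xs), abs=1e-8)

    def test_intersection_geometry(self):
        # segments y = -x (left) and y = x (right) intersect at 0: prediction
        # inside the central gap follows |x*|
        regions = ((-3.0, -1.0), (1.0, 3.0))
        x = np.array([-3.0, -2.0, -1.5, -1.0, 1.0, 1.5, 2.0, 3.0])
        y = np.abs(x)
        m = ExtrapolationHeuristic(regions).fit(x, y)
        for xs in (-0.8, -0.2, 0.3, 0.9):
            assert m.predict(np.array([xs]))[0] == pytest.approx(abs(xs), abs=1e-10)

    def test_parallel_segments_fall_back_to_interpolation(self):
        regions = ((-3.0, -1.0), (1.0, 3.0))
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = np.where(x < 0, 2.0 * x + 10.0, 2.0 * x + 20.0)  # parallel lines
        ext = ExtrapolationHeuristic(regions).fit(x, y)
        intp = InterpolationHeuristic(regions).fit(x, y)
        xs = np.array([0.0])
        assert ext.predict(xs)[0] == pytest.approx(intp.predict(xs)[0])

    def test_peripheral_variance_grows_with_distance(self, rng):
        x, y = _segment_data(lambda x: 2 * x + 5, REGIONS2, noise=5.0, seed=6)
        m = ExtrapolationHeuristic(REGIONS2).fit(x, y)
        _, sds = m.predict(np.array([65.0, 75.0, 90.0, 100.0]), return_std=True)
        assert np.all(np.diff(sds) > 0)


class TestGaussianProcess:
    def test_interpolation_property(self, rng):
        x = np.linspace(-60, 60, 25)
        y = 1500 + 100 * np.sin(x / 30)
        m = SquaredExponentialGP().fit(x, y)
        mean = m.predict(x)
        assert np.max(np.abs(mean - y)) < 5.0

    def test_far_field_reverts_to_prior(self, rng):
        x = rng.uniform(-20, 20, 20)
        y = 1500 + rng.normal(0, 30, 20)
        m = SquaredExponentialGP().fit(x, y)
        h = m.hyperparams_
        mean, sd = m.predict(np.array([20000.0]), return_std=True)
        assert mean[0] == pytest.approx(m.y_mean_, abs=1e-6)
        assert sd[0] == pytest.approx(np.sqrt(h.signal_sd**2 + h.noise_sd**2), rel=1e-6)

    def test_against_sklearn_gp(self, rng):
        # independent route: sklearn's GP with the same kernel and fixed
        # hyperparameters must reproduce our marginal likelihood and predictions
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        x = rng.uniform(-60, 60, 30)
        y = 1700 + 0.5 * x - 0.1 * x**2 + rng.normal(0, 20, 30)
        m = SquaredExponentialGP().fit(x, y)
        h = m.hyperparams_
        kernel = ConstantKernel(h.signal_sd**2, "fixed") * RBF(
            h.length_scale, "fixed"
        ) + WhiteKernel(h.noise_sd**2, "fixed")
        sk = GaussianProcessRegressor(kernel=kernel, alpha=1e-10 * h.signal_sd**2).fit(
            x[:, None], y - m.y_mean_
        )
        assert sk.log_marginal_likelihood() == pytest.approx(
            m.log_marginal_likelihood_, abs=1e-3
        )
        xs = np.linspace(-80, 80, 9)
        mean_sk, sd_sk = sk.predict(xs[:, None], return_std=True)
        mean, sd = m.predict(xs, return_std=True)
        np.testing.assert_allclose(mean, mean_sk + m.y_mean_, atol=1e-4)
        np.testing.assert_allclose(sd, sd_sk, rtol=1e-3)

    def test_refinement_not_worse_than_grid(self, rng):
        # the local optimizer must end at least as high as the best grid point
        x = rng.uniform(-60, 60, 25)
        y = 1350 + 7 * x + rng.normal(0, 25, 25)
        m = SquaredExponentialGP().fit(x, y)
        yc = y - m.y_mean_
        grid_best = -min(
            m._neg_lml(np.log([ls, sig, noi]), x, yc)
            for ls in np.geomspace(np.ptp(x) / 30, 3 * np.ptp(x), 5)
            for sig in np.geomspace(0.1 * np.std(yc), 10 * np.std(yc), 5)
            for noi in np.geomspace(0.05 * np.std(yc), 2 * np.std(yc), 5)
        )
        assert m.log_marginal_likelihood_ >= grid_best - 1e-9


class TestTestNLL:
    def test_closed_form_single_trial(self):
        assert nll_of([0.0], [1.0], [0.0]) == pytest.approx(0.5 * np.log(2 * np.pi))

    def test_density_oracle(self, rng):
        means = rng.normal(0, 1, 15)
        sds = rng.uniform(0.5, 3.0, 15)
        resp = means + rng.normal(0, 1, 15)
        direct = -np.sum(np.log(stats.norm.pdf(resp, means, sds)))
        assert nll_of(means, sds, resp) == pytest.approx(direct)
        # doubling every sd changes NLL exactly per the density
        direct2 = -np.sum(np.log(stats.norm.pdf(resp, means, 2 * sds)))
        assert nll_of(means, 2 * sds, resp) == pytest.approx(direct2)

    def test_empty_and_invalid(self):
        assert nll_of([], [], []) == 0.0
        with pytest.raises(ValueError):
            nll_of([0.0], [0.0], [0.0])
        with pytest.raises(ValueError):
            nll_of([0.0, 1.0], [1.0], [0.0])
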