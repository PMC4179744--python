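"""Experiment-1 model zoo: predictive distributions from five model families.

Each family is fit by maximum likelihood to the training-region responses of
a session and then emits a Gaussian predictive distribution (mean, sd) for
every test-region stimulus:

* ``PolynomialRegression`` — OLS polynomial of a given degree; predictive
  variance propagates the coefficient covariance, var(v'theta) = v' Cov v
  with v = (1, x*, ..., x*^d), plus the residual (observation) variance.
* ``InterpolationHeuristic`` — an independent line segment per training
  region; predictions interpolate linearly between segment edge values in
  the gaps and extend as flat flanks outside the trained range.  Stands in
  for associative-map accounts that interpolate but do not extrapolate.
* ``ExtrapolationHeuristic`` — the same segments, but extrapolated: flanking
  test regions use the nearest segment's line; a central gap uses the two
  neighboring lines up to their intersection when that intersection falls
  inside the gap, and falls back to interpolation otherwise.  Stands in for
  partition/linear-expert accounts.
* ``SquaredExponentialGP`` — GP regression with an SE kernel (length scale,
  signal sd, noise sd fit by marginal-likelihood maximization over a grid
  multistart with local refinement); the abstraction-free nonparametric
  reference.

Model comparison happens downstream on summed test negative log likelihoods
(:func:`test_nll`) and marginal likelihoods (:mod:`funclearn.evidence`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .bms import design_matrix

__all__ = [
    "PredictiveDistribution",
    "GPHyperparams",
    "PolynomialRegression",
    "InterpolationHeuristic",
    "ExtrapolationHeuristic",
    "SquaredExponentialGP",
    "test_nll",
    "fit_polynomial",
    "predict_polynomial",
    "fit_interpolation_heuristic",
    "predict_interpolation",
    "fit_extrapolation_heuristic",
    "predict_extrapolation",
    "fit_gp",
    "predict_gp",
]


class PredictiveDistribution(NamedTuple):
    """Gaussian predictive distribution at a single stimulus position."""

    x_star: float
    mean: float
    sd: float


@dataclass(frozen=True)
class GPHyperparams:
    """SE-kernel hyperparameters: length scale (mm), signal and noise sds (ms)."""

    length_scale: float
    signal_sd: float
    noise_sd: float

    def __post_init__(self):
        if min(self.length_scale, self.signal_sd, self.noise_sd) <= 0:
            raise ValueError("all GP hyperparameters must be strictly positive")


def _as_x(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("X must be 1-d positions or a single-column matrix")
    return x


class PolynomialRegression(RegressorMixin, BaseEstimator):
    """OLS polynomial fit with coefficient-covariance error propagation.

    Parameters
    ----------
    degree : int
        Polynomial degree of the mean function.

    Attributes
    ----------
    coef_ : ndarray, ascending degree.
    coef_covariance_ : ndarray, (d+1, d+1) covariance of the estimates,
        ``(X'X)^-1 sigma_hat^2`` with the MLE residual variance (divisor n).
    residual_sd_ : float, MLE residual sd.
    """

    def __init__(self, degree: int = 1):
        self.degree = degree

    def fit(self, X, y):
        x = _as_x(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if n < self.degree + 2:
            raise ValueError(
                f"degree-{self.degree} fit needs >= {self.degree + 2} trials, got {n}"
            )
        F = design_matrix(x, self.degree)
        if np.linalg.matrix_rank(F) < F.shape[1]:
            raise ValueError("rank-deficient design (too few distinct x values)")
        theta, *_ = np.linalg.lstsq(F, y, rcond=None)
        resid = y - F @ theta
        sigma2 = float(np.mean(resid**2))
        self.coef_ = theta
        self.coef_covariance_ = np.linalg.inv(F.T @ F) * sigma2
        self.residual_sd_ = float(np.sqrt(sigma2))
        self.n_train_ = n
        return self

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "coef_")
        x = _as_x(X)
        V = design_matrix(x, self.degree)
        mean = V @ self.coef_
        if not return_std:
            return mean
        var = np.einsum("ij,jk,ik->i", V, self.coef_covariance_, V)
        var = var + self.residual_sd_**2
        return mean, np.sqrt(np.maximum(var, 0.0))


@dataclass
class _Segment:
    """A per-region fitted line with its own covariance and residual sd."""

    lo: float
    hi: float
    coef: np.ndarray  # (intercept, slope)
    cov: np.ndarray
    residual_sd: float

    def value(self, x):
        return self.coef[0] + self.coef[1] * np.asarray(x, dtype=float)

    def param_var(self, x):
        v0, v1 = self.cov[0, 0], self.cov[1, 1]
        c = self.cov[0, 1]
        x = np.asarray(x, dtype=float)
        return v0 + v1 * x**2 + 2 * x * c


def _fit_segments(x, y, regions) -> list[_Segment]:
    segments = []
    for lo, hi in sorted(regions):
        m = (x >= lo) & (x <= hi)
        if m.sum() < 3:
            raise ValueError(f"region ({lo}, {hi}) has fewer than 3 training trials")
        model = PolynomialRegression(degree=1).fit(x[m], y[m])
        segments.append(
            _Segment(lo, hi, model.coef_, model.coef_covariance_, model.residual_sd_)
        )
    return segments


class _SegmentHeuristicBase(RegressorMixin, BaseEstimator):
    def __init__(self, regions: Sequence[tuple[float, float]] = ()):
        self.regions = regions

    def fit(self, X, y):
        if not self.regions:
            raise ValueError("regions must be provided")
        x = _as_x(X)
        y = np.asarray(y, dtype=float).ravel()
        self.segments_ = _fit_segments(x, y, self.regions)
        return self

    # -- shared geometry helpers -------------------------------------------------
    def _locate(self, xs: float):
        """('inside', seg) | ('gap', (segL, segR)) | ('flank', seg)."""
        segs = self.segments_
        for seg in segs:
            if seg.lo <= xs <= seg.hi:
                return "inside", seg
        if xs < segs[0].lo:
            return "flank", segs[0]
        if xs > segs[-1].hi:
            return "flank", segs[-1]
        for left, right in zip(segs, segs[1:]):
            if left.hi < xs < right.lo:
                return "gap", (left, right)
        raise RuntimeError("unreachable")  # pragma: no cover

    def _nearest_segment(self, xs: float) -> _Segment:
        # ties at equidistant x go to the lower-x segment (deterministic)
        best, best_d = None, np.inf
        for seg in self.segments_:
            d = max(seg.lo - xs, 0.0, xs - seg.hi)
            if d < best_d:
                best, best_d = seg, d
        return best

    def _interp_gap(self, xs, left: _Segment, right: _Segment):
        eL, eR = left.hi, right.lo
        w = (eR - xs) / (eR - eL)
        mean = w * left.value(eL) + (1 - w) * right.value(eR)
        var = w**2 * left.param_var(eL) + (1 - w) ** 2 * right.param_var(eR)
        resid2 = w * left.residual_sd**2 + (1 - w) * right.residual_sd**2
        return mean, var + resid2

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "segments_")
        x = _as_x(X)
        mean = np.empty_like(x)
        var = np.empty_like(x)
        for i, xs in enumerate(x):
            mean[i], var[i] = self._predict_one(xs)
        if not return_std:
            return mean
        return mean, np.sqrt(np.maximum(var, 0.0))


class InterpolationHeuristic(_SegmentHeuristicBase):
    """Per-region line segments; linear interpolation in gaps, flat flanks.

    Inside a training region the segment's own line applies.  Between two
    regions the prediction interpolates linearly between the segments' edge
    values, with variance ``w^2 var_L + (1-w)^2 var_R`` (edge predictions are
    independent: segments are fit on disjoint data) plus the weight-averaged
    residual variance.  Outside the trained range the prediction is constant
    at the nearest segment's value at its outer boundary.
    """

    def _predict_one(self, xs):
        kind, obj = self._locate(xs)
        if kind == "inside":
            return obj.value(xs), obj.param_var(xs) + obj.residual_sd**2
        if kind == "flank":
            edge = obj.lo if xs < obj.lo else obj.hi
            return obj.value(edge), obj.param_var(edge) + obj.residual_sd**2
        return self._interp_gap(xs, *obj)


class ExtrapolationHeuristic(_SegmentHeuristicBase):
    """Per-region line segments, extrapolated into the test regions.

    Peripheral test positions use the nearest segment's line evaluated at
    ``x*`` (variance grows with distance by the linear propagation formula).
    In a central gap, when the two neighboring lines intersect inside the
    gap, each line is used on its own side of the intersection; parallel or
    outside-gap intersections fall back to linear interpolation.
    """

    def _predict_one(self, xs):
        kind, obj = self._locate(xs)
        if kind == "inside":
            return obj.value(xs), obj.param_var(xs) + obj.residual_sd**2
        if kind == "flank":
            seg = self._nearest_segment(xs)
            return seg.value(xs), seg.param_var(xs) + seg.residual_sd**2
        left, right = obj
        bL, bR = left.coef[1], right.coef[1]
        if bL != bR:
            x_int = (right.coef[0] - left.coef[0]) / (bL - bR)
            if left.hi < x_int < right.lo:
                seg = left if xs <= x_int else right
                return seg.value(xs), seg.param_var(xs) + seg.residual_sd**2
        return self._interp_gap(xs, left, right)


class SquaredExponentialGP(RegressorMixin, BaseEstimator):
    """GP regression with a squared-exponential kernel.

    The prior mean is the training-response mean; hyperparameters (length
    scale, signal sd, noise sd) maximize the GP log marginal likelihood via
    a multistart over a coarse log-spaced grid followed by L-BFGS-B
    refinement in log space.  Predictive variance includes the observation
    noise, so the emitted distributions are directly comparable with the
    other families' test likelihoods.

    Parameters
    ----------
    init : GPHyperparams or None
        Optional starting point added to the multistart set.
    n_grid : int
        Points per axis of the multistart grid (default 5).
    """

    def __init__(self, init: GPHyperparams | None = None, n_grid: int = 5):
        self.init = init
        self.n_grid = n_grid

    @staticmethod
    def _kernel(xa, xb, ls, sig):
        d = xa[:, None] - xb[None, :]
        return sig**2 * np.exp(-0.5 * (d / ls) ** 2)

    def _neg_lml(self, log_params, x, yc):
        ls, sig, noise = np.exp(log_params)
        n = len(x)
        K = self._kernel(x, x, ls, sig) + (noise**2 + 1e-10 * sig**2) * np.eye(n)
        try:
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            return np.inf
        alpha = np.linalg.solve(L.T, np.linalg.solve(L, yc))
        return float(
            0.5 * yc @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi)
        )

    def fit(self, X, y):
        x = _as_x(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(x) < 2:
            raise ValueError("GP fit needs at least 2 training trials")
        self.x_train_ = x
        self.y_mean_ = float(y.mean())
        yc = y - self.y_mean_
        span = max(np.ptp(x), 1e-3)
        sy = max(float(np.std(yc)), 1e-3)
        g = self.n_grid
        ls_grid = np.geomspace(span / 30, 3 * span, g)
        sig_grid = np.geomspace(0.1 * sy, 10 * sy, g)
        noise_grid = np.geomspace(0.05 * sy, 2 * sy, g)
        starts = [
            np.log([ls, sig, noi])
            for ls in ls_grid
            for sig in sig_grid
            for noi in noise_grid
        ]
        if self.init is not None:
            starts.append(
                np.log([self.init.length_scale, self.init.signal_sd, self.init.noise_sd])
            )
        vals = np.array([self._neg_lml(p, x, yc) for p in starts])
        best = int(np.argmin(vals))
        res = optimize.minimize(
            self._neg_lml,
            starts[best],
            args=(x, yc),
            method="L-BFGS-B",
            bounds=[(np.log(span / 1000), np.log(50 * span))]
            + [(np.log(sy / 1000), np.log(1000 * sy))] * 2,
        )
        if res.success and res.fun < vals[best]:
            log_opt, self.log_marginal_likelihood_ = res.x, -float(res.fun)
        else:
            if not res.success:
                warnings.warn("GP hyperparameter refinement did not converge; "
                              "using best multistart grid point")
            log_opt, self.log_marginal_likelihood_ = starts[best], -float(vals[best])
        ls, sig, noise = np.exp(log_opt)
        self.hyperparams_ = GPHyperparams(float(ls), float(sig), float(noise))
        # cache the training factorization for prediction
        K = self._kernel(x, x, ls, sig) + (noise**2 + 1e-10 * sig**2) * np.eye(len(x))
        self._L = np.linalg.cholesky(K)
        self._alpha = np.linalg.solve(self._L.T, np.linalg.solve(self._L, yc))
        return self

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "hyperparams_")
        x = _as_x(X)
        h = self.hyperparams_
        Ks = self._kernel(x, self.x_train_, h.length_scale, h.signal_sd)
        mean = self.y_mean_ + Ks @ self._alpha
        if not return_std:
            return mean
        v = np.linalg.solve(self._L, Ks.T)
        var = h.signal_sd**2 + h.noise_sd**2 - np.sum(v**2, axis=0)
        return mean, np.sqrt(np.maximum(var, 1e-12))


def test_nll(means, sds, responses) -> float:
    """Summed negative log likelihood of responses under per-trial Gaussians."""
    means = np.asarray(means, dtype=float).ravel()
    sds = np.asarray(sds, dtype=float).ravel()
    responses = np.asarray(responses, dtype=float).ravel()
    if not (len(means) == len(sds) == len(responses)):
        raise ValueError("need one predictive distribution per test trial")
    if len(means) == 0:
        return 0.0
    if np.any(sds <= 0):
        raise ValueError("predictive sd must be strictly positive")
    return float(-np.sum(stats.norm.logpdf(responses, loc=means, scale=sds)))


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators (trial-table interface)


def _train_xy(train: pd.DataFrame):
    return train["x_mm"].to_numpy(dtype=float), train["response_ms"].to_numpy(dtype=float)


def fit_polynomial(train: pd.DataFrame, degree: int) -> PolynomialRegression:
    x, y = _train_xy(train)
    return PolynomialRegression(degree=degree).fit(x, y)


def predict_polynomial(model: PolynomialRegression, x_star: float) -> PredictiveDistribution:
    mean, sd = model.predict(np.array([x_star]), return_std=True)
    return PredictiveDistribution(float(x_star), float(mean[0]), float(sd[0]))


def fit_interpolation_heuristic(train: pd.DataFrame, regions) -> InterpolationHeuristic:
    x, y = _train_xy(train)
    return InterpolationHeuristic(regions=tuple(regions)).fit(x, y)


def predict_interpolation(model: InterpolationHeuristic, x_star: float) -> PredictiveDistribution:
    mean, sd = model.predict(np.array([x_star]), return_std=True)
    return PredictiveDistribution(float(x_star), float(mean[0]), float(sd[0]))


def fit_extrapolation_heuristic(train: pd.DataFrame, regions) -> ExtrapolationHeuristic:
    x, y = _train_xy(train)
    return ExtrapolationHeuristic(regions=tuple(regions)).fit(x, y)


def predict_extrapolation(model: ExtrapolationHeuristic, x_star: float) -> PredictiveDistribution:
    mean, sd = model.predict(np.array([x_star]), return_std=True)
    return PredictiveDistribution(float(x_star), float(mean[0]), float(sd[0]))


def fit_gp(train: pd.DataFrame, init: GPHyperparams | None = None) -> SquaredExponentialGP:
    x, y = _train_xy(train)
    return SquaredExponentialGP(init=init).fit(x, y)


def predict_gp(model: SquaredExponentialGP, x_star: float) -> PredictiveDistribution:
    mean, sd = model.predict(np.array([x_star]), return_std=True)
    return PredictiveDistribution(float(x_star), float(mean[0]), float(sd[0]))
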