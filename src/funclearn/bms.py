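"""Bayesian model selection over nested polynomial function hypotheses.

The candidate set contains polynomial response models of degrees 0, 1 and 2
(constant, linear, quadratic).  For a window of trials with stimuli
``x`` and responses ``y``, each model ``M_j`` says

    y = F_j(x) @ theta + eps,   eps ~ N(0, sigma^2 I),

with ``F_j`` the Vandermonde design of degree ``j`` and independent Gaussian
priors on the coefficients.  Because the model is linear in ``theta`` and the
prior Gaussian, the coefficients integrate out analytically: marginally,

    y ~ N(F mu, sigma^2 I + F diag(sd_i^2) F^T).

The observation-noise sd ``sigma`` is unknown and is marginalized numerically
under a uniform prior over (0, 5000] ms.  Model posteriors are the softmax of
the resulting log marginals under a uniform model prior.  The deliberately
vague coefficient priors (means far from every veridical value, sds ten times
the means) make the posterior insensitive to the prior choice while retaining
the marginal-likelihood Occam penalty on extra parameters: no quantity in the
default path is tuned to the data.

All accumulation is in log space; probabilities only appear in the final
softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "CoefficientPrior",
    "NoisePrior",
    "default_prior",
    "default_noise_prior",
    "design_matrix",
    "log_marginal_given_noise",
    "log_marginal",
    "model_posteriors",
    "BayesianModelSelector",
]

#: Prior mean for the coefficient of each term degree (ms·mm⁻ᵈ).  Deliberately
#: far from every veridical value; sds are 10x the means so the prior carries
#: essentially no information about the coefficient's location.
PRIOR_TERM_MEANS = (5000.0, 50.0, 5.0, 0.5)


@dataclass(frozen=True)
class CoefficientPrior:
    """Independent Gaussian priors over a model's coefficients.

    ``sd_i`` must be at least ten times ``|mean_i|`` whenever the mean is
    nonzero — the inflation rule that keeps the prior location immaterial.
    """

    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self):
        means = tuple(float(m) for m in self.means)
        sds = tuple(float(s) for s in self.sds)
        if len(means) != len(sds):
            raise ValueError("means and sds must have equal length")
        for m, s in zip(means, sds):
            if not s > 0:
                raise ValueError("prior sds must be positive")
            if m != 0 and s < 10 * abs(m):
                raise ValueError("prior sd must be >= 10 * |mean| (vague-prior rule)")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @property
    def n_coefficients(self) -> int:
        return len(self.means)


def default_prior(degree: int) -> CoefficientPrior:
    """Default vague prior for a polynomial model of ``degree``."""
    means = PRIOR_TERM_MEANS[: degree + 1]
    return CoefficientPrior(means=means, sds=tuple(10 * m for m in means))


@dataclass(frozen=True)
class NoisePrior:
    """Uniform prior over the observation-noise sd, discretized for quadrature.

    The prior is uniform in sigma over (0, 5000] ms.  The default quadrature
    nodes are 500 *log-spaced* sd values with non-uniform trapezoid weights:
    the integrand's peak width scales with sigma (~ sigma/sqrt(2n)), so
    log spacing resolves it at every noise level where a linear grid would
    miss narrow low-sigma peaks entirely.  The weights, not the node
    placement, carry the uniform prior.
    """

    grid: np.ndarray
    weights: np.ndarray

    @classmethod
    def uniform(cls, low: float = 0.0, high: float = 5000.0, n: int = 500) -> "NoisePrior":
        if not 0 <= low < high:
            raise ValueError("need 0 <= low < high")
        lo = max(low, high / 5000.0)  # sd = 0 is excluded (degenerate likelihood)
        grid = np.geomspace(lo, high, n)
        d = np.diff(grid)
        w = np.empty(n)
        w[0], w[-1] = d[0] / 2.0, d[-1] / 2.0
        w[1:-1] = (d[:-1] + d[1:]) / 2.0
        return cls(grid=grid, weights=w)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if grid.ndim != 1 or grid.shape != weights.shape or np.any(grid <= 0):
            raise ValueError("invalid noise grid")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", weights)


def default_noise_prior() -> NoisePrior:
    return NoisePrior.uniform()


def design_matrix(x, degree: int) -> np.ndarray:
    """Vandermonde design: row i = (1, x_i, ..., x_i^degree)."""
    return P.polyvander(np.asarray(x, dtype=float).ravel(), degree)


def _marginal_factors(Y, F, prior: CoefficientPrior):
    """SVD factorization of the coefficient-marginalized Gaussian.

    With G = F diag(sd) = U S V^T, the marginal covariance is
    sigma^2 I + U S^2 U^T, so its log-density at Y is available for any
    sigma in O(rank) once (U, S, r = Y - F mu) are known.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    F = np.asarray(F, dtype=float)
    if F.shape[0] != Y.shape[0]:
        raise ValueError("Y and design matrix disagree on n")
    if F.shape[1] != prior.n_coefficients:
        raise ValueError("prior dimension does not match design matrix")
    G = F * np.asarray(prior.sds)
    U, s, _ = np.linalg.svd(G, full_matrices=False)
    r = Y - F @ np.asarray(prior.means)
    u = U.T @ r
    rho2 = r @ r - u @ u
    return s, u, max(rho2, 0.0), Y.shape[0]


def _log_marginal_at_sigmas(s, u, rho2, n, sigmas):
    """Log marginal density at each sigma in a vector, vectorized."""
    sig2 = np.asarray(sigmas, dtype=float) ** 2
    lam = sig2[..., None] + s**2  # eigenvalues along U's columns
    quad = rho2 / sig2 + np.sum(u**2 / lam, axis=-1)
    logdet = (n - len(s)) * np.log(sig2) + np.sum(np.log(lam), axis=-1)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def log_marginal_given_noise(Y, X, degree: int, prior: CoefficientPrior, sigma: float) -> float:
    """Closed-form log marginal likelihood with coefficients integrated out.

    ``log ∫ p(Y | theta, sigma, M) p(theta | M) dtheta`` for the polynomial
    model of ``degree`` at a fixed observation-noise sd ``sigma``.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    F = design_matrix(X, degree)
    s, u, rho2, n = _marginal_factors(Y, F, prior)
    return float(_log_marginal_at_sigmas(s, u, rho2, n, np.array([sigma]))[0])


def log_marginal(
    Y, X, degree: int, prior: CoefficientPrior, noise_prior: NoisePrior | None = None
) -> float:
    """Log marginal likelihood with the noise sd marginalized numerically.

    Uniform-prior quadrature average of the fixed-noise marginal over the sd
    grid, accumulated stably in log space.
    """
    noise_prior = noise_prior or default_noise_prior()
    F = design_matrix(X, degree)
    s, u, rho2, n = _marginal_factors(Y, F, prior)
    ll = _log_marginal_at_sigmas(s, u, rho2, n, noise_prior.grid)
    out = logsumexp(ll, b=noise_prior.weights) - np.log(noise_prior.weights.sum())
    if not np.isfinite(out):
        raise FloatingPointError(
            "marginal likelihood underflowed on the entire noise grid"
        )
    return float(out)


def model_posteriors(
    Y,
    X,
    degrees=(0, 1, 2),
    priors=None,
    noise_prior: NoisePrior | None = None,
):
    """Posterior simplex over candidate polynomial models (uniform model prior).

    Returns ``(posterior, log_marginals)`` as arrays aligned with ``degrees``.
    """
    degrees = tuple(degrees)
    if priors is None:
        priors = [default_prior(d) for d in degrees]
    lm = np.array(
        [log_marginal(Y, X, d, p, noise_prior) for d, p in zip(degrees, priors)]
    )
    post = np.exp(lm - logsumexp(lm))
    post /= post.sum()
    return post, lm


class BayesianModelSelector(BaseEstimator):
    """Posterior probabilities over nested polynomial response models.

    A scikit-learn-style estimator: ``fit(X, y)`` computes, for responses
    ``y`` at stimulus positions ``X``, the marginal likelihood of each
    candidate polynomial degree (coefficients integrated analytically, noise
    sd marginalized numerically) and the posterior simplex under a uniform
    model prior.

    Parameters
    ----------
    degrees : tuple of int
        Candidate polynomial degrees (default constant/linear/quadratic).
    priors : sequence of CoefficientPrior or None
        Per-model coefficient priors; defaults to the vague priors.
    noise_prior : NoisePrior or None
        Noise-sd quadrature grid; defaults to 500 points on (0, 5000] ms.

    Attributes
    ----------
    log_marginals_ : ndarray
        Per-model log marginal likelihood, nats.
    posterior_ : ndarray
        Posterior probability of each model; sums to 1.
    degenerate_ : bool
        True when the window has fewer observations than the largest model
        has coefficients (the marginal is still proper).
    """

    def __init__(self, degrees=(0, 1, 2), priors=None, noise_prior=None):
        self.degrees = degrees
        self.priors = priors
        self.noise_prior = noise_prior

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y) or len(y) < 1:
            raise ValueError("X and y must be equal-length and non-empty")
        self.posterior_, self.log_marginals_ = model_posteriors(
            y, X, self.degrees, self.priors, self.noise_prior
        )
        self.n_observations_ = len(y)
        self.degenerate_ = len(y) < max(self.degrees) + 1
        return self

    def predict_proba(self, X=None):
        """The fitted posterior simplex (stimulus-independent)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "posterior_")
        return self.posterior_
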