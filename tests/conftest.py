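"""Shared fixtures and the brute-force marginal-likelihood oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from funclearn.bms import design_matrix


def brute_force_log_marginal(y, x, degree, prior, sigma, n_nodes=80, half_width=10.0):
    """Brute-force tensor-grid integration of likelihood x coefficient prior.

    Integrates the explicit product of the Gaussian data likelihood and the
    independent Gaussian coefficient priors over a Gauss-Legendre tensor grid.
    The grid is placed via the conjugate posterior mean/covariance (a linear
    change of variables; the integrand itself is evaluated directly), which
    keeps the oracle independent of the analytic marginal-covariance formula
    it checks.
    """
    y = np.asarray(y, dtype=float)
    F = design_matrix(x, degree)
    m = degree + 1
    mus = np.asarray(prior.means)
    sds = np.asarray(prior.sds)
    Om = np.diag(1.0 / sds**2)
    A = F.T @ F / sigma**2 + Om
    mu_post = np.linalg.solve(A, F.T @ y / sigma**2 + Om @ mus)
    evals, evecs = np.linalg.eigh(np.linalg.inv(A))
    E = evecs * np.sqrt(evals)
    nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
    axes = [half_width * nodes] * m
    grids = np.meshgrid(*axes, indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])
    logw = np.zeros(Z.shape[0])
    for wg in np.meshgrid(*([np.log(half_width * wts)] * m), indexing="ij"):
        logw += wg.ravel()
    theta = mu_post[None, :] + Z @ E.T
    resid = y[None, :] - theta @ F.T
    loglik = -0.5 * len(y) * np.log(2 * np.pi * sigma**2) - np.sum(resid**2, axis=1) / (
        2 * sigma**2
    )
    logprior = np.sum(
        -0.5 * np.log(2 * np.pi * sds**2) - (theta - mus) ** 2 / (2 * sds**2), axis=1
    )
    log_jac = 0.5 * float(np.sum(np.log(evals)))
    return float(logsumexp(loglik + logprior + logw) + log_jac)


def make_trial_table(x, y, trial_type="train", phase="segment1"):
    """Minimal trial table around given positions/responses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pd.DataFrame(
        {
            "trial": np.arange(1, len(x) + 1),
            "phase": phase,
            "x_mm": x,
            "onset_ms": y,
            "response_ms": y,
            "trial_type": trial_type,
            "hit": pd.array([None] * len(x), dtype="boolean"),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_window(rng):
    """50 trials from the constant function (1350 ms) with sd-10 noise."""
    x = rng.uniform(-100, 100, 50)
    y = 1350.0 + rng.normal(0, 10, 50)
    return x, y
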