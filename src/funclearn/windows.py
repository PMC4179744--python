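"""Sliding-window time courses of model posteriors and parameter estimates.

A session of ``n`` trials is analyzed in moving windows of ``W`` trials
(step 1), giving ``n - W + 1`` window frames; the canonical session uses
n = 500, W = 50 and hence 451 frames.  Each frame is *anchored at its last
trial* so the time courses are causal: the value reported at trial ``t``
uses trials ``t - W + 1 .. t`` only.

Per frame this module computes

* the Bayesian-model-selection posterior over the candidate polynomial
  degrees (see :mod:`funclearn.bms`), and
* per-model maximum-likelihood coefficient estimates, with the noise level
  re-estimated in every window, optionally smoothed with a discrete Gaussian
  kernel (radius 5 frames).

The posterior sweep is computed in a batched vectorized form (one stacked
SVD over all frames per model); ``funclearn.bms.log_marginal`` is the
single-window reference it must agree with.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import lsq_linear
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .bms import NoisePrior, default_noise_prior, default_prior, design_matrix
from .simulate import SwitchDesign

__all__ = [
    "sliding_windows",
    "posterior_timecourse",
    "mle_parameter_timecourse",
    "smooth_trajectory",
    "selection_extent",
    "SlidingWindowBMS",
    "DEFAULT_SEARCH_RANGES",
]

#: MLE search ranges per term degree, two orders of magnitude beyond the
#: veridical parameter scales: constant +-10000 ms, linear +-100 ms/mm,
#: quadratic +-10 ms/mm^2.
DEFAULT_SEARCH_RANGES = {0: (-10000.0, 10000.0), 1: (-100.0, 100.0), 2: (-10.0, 10.0)}

MODEL_NAMES = {0: "constant", 1: "linear", 2: "quadratic", 3: "cubic"}


def sliding_windows(n_trials: int, window: int = 50) -> list[tuple[int, int]]:
    """All contiguous ``window``-trial spans (1-based inclusive), step 1."""
    if window < 1 or window > n_trials:
        raise ValueError("need 1 <= window <= n_trials")
    return [(s, s + window - 1) for s in range(1, n_trials - window + 2)]


def _window_views(x, y, window):
    xw = sliding_window_view(x, window)  # (frames, W)
    yw = sliding_window_view(y, window)
    return xw, yw


def posterior_timecourse(
    table: pd.DataFrame,
    window: int = 50,
    degrees=(0, 1, 2),
    priors=None,
    noise_prior: NoisePrior | None = None,
) -> pd.DataFrame:
    """Per-frame BMS posterior over candidate models for a trial table.

    Returns a DataFrame with ``frame`` (1-based), ``last_trial`` (the anchor)
    and one ``p_<model>`` column per candidate degree, plus the per-model log
    marginals ``lm_<model>``.
    """
    x = table["x_mm"].to_numpy(dtype=float)
    y = table["response_ms"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("responses must be present on all trials")
    degrees = tuple(degrees)
    if priors is None:
        priors = [default_prior(d) for d in degrees]
    noise_prior = noise_prior or default_noise_prior()
    xw, yw = _window_views(x, y, window)
    n_frames, W = xw.shape
    log_w = np.log(noise_prior.weights)
    log_norm = np.log(noise_prior.weights.sum())
    sig2 = noise_prior.grid**2  # (S,)

    lms = np.empty((n_frames, len(degrees)))
    for j, (d, prior) in enumerate(zip(degrees, priors)):
        sds = np.asarray(prior.sds)
        mu = np.asarray(prior.means)
        # stacked design (frames, W, m); one batched SVD per model
        F = xw[..., None] ** np.arange(d + 1)
        G = F * sds
        U, s, _ = np.linalg.svd(G, full_matrices=False)  # s: (frames, k)
        r = yw - F @ mu
        u = np.einsum("fwk,fw->fk", U, r)
        rho2 = np.maximum(np.sum(r**2, axis=1) - np.sum(u**2, axis=1), 0.0)
        lam = sig2[None, None, :] + (s**2)[..., None]  # (frames, k, S)
        quad = rho2[:, None] / sig2[None, :] + np.sum(u[..., None] ** 2 / lam, axis=1)
        logdet = (W - s.shape[1]) * np.log(sig2)[None, :] + np.sum(np.log(lam), axis=1)
        ll = -0.5 * (W * np.log(2 * np.pi) + logdet + quad)  # (frames, S)
        lms[:, j] = logsumexp(ll + log_w[None, :], axis=1) - log_norm

    post = np.exp(lms - logsumexp(lms, axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)
    trials = table["trial"].to_numpy()
    out = pd.DataFrame(
        {
            "frame": np.arange(1, n_frames + 1),
            "last_trial": trials[window - 1 :],
        }
    )
    for j, d in enumerate(degrees):
        out[f"p_{MODEL_NAMES[d]}"] = post[:, j]
    for j, d in enumerate(degrees):
        out[f"lm_{MODEL_NAMES[d]}"] = lms[:, j]
    return out


def _constrained_ols(F, y, lo, hi):
    theta, *_ = np.linalg.lstsq(F, y, rcond=None)
    if np.all(theta >= lo) and np.all(theta <= hi):
        return theta
    res = lsq_linear(F, y, bounds=(lo, hi))
    return res.x


def mle_parameter_timecourse(
    table: pd.DataFrame,
    window: int = 50,
    degrees=(0, 1, 2),
    search_ranges: dict[int, tuple[float, float]] | None = None,
    smooth_radius: int = 5,
) -> pd.DataFrame:
    """Per-frame, per-model maximum-likelihood coefficients (long form).

    Each window refits every candidate model by least squares (the Gaussian
    MLE), with the noise sd re-estimated per window (MLE, divisor n).  OLS
    solutions are accepted when inside the per-degree search ranges and
    replaced by the boundary-constrained solution otherwise.  The smoothed
    column applies a Gaussian kernel of ``smooth_radius`` frames along each
    coefficient trajectory.
    """
    search_ranges = search_ranges or DEFAULT_SEARCH_RANGES
    x = table["x_mm"].to_numpy(dtype=float)
    y = table["response_ms"].to_numpy(dtype=float)
    xw, yw = _window_views(x, y, window)
    n_frames, W = xw.shape
    trials = table["trial"].to_numpy()
    rows = []
    for d in degrees:
        lo = np.array([search_ranges[t][0] for t in range(d + 1)])
        hi = np.array([search_ranges[t][1] for t in range(d + 1)])
        coefs = np.empty((n_frames, d + 1))
        noise = np.empty(n_frames)
        for f in range(n_frames):
            F = design_matrix(xw[f], d)
            theta = _constrained_ols(F, yw[f], lo, hi)
            coefs[f] = theta
            noise[f] = np.sqrt(np.mean((yw[f] - F @ theta) ** 2))
        smoothed = np.column_stack(
            [smooth_trajectory(coefs[:, t], radius=smooth_radius) for t in range(d + 1)]
        )
        for t in range(d + 1):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(1, n_frames + 1),
                        "last_trial": trials[window - 1 :],
                        "model": MODEL_NAMES[d],
                        "term_degree": t,
                        "mle": coefs[:, t],
                        "smoothed": smoothed[:, t],
                        "noise_sd_mle": noise,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def smooth_trajectory(series, radius: int = 5) -> np.ndarray:
    """Discrete Gaussian smoothing (sd = ``radius`` points, truncated at 3 sd).

    The kernel is renormalized at the edges (normalized convolution), so a
    constant series is returned unchanged everywhere including the ends.
    """
    y = np.asarray(series, dtype=float)
    if radius <= 0:
        return y.copy()
    half = int(np.ceil(3 * radius))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / radius) ** 2)
    k /= k.sum()
    # slice the full convolution so short series (len < kernel) work too
    start = half
    num = np.convolve(y, k, mode="full")[start : start + len(y)]
    den = np.convolve(np.ones_like(y), k, mode="full")[start : start + len(y)]
    return num / den


def selection_extent(timecourse: pd.DataFrame, design: SwitchDesign) -> dict[str, float]:
    """Mean posterior of each segment's generating model while it was active.

    Frames are attributed to a segment by their anchor (last) trial; the
    first segment includes the early frames where learning is incomplete.
    """
    out: dict[str, float] = {}
    last = timecourse["last_trial"].to_numpy()
    for first, last_trial, f in design.segments():
        name = MODEL_NAMES[f.degree]
        m = (last >= first) & (last <= last_trial)
        if not m.any():
            raise ValueError(f"no frames anchored inside segment of {name}")
        out[name] = float(timecourse.loc[m, f"p_{name}"].mean())
    return out


class SlidingWindowBMS(BaseEstimator):
    """Sliding-window Bayesian model selection over a whole session.

    ``fit(table)`` runs the windowed posterior sweep and the windowed MLE
    parameter sweep on a trial table.

    Parameters
    ----------
    window : int
        Window width in trials (default 50).
    degrees : tuple of int
        Candidate polynomial degrees.
    priors, noise_prior :
        As in :class:`funclearn.bms.BayesianModelSelector`.
    smooth_radius : int
        Gaussian kernel radius (frames) for the parameter trajectories.

    Attributes
    ----------
    posteriors_ : DataFrame
        Frame-wise posterior simplex (``posterior_timecourse`` output).
    parameters_ : DataFrame
        Frame-wise per-model MLE coefficients, raw and smoothed.
    """

    def __init__(
        self,
        window: int = 50,
        degrees=(0, 1, 2),
        priors=None,
        noise_prior=None,
        search_ranges=None,
        smooth_radius: int = 5,
    ):
        self.window = window
        self.degrees = degrees
        self.priors = priors
        self.noise_prior = noise_prior
        self.search_ranges = search_ranges
        self.smooth_radius = smooth_radius

    def fit(self, table: pd.DataFrame, y=None):
        self.posteriors_ = posterior_timecourse(
            table, self.window, self.degrees, self.priors, self.noise_prior
        )
        self.parameters_ = mle_parameter_timecourse(
            table, self.window, self.degrees, self.search_ranges, self.smooth_radius
        )
        self.n_frames_ = len(self.posteriors_)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Posterior time course for ``table`` (stateless convenience)."""
        return posterior_timecourse(
            table, self.window, self.degrees, self.priors, self.noise_prior
        )
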