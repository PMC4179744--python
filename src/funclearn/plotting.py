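"""Optional quick-look figures (requires matplotlib).

Includes the spatial response-smoothing utility (Gaussian kernel, 10 mm
radius) used for presentation-style averages of responses over cue
position.  These helpers are cosmetic conveniences, not part of the tested
analysis path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def smooth_responses_spatial(x_mm, response_ms, grid=None, radius_mm: float = 10.0):
    """Nadaraya-Watson average of responses over position with a Gaussian
    kernel of ``radius_mm`` (sd, mm).  Returns (grid, smoothed)."""
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(response_ms, dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 201)
    w = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / radius_mm) ** 2)
    return grid, (w @ y) / w.sum(axis=1)


def plot_posterior_timecourse(timecourse: pd.DataFrame, design=None, ax=None):
    """Stacked view of the windowed model posteriors over trials."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    cols = [c for c in timecourse.columns if c.startswith("p_")]
    for c in cols:
        ax.plot(timecourse["last_trial"], timecourse[c], label=c[2:])
    if design is not None:
        for t in design.switch_trials:
            ax.axvline(t, color="k", ls="--", lw=0.8)
    ax.set(xlabel="trial (window anchor)", ylabel="posterior", ylim=(0, 1))
    ax.legend(frameon=False)
    return ax


def plot_parameter_timecourse(parameters: pd.DataFrame, model: str, ax=None):
    """Smoothed MLE trajectories of one model's coefficients."""
    import matplotlib.pyplot as plt

    sub = parameters[parameters["model"] == model]
    terms = sorted(sub["term_degree"].unique())
    if ax is None:
        _, axes = plt.subplots(len(terms), 1, sharex=True, figsize=(8, 2 * len(terms)))
    else:
        axes = np.atleast_1d(ax)
    for a, t in zip(np.atleast_1d(axes), terms):
        s = sub[sub["term_degree"] == t]
        a.plot(s["last_trial"], s["mle"], alpha=0.4, label="MLE")
        a.plot(s["last_trial"], s["smoothed"], label="smoothed")
        a.set_ylabel(f"term x^{t}")
        a.legend(frameon=False)
    return axes
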