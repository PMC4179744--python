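"""Synthetic experiment designs and simulated-participant trial tables.

Both analyses in this package operate on a *trial table*: one row per trial
with the cue's lateral position ``x_mm``, the scheduled (noiseless) target
onset ``onset_ms``, the observed/simulated interception time ``response_ms``,
a phase label, a train/test flag and a hit flag.  This module generates such
tables for

* Experiment-1 style sessions: a single hidden generating function, 50
  burn-in training trials followed by 120 interleaved test/training trials
  drawn from disjoint spatial regions, and
* Experiment-2 style sessions: 500 trials uniformly covering the full span
  with the generating function surreptitiously switched after trials 100 and
  250.

The simulated agent is an *omniscient observer*: it knows the active
generating function (switching instantly at the switch trials) and responds
with the true value plus zero-mean Gaussian noise.  Its responses are stored
on the onset/arrival time scale — that is the observation vector Y every
analysis consumes.  The hit flag assumes the agent fired its animated bullet
300 ms before that arrival time (the bullet travels 300 ms; the target is
visible for 150 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .functions import DEGREE_LETTERS, EXP1_FUNCTIONS, EXP2_FUNCTIONS, PolynomialFunction

__all__ = [
    "SessionDesign",
    "SwitchDesign",
    "ObserverSpec",
    "REGION_PRESETS",
    "exp1_session_design",
    "exp2_group_design",
    "EXP2_GROUP_ORDERS",
    "sample_stimuli",
    "simulate_responses",
    "simulate_session",
    "determine_hit",
    "hit_rate",
    "exclude_participants",
]

#: Full lateral span of the display used for stimuli, mm (0 = display center).
DEFAULT_SPAN = (-100.0, 100.0)

BULLET_TRAVEL_MS = 300.0
TARGET_VISIBLE_MS = 150.0

Region = tuple[float, float]


def _check_regions(regions: Sequence[Region], what: str) -> tuple[Region, ...]:
    regions = tuple((float(a), float(b)) for a, b in regions)
    if not regions:
        raise ValueError(f"{what} regions must be non-empty")
    for a, b in regions:
        if not b > a:
            raise ValueError(f"invalid {what} region ({a}, {b})")
    return regions


@dataclass(frozen=True)
class SessionDesign:
    """Experiment-1 single-function session layout.

    Training and test trials are drawn from disjoint x-regions.  The first
    ``n_burn_in`` trials are training only; thereafter test and training
    trials strictly alternate (test first by default).
    """

    generating: PolynomialFunction
    train_regions: tuple[Region, ...]
    test_regions: tuple[Region, ...]
    n_burn_in: int = 50
    n_interleaved: int = 120

    def __post_init__(self):
        object.__setattr__(self, "train_regions", _check_regions(self.train_regions, "train"))
        object.__setattr__(self, "test_regions", _check_regions(self.test_regions, "test"))
        for a, b in self.train_regions:
            for c, d in self.test_regions:
                if a < d and c < b:
                    raise ValueError("train and test regions must be disjoint")

    @property
    def n_trials(self) -> int:
        return self.n_burn_in + self.n_interleaved


@dataclass(frozen=True)
class SwitchDesign:
    """Experiment-2 session: three functions with surreptitious switches.

    Function ``k+1`` becomes active from trial ``switch_trials[k] + 1``
    (1-based), i.e. a switch "after 100 trials" changes the function on
    trial 101.
    """

    functions: tuple[PolynomialFunction, PolynomialFunction, PolynomialFunction]
    switch_trials: tuple[int, ...] = (100, 250)
    n_trials: int = 500
    span: tuple[float, float] = DEFAULT_SPAN
    name: str = ""

    def __post_init__(self):
        st = tuple(int(t) for t in self.switch_trials)
        if list(st) != sorted(set(st)) or (st and st[-1] >= self.n_trials):
            raise ValueError("switch_trials must be strictly increasing and < n_trials")
        if len(self.functions) != len(st) + 1:
            raise ValueError("need one function per segment")
        object.__setattr__(self, "switch_trials", st)
        object.__setattr__(self, "functions", tuple(self.functions))

    def segments(self) -> list[tuple[int, int, PolynomialFunction]]:
        """(first_trial, last_trial, function) per segment, 1-based inclusive."""
        bounds = (0,) + self.switch_trials + (self.n_trials,)
        return [
            (bounds[i] + 1, bounds[i + 1], self.functions[i])
            for i in range(len(self.functions))
        ]

    def active_function(self, trial: int) -> PolynomialFunction:
        for first, last, f in self.segments():
            if first <= trial <= last:
                return f
        raise ValueError(f"trial {trial} outside session")

    def transitions(self) -> list[tuple[int, str, PolynomialFunction]]:
        """(switch_trial, label, new_function) per switch; label e.g. 'CL'."""
        out = []
        segs = self.segments()
        for k, t in enumerate(self.switch_trials):
            old, new = segs[k][2], segs[k + 1][2]
            label = DEGREE_LETTERS[old.degree] + DEGREE_LETTERS[new.degree]
            out.append((t, label, new))
        return out


@dataclass(frozen=True)
class ObserverSpec:
    """Omniscient simulated participant: truth plus Gaussian response noise."""

    noise_sd: float
    seed: int = 0
    knowledge: str = "omniscient"

    def __post_init__(self):
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.knowledge != "omniscient":
            raise ValueError("only the omniscient observer is implemented")


# The published figures give the train/test region boundaries only
# graphically, so they are configurable presets here.  "interpolation":
# three training islands with the gaps as test regions (central transfer);
# "extrapolation": two central training segments with the flanks as test
# regions (peripheral transfer).
REGION_PRESETS: dict[str, dict[str, tuple[Region, ...]]] = {
    "interpolation": {
        "train": ((-100.0, -60.0), (-20.0, 20.0), (60.0, 100.0)),
        "test": ((-60.0, -20.0), (20.0, 60.0)),
    },
    "extrapolation": {
        "train": ((-60.0, -10.0), (10.0, 60.0)),
        "test": ((-100.0, -60.0), (60.0, 100.0)),
    },
}

#: Which region preset each Experiment-1 session uses by default.
EXP1_SESSION_PRESETS = {
    "linear": "extrapolation",
    "quadratic": "interpolation",
    "cubic": "extrapolation",
}


def exp1_session_design(session: str, preset: str | None = None) -> SessionDesign:
    """Default Experiment-1 design for ``session`` in {linear, quadratic, cubic}."""
    if session not in EXP1_FUNCTIONS:
        raise ValueError(f"unknown session {session!r}")
    preset = preset or EXP1_SESSION_PRESETS[session]
    regions = REGION_PRESETS[preset]
    return SessionDesign(
        generating=EXP1_FUNCTIONS[session],
        train_regions=regions["train"],
        test_regions=regions["test"],
    )


#: Function orders of the four Experiment-2 groups (C=constant, L=linear,
#: Q=quadratic).  Together they cover all six ordered transitions.
EXP2_GROUP_ORDERS = {
    "G1": ("constant", "linear", "quadratic"),
    "G2": ("quadratic", "linear", "constant"),
    "G3": ("constant", "quadratic", "linear"),
    "G4": ("quadratic", "constant", "linear"),
}


def exp2_group_design(group: str) -> SwitchDesign:
    """Default 500-trial switch design for group ``G1``–``G4``."""
    try:
        order = EXP2_GROUP_ORDERS[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(EXP2_GROUP_ORDERS)}")
    return SwitchDesign(
        functions=tuple(EXP2_FUNCTIONS[k] for k in order), name=group
    )


def _sample_from_regions(rng: np.random.Generator, regions: Sequence[Region], n: int) -> np.ndarray:
    """Uniform samples over a union of intervals, weighted by interval length."""
    regions = list(regions)
    lengths = np.array([b - a for a, b in regions], dtype=float)
    idx = rng.choice(len(regions), size=n, p=lengths / lengths.sum())
    u = rng.uniform(size=n)
    lo = np.array([regions[i][0] for i in idx])
    hi = np.array([regions[i][1] for i in idx])
    return lo + u * (hi - lo)


def sample_stimuli(design: SessionDesign | SwitchDesign, seed: int) -> pd.DataFrame:
    """Draw the stimulus sequence (serially uncorrelated, uniform) for a design.

    Returns a DataFrame with columns ``trial`` (1-based), ``x_mm``,
    ``trial_type`` and ``phase``.  Experiment-1 sessions put 50 burn-in
    training trials first and then strictly alternate test/train; Experiment-2
    sessions sample every trial uniformly over the full span, with the phase
    label recording the active segment.
    """
    rng = np.random.default_rng(seed)
    if isinstance(design, SessionDesign):
        n = design.n_trials
        x = np.empty(n)
        trial_type = np.empty(n, dtype=object)
        phase = np.empty(n, dtype=object)
        x[: design.n_burn_in] = _sample_from_regions(rng, design.train_regions, design.n_burn_in)
        trial_type[: design.n_burn_in] = "train"
        phase[: design.n_burn_in] = "burn_in"
        for i in range(design.n_burn_in, n):
            is_test = (i - design.n_burn_in) % 2 == 0
            regions = design.test_regions if is_test else design.train_regions
            x[i] = _sample_from_regions(rng, regions, 1)[0]
            trial_type[i] = "test" if is_test else "train"
            phase[i] = "interleaved"
    elif isinstance(design, SwitchDesign):
        n = design.n_trials
        x = rng.uniform(design.span[0], design.span[1], size=n)
        trial_type = np.full(n, "train", dtype=object)
        phase = np.empty(n, dtype=object)
        for k, (first, last, _f) in enumerate(design.segments(), start=1):
            phase[first - 1 : last] = f"segment{k}"
    else:
        raise TypeError(f"unsupported design type {type(design).__name__}")
    return pd.DataFrame(
        {"trial": np.arange(1, n + 1), "x_mm": x, "trial_type": trial_type, "phase": phase}
    )


def determine_hit(fire_time: float, onset: float) -> bool:
    """Whether a bullet fired at ``fire_time`` hits a target appearing at ``onset``.

    The bullet travels for 300 ms; the target is visible for 150 ms, so the
    shot scores iff ``onset <= fire_time + 300 <= onset + 150``.  A shot fired
    at or after the target's appearance always misses.
    """
    arrival = np.asarray(fire_time, dtype=float) + BULLET_TRAVEL_MS
    onset = np.asarray(onset, dtype=float)
    hit = (arrival >= onset) & (arrival <= onset + TARGET_VISIBLE_MS)
    return bool(hit) if hit.ndim == 0 else hit


def _active_onsets(stimuli: pd.DataFrame, design: SessionDesign | SwitchDesign) -> np.ndarray:
    x = stimuli["x_mm"].to_numpy()
    if isinstance(design, SessionDesign):
        return design.generating(x)
    onset = np.empty(len(x))
    trials = stimuli["trial"].to_numpy()
    for first, last, f in design.segments():
        m = (trials >= first) & (trials <= last)
        onset[m] = f(x[m])
    return onset


def simulate_responses(
    stimuli: pd.DataFrame,
    design: SessionDesign | SwitchDesign,
    observer: ObserverSpec,
) -> pd.DataFrame:
    """Add onsets, noisy responses and hit flags for an omniscient observer.

    ``onset_ms`` stores the noiseless value of the active generating function;
    ``response_ms`` = onset + N(0, noise_sd²) on every trial (test trials also
    receive responses — participants respond, they just get no feedback).  Hit
    flags are set on feedback (train) trials only, assuming the agent fired
    300 ms before its noisy arrival time.
    """
    rng = np.random.default_rng(observer.seed)
    out = stimuli.copy()
    onset = _active_onsets(stimuli, design)
    response = onset + rng.normal(0.0, observer.noise_sd, size=len(onset))
    out["onset_ms"] = onset
    out["response_ms"] = response
    hit = pd.array([pd.NA] * len(out), dtype="boolean")
    feedback = out["trial_type"].to_numpy() == "train"
    hit[feedback] = determine_hit(response[feedback] - BULLET_TRAVEL_MS, onset[feedback])
    out["hit"] = hit
    return out[["trial", "phase", "x_mm", "onset_ms", "response_ms", "trial_type", "hit"]]


def simulate_session(
    design: SessionDesign | SwitchDesign, noise_sd: float, seed: int
) -> pd.DataFrame:
    """Convenience: sample stimuli and simulate an observer in one call.

    Stimuli and response noise use independent streams spawned from ``seed``
    so the same stimulus sequence can be reused across noise levels.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    stim_seed = int(ss[0].generate_state(1)[0] % (2**31))
    obs_seed = int(ss[1].generate_state(1)[0] % (2**31))
    stimuli = sample_stimuli(design, stim_seed)
    return simulate_responses(stimuli, design, ObserverSpec(noise_sd, seed=obs_seed))


def hit_rate(table: pd.DataFrame) -> float:
    """Fraction of feedback (training) trials with a hit."""
    feedback = table[table["trial_type"] == "train"]
    if len(feedback) == 0:
        raise ValueError("no feedback trials in table")
    hits = feedback["hit"]
    if hits.isna().any():
        raise ValueError("feedback trials missing hit flags")
    return float(hits.astype(bool).mean())


def exclude_participants(
    rates: Mapping[str, Sequence[float]], threshold: float = 0.10
) -> set[str]:
    """Retained participants under the hit-rate rule.

    A participant is excluded iff their hit rate is below ``threshold`` in
    *every* session; one adequate session retains them.
    """
    return {
        pid
        for pid, session_rates in rates.items()
        if not all(r < threshold for r in session_rates)
    }
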