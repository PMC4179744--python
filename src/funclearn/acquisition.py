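"""Acquisition times after function switches and the simulated baseline.

After each surreptitious switch, the *acquisition time* of the new function
is the number of post-switch trials until the windowed posterior of the
correct model first reaches a selection threshold (0.33 — chance level for
three models — by default; 0.5, 0.66 and 0.99 in the threshold sweep).
Times are counted on the trailing-anchor convention of
:mod:`funclearn.windows`: the frame anchored at trial ``switch + k``
contributes at time ``k``.  A transition whose threshold is never reached
before the segment ends is censored; censored times are excluded from means
but counted.

The omniscient-observer baseline repeats the full windowed analysis on
Monte-Carlo simulated sessions (truth plus Gaussian noise at the seven
canonical sd levels, 10–400 ms) and quantifies the asymmetry the sliding
window itself induces: windows straddling a switch contain a mixture of two
functions, and the more complex candidate distinguishes itself from that
mixture sooner, so the baseline acquires complex functions *faster* — the
opposite of the parsimony effect reported for humans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SwitchDesign, simulate_session
from .windows import MODEL_NAMES, posterior_timecourse

__all__ = [
    "AcquisitionResult",
    "BaselineSpec",
    "ComparisonReport",
    "acquisition_time",
    "extract_acquisitions",
    "threshold_sweep",
    "simulated_baseline",
    "transition_differences",
    "compare_to_baseline",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.33, 0.5, 0.66, 0.99)

#: Complexity rank of the one-letter model labels.
_COMPLEXITY = {"C": 0, "L": 1, "Q": 2}


@dataclass(frozen=True)
class AcquisitionResult:
    """Trials-to-threshold for one transition of one session."""

    transition: str
    threshold: float
    trials: int | None
    censored: bool


@dataclass(frozen=True)
class BaselineSpec:
    """Monte-Carlo plan for the omniscient-observer baseline."""

    noise_sds: tuple[float, ...] = (10.0, 30.0, 50.0, 100.0, 150.0, 200.0, 400.0)
    runs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass(frozen=True)
class ComparisonReport:
    """One-sample two-tailed t-test of per-participant differences vs a baseline."""

    pair: str
    mean_difference: float
    baseline_difference: float
    t: float
    dof: int
    p_value: float


def acquisition_time(
    timecourse: pd.DataFrame,
    switch_trial: int,
    correct_model: str,
    threshold: float,
    segment_end: int | None = None,
) -> AcquisitionResult:
    """Smallest ``k >= 1`` with the frame anchored at ``switch_trial + k``
    giving the correct model posterior >= ``threshold``.

    ``segment_end`` bounds the search (default: last frame); if the threshold
    is never reached inside the segment the result is censored.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    last = timecourse["last_trial"].to_numpy()
    p = timecourse[f"p_{correct_model}"].to_numpy()
    end = segment_end if segment_end is not None else int(last.max())
    m = (last > switch_trial) & (last <= end)
    label = correct_model
    if m.any():
        crossed = p[m] >= threshold
        if crossed.any():
            t_hit = last[m][np.argmax(crossed)]
            return AcquisitionResult(label, threshold, int(t_hit - switch_trial), False)
    return AcquisitionResult(label, threshold, None, True)


def extract_acquisitions(
    timecourse: pd.DataFrame,
    design: SwitchDesign,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Acquisition rows for every transition of ``design`` at each threshold."""
    segs = design.segments()
    rows = []
    for k, (switch_trial, label, new_f) in enumerate(design.transitions()):
        seg_end = segs[k + 1][1]
        for thr in thresholds:
            res = acquisition_time(
                timecourse, switch_trial, MODEL_NAMES[new_f.degree], thr, seg_end
            )
            rows.append(
                {
                    "transition": label,
                    "threshold": thr,
                    "trials": np.nan if res.censored else res.trials,
                    "censored": res.censored,
                }
            )
    return pd.DataFrame(rows)


def threshold_sweep(
    timecourse: pd.DataFrame,
    design: SwitchDesign,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Acquisition table across selection thresholds (alias with the
    canonical threshold set; times are monotone non-decreasing in threshold)."""
    return extract_acquisitions(timecourse, design, thresholds)


def simulated_baseline(
    designs: Iterable[SwitchDesign],
    spec: BaselineSpec,
    window: int = 50,
    thresholds: Sequence[float] = (0.33,),
    degrees=(0, 1, 2),
) -> pd.DataFrame:
    """Monte-Carlo omniscient-observer acquisition distribution.

    For each noise sd and run, every design is simulated (truth + noise,
    instant switching), the windowed posterior sweep is run, and acquisition
    times are extracted per transition and threshold.  Bit-identical under a
    fixed ``spec.seed``.

    Returns a long DataFrame: ``noise_sd, run, group, transition, threshold,
    trials, censored``.
    """
    designs = list(designs)
    root = np.random.SeedSequence(spec.seed)
    frames = []
    for i_sd, sd in enumerate(spec.noise_sds):
        for run in range(spec.runs):
            for i_d, design in enumerate(designs):
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(i_sd, run, i_d)
                )
                seed = int(child.generate_state(1)[0] % (2**31))
                table = simulate_session(design, sd, seed)
                tc = posterior_timecourse(table, window, degrees)
                acq = extract_acquisitions(tc, design, thresholds)
                acq.insert(0, "group", design.name or f"design{i_d}")
                acq.insert(0, "run", run)
                acq.insert(0, "noise_sd", sd)
                frames.append(acq)
    return pd.concat(frames, ignore_index=True)


def _pair_key(transition: str) -> tuple[str, bool]:
    """Canonical pair label and whether the transition is complexifying."""
    a, b = transition[0], transition[1]
    complexifying = _COMPLEXITY[b] > _COMPLEXITY[a]
    simple, complex_ = (a, b) if complexifying else (b, a)
    return f"{simple}{complex_}-{complex_}{simple}", complexifying


def transition_differences(results: pd.DataFrame, unit: str = "run") -> pd.DataFrame:
    """Per-unit acquisition-time differences, complexifying minus simplifying.

    ``results`` must carry columns ``unit``, ``transition``, ``threshold``,
    ``trials`` and ``censored``.  For each complexity pair (e.g. CL/LC) and
    unit, the difference is mean(trials of the transition *to the complex*
    model) − mean(trials *to the simple* model); the pair column records the
    orientation explicitly.  A unit with one direction entirely censored
    yields a censored (NaN) difference.
    """
    rows = []
    df = results.copy()
    df[["pair", "complexifying"]] = df["transition"].map(_pair_key).apply(pd.Series)
    for (u, pair, thr), grp in df.groupby([unit, "pair", "threshold"]):
        cx = grp[grp["complexifying"]]["trials"].dropna()
        sx = grp[~grp["complexifying"]]["trials"].dropna()
        if len(cx) == 0 or len(sx) == 0:
            if grp["complexifying"].nunique() < 2:
                continue  # pair not observed in both directions for this unit
            diff = np.nan
        else:
            diff = cx.mean() - sx.mean()
        rows.append(
            {
                unit: u,
                "pair": pair,
                "threshold": thr,
                "difference": diff,
                "orientation": "complexifying_minus_simplifying",
                "censored": not np.isfinite(diff),
            }
        )
    return pd.DataFrame(rows)


def compare_to_baseline(
    participant_diffs: Sequence[float], baseline_diff: float, pair: str = ""
) -> ComparisonReport:
    """Two-tailed one-sample t-test of participant differences against the
    simulated-baseline difference (treated as a constant)."""
    diffs = np.asarray(list(participant_diffs), dtype=float)
    if len(diffs) < 2:
        raise ValueError("need at least two participants")
    if np.std(diffs, ddof=1) == 0:
        t = 0.0 if np.isclose(diffs.mean(), baseline_diff) else np.inf * np.sign(
            diffs.mean() - baseline_diff
        )
        p = 1.0 if t == 0.0 else 0.0
    else:
        res = stats.ttest_1samp(diffs, popmean=baseline_diff)
        t, p = float(res.statistic), float(res.pvalue)
    return ComparisonReport(
        pair=pair,
        mean_difference=float(diffs.mean()),
        baseline_difference=float(baseline_diff),
        t=t,
        dof=len(diffs) - 1,
        p_value=p,
    )
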