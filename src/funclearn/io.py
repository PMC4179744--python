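"""Trial-table CSV I/O, run configuration, and the end-to-end pipeline.

The on-disk trial format is a flat UTF-8 CSV with a mandatory header::

    trial,phase,x_mm,onset_ms,response_ms,trial_type,hit

'.' decimal separator; missing values are empty fields.  Validation errors
name the offending row and column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import extract_acquisitions
from .evidence import exp1_compare
from .simulate import (
    ObserverSpec,
    exp1_session_design,
    exp2_group_design,
    sample_stimuli,
    simulate_responses,
)
from .windows import mle_parameter_timecourse, posterior_timecourse

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "load_config", "config_hash", "run_pipeline"]

TRIAL_COLUMNS = ["trial", "phase", "x_mm", "onset_ms", "response_ms", "trial_type", "hit"]
_NUMERIC = {"trial", "x_mm", "onset_ms", "response_ms"}


class TrialSchemaError(ValueError):
    """A trial CSV violated the schema; the message names row and column."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialSchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in _NUMERIC:
        numeric = pd.to_numeric(df[col], errors="coerce")
        required = col in {"trial", "x_mm", "onset_ms"}
        bad = numeric.isna() & (df[col].notna() if not required else True)
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise TrialSchemaError(f"{path}: non-numeric value in column '{col}' at line {row}")
        df[col] = numeric
    df["trial"] = df["trial"].astype(int)
    if df["trial"].duplicated().any():
        dup = int(df.loc[df["trial"].duplicated(), "trial"].iloc[0])
        raise TrialSchemaError(f"{path}: duplicate trial index {dup}")
    bad_type = ~df["trial_type"].isin(["train", "test"])
    if bad_type.any():
        row = int(bad_type.idxmax()) + 2
        raise TrialSchemaError(f"{path}: invalid trial_type at line {row}")
    hit = df["hit"]
    df["hit"] = pd.array(
        [pd.NA if (pd.isna(v) or v == "") else _parse_bool(v, path) for v in hit],
        dtype="boolean",
    )
    return df[TRIAL_COLUMNS]


def _parse_bool(v, path):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "1.0"}:
        return True
    if s in {"false", "0", "0.0"}:
        return False
    raise TrialSchemaError(f"{path}: invalid hit flag {v!r}")


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (lossless round-trip; row order preserved)."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialSchemaError(f"cannot write: missing column(s) {', '.join(missing)}")
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a config mapping (embedded in every output)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config, seed):
    return {
        "funclearn_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "config": dict(config),
    }


def run_pipeline(config: Mapping[str, Any], out_dir) -> dict[str, Any]:
    """Simulate and analyze per a run configuration; write a report bundle.

    Config keys: ``experiment`` (1 or 2), ``seed``, ``noise_sd``, and either
    ``session`` (Experiment 1: linear/quadratic/cubic) or ``group``
    (Experiment 2: G1-G4), plus optional ``window``, ``thresholds``.
    Outputs (CSV/JSON) land in ``out_dir`` together with a ``run.json`` log
    recording version, seed and config hash; reruns with the same config are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    experiment = int(config["experiment"])
    seed = int(config.get("seed", 0))
    noise_sd = float(config.get("noise_sd", 10.0))
    log: dict[str, Any] = _provenance(config, seed)
    if experiment == 1:
        design = exp1_session_design(config.get("session", "quadratic"))
        stimuli = sample_stimuli(design, seed)
        table = simulate_responses(stimuli, design, ObserverSpec(noise_sd, seed=seed + 1))
        write_trials(table, out_dir / "trials.csv")
        report = exp1_compare(table, design, with_evidence=bool(config.get("evidence", False)), seed=seed)
        report.to_csv(out_dir / "exp1_report.csv", index=False)
        log["stages"] = ["simulate", "exp1-compare"]
        log["outputs"] = ["trials.csv", "exp1_report.csv"]
    elif experiment == 2:
        design = exp2_group_design(config.get("group", "G1"))
        stimuli = sample_stimuli(design, seed)
        table = simulate_responses(stimuli, design, ObserverSpec(noise_sd, seed=seed + 1))
        write_trials(table, out_dir / "trials.csv")
        window = int(config.get("window", 50))
        posts = posterior_timecourse(table, window)
        posts.to_csv(out_dir / "posteriors.csv", index=False)
        params = mle_parameter_timecourse(table, window)
        params.to_csv(out_dir / "parameters.csv", index=False)
        thresholds = tuple(config.get("thresholds", (0.33, 0.5, 0.66, 0.99)))
        acq = extract_acquisitions(posts, design, thresholds)
        acq.to_csv(out_dir / "acquisition.csv", index=False)
        log["stages"] = ["simulate", "exp2-bms", "acquisition"]
        log["outputs"] = ["trials.csv", "posteriors.csv", "parameters.csv", "acquisition.csv"]
    else:
        raise ValueError(f"unknown experiment {experiment}")
    with open(out_dir / "run.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
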