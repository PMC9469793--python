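"""Columnar trial-file and artifact I/O.

Trial files are CSV with a header: column 1 ``time_s`` then one column per
trial named ``trial_<k>``.  Missing values are forbidden.  Artifact JSON
documents embed the seed and a hash of the producing configuration so
reruns are comparable byte for byte (timestamps are never written).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError


def write_trials_csv(path, t: np.ndarray, trials: np.ndarray) -> None:
    trials = np.atleast_2d(np.asarray(trials, float))
    df = pd.DataFrame({"time_s": np.asarray(t, float)})
    for k, row in enumerate(trials, start=1):
        df[f"trial_{k}"] = row
    df.to_csv(path, index=False, float_format="%.10g")


def read_trials_csv(path) -> tuple:
    """Returns (t, trials) with trials shaped (k, N)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"malformed CSV {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise InvalidInputError(f"{path}: first column must be 'time_s'")
    trial_cols = [c for c in df.columns if c.startswith("trial_")]
    if not trial_cols:
        raise InvalidInputError(f"{path}: no trial_<k> columns found")
    sub = df[["time_s"] + trial_cols]
    if sub.isna().any().any():
        bad = int(np.argwhere(sub.isna().to_numpy())[0][0]) + 2  # header line
        raise InvalidInputError(f"{path}: missing/non-numeric value near line {bad}")
    for c in trial_cols:
        if not np.issubdtype(sub[c].dtype, np.number):
            raise InvalidInputError(f"{path}: non-numeric cells in column {c}")
    t = sub["time_s"].to_numpy(float)
    trials = sub[trial_cols].to_numpy(float).T
    return t, trials


def config_hash(doc: dict) -> str:
    """Stable short hash of a JSON-serializable configuration document."""
    canon = json.dumps(doc, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_artifact_json(path, payload: dict, config: dict, seed) -> None:
    doc = dict(payload)
    doc["_provenance"] = {"config_hash": config_hash(config), "seed": seed}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def write_sweep_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def write_psd_csv(path, freqs_hz: np.ndarray, psd: np.ndarray) -> None:
    pd.DataFrame({"freq_hz": freqs_hz, "psd": psd}).to_csv(
        path, index=False, float_format="%.10g"
    )
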