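"""File-format contracts: trial-log CSV, fits JSON/CSV, IL-6 and ROI files.

CSV dialect: UTF-8, comma-separated, header row, '.' decimal.  Nested
structures go to JSON.  Writers emit exactly the contract columns so
synthetic and (hypothetical) real data are interchangeable.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DataError

#: trial-log contract columns, in order
TRIAL_COLUMNS = [
    "subject_id", "treatment", "session_order", "run", "trial",
    "condition", "pair_id", "side_A", "choice", "go_flag", "outcome",
]

_VALID_CHOICES = {"A", "B"}
_VALID_TREATMENTS = {"placebo", "vaccine"}


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial log lacks columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    bad = ~df["choice"].isin(_VALID_CHOICES)
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        raise DataError(f"{path}: invalid choice codes at lines {lines[:10]}")
    bad_t = ~df["treatment"].isin(_VALID_TREATMENTS)
    if bad_t.any():
        lines = (df.index[bad_t] + 2).tolist()
        raise DataError(f"{path}: invalid treatment labels at lines {lines[:10]}")
    return df


def write_fits(fits: pd.DataFrame, results: dict, csv_path, json_path=None) -> None:
    fits.to_csv(csv_path, index=False)
    if json_path is not None:
        records = []
        for (s, t, c), fr in sorted(results.items()):
            records.append({
                "subject_id": s, "treatment": t, "condition": c,
                "alpha": fr.params.alpha, "beta": fr.params.beta, "r": fr.params.r,
                "neg_log_likelihood": fr.neg_log_likelihood,
                "n_trials": fr.n_trials, "n_pairs": fr.n_pairs,
                "mean_log_likelihood_per_pair": fr.mean_log_likelihood_per_pair,
                "converged": bool(fr.converged),
                "n_restarts_used": fr.n_restarts_used,
                "q_series": [float(v) for v in fr.q_series],
                "delta_series": [float(v) for v in fr.delta_series],
            })
        Path(json_path).write_text(json.dumps(records, indent=1))


def read_fits(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def write_il6(il6: pd.DataFrame, path) -> None:
    il6.to_csv(path, index=False)


def write_roi_session(roi_datasets: dict, out_dir, sid: str, treatment: str) -> None:
    """One signal CSV (time + one column per ROI) and one events CSV per scan."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    any_ds = next(iter(roi_datasets.values()))
    n = len(any_ds.signal)
    sig = pd.DataFrame({"time": np.arange(n) * any_ds.tr})
    for name, ds in roi_datasets.items():
        sig[name] = ds.signal
    sig.to_csv(out_dir / f"{sid}_{treatment}.csv", index=False)
    any_ds.events.to_csv(out_dir / f"{sid}_{treatment}_events.csv", index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int, extra: dict | None = None) -> None:
    from . import __version__

    payload = {
        "package": "rlcross",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
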