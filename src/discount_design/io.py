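"""CSV / JSON input-output for trial tables, choice datasets and fits.

Trial tables and choice datasets travel as plain CSV with fixed column
schemas; models, parameters and fit results as JSON objects with parameter
names exactly ``kappa, beta, gamma, s, w, kappa2, delta``.  Currency values
are written with two decimals (fixed-point pennies).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import pandas as pd

from .inference import ChoiceDataset, FitResult
from .models import ModelParams
from .trials import TRIAL_COLUMNS, RunAConfig, RunBConfig

__all__ = [
    "write_trials", "read_trials",
    "write_datasets", "read_datasets",
    "write_params", "read_params",
    "write_fit", "read_run_a_config", "read_run_b_config",
]

DATASET_COLUMNS = ["subject_id", "run", "condition", "trial_index",
                   "r1", "r2", "delay_days", "target_p1", "action", "rt_ms"]


def write_trials(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    out = trials.copy()
    for col in ("r1", "r2"):
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} lacks columns: {missing}")
    return df


def write_datasets(datasets: List[ChoiceDataset], path: Union[str, Path]) -> None:
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(path, index=False)


def read_datasets(path: Union[str, Path]) -> List[ChoiceDataset]:
    """Read a choices CSV, splitting it into per subject/run/condition datasets."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choices table {path} lacks columns: {missing}")
    out = []
    for _, sub in df.groupby(["subject_id", "run", "condition"], sort=True):
        out.append(ChoiceDataset.from_frame(sub.sort_values("trial_index")))
    return out


def write_params(params: Dict[str, ModelParams], path: Union[str, Path]) -> None:
    """Write per-condition parameters as JSON."""
    Path(path).write_text(json.dumps(
        {cond: p.to_dict() for cond, p in params.items()}, indent=2))


def read_params(path: Union[str, Path]) -> Dict[str, ModelParams]:
    raw = json.loads(Path(path).read_text())
    if "model" in raw:  # single parameter set, not keyed by condition
        return {"reward": ModelParams.from_dict(raw), "loss": ModelParams.from_dict(raw)}
    return {cond: ModelParams.from_dict(d) for cond, d in raw.items()}


def write_fit(fits: Dict[str, FitResult], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(
        {key: f.to_dict() for key, f in fits.items()}, indent=2))


def read_run_a_config(path: Union[str, Path]) -> RunAConfig:
    return RunAConfig.from_dict(json.loads(Path(path).read_text()))


def read_run_b_config(path: Union[str, Path]) -> RunBConfig:
    return RunBConfig.from_dict(json.loads(Path(path).read_text()))
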