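"""Behavioral variables and subject classification.

Discounting is measured as the frequency of *discounted* choices: in the
reward condition the discounted choice is the immediate option (taking less
now rather than waiting for more), in the loss condition it is the delayed
option (postponing a loss at the price of a larger one).  Consequently the
manipulated immediate-choice probability ``p1`` equals the discounting
probability in reward trials and ``1 - p1`` in loss trials.

Subjects are classified against configurable thresholds: *non-discounters*
discount in fewer than 5% of a condition's trials; *repeaters* choose the
same option in more than 95% of a run's trials (too little variability for
valid parameter inference); fitted discount rates above 2 are flagged as
extreme; and subjects missing more than 10% of a run's responses are
flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .inference import ChoiceDataset, FitResult

__all__ = [
    "ClassificationThresholds",
    "SubjectFlags",
    "lower_median",
    "discounted_choice_frequency",
    "behavioral_summary",
    "classify_subjects",
]


def lower_median(values: Sequence[float]) -> float:
    """Median taking the lower of the two middle values for even counts."""
    arr = np.sort(np.asarray([v for v in values if not np.isnan(v)], dtype=float))
    if arr.size == 0:
        return float("nan")
    return float(arr[(arr.size - 1) // 2])


def _discounted_mask(data: ChoiceDataset) -> np.ndarray:
    if data.condition == "reward":
        return data.immediate
    return (data.action == "delayed")


def discounted_choice_frequency(data: ChoiceDataset,
                                stratify_by_target: bool = False) -> pd.DataFrame:
    """Frequencies of discounted and immediate choices (plus median RT).

    One row per stratum: the whole dataset, or — with ``stratify_by_target``
    — one row per manipulated target probability level.  Frequencies are
    computed over non-missing trials; empty strata are omitted.
    """
    strata: List[tuple] = []
    if stratify_by_target:
        levels = sorted({p for p in data.target_p1 if not np.isnan(p)})
        for p1 in levels:
            strata.append((p1, np.isclose(data.target_p1, p1)))
        if not levels:
            strata.append((np.nan, np.ones(len(data), dtype=bool)))
    else:
        strata.append((np.nan, np.ones(len(data), dtype=bool)))

    discounted = _discounted_mask(data)
    rows = []
    for p1, mask in strata:
        used = mask & data.responded
        n = int(used.sum())
        if n == 0:
            continue
        rows.append({
            "subject_id": data.subject_id,
            "run": data.run,
            "condition": data.condition,
            "target_p1": p1,
            "n": n,
            "discounted_frequency": float(discounted[used].mean()),
            "immediate_frequency": float(data.immediate[used].mean()),
            "median_rt_ms": lower_median(data.rt_ms[used]),
        })
    return pd.DataFrame(rows)


def behavioral_summary(datasets: Iterable[ChoiceDataset],
                       stratify_by_target: bool = True) -> pd.DataFrame:
    """Concatenated per-dataset frequency tables across runs and conditions."""
    parts = [discounted_choice_frequency(d, stratify_by_target) for d in datasets]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


@dataclass
class ClassificationThresholds:
    """Exclusion/flagging thresholds (all configurable)."""

    non_discounter: float = 0.05
    repeater: float = 0.95
    extreme_kappa: float = 2.0
    excess_missing: float = 0.10


@dataclass
class SubjectFlags:
    """Deterministic per-subject quality flags."""

    subject_id: str
    non_discounter: Dict[str, bool] = field(default_factory=dict)  # per condition
    repeater: Dict[str, bool] = field(default_factory=dict)        # per run
    excess_missing: Dict[str, bool] = field(default_factory=dict)  # per run
    extreme_kappa: Dict[str, bool] = field(default_factory=dict)   # per fit key

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "non_discounter": self.non_discounter,
            "repeater": self.repeater,
            "excess_missing": self.excess_missing,
            "extreme_kappa": self.extreme_kappa,
        }


def classify_subjects(datasets: Iterable[ChoiceDataset],
                      fits: Optional[Mapping[str, FitResult]] = None,
                      thresholds: Optional[ClassificationThresholds] = None,
                      ) -> SubjectFlags:
    """Classify one subject's datasets (and optional fits) against thresholds.

    Non-discounting is judged per condition over all that condition's trials;
    repeating and missingness per run over all that run's trials.  *fits*
    maps an arbitrary key (e.g. ``"A/reward"``) to a :class:`FitResult`
    whose ``kappa`` is checked against the extreme-rate threshold.
    Classification is invariant to trial order.
    """
    th = thresholds or ClassificationThresholds()
    datasets = list(datasets)
    if not datasets:
        raise ValueError("classify_subjects needs at least one dataset")
    subject_ids = {d.subject_id for d in datasets}
    if len(subject_ids) != 1:
        raise ValueError("classify_subjects handles one subject at a time")
    flags = SubjectFlags(subject_id=next(iter(subject_ids)))

    by_condition: Dict[str, List[ChoiceDataset]] = {}
    by_run: Dict[str, List[ChoiceDataset]] = {}
    for d in datasets:
        by_condition.setdefault(d.condition, []).append(d)
        by_run.setdefault(d.run, []).append(d)

    for cond, ds in by_condition.items():
        discounted = np.concatenate([_discounted_mask(d)[d.responded] for d in ds])
        flags.non_discounter[cond] = bool(
            discounted.size and discounted.mean() < th.non_discounter
        )

    for run, ds in by_run.items():
        imm = np.concatenate([d.immediate[d.responded] for d in ds])
        n = imm.size
        flags.repeater[run] = bool(
            n and max(imm.mean(), 1.0 - imm.mean()) > th.repeater
        )
        total = sum(len(d) for d in ds)
        missing = total - sum(d.n_used for d in ds)
        flags.excess_missing[run] = bool(total and missing / total > th.excess_missing)

    for key, fit in (fits or {}).items():
        flags.extreme_kappa[key] = bool(fit.params.get("kappa") > th.extreme_kappa)
    return flags
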