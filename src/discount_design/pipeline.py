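"""End-to-end orchestration of the adaptive paradigm loop.

One iteration of the paradigm-optimization loop: generate the common
calibration run, obtain choices (simulated from synthetic agents or
ingested from CSV), fit the trial-generating model, generate the adaptive
run from the fits, obtain choices again, then compute behavioral variables,
subject flags and the cross-run model-comparison table.  All randomness is
seeded and the seeds are logged in the report, so a rerun with identical
inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .inference import (
    ChoiceDataset,
    FitConfig,
    FitResult,
    cross_run_model_comparison,
    fit_mle,
)
from .metrics import (
    ClassificationThresholds,
    SubjectFlags,
    behavioral_summary,
    classify_subjects,
)
from .models import ModelId
from .simulate import SyntheticAgent, simulate_choices
from .trials import RunAConfig, RunBConfig, generate_run_a, generate_run_b

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment_loop"]

ALL_MODELS = tuple(m for m in ModelId)


@dataclass
class ExperimentConfig:
    """Configuration of one loop iteration."""

    run_a: RunAConfig
    run_b: RunBConfig
    trial_model: ModelId = ModelId.HYPERBOLIC
    comparison_models: Sequence[Union[ModelId, str]] = ALL_MODELS
    fit_config: FitConfig = field(default_factory=FitConfig)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)

    def __post_init__(self):
        self.trial_model = ModelId.coerce(self.trial_model)


@dataclass
class ExperimentReport:
    """Bundle of everything one loop iteration produced."""

    run_a_trials: Dict[str, pd.DataFrame]
    run_b_trials: Dict[str, pd.DataFrame]
    datasets: Dict[str, ChoiceDataset]          # key "subject/run/condition"
    fits: Dict[str, FitResult]                  # key "subject/run/condition"
    behavioral: pd.DataFrame
    flags: Dict[str, SubjectFlags]
    comparisons: Dict[str, pd.DataFrame]        # key "subject/condition"
    seeds: Dict[str, int]
    errors: List[str]

    def save(self, outdir: Union[str, Path]) -> None:
        """Write the report as CSVs plus a JSON index (no timestamps)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.concat(self.run_a_trials.values(), ignore_index=True).to_csv(
            outdir / "run_a_trials.csv", index=False)
        if self.run_b_trials:
            pd.concat(self.run_b_trials.values(), ignore_index=True).to_csv(
                outdir / "run_b_trials.csv", index=False)
        if self.datasets:
            pd.concat([d.to_frame() for d in self.datasets.values()],
                      ignore_index=True).to_csv(outdir / "choices.csv", index=False)
        self.behavioral.to_csv(outdir / "behavioral_summary.csv", index=False)
        if self.comparisons:
            pd.concat(
                [t.assign(key=k) for k, t in self.comparisons.items()],
                ignore_index=True,
            ).to_csv(outdir / "model_comparison.csv", index=False)
        index = {
            "seeds": self.seeds,
            "errors": self.errors,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "flags": {k: f.to_dict() for k, f in self.flags.items()},
        }
        (outdir / "report.json").write_text(json.dumps(index, indent=2, sort_keys=True))


def run_experiment_loop(config: ExperimentConfig,
                        population: Optional[Sequence[SyntheticAgent]] = None,
                        data: Optional[Dict[str, Dict[str, ChoiceDataset]]] = None,
                        seed: int = 0) -> ExperimentReport:
    """Run one loop iteration on a synthetic population or ingested data.

    Exactly one of *population* (synthetic agents whose choices are
    simulated) or *data* (mapping ``subject -> {"A": {cond: dataset}, "B":
    ...}`` of observed choices; run B datasets optional) must be given.
    Stage failures are recorded per subject with stage provenance and do not
    abort the loop.
    """
    if (population is None) == (data is None):
        raise ValueError("provide exactly one of population= or data=")

    seeds: Dict[str, int] = {"root": int(seed)}
    ss = np.random.SeedSequence(seed)
    run_a = generate_run_a(config.run_a, seed=int(ss.generate_state(1)[0]) & 0x7FFFFFFF)
    seeds["run_a"] = int(run_a["seed"].iloc[0])

    subjects = ([a.subject_id for a in population] if population is not None
                else sorted(data.keys()))
    agent_by_id = {a.subject_id: a for a in population} if population is not None else {}
    subject_seeds = {
        sid: [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence((seed, i)).generate_state(3)]
        for i, sid in enumerate(subjects)
    }

    report = ExperimentReport(
        run_a_trials={}, run_b_trials={}, datasets={}, fits={},
        behavioral=pd.DataFrame(), flags={}, comparisons={},
        seeds=seeds, errors=[],
    )

    for sid in subjects:
        s_sim_a, s_runb, s_sim_b = subject_seeds[sid]
        seeds[f"{sid}/simulate_a"] = s_sim_a
        seeds[f"{sid}/run_b"] = s_runb
        seeds[f"{sid}/simulate_b"] = s_sim_b
        run_a_s = run_a.assign(subject_id=sid)
        report.run_a_trials[sid] = run_a_s
        conditions = list(config.run_a.conditions)

        # --- run A choices -------------------------------------------------
        try:
            if population is not None:
                ds_a = simulate_choices(agent_by_id[sid], run_a_s, seed=s_sim_a)
                if isinstance(ds_a, ChoiceDataset):
                    ds_a = {ds_a.condition: ds_a}
            else:
                ds_a = data[sid]["A"]
        except Exception as exc:
            report.errors.append(f"{sid}/run_a_choices: {exc}")
            continue
        for cond, d in ds_a.items():
            report.datasets[f"{sid}/A/{cond}"] = d

        # --- fit the trial-generating model on run A -----------------------
        fits_a: Dict[str, FitResult] = {}
        try:
            for cond in conditions:
                fits_a[cond] = fit_mle(config.trial_model, ds_a[cond], config.fit_config)
                report.fits[f"{sid}/A/{cond}"] = fits_a[cond]
        except Exception as exc:
            report.errors.append(f"{sid}/fit_run_a: {exc}")
            continue

        # --- generate + answer run B --------------------------------------
        try:
            run_b_s = generate_run_b({c: f.params for c, f in fits_a.items()},
                                     config.run_b, subject_id=sid, seed=s_runb)
            report.run_b_trials[sid] = run_b_s
            if population is not None:
                ds_b = simulate_choices(agent_by_id[sid], run_b_s, seed=s_sim_b)
                if isinstance(ds_b, ChoiceDataset):
                    ds_b = {ds_b.condition: ds_b}
            else:
                ds_b = data[sid].get("B", {})
        except Exception as exc:
            report.errors.append(f"{sid}/run_b: {exc}")
            continue
        for cond, d in ds_b.items():
            report.datasets[f"{sid}/B/{cond}"] = d

        # --- model comparison + flags -------------------------------------
        for cond in conditions:
            if cond not in ds_b:
                continue
            try:
                table = cross_run_model_comparison(
                    ds_a[cond], ds_b[cond], config.comparison_models, config.fit_config)
                report.comparisons[f"{sid}/{cond}"] = table
            except Exception as exc:
                report.errors.append(f"{sid}/compare/{cond}: {exc}")
        try:
            subject_datasets = [d for k, d in report.datasets.items()
                                if k.startswith(f"{sid}/")]
            subject_fits = {k.split("/", 1)[1]: f for k, f in report.fits.items()
                            if k.startswith(f"{sid}/")}
            report.flags[sid] = classify_subjects(
                subject_datasets, subject_fits, config.thresholds)
        except Exception as exc:
            report.errors.append(f"{sid}/classify: {exc}")

    report.behavioral = behavioral_summary(report.datasets.values())
    return report
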