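"""Trial generation: common calibration trials (run A) and model-inverted,
subject-tailored trials (run B).

Run A presents every combination of a delay grid, a delayed-outcome grid and
a grid of *hypothetical* hyperbolic discount rates; for each combination the
immediate outcome is placed at the hypothetical indifference point
(``r1 = r2 / (1 + kappa * D)``, i.e. the inversion at target probability 0.5
with sensitivity fixed to 1).

Run B inverts the subject's own fitted choice model: solving the logistic
link for the immediate outcome that evokes a predetermined immediate-choice
probability ``p1`` gives

    r1 = V(delayed) + log(p1 / (1 - p1)) / beta

valid for ``0 < p1 < 1`` and ``beta > 0``.  A few parameter constellations
yield atypical candidates (sign-violating, equal, or magnitude-inverted
outcome pairs); these are resolved by stepping the delay one day at a time
and re-solving, with penny-level fallbacks when the delay grid is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelId, ModelParams, Trial, _require_valid, discount_factor

__all__ = [
    "RunAConfig",
    "RunBConfig",
    "EXP1_RUN_A",
    "EXP2_RUN_A",
    "EXP3_RUN_A",
    "run_b_config_for",
    "penny_round",
    "solve_immediate_outcome",
    "generate_run_a",
    "resolve_atypical_trial",
    "generate_run_b",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "subject_id", "run", "condition", "block", "trial_index",
    "r1", "r2", "delay_days", "target_p1", "generating_model",
    "adjusted", "seed",
]

_CONDITION_SIGN = {"reward": 1.0, "loss": -1.0}


def penny_round(x: float, penny: float = 0.01) -> float:
    """Round to the smallest currency unit, half away from zero.

    The result is re-rounded to 10 decimals so that e.g. 53 * 0.01 compares
    equal to the literal 0.53.
    """
    if x == 0.0:
        return 0.0
    return round(math.copysign(math.floor(abs(x) / penny + 0.5) * penny, x), 10)


@dataclass
class RunAConfig:
    """Grids defining the common calibration run.

    ``hypothetical_kappas`` are the assumed hyperbolic discount rates at
    whose indifference points the trials are placed.  ``delayed_outcomes``
    are magnitudes in GBP; the sign is applied per condition.  Per-condition
    delay grids may override ``delays`` (used when the loss condition needs
    longer delays to tempt discounting).
    """

    delays: Sequence[int]
    delayed_outcomes: Sequence[float]
    hypothetical_kappas: Sequence[float]
    conditions: Sequence[str] = ("reward", "loss")
    delay_overrides: Dict[str, Sequence[int]] = field(default_factory=dict)
    block_size: int = 40

    def __post_init__(self):
        if not (len(self.delays) and len(self.delayed_outcomes) and len(self.hypothetical_kappas)
                and len(self.conditions)):
            raise ValueError("all run-A grids must be non-empty")
        if any(d <= 0 or int(d) != d for d in self.delays):
            raise ValueError("delays must be positive integers")
        if any(o <= 0 for o in self.delayed_outcomes):
            raise ValueError("delayed outcome magnitudes must be positive")
        for cond in self.conditions:
            if cond not in _CONDITION_SIGN:
                raise ValueError(f"unknown condition {cond!r}")

    def delays_for(self, condition: str) -> Sequence[int]:
        return self.delay_overrides.get(condition, self.delays)

    @property
    def n_trials(self) -> int:
        return (len(self.delays) * len(self.delayed_outcomes)
                * len(self.hypothetical_kappas) * len(self.conditions))

    def to_dict(self) -> dict:
        return {
            "delays": list(self.delays),
            "delayed_outcomes": list(self.delayed_outcomes),
            "hypothetical_kappas": list(self.hypothetical_kappas),
            "conditions": list(self.conditions),
            "delay_overrides": {k: list(v) for k, v in self.delay_overrides.items()},
            "block_size": self.block_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunAConfig":
        return cls(**d)


@dataclass
class RunBConfig:
    """Grids defining the adaptive run.

    ``target_probs`` are the immediate-choice probabilities the generated
    trials should evoke, each strictly inside (0, 1).  The delay sweep used
    to resolve atypical candidates runs between ``min_delay`` and
    ``max_delay`` (defaulting to the condition's grid extremes).
    """

    target_probs: Sequence[float]
    delays: Sequence[int]
    delayed_outcomes: Sequence[float]
    conditions: Sequence[str] = ("reward", "loss")
    delay_overrides: Dict[str, Sequence[int]] = field(default_factory=dict)
    min_delay: Optional[int] = None
    max_delay: Optional[int] = None
    penny: float = 0.01
    block_size: int = 40

    def __post_init__(self):
        if not (len(self.target_probs) and len(self.delays) and len(self.delayed_outcomes)
                and len(self.conditions)):
            raise ValueError("all run-B grids must be non-empty")
        if any(not (0.0 < p < 1.0) for p in self.target_probs):
            raise ValueError("each target probability must lie strictly inside (0, 1)")
        if any(d <= 0 or int(d) != d for d in self.delays):
            raise ValueError("delays must be positive integers")

    def delays_for(self, condition: str) -> Sequence[int]:
        return self.delay_overrides.get(condition, self.delays)

    def sweep_bounds(self, condition: str) -> tuple:
        delays = self.delays_for(condition)
        lo = self.min_delay if self.min_delay is not None else min(delays)
        hi = self.max_delay if self.max_delay is not None else max(delays)
        return int(lo), int(hi)

    @property
    def n_trials(self) -> int:
        return (len(self.delays) * len(self.delayed_outcomes)
                * len(self.target_probs) * len(self.conditions))

    def to_dict(self) -> dict:
        return {
            "target_probs": list(self.target_probs),
            "delays": list(self.delays),
            "delayed_outcomes": list(self.delayed_outcomes),
            "conditions": list(self.conditions),
            "delay_overrides": {k: list(v) for k, v in self.delay_overrides.items()},
            "min_delay": self.min_delay,
            "max_delay": self.max_delay,
            "penny": self.penny,
            "block_size": self.block_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunBConfig":
        return cls(**d)


# Grids used across the three experiment iterations: the initial literature
# grids, the recalibrated grids matching the empirically observed (mostly
# very low) discount rates, and the loss-delay extension.
EXP1_RUN_A = RunAConfig(
    delays=(2, 7, 30, 90, 180),
    delayed_outcomes=(2, 5, 10, 20),
    hypothetical_kappas=(0.01, 0.1, 0.2, 0.6),
)
EXP2_RUN_A = RunAConfig(
    delays=(7, 30, 90, 180, 365),
    delayed_outcomes=(5, 10, 20, 50),
    hypothetical_kappas=(0.00001, 0.001, 0.01, 0.6),
)
EXP3_RUN_A = RunAConfig(
    delays=(7, 30, 90, 180, 365),
    delayed_outcomes=(5, 10, 20, 50),
    hypothetical_kappas=(0.00001, 0.001, 0.01, 0.6),
    delay_overrides={"loss": (30, 90, 180, 365, 1095)},
)


def run_b_config_for(run_a: RunAConfig,
                     target_probs: Sequence[float] = (0.3, 0.5, 0.7)) -> RunBConfig:
    """Adaptive-run config reusing the delays and outcomes of *run_a*."""
    return RunBConfig(
        target_probs=target_probs,
        delays=run_a.delays,
        delayed_outcomes=run_a.delayed_outcomes,
        conditions=run_a.conditions,
        delay_overrides=dict(run_a.delay_overrides),
    )


def solve_immediate_outcome(params: ModelParams, r2: float, delay_days: float,
                            p1: float) -> float:
    """Immediate outcome evoking immediate-choice probability *p1*.

    Inverts the logistic link: ``r1 = v2 + log(p1 / (1 - p1)) / beta`` where
    ``v2`` is the model's discounted value of ``(r2, delay_days)``.  The
    result is raw (unrounded) and may be atypical — negative, equal to or
    exceeding ``r2`` — for extreme parameter constellations.  At ``p1 = 0.5``
    the logit term drops and ``r1`` equals the discounted value exactly.
    """
    if not 0.0 < p1 < 1.0:
        raise ValueError("p1 must lie strictly inside (0, 1)")
    _require_valid(params)
    beta = params.get("beta")
    if beta <= 0.0:
        raise ValueError("inversion requires beta > 0")
    v2 = discount_factor(params, delay_days) * r2
    if p1 == 0.5:
        return float(v2)
    return float(v2 + math.log(p1 / (1.0 - p1)) / beta)


def _shuffled_blocks(trials: List[dict], conditions: Sequence[str], block_size: int,
                     seed: int) -> pd.DataFrame:
    """Randomize trial order within conditions and interleave condition blocks."""
    rng = np.random.default_rng(seed)
    per_condition = {}
    for cond in conditions:
        rows = [t for t in trials if t["condition"] == cond]
        order = rng.permutation(len(rows))
        per_condition[cond] = [rows[i] for i in order]
    # Alternate fixed-size blocks of each condition (reward first), the
    # remainder forming a final shorter block per condition.
    out, block = [], 0
    while any(per_condition[c] for c in conditions):
        for cond in conditions:
            chunk, per_condition[cond] = (
                per_condition[cond][:block_size], per_condition[cond][block_size:]
            )
            for t in chunk:
                out.append({**t, "block": block})
            if chunk:
                block += 1
    df = pd.DataFrame(out)
    df["trial_index"] = np.arange(len(df))
    return df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]


def generate_run_a(config: RunAConfig, subject_id: str = "s0", seed: int = 0) -> pd.DataFrame:
    """Generate the common calibration trial table.

    One trial per condition x delay x delayed outcome x hypothetical kappa,
    with the immediate outcome at the hyperbolic indifference point of the
    hypothetical rate (penny-rounded).  Trial order within condition blocks
    is randomized with *seed*; the table carries the seed for reproducibility.
    """
    trials = []
    for cond in config.conditions:
        sign = _CONDITION_SIGN[cond]
        for kappa in config.hypothetical_kappas:
            params = ModelParams(ModelId.HYPERBOLIC, kappa=kappa, beta=1.0)
            for D in config.delays_for(cond):
                for mag in config.delayed_outcomes:
                    r2 = sign * mag
                    r1 = penny_round(solve_immediate_outcome(params, r2, D, 0.5))
                    trials.append({
                        "subject_id": subject_id,
                        "run": "A",
                        "condition": cond,
                        "r1": r1,
                        "r2": float(r2),
                        "delay_days": int(D),
                        "target_p1": np.nan,
                        "generating_model": ModelId.HYPERBOLIC.value,
                        "adjusted": False,
                        "seed": seed,
                        "hypothetical_kappa": kappa,
                    })
    return _shuffled_blocks(trials, config.conditions, config.block_size, seed)


def _atypical_case(r1: float, r2: float, condition: str) -> Optional[int]:
    """Which atypical case a rounded candidate falls in (None if valid).

    1: sign violation (non-positive immediate reward / non-negative
       immediate loss); 2: immediate equals delayed outcome; 3: immediate
       exceeds the delayed outcome in magnitude.
    """
    if condition == "reward":
        if r1 <= 0:
            return 1
        if r1 == r2:
            return 2
        if r1 > r2:
            return 3
    else:
        if r1 >= 0:
            return 1
        if r1 == r2:
            return 2
        if r1 < r2:
            return 3
    return None


def resolve_atypical_trial(trial: Trial, params: ModelParams,
                           config: RunBConfig) -> Trial:
    """Resolve an atypical run-B candidate into a well-formed trial.

    The delay is stepped by one day — shrinking it when the immediate
    outcome is too small (raising the discounted value raises ``r1``),
    growing it when the immediate outcome matches or exceeds the delayed one
    — re-solving the inversion at each step until the candidate is valid or
    the sweep bounds are reached.  Unresolved candidates fall back to penny
    adjustments: sign violations are set to +/- one penny, equalities are
    moved one penny toward zero, and magnitude inversions are clamped one
    penny inside the delayed outcome.  Resolving an already-valid trial
    changes nothing.
    """
    if trial.target_p1 is None:
        raise ValueError("candidate must carry its target p1")
    penny = config.penny
    r2 = trial.r2
    lo, hi = config.sweep_bounds(trial.condition)
    D = int(trial.delay_days)
    r1 = penny_round(trial.r1, penny)
    case = _atypical_case(r1, r2, trial.condition)
    changed = r1 != trial.r1

    guard = 0
    while case is not None and guard <= (hi - lo) + 2:
        guard += 1
        step = -1 if case == 1 else 1
        D_next = D + step
        if D_next < max(lo, 1) or D_next > hi:
            break
        D = D_next
        r1 = penny_round(solve_immediate_outcome(params, r2, D, trial.target_p1), penny)
        changed = True
        case = _atypical_case(r1, r2, trial.condition)

    if case == 1:
        r1 = penny if trial.condition == "reward" else -penny
        changed = True
        case = _atypical_case(r1, r2, trial.condition)
    if case == 3:
        # No stated fallback for this case; clamp one penny inside r2.
        r1 = r2 - penny if trial.condition == "reward" else r2 + penny
        changed = True
        case = _atypical_case(r1, r2, trial.condition)
    if case == 2:
        r1 = r1 - penny if trial.condition == "reward" else r1 + penny
        changed = True

    resolved = replace(trial, r1=r1, delay_days=D,
                       adjusted=trial.adjusted or changed)
    assert resolved.is_valid(), f"unresolvable candidate: {resolved}"
    return resolved


def generate_run_b(fits: Dict[str, ModelParams], config: RunBConfig,
                   subject_id: str = "s0", seed: int = 0,
                   round_to_penny: bool = True, resolve: bool = True) -> pd.DataFrame:
    """Generate the subject-tailored adaptive trial table.

    *fits* maps each requested condition to that subject's fitted model
    parameters (``beta > 0`` required — the inversion is undefined at the
    zero boundary, in which case the caller must supply a fallback).  One
    trial per condition x target probability x delay x delayed outcome;
    immediate outcomes come from the model inversion, are penny-rounded and
    passed through atypical-trial resolution (both steps can be disabled to
    inspect the raw inversion).  Trial order within condition blocks is
    randomized with *seed*.
    """
    trials = []
    for cond in config.conditions:
        params = fits.get(cond)
        if params is None:
            raise ValueError(f"no fitted parameters supplied for condition {cond!r}")
        if hasattr(params, "params"):  # accept FitResult
            params = params.params
        if params.get("beta") <= 0.0:
            raise ValueError(
                f"fitted beta is at the zero boundary for condition {cond!r}; "
                "trial inversion is undefined — supply a fallback beta"
            )
        sign = _CONDITION_SIGN[cond]
        for p1 in config.target_probs:
            for D in config.delays_for(cond):
                for mag in config.delayed_outcomes:
                    r2 = sign * mag
                    r1 = solve_immediate_outcome(params, r2, D, p1)
                    adjusted = False
                    delay = int(D)
                    if round_to_penny:
                        r1 = penny_round(r1, config.penny)
                    if resolve:
                        resolved = resolve_atypical_trial(
                            Trial(cond, r1, float(r2), delay, target_p1=p1),
                            params, config,
                        )
                        r1, delay, adjusted = resolved.r1, int(resolved.delay_days), resolved.adjusted
                    trials.append({
                        "subject_id": subject_id,
                        "run": "B",
                        "condition": cond,
                        "r1": r1,
                        "r2": float(r2),
                        "delay_days": delay,
                        "target_p1": p1,
                        "generating_model": params.model.value,
                        "adjusted": adjusted,
                        "seed": seed,
                    })
    return _shuffled_blocks(trials, config.conditions, config.block_size, seed)
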