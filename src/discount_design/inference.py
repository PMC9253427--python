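"""Softmax choice link, likelihood, ML fitting and out-of-sample prediction.

The probability of choosing the immediate option given subjective values
``v1`` (immediate) and ``v2`` (delayed) is the logistic link

    p(immediate) = 1 / (1 + exp(beta * (v2 - v1)))

with sensitivity ``beta >= 0`` (``beta -> 0`` random choice, ``beta -> inf``
deterministic choice of the higher-valued option).  Model parameters are
inferred by maximising the Bernoulli log-likelihood of observed choices over
the model's constrained parameter space with multi-start bounded local
optimization.  Fitted models are evaluated by the average predicted
probability of observed choices ``p_hat`` on held-out data; the prediction
error is ``PE = 1 - p_hat``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    DELTA_CAP,
    KAPPA_CAP,
    ModelId,
    ModelParams,
    Trial,
    _factor_unchecked,
    _require_valid,
    free_param_names,
    param_bounds,
)

__all__ = [
    "ACTIONS",
    "ChoiceRecord",
    "ChoiceDataset",
    "FitConfig",
    "FitResult",
    "PredictionSummary",
    "immediate_choice_prob",
    "log_likelihood",
    "fit_mle",
    "predicted_probability_summary",
    "cross_run_model_comparison",
]

ACTIONS = ("immediate", "delayed", "missing")

# Numeric guards: clamp the softmax exponent and clip probabilities inside
# the log. Both are far below any reportable tolerance.
_EXP_CLAMP = 700.0
_P_CLIP = 1e-12
#: A parameter within this absolute distance of a bound is flagged.
BOUNDARY_TOL = 1e-6


@dataclass
class ChoiceRecord:
    """One trial plus the observed action and reaction time.

    ``action == "missing"`` (no response within the decision window) carries
    no likelihood contribution.
    """

    trial: Trial
    action: str
    rt_ms: Optional[float] = None

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"action must be one of {ACTIONS}, got {self.action!r}")
        if self.rt_ms is not None and self.rt_ms < 0:
            raise ValueError("rt_ms must be nonnegative")


class ChoiceDataset:
    """Ordered choices of one subject in one condition of one run.

    Internally column-oriented (numpy arrays) so the likelihood is fully
    vectorized; construct from :class:`ChoiceRecord` lists or data frames.
    """

    def __init__(self, subject_id: str, condition: str, run: str,
                 records: Sequence[ChoiceRecord]):
        if condition not in ("reward", "loss"):
            raise ValueError(f"condition must be 'reward' or 'loss', got {condition!r}")
        for rec in records:
            if rec.trial.condition != condition:
                raise ValueError("all records must share the dataset's condition")
        self.subject_id = str(subject_id)
        self.condition = condition
        self.run = str(run)
        self.records: List[ChoiceRecord] = list(records)
        self.r1 = np.array([r.trial.r1 for r in records], dtype=float)
        self.r2 = np.array([r.trial.r2 for r in records], dtype=float)
        self.delay_days = np.array([r.trial.delay_days for r in records], dtype=float)
        self.target_p1 = np.array(
            [np.nan if r.trial.target_p1 is None else r.trial.target_p1 for r in records],
            dtype=float,
        )
        self.action = np.array([r.action for r in records], dtype=object)
        self.rt_ms = np.array(
            [np.nan if r.rt_ms is None else r.rt_ms for r in records], dtype=float
        )
        self.responded = self.action != "missing"
        self.immediate = self.action == "immediate"

    def __len__(self):
        return len(self.records)

    @property
    def n_used(self) -> int:
        """Number of non-missing (responded) trials."""
        return int(self.responded.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "run": self.run,
                "condition": self.condition,
                "trial_index": np.arange(len(self)),
                "r1": self.r1,
                "r2": self.r2,
                "delay_days": self.delay_days,
                "target_p1": self.target_p1,
                "action": self.action,
                "rt_ms": self.rt_ms,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceDataset":
        if df.empty:
            raise ValueError("cannot build a ChoiceDataset from an empty frame")
        subject = str(df["subject_id"].iloc[0])
        run = str(df["run"].iloc[0])
        condition = str(df["condition"].iloc[0])
        records = []
        for row in df.itertuples(index=False):
            p1 = getattr(row, "target_p1", np.nan)
            rt = getattr(row, "rt_ms", np.nan)
            records.append(
                ChoiceRecord(
                    Trial(
                        condition=condition,
                        r1=float(row.r1),
                        r2=float(row.r2),
                        delay_days=float(row.delay_days),
                        target_p1=None if pd.isna(p1) else float(p1),
                    ),
                    action=str(row.action),
                    rt_ms=None if pd.isna(rt) else float(rt),
                )
            )
        return cls(subject, condition, run, records)


def immediate_choice_prob(beta: float, v1, v2):
    """Probability of the immediate choice under the logistic value link.

    Vectorized over ``v1``/``v2``; the complementary delayed probability is
    one minus the returned value.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = np.clip(np.asarray(beta * (np.asarray(v2, dtype=float) - np.asarray(v1, dtype=float))),
                -_EXP_CLAMP, _EXP_CLAMP)
    p = 1.0 / (1.0 + np.exp(x))
    return float(p) if p.ndim == 0 else p


def _observed_choice_probs(params: ModelParams, data: ChoiceDataset) -> np.ndarray:
    """Predicted probability of each observed (non-missing) choice."""
    mask = data.responded
    factor = _factor_unchecked(params, data.delay_days[mask])
    v2 = factor * data.r2[mask]
    p1 = immediate_choice_prob(params.get("beta"), data.r1[mask], v2)
    p1 = np.atleast_1d(p1)
    return np.where(data.immediate[mask], p1, 1.0 - p1)


def log_likelihood(params: ModelParams, data: ChoiceDataset) -> float:
    """Bernoulli log-likelihood of the observed choices under *params*.

    Missing responses are excluded; an empty or all-missing dataset scores 0.
    """
    _require_valid(params)
    if data.n_used == 0:
        return 0.0
    p = np.clip(_observed_choice_probs(params, data), _P_CLIP, 1.0 - _P_CLIP)
    return float(np.log(p).sum())


@dataclass
class FitConfig:
    """Multi-start optimizer settings for :func:`fit_mle`.

    The likelihood surface is multimodal for the flexible models, so each fit
    runs ``n_starts`` bounded L-BFGS-B searches from seeded random starting
    points: ``kappa`` log-uniform over its range (lower edge 1e-6), ``beta``
    log-uniform over [0.01, 100], the extra parameters uniform over their
    ranges.  Models with more than two parameters additionally get one
    *nested warm start* from the fitted two-parameter backbone they reduce
    to (hyperbolic at ``s = 1``, exponential at ``gamma = 1`` / ``w = 1`` /
    ``delta = 1``): on adaptive-run data the random starts frequently all
    collapse into the flat "random choice" basin (``beta ~ 0``) while the
    backbone solution sits on the narrow ridge, and the warm start also
    guarantees a nesting model never fits worse than its special case.  The
    best start wins.
    """

    n_starts: int = 10
    seed: int = 0
    maxiter: int = 500
    boundary_tol: float = BOUNDARY_TOL
    nested_warm_start: bool = True


@dataclass
class FitResult:
    """Maximum-likelihood estimate with diagnostics."""

    params: ModelParams
    log_lik: float
    converged: bool
    n_starts: int
    at_boundary: Dict[str, bool]
    n_used: int

    def to_dict(self) -> dict:
        return {
            **self.params.to_dict(),
            "log_lik": self.log_lik,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "at_boundary": self.at_boundary,
            "n_used": self.n_used,
        }


# Two-parameter backbone of each flexible model, plus the mapping from the
# backbone's (kappa, beta) solution to a start on the flexible model's
# reduction manifold.
def _nested_starts(model: ModelId, data: "ChoiceDataset", cfg: "FitConfig") -> list:
    backbone = {
        ModelId.HYPERBOLOID: ModelId.HYPERBOLIC,
        ModelId.MODIFIED_HYPERBOLOID: ModelId.HYPERBOLIC,
        ModelId.QUASI_HYPERBOLIC: ModelId.EXPONENTIAL,
        ModelId.DOUBLE_EXPONENTIAL: ModelId.EXPONENTIAL,
        ModelId.CONSTANT_SENSITIVITY: ModelId.EXPONENTIAL,
    }.get(model)
    if backbone is None:
        return []
    sub_cfg = FitConfig(n_starts=cfg.n_starts, seed=cfg.seed, maxiter=cfg.maxiter,
                        nested_warm_start=False)
    fit = fit_mle(backbone, data, sub_cfg)
    k, b = fit.params.get("kappa"), fit.params.get("beta")
    if model in (ModelId.HYPERBOLOID, ModelId.MODIFIED_HYPERBOLOID):
        start = {"kappa": k, "s": 1.0, "beta": b}
    elif model is ModelId.QUASI_HYPERBOLIC:
        start = {"kappa": k, "gamma": 1.0, "beta": b}
    elif model is ModelId.DOUBLE_EXPONENTIAL:
        start = {"kappa": k, "kappa2": k, "w": 0.5, "beta": b}
    else:  # constant sensitivity: exponential kappa_e = exp(-kappa)
        k_cs = -math.log(k) if k > 0 else DELTA_CAP
        start = {"kappa": float(np.clip(k_cs, 1e-9, KAPPA_CAP)), "delta": 1.0, "beta": b}
    return [np.array([start[n] for n in free_param_names(model)])]


def _random_start(model: ModelId, rng: np.random.Generator) -> np.ndarray:
    values = []
    for name in free_param_names(model):
        lo, hi = param_bounds(model, name)
        if name == "kappa":
            if hi == 1.0:
                # unit-interval kappa is a daily retention whose informative
                # region sits near 1; initialize log-uniformly on the decay
                # *rate* r = -ln(kappa) so starts cover kappa up to ~0.9999
                # instead of piling into the flat kappa ~ 0 basin.
                rate = np.exp(rng.uniform(np.log(1e-4), np.log(10.0)))
                values.append(float(np.exp(-rate)))
                continue
            lo_eff = max(lo, 1e-6)
            values.append(np.exp(rng.uniform(np.log(lo_eff), np.log(hi))))
        elif name == "beta":
            values.append(np.exp(rng.uniform(np.log(0.01), np.log(hi))))
        else:
            lo_eff = max(lo, 1e-6) if name == "delta" else lo
            values.append(rng.uniform(lo_eff, hi))
    return np.array(values)


def fit_mle(model: Union[ModelId, str], data: ChoiceDataset,
            fit_config: Optional[FitConfig] = None) -> FitResult:
    """Fit *model* to *data* by constrained maximum likelihood.

    Deterministic given ``fit_config.seed``.  Raises if the dataset has no
    responded trials; if every optimizer start fails, the best evaluated
    start is returned with ``converged=False``.
    """
    model = ModelId.coerce(model)
    cfg = fit_config or FitConfig()
    if data.n_used == 0:
        raise ValueError("fit_mle requires at least one non-missing record")

    names = free_param_names(model)
    bounds = [param_bounds(model, n) for n in names]
    # Keep strictly-positive parameters off their singular lower edge.
    bounds = [
        (max(lo, 1e-9) if n in ("delta",) or (n == "kappa" and model is ModelId.CONSTANT_SENSITIVITY) else lo, hi)
        for (lo, hi), n in zip(bounds, names)
    ]
    template = ModelParams(model, **{n: 0.5 * (lo + hi) for n, (lo, hi) in zip(names, bounds)})

    mask = data.responded
    r1, r2, D = data.r1[mask], data.r2[mask], data.delay_days[mask]
    imm = data.immediate[mask]

    def neg_ll(theta: np.ndarray) -> float:
        p = template.replace_free(np.clip(theta, [b[0] for b in bounds], [b[1] for b in bounds]))
        factor = _factor_unchecked(p, D)
        x = np.clip(p.get("beta") * (factor * r2 - r1), -_EXP_CLAMP, _EXP_CLAMP)
        p1 = 1.0 / (1.0 + np.exp(x))
        p_obs = np.clip(np.where(imm, p1, 1.0 - p1), _P_CLIP, 1.0 - _P_CLIP)
        return -float(np.log(p_obs).sum())

    rng = np.random.default_rng(cfg.seed)
    starts = [_random_start(model, rng) for _ in range(cfg.n_starts)]
    if cfg.nested_warm_start:
        starts += _nested_starts(model, data, cfg)
    best = None
    any_success = False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": cfg.maxiter})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    params = template.replace_free(theta)
    at_boundary = {
        n: bool(min(abs(t - lo), abs(hi - t)) <= cfg.boundary_tol)
        for n, t, (lo, hi) in zip(names, theta, bounds)
    }
    return FitResult(
        params=params,
        log_lik=-float(best.fun),
        converged=any_success,
        n_starts=cfg.n_starts,
        at_boundary=at_boundary,
        n_used=data.n_used,
    )


@dataclass
class PredictionSummary:
    """Average predicted probability of observed choices and its complements.

    ``p_hat`` averages over all responded trials; ``p_hat_weighted`` averages
    the two per-class means (immediate-observed, delayed-observed) equally so
    a model is not rewarded for only predicting the majority class.  When one
    class is absent the weighted variant falls back to ``p_hat`` and
    ``weighted_fallback`` is set.
    """

    p_hat: float
    pe: float
    p_hat_weighted: float
    n_immediate: int
    n_delayed: int
    weighted_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "pe": self.pe,
            "p_hat_weighted": self.p_hat_weighted,
            "n_immediate": self.n_immediate,
            "n_delayed": self.n_delayed,
            "weighted_fallback": self.weighted_fallback,
        }


def predicted_probability_summary(params: ModelParams, data: ChoiceDataset) -> PredictionSummary:
    """Summarize how well *params* predicts the observed choices in *data*."""
    _require_valid(params)
    if data.n_used == 0:
        raise ValueError("predicted_probability_summary requires >= 1 non-missing record")
    p_obs = _observed_choice_probs(params, data)
    imm = data.immediate[data.responded]
    p_hat = float(p_obs.mean())
    n_imm = int(imm.sum())
    n_del = int((~imm).sum())
    if n_imm and n_del:
        p_hat_weighted = 0.5 * (float(p_obs[imm].mean()) + float(p_obs[~imm].mean()))
        fallback = False
    else:
        p_hat_weighted = p_hat
        fallback = True
    return PredictionSummary(
        p_hat=p_hat,
        pe=1.0 - p_hat,
        p_hat_weighted=p_hat_weighted,
        n_immediate=n_imm,
        n_delayed=n_del,
        weighted_fallback=fallback,
    )


def cross_run_model_comparison(run_a: ChoiceDataset, run_b: ChoiceDataset,
                               models: Sequence[Union[ModelId, str]],
                               fit_config: Optional[FitConfig] = None) -> pd.DataFrame:
    """Compare *models* by out-of-sample prediction between two runs.

    Each model is fitted on run A and evaluated on run B and vice versa; the
    table reports per-direction and averaged ``p_hat`` (and the class-weighted
    variants), sorted by averaged ``p_hat`` descending with ties broken by
    fewer free parameters.  Per-model failures are recorded in the ``error``
    column without aborting the table.
    """
    if (run_a.subject_id, run_a.condition) != (run_b.subject_id, run_b.condition):
        raise ValueError("both runs must come from the same subject and condition")
    rows = []
    for model in models:
        model = ModelId.coerce(model)
        row = {"model": model.value, "n_free_params": len(free_param_names(model))}
        try:
            fit_a = fit_mle(model, run_a, fit_config)
            fit_b = fit_mle(model, run_b, fit_config)
            sum_ab = predicted_probability_summary(fit_a.params, run_b)
            sum_ba = predicted_probability_summary(fit_b.params, run_a)
            row.update(
                log_lik_a=fit_a.log_lik,
                log_lik_b=fit_b.log_lik,
                converged=fit_a.converged and fit_b.converged,
                p_hat_a_to_b=sum_ab.p_hat,
                p_hat_b_to_a=sum_ba.p_hat,
                p_hat_avg=0.5 * (sum_ab.p_hat + sum_ba.p_hat),
                p_hat_weighted_a_to_b=sum_ab.p_hat_weighted,
                p_hat_weighted_b_to_a=sum_ba.p_hat_weighted,
                p_hat_weighted_avg=0.5 * (sum_ab.p_hat_weighted + sum_ba.p_hat_weighted),
                error="",
            )
        except Exception as exc:  # pragma: no cover - defensive per-model isolation
            row.update(error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["p_hat_avg", "n_free_params"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return table
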