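"""Delay-discounting value models.

Seven discounting functions commonly compared in the intertemporal-choice
literature.  Each model maps a delay ``D`` (days) to a *discount factor* in
``[0, 1]`` that multiplies the delayed outcome ``r2``; the immediate outcome
``r1`` is never discounted (its delay is implicitly zero).

Models and their discount factors
---------------------------------
``hyperbolic``              ``1 / (1 + kappa * D)``
``exponential``             ``kappa ** D``
``quasi_hyperbolic``        ``gamma * kappa ** D``  (beta-delta model)
``hyperboloid``             ``1 / (1 + kappa * D) ** s``
``modified_hyperboloid``    ``1 / (1 + kappa * D ** s)``  (s scales the delay,
                            i.e. nonlinear time perception)
``double_exponential``      ``w * kappa ** D + (1 - w) * kappa2 ** D``
``constant_sensitivity``    ``exp(-(kappa * D) ** delta)``

Parameter spaces follow the standard constraints: ``kappa`` lives in
``[0, 1]`` for the exponential-family models and in ``[0, 10]`` for the
hyperbolic family (operational cap on a conceptually unbounded rate, matching
the inference bound used for fitting); ``gamma, s, w, kappa2`` in ``[0, 1]``;
``delta > 0``; the softmax sensitivity ``beta`` in ``[0, 100]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np

__all__ = [
    "ModelId",
    "ModelParams",
    "Trial",
    "ValueResult",
    "KAPPA_CAP",
    "BETA_MAX",
    "DELTA_CAP",
    "free_param_names",
    "param_bounds",
    "discount_factor",
    "discounted_value",
    "validate_params",
]


class ModelId(str, Enum):
    """Identifier of a discounting model family."""

    HYPERBOLIC = "hyperbolic"
    EXPONENTIAL = "exponential"
    QUASI_HYPERBOLIC = "quasi_hyperbolic"
    HYPERBOLOID = "hyperboloid"
    MODIFIED_HYPERBOLOID = "modified_hyperboloid"
    DOUBLE_EXPONENTIAL = "double_exponential"
    CONSTANT_SENSITIVITY = "constant_sensitivity"

    @classmethod
    def coerce(cls, value: Union["ModelId", str]) -> "ModelId":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            names = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown model {value!r}; expected one of: {names}")


#: Operational upper cap on kappa for the conceptually unbounded models
#: (hyperbolic family and constant sensitivity).
KAPPA_CAP = 10.0
#: Upper bound on the softmax sensitivity beta.
BETA_MAX = 100.0
#: Operational cap on the constant-sensitivity time exponent delta
#: (conceptually unbounded; capped for bounded optimization).
DELTA_CAP = 10.0

# Per-model free parameters, in canonical order (kappa first, beta last).
_FREE_PARAMS = {
    ModelId.HYPERBOLIC: ("kappa", "beta"),
    ModelId.EXPONENTIAL: ("kappa", "beta"),
    ModelId.QUASI_HYPERBOLIC: ("kappa", "gamma", "beta"),
    ModelId.HYPERBOLOID: ("kappa", "s", "beta"),
    ModelId.MODIFIED_HYPERBOLOID: ("kappa", "s", "beta"),
    ModelId.DOUBLE_EXPONENTIAL: ("kappa", "kappa2", "w", "beta"),
    ModelId.CONSTANT_SENSITIVITY: ("kappa", "delta", "beta"),
}

_UNIT_KAPPA_MODELS = frozenset(
    {ModelId.EXPONENTIAL, ModelId.QUASI_HYPERBOLIC, ModelId.DOUBLE_EXPONENTIAL}
)
# Models where kappa > 0 is strict (the discount factor is undefined or
# degenerate at exactly 0).
_STRICT_POSITIVE_KAPPA = frozenset({ModelId.CONSTANT_SENSITIVITY})


def free_param_names(model: Union[ModelId, str]) -> tuple:
    """Names of the free parameters of *model*, kappa first and beta last."""
    return _FREE_PARAMS[ModelId.coerce(model)]


def param_bounds(model: Union[ModelId, str], name: str) -> tuple:
    """Closed optimization bounds ``(lo, hi)`` for parameter *name* of *model*."""
    model = ModelId.coerce(model)
    if name == "beta":
        return (0.0, BETA_MAX)
    if name == "kappa":
        if model in _UNIT_KAPPA_MODELS:
            return (0.0, 1.0)
        return (0.0, KAPPA_CAP)
    if name in ("gamma", "s", "w", "kappa2"):
        return (0.0, 1.0)
    if name == "delta":
        return (0.0, DELTA_CAP)
    raise KeyError(name)


@dataclass
class ModelParams:
    """A discounting model with its parameter vector.

    Fields not used by ``model`` are ignored; ``validate_params`` reports any
    out-of-range value for the fields the model does use.
    """

    model: ModelId
    kappa: float = 0.0
    beta: float = 1.0
    gamma: Optional[float] = None
    s: Optional[float] = None
    w: Optional[float] = None
    kappa2: Optional[float] = None
    delta: Optional[float] = None

    def __post_init__(self):
        self.model = ModelId.coerce(self.model)

    def get(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"parameter {name!r} required by {self.model.value} is unset")
        return float(value)

    def free_values(self) -> np.ndarray:
        return np.array([self.get(n) for n in free_param_names(self.model)])

    def replace_free(self, values) -> "ModelParams":
        kwargs = dict(zip(free_param_names(self.model), map(float, values)))
        return ModelParams(self.model, **{**self._used_dict(), **kwargs})

    def _used_dict(self) -> dict:
        return {n: getattr(self, n) for n in free_param_names(self.model)}

    def to_dict(self) -> dict:
        return {"model": self.model.value, "params": self._used_dict()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(ModelId.coerce(d["model"]), **d.get("params", {}))

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


@dataclass
class Trial:
    """One binary intertemporal choice: immediate ``r1`` now vs ``r2`` in
    ``delay_days`` days.

    Reward trials satisfy ``0 < r1 < r2``; loss trials ``r2 < r1 < 0`` (the
    delayed outcome always has the larger magnitude).  Candidates produced by
    the trial generator may violate this until resolved.
    """

    condition: str  # "reward" | "loss"
    r1: float
    r2: float
    delay_days: float
    target_p1: Optional[float] = None
    adjusted: bool = False

    def __post_init__(self):
        if self.condition not in ("reward", "loss"):
            raise ValueError(f"condition must be 'reward' or 'loss', got {self.condition!r}")
        if self.delay_days < 1:
            raise ValueError("delay_days must be >= 1 for the delayed option")

    def is_valid(self) -> bool:
        """Whether the smaller-sooner / larger-later structure holds."""
        if self.condition == "reward":
            return 0 < self.r1 < self.r2
        return self.r2 < self.r1 < 0


@dataclass
class ValueResult:
    """Subjective values of the two options plus the applied discount factor."""

    v1: float
    v2: float
    factor: float


def validate_params(params: ModelParams) -> list:
    """Return the list of constraint violations for *params* (empty if valid).

    Reports rather than raises, so callers can aggregate diagnostics.
    """
    model = params.model
    violations = []
    for name in free_param_names(model):
        value = getattr(params, name)
        if value is None:
            violations.append(f"{name} required by {model.value} is unset")
            continue
        if not np.isfinite(value):
            violations.append(f"{name} must be finite")
            continue
        lo, hi = param_bounds(model, name)
        if name == "kappa" and model in _STRICT_POSITIVE_KAPPA:
            if value <= 0:
                violations.append("kappa must be > 0")
            elif value > hi:
                violations.append(f"kappa out of (0, {hi:g}]")
        elif name == "delta":
            if value <= 0:
                violations.append("delta must be > 0")
            elif value > hi:
                violations.append(f"delta out of (0, {hi:g}]")
        elif not lo <= value <= hi:
            violations.append(f"{name} out of [{lo:g}, {hi:g}]")
    return violations


def _require_valid(params: ModelParams) -> None:
    violations = validate_params(params)
    if violations:
        raise ValueError(
            f"invalid parameters for {params.model.value}: " + "; ".join(violations)
        )


def discount_factor(params: ModelParams, delay_days) -> Union[float, np.ndarray]:
    """Discount factor in ``[0, 1]`` multiplying the delayed outcome.

    Vectorized over *delay_days*; every delay must be strictly positive.
    """
    _require_valid(params)
    D = np.asarray(delay_days, dtype=float)
    if np.any(D <= 0):
        raise ValueError("delay_days must be > 0")
    factor = _factor_unchecked(params, D)
    if np.isscalar(delay_days) or D.ndim == 0:
        return float(factor)
    return factor


def _factor_unchecked(params: ModelParams, D: np.ndarray) -> np.ndarray:
    """Model-specific discount factor without validation (hot path)."""
    m = params.model
    k = params.get("kappa")
    if m is ModelId.HYPERBOLIC:
        return 1.0 / (1.0 + k * D)
    if m is ModelId.EXPONENTIAL:
        return _safe_pow(k, D)
    if m is ModelId.QUASI_HYPERBOLIC:
        return params.get("gamma") * _safe_pow(k, D)
    if m is ModelId.HYPERBOLOID:
        return 1.0 / (1.0 + k * D) ** params.get("s")
    if m is ModelId.MODIFIED_HYPERBOLOID:
        return 1.0 / (1.0 + k * D ** params.get("s"))
    if m is ModelId.DOUBLE_EXPONENTIAL:
        w = params.get("w")
        return w * _safe_pow(k, D) + (1.0 - w) * _safe_pow(params.get("kappa2"), D)
    if m is ModelId.CONSTANT_SENSITIVITY:
        return np.exp(-((k * D) ** params.get("delta")))
    raise AssertionError(m)


def _safe_pow(base: float, D: np.ndarray) -> np.ndarray:
    # 0 ** D underflows cleanly for D > 0; define 0 ** 0 := 1 for continuity
    # of the immediate identity (never reached via discount_factor, which
    # requires D > 0).
    with np.errstate(divide="ignore"):
        out = np.power(float(base), D)
    return np.where((base == 0.0) & (D == 0.0), 1.0, out)


def discounted_value(params: ModelParams, trial: Trial) -> ValueResult:
    """Subjective values of both options of *trial* under *params*.

    The immediate option keeps its face value (``v1 = r1``); the delayed
    option is multiplied by the model's discount factor.  Works identically
    for signed loss outcomes: the factor is sign-free, so ``v2`` keeps the
    sign of ``r2`` and never exceeds it in magnitude.
    """
    factor = discount_factor(params, trial.delay_days)
    return ValueResult(v1=trial.r1, v2=factor * trial.r2, factor=factor)
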