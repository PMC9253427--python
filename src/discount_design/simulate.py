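"""Synthetic discounting agents and choice simulation.

Agents are parameter vectors of a chosen discounting model whose choices on
a trial table are Bernoulli draws from the logistic choice link.  The
population sampler emulates the empirically observed spread of human
discount rates — a bimodal distribution with most mass at low rates
(roughly 1e-11 .. 3) and a small mode of extreme discounters above 7 — and
links reward- and loss-condition parameters through a rank-correlation knob
(people who discount rewards steeply tend to discount losses steeply too,
though less so).

The module also provides the full-loop parameter-recovery harness: generate
the calibration run, simulate, fit, generate the adaptive run from the fit,
simulate, refit — reporting true-vs-estimated parameter agreement and the
observed-vs-target choice frequencies at each manipulated probability level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .inference import (
    ChoiceDataset,
    ChoiceRecord,
    FitConfig,
    fit_mle,
    immediate_choice_prob,
)
from .models import ModelId, ModelParams, Trial, discount_factor, free_param_names, validate_params
from .trials import RunAConfig, RunBConfig, generate_run_a, generate_run_b

__all__ = [
    "Distribution",
    "Uniform",
    "LogUniform",
    "Constant",
    "Mixture",
    "distribution_from_spec",
    "PopulationSpec",
    "SyntheticAgent",
    "default_population",
    "sample_population",
    "simulate_choices",
    "modal_choice_dataset",
    "RecoveryReport",
    "parameter_recovery",
]


class Distribution:
    """A one-dimensional sampling distribution with an inverse CDF.

    The inverse CDF (``ppf``) is what makes Gaussian-copula coupling of
    reward and loss parameters possible.
    """

    def ppf(self, q):  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))

    def cdf(self, x):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class Uniform(Distribution):
    low: float
    high: float

    def ppf(self, q):
        return self.low + np.asarray(q) * (self.high - self.low)

    def cdf(self, x):
        return np.clip((np.asarray(x) - self.low) / (self.high - self.low), 0.0, 1.0)


@dataclass
class LogUniform(Distribution):
    """Log-uniform (reciprocal) distribution; the standard vague choice for
    positive scale parameters such as discount rates and sensitivities."""

    low: float
    high: float

    def __post_init__(self):
        if self.low <= 0:
            raise ValueError("LogUniform requires low > 0")

    def ppf(self, q):
        return np.exp(np.log(self.low) + np.asarray(q) * (np.log(self.high) - np.log(self.low)))

    def cdf(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.low, self.high)
        return (np.log(x) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))


@dataclass
class Constant(Distribution):
    value: float

    def ppf(self, q):
        return np.full_like(np.asarray(q, dtype=float), self.value)

    def cdf(self, x):
        return (np.asarray(x, dtype=float) >= self.value).astype(float)


@dataclass
class Mixture(Distribution):
    """Finite mixture; the ppf is obtained by bisection on the mixture CDF."""

    components: Sequence[Distribution]
    weights: Sequence[float]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.components) or np.any(w < 0) or not math.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must be nonnegative and sum to 1")

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(w * np.asarray(c.cdf(x)) for c, w in zip(self.components, self.weights))

    def _support(self) -> tuple:
        los, his = [], []
        for c in self.components:
            if isinstance(c, Constant):
                los.append(c.value)
                his.append(c.value)
            else:
                los.append(c.low)
                his.append(c.high)
        return min(los), max(his)

    def ppf(self, q):
        q = np.atleast_1d(np.asarray(q, dtype=float))
        lo, hi = self._support()
        a = np.full_like(q, lo)
        b = np.full_like(q, hi)
        for _ in range(80):  # bisection to ~2**-80 of the support width
            mid = 0.5 * (a + b)
            below = np.asarray(self.cdf(mid)) < q
            a = np.where(below, mid, a)
            b = np.where(below, b, mid)
        return 0.5 * (a + b)


def distribution_from_spec(spec: Union[Distribution, dict, float, int]) -> Distribution:
    """Build a distribution from a JSON-style spec.

    Accepts an existing :class:`Distribution`, a bare number (constant), or
    a dict like ``{"kind": "loguniform", "low": 1e-5, "high": 0.6}`` /
    ``{"kind": "mixture", "components": [...], "weights": [...]}``.
    """
    if isinstance(spec, Distribution):
        return spec
    if isinstance(spec, (int, float)):
        return Constant(float(spec))
    kind = spec.get("kind")
    if kind == "uniform":
        return Uniform(float(spec["low"]), float(spec["high"]))
    if kind == "loguniform":
        return LogUniform(float(spec["low"]), float(spec["high"]))
    if kind == "constant":
        return Constant(float(spec["value"]))
    if kind == "mixture":
        return Mixture([distribution_from_spec(c) for c in spec["components"]],
                       [float(w) for w in spec["weights"]])
    raise ValueError(f"unknown distribution spec: {spec!r}")


@dataclass
class PopulationSpec:
    """Specification of a synthetic-agent population.

    The default discount-rate distribution is a stand-in for the empirical
    bimodal spread of human rates: 90% log-uniform over [1e-5, 0.6] (the
    dominant low-rate mode) plus 10% uniform over [7, 10] (a minority of
    extreme discounters).  Reward and loss parameters share marginals and
    are rank-correlated through a Gaussian copula
    (``reward_loss_correlation``, default 0.5).
    """

    n_subjects: int
    model: ModelId = ModelId.HYPERBOLIC
    kappa_distribution: Union[Distribution, dict, float, None] = None
    beta_distribution: Union[Distribution, dict, float, None] = None
    extras_distributions: Dict[str, Union[Distribution, dict, float]] = field(default_factory=dict)
    seed: int = 0
    reward_loss_correlation: float = 0.5

    def __post_init__(self):
        self.model = ModelId.coerce(self.model)
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if not -1.0 <= self.reward_loss_correlation <= 1.0:
            raise ValueError("reward_loss_correlation must lie in [-1, 1]")

    def resolved_distributions(self) -> Dict[str, Distribution]:
        dists: Dict[str, Distribution] = {}
        for name in free_param_names(self.model):
            if name == "kappa":
                spec = self.kappa_distribution
                if spec is None:
                    spec = _default_kappa_spec(self.model)
            elif name == "beta":
                spec = self.beta_distribution
                if spec is None:
                    spec = LogUniform(0.1, 5.0)
            else:
                spec = self.extras_distributions.get(name)
                if spec is None:
                    spec = _DEFAULT_EXTRAS[name]
            dists[name] = distribution_from_spec(spec)
        return dists


def _default_kappa_spec(model: ModelId) -> Distribution:
    if model in (ModelId.EXPONENTIAL, ModelId.QUASI_HYPERBOLIC, ModelId.DOUBLE_EXPONENTIAL):
        # daily retention rates: most mass near 1 (shallow discounting)
        return Uniform(0.8, 0.999)
    if model is ModelId.CONSTANT_SENSITIVITY:
        return LogUniform(1e-4, 0.5)
    # bimodal stand-in for the empirical rate distribution
    return Mixture([LogUniform(1e-5, 0.6), Uniform(7.0, 10.0)], [0.9, 0.1])


_DEFAULT_EXTRAS: Dict[str, Distribution] = {
    "gamma": Uniform(0.5, 1.0),
    "s": Uniform(0.2, 0.8),
    "w": Uniform(0.2, 0.8),
    "kappa2": Uniform(0.8, 0.999),
    "delta": Uniform(0.5, 1.5),
}


@dataclass
class SyntheticAgent:
    """A simulated subject with per-condition model parameters."""

    subject_id: str
    params: Dict[str, ModelParams]  # condition -> parameters

    def params_for(self, condition: str) -> ModelParams:
        return self.params[condition]


def default_population(n_subjects: int, model: Union[ModelId, str] = ModelId.HYPERBOLIC,
                       seed: int = 0, **kwargs) -> List[SyntheticAgent]:
    """Convenience wrapper: sample a population from default distributions."""
    return sample_population(PopulationSpec(n_subjects, ModelId.coerce(model),
                                            seed=seed, **kwargs))


def sample_population(spec: PopulationSpec) -> List[SyntheticAgent]:
    """Sample a deterministic population of synthetic agents from *spec*.

    Per parameter, reward and loss values are drawn from the same marginal
    and coupled with a Gaussian copula at ``spec.reward_loss_correlation``.
    Sampled parameters always satisfy the model's constraints.
    """
    rng = np.random.default_rng(spec.seed)
    dists = spec.resolved_distributions()
    rho = spec.reward_loss_correlation
    agents = []
    for i in range(spec.n_subjects):
        per_cond = {"reward": {}, "loss": {}}
        for name, dist in dists.items():
            z_r = rng.standard_normal()
            z_l = rho * z_r + math.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal()
            per_cond["reward"][name] = float(np.asarray(dist.ppf(stats.norm.cdf(z_r))).ravel()[0])
            per_cond["loss"][name] = float(np.asarray(dist.ppf(stats.norm.cdf(z_l))).ravel()[0])
        params = {c: ModelParams(spec.model, **v) for c, v in per_cond.items()}
        for c, p in params.items():
            violations = validate_params(p)
            if violations:
                raise ValueError(
                    f"distribution spec produced invalid {c} parameters: {violations}"
                )
        agents.append(SyntheticAgent(subject_id=f"s{i:03d}", params=params))
    return agents


def _trial_probs(params: ModelParams, trials: pd.DataFrame) -> np.ndarray:
    """Immediate-choice probability for each row of a trial table."""
    factor = np.asarray(discount_factor(params, trials["delay_days"].to_numpy(dtype=float)))
    v2 = factor * trials["r2"].to_numpy(dtype=float)
    return np.atleast_1d(
        immediate_choice_prob(params.get("beta"), trials["r1"].to_numpy(dtype=float), v2)
    )


def _dataset_from_actions(subject_id: str, condition: str, run: str,
                          trials: pd.DataFrame, actions: Sequence[str]) -> ChoiceDataset:
    records = []
    for (row, action) in zip(trials.itertuples(index=False), actions):
        p1 = getattr(row, "target_p1", np.nan)
        records.append(
            ChoiceRecord(
                Trial(condition, float(row.r1), float(row.r2), float(row.delay_days),
                      target_p1=None if pd.isna(p1) else float(p1)),
                action=action,
            )
        )
    return ChoiceDataset(subject_id, condition, run, records)


def simulate_choices(agent: SyntheticAgent, trials: pd.DataFrame, seed: int = 0,
                     missing_rate: float = 0.0,
                     ) -> Union[ChoiceDataset, Dict[str, ChoiceDataset]]:
    """Simulate the agent's choices on a trial table.

    Each trial's action is a Bernoulli draw of the immediate option with the
    probability given by the agent's condition-specific parameters; missing
    responses (if any) are uniform at ``missing_rate``.  Returns one
    :class:`ChoiceDataset` if the table holds a single condition, else a
    dict keyed by condition.  Reproducible given *seed*.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, ChoiceDataset] = {}
    run = str(trials["run"].iloc[0]) if "run" in trials and len(trials) else "?"
    for cond in pd.unique(trials["condition"]):
        sub = trials[trials["condition"] == cond]
        p1 = _trial_probs(agent.params_for(cond), sub)
        draws = rng.uniform(size=len(sub))
        actions = np.where(draws < p1, "immediate", "delayed").astype(object)
        if missing_rate > 0:
            actions[rng.uniform(size=len(sub)) < missing_rate] = "missing"
        out[cond] = _dataset_from_actions(agent.subject_id, cond, run, sub, actions)
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def modal_choice_dataset(params: ModelParams, trials: pd.DataFrame, subject_id: str = "s0",
                         ) -> Union[ChoiceDataset, Dict[str, ChoiceDataset]]:
    """Deterministic dataset of modal choices (the option with p > 0.5).

    Ties at exactly 0.5 resolve to the immediate option; the choice link
    assigns them probability 0.5 either way.
    """
    out: Dict[str, ChoiceDataset] = {}
    run = str(trials["run"].iloc[0]) if "run" in trials and len(trials) else "?"
    for cond in pd.unique(trials["condition"]):
        sub = trials[trials["condition"] == cond]
        p1 = _trial_probs(params, sub)
        actions = np.where(p1 >= 0.5, "immediate", "delayed").astype(object)
        out[cond] = _dataset_from_actions(subject_id, cond, run, sub, actions)
    if len(out) == 1:
        return next(iter(out.values()))
    return out


@dataclass
class RecoveryReport:
    """Result of the full-loop parameter-recovery simulation."""

    estimates: pd.DataFrame
    """One row per agent x condition: true and fitted parameter values."""
    frequencies: pd.DataFrame
    """Observed immediate-choice counts of the *true* agents per condition x
    target probability (the full loop, including parameter-estimation error)."""
    generator_frequencies: pd.DataFrame
    """Same counts for *self-consistent* agents whose parameters are the
    trial-generating (fitted) ones — the pure calibration of the inversion
    machinery, deviating from the targets only through penny rounding,
    atypical-trial fallbacks and binomial noise."""
    correlations: Dict[str, float]
    """Spearman correlations, bias and RMSE between true and fitted values."""
    failures: List[str]

    def frequency_table(self, source: str = "observed") -> pd.DataFrame:
        """Observed vs target immediate-choice frequency per p1 level.

        ``source="observed"`` uses the true agents' choices;
        ``source="self_consistent"`` the trial-generating parameters' own.
        """
        table = {"observed": self.frequencies,
                 "self_consistent": self.generator_frequencies}[source]
        g = table.groupby("target_p1", as_index=False).agg(
            n_immediate=("n_immediate", "sum"), n=("n", "sum")
        )
        g["observed_freq"] = g["n_immediate"] / g["n"]
        g["binomial_se"] = np.sqrt(g["target_p1"] * (1 - g["target_p1"]) / g["n"])
        return g

    def to_dict(self) -> dict:
        return {
            "correlations": self.correlations,
            "frequencies": self.frequency_table("observed").to_dict(orient="records"),
            "self_consistent_frequencies": self.frequency_table(
                "self_consistent").to_dict(orient="records"),
            "n_agents": int(self.estimates["subject_id"].nunique()) if len(self.estimates) else 0,
            "failures": self.failures,
        }


def parameter_recovery(spec: PopulationSpec, run_a_config: RunAConfig,
                       run_b_config: RunBConfig,
                       fit_config: Optional[FitConfig] = None,
                       conditions: Optional[Sequence[str]] = None) -> RecoveryReport:
    """Exercise the full adaptive loop on a synthetic population.

    For each agent and condition: simulate the common calibration run, fit
    the generating model family, generate the adaptive run from the fit,
    simulate it, and refit.  Per-agent failures are recorded, not fatal.
    """
    cfg = fit_config or FitConfig()
    agents = sample_population(spec)
    conditions = list(conditions or run_a_config.conditions)
    run_a = generate_run_a(run_a_config, seed=spec.seed)
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(4 * max(1, len(agents)))]

    rows, freq_rows, gen_freq_rows, failures = [], [], [], []
    for i, agent in enumerate(agents):
        try:
            sim_a = simulate_choices(agent, run_a, seed=child_seeds[4 * i])
            if isinstance(sim_a, ChoiceDataset):
                sim_a = {sim_a.condition: sim_a}
            fits_a = {c: fit_mle(spec.model, sim_a[c], cfg) for c in conditions}
            run_b = generate_run_b({c: f.params for c, f in fits_a.items()},
                                   run_b_config, subject_id=agent.subject_id,
                                   seed=child_seeds[4 * i + 1])
            sim_b = simulate_choices(agent, run_b, seed=child_seeds[4 * i + 2])
            if isinstance(sim_b, ChoiceDataset):
                sim_b = {sim_b.condition: sim_b}
            fits_b = {c: fit_mle(spec.model, sim_b[c], cfg) for c in conditions}
            generator = SyntheticAgent(agent.subject_id,
                                       {c: f.params for c, f in fits_a.items()})
            sim_b_gen = simulate_choices(generator, run_b, seed=child_seeds[4 * i + 3])
            if isinstance(sim_b_gen, ChoiceDataset):
                sim_b_gen = {sim_b_gen.condition: sim_b_gen}
        except Exception as exc:
            failures.append(f"{agent.subject_id}: {exc}")
            continue
        for cond in conditions:
            true = agent.params_for(cond)
            row = {"subject_id": agent.subject_id, "condition": cond}
            for name in free_param_names(spec.model):
                row[f"true_{name}"] = true.get(name)
                row[f"est_a_{name}"] = fits_a[cond].params.get(name)
                row[f"est_b_{name}"] = fits_b[cond].params.get(name)
            rows.append(row)
            for ds, sink in ((sim_b[cond], freq_rows), (sim_b_gen[cond], gen_freq_rows)):
                for p1 in run_b_config.target_probs:
                    at_level = np.isclose(ds.target_p1, p1) & ds.responded
                    sink.append({
                        "subject_id": agent.subject_id,
                        "condition": cond,
                        "target_p1": p1,
                        "n_immediate": int(ds.immediate[at_level].sum()),
                        "n": int(at_level.sum()),
                    })

    estimates = pd.DataFrame(rows)
    correlations: Dict[str, float] = {}
    if len(estimates) >= 3:
        for name in free_param_names(spec.model):
            true_v = estimates[f"true_{name}"].to_numpy()
            for run_label in ("a", "b"):
                est_v = estimates[f"est_{run_label}_{name}"].to_numpy()
                rho = stats.spearmanr(true_v, est_v).statistic
                correlations[f"spearman_{name}_run{run_label}"] = float(rho)
                correlations[f"bias_{name}_run{run_label}"] = float(np.mean(est_v - true_v))
                correlations[f"rmse_{name}_run{run_label}"] = float(
                    np.sqrt(np.mean((est_v - true_v) ** 2))
                )
            cross = stats.spearmanr(estimates[f"est_a_{name}"], estimates[f"est_b_{name}"]).statistic
            correlations[f"spearman_{name}_runa_runb"] = float(cross)
    return RecoveryReport(
        estimates=estimates,
        frequencies=pd.DataFrame(freq_rows),
        generator_frequencies=pd.DataFrame(gen_freq_rows),
        correlations=correlations,
        failures=failures,
    )
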