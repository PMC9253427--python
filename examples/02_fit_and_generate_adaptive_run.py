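"""Fit a subject's discounting model and invert it into adaptive trials.

A synthetic subject answers the calibration run; maximum likelihood recovers
their (kappa, beta); inverting the choice model then yields immediate
outcomes expected to evoke immediate-choice probabilities of 0.3, 0.5 and
0.7 — the indifference point plus one graded step to either side.
"""

from discount_design import (
    EXP2_RUN_A,
    FitConfig,
    ModelParams,
    SyntheticAgent,
    fit_mle,
    generate_run_a,
    generate_run_b,
    run_b_config_for,
    simulate_choices,
)

true = ModelParams("hyperbolic", kappa=0.02, beta=2.0)
agent = SyntheticAgent("s01", {"reward": true, "loss": true})

run_a = generate_run_a(EXP2_RUN_A, subject_id="s01", seed=11)
choices = simulate_choices(agent, run_a, seed=12)

fits = {}
for cond in ("reward", "loss"):
    fit = fit_mle("hyperbolic", choices[cond], FitConfig(seed=0))
    fits[cond] = fit.params
    print(f"{cond:6s}: kappa_hat={fit.params.kappa:.4f} (true {true.kappa}), "
          f"beta_hat={fit.params.beta:.2f} (true {true.beta}), "
          f"log_lik={fit.log_lik:.1f} over {fit.n_used} trials")

run_b = generate_run_b(fits, run_b_config_for(EXP2_RUN_A), subject_id="s01", seed=13)
print(f"\nadaptive run: {len(run_b)} trials, {int(run_b.adjusted.sum())} "
      "needed atypical-trial resolution")

# For one delayed outcome, show how the immediate outcome steps with the
# target probability: higher target -> more generous immediate offer.
sel = run_b.query("condition == 'reward' and r2 == 20 and delay_days == 90")
for row in sel.sort_values("target_p1").itertuples():
    print(f"  target p1={row.target_p1:.1f}: {row.r1:6.2f} now  vs  "
          f"{row.r2:.2f} in {row.delay_days} days")
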