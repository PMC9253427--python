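"""Compare discounting models by out-of-sample prediction.

Each candidate model is fitted on one run and scored on the other by the
average predicted probability of the observed choices (p_hat; the prediction
error is 1 - p_hat). Data are simulated from a modified-hyperboloid agent,
so the hyperboloid family should top the table.
"""

from discount_design import (
    EXP2_RUN_A,
    FitConfig,
    ModelId,
    ModelParams,
    SyntheticAgent,
    cross_run_model_comparison,
    fit_mle,
    generate_run_a,
    generate_run_b,
    run_b_config_for,
    simulate_choices,
)

true = ModelParams("modified_hyperboloid", kappa=0.15, s=0.5, beta=1.0)
agent = SyntheticAgent("s02", {"reward": true, "loss": true})

run_a = generate_run_a(EXP2_RUN_A, subject_id="s02", seed=21)
ds_a = simulate_choices(agent, run_a, seed=22)
fit = fit_mle("modified_hyperboloid", ds_a["reward"], FitConfig(seed=0))
run_b = generate_run_b({"reward": fit.params, "loss": fit.params},
                       run_b_config_for(EXP2_RUN_A), subject_id="s02", seed=23)
ds_b = simulate_choices(agent, run_b, seed=24)

table = cross_run_model_comparison(ds_a["reward"], ds_b["reward"],
                                   list(ModelId), FitConfig(seed=0))
cols = ["model", "n_free_params", "p_hat_a_to_b", "p_hat_b_to_a", "p_hat_avg"]
print(table[cols].round(3).to_string(index=False))
print("\nRows are sorted by averaged out-of-sample p_hat; values near 0.5 "
      "mean chance-level prediction, the adaptive run is built to cap "
      "attainable p_hat near 0.63 even for the true model.")
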