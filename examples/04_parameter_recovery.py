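"""Exercise the full adaptive loop on a synthetic population.

For each agent: simulate the calibration run, fit, generate the adaptive run
from the fit, simulate it, refit. The report shows how well discount rates
are recovered and how close the evoked choice frequencies come to the
targets 0.3 / 0.5 / 0.7.
"""

from discount_design import (
    EXP2_RUN_A,
    FitConfig,
    LogUniform,
    PopulationSpec,
    parameter_recovery,
    run_b_config_for,
)

spec = PopulationSpec(
    12, "hyperbolic",
    kappa_distribution=LogUniform(0.001, 0.6),
    beta_distribution=LogUniform(0.1, 5.0),
    seed=42,
)
report = parameter_recovery(spec, EXP2_RUN_A, run_b_config_for(EXP2_RUN_A),
                            FitConfig(seed=0))

print("rate recovery: Spearman(true kappa, kappa_hat) ="
      f" {report.correlations['spearman_kappa_runa']:.3f}")

print("\ntrue agents on their adaptive trials (includes estimation error):")
print(report.frequency_table("observed").round(3).to_string(index=False))
print("\nself-consistent agents (choices drawn from the trial-generating "
      "parameters — pure calibration of the inversion):")
print(report.frequency_table("self_consistent").round(3).to_string(index=False))
print("\nThe self-consistent frequencies sit within binomial noise of the "
      "targets; the true-agent frequencies compress toward 0.5 to the extent "
      "the calibration run misestimates choice sensitivity.")
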