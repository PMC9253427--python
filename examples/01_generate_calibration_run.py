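"""Generate the common calibration run (run A).

Every subject sees the same grid: each trial pairs a delayed outcome with the
immediate outcome lying at the *hypothetical* indifference point of a
hyperbolic discounter (r1 = r2 / (1 + kappa * D)), so that subjects with
discount rates near one of the hypothetical values face genuinely hard
choices somewhere in the grid.
"""

from discount_design import EXP1_RUN_A, EXP2_RUN_A, generate_run_a

trials = generate_run_a(EXP1_RUN_A, subject_id="demo", seed=1)
print(f"initial grid: {len(trials)} trials "
      f"({(trials.condition == 'reward').sum()} reward, "
      f"{(trials.condition == 'loss').sum()} loss)")
print(trials.head(8)[["condition", "block", "r1", "r2", "delay_days",
                      "hypothetical_kappa"]].to_string(index=False))

# A trial like r1=0.53 vs r2=10.00 at 90 days is the indifference point of a
# kappa=0.2 discounter: both options have equal subjective value for them.
row = trials.query("hypothetical_kappa == 0.2 and delay_days == 90 and r2 == 10").iloc[0]
print(f"\nindifference trial for kappa=0.2: {row.r1:.2f} now vs "
      f"{row.r2:.2f} in {row.delay_days} days")

# The recalibrated grid targets the much lower rates real cohorts showed.
print(f"\nrecalibrated grid kappas: {EXP2_RUN_A.hypothetical_kappas}, "
      f"delays: {EXP2_RUN_A.delays}")
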