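"""Run-A/run-B trial generation, model inversion and atypical-trial resolution."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from discount_design import (
    EXP1_RUN_A,
    EXP2_RUN_A,
    EXP3_RUN_A,
    ModelParams,
    RunBConfig,
    Trial,
    discount_factor,
    generate_run_a,
    generate_run_b,
    immediate_choice_prob,
    penny_round,
    resolve_atypical_trial,
    run_b_config_for,
    solve_immediate_outcome,
)

HYP = ModelParams("hyperbolic", kappa=0.1, beta=0.4)


class TestSolveImmediateOutcome:
    def test_half_probability_is_discounted_value(self):
        # at p1 = 0.5 the logit term drops: r1 equals v2 exactly
        assert solve_immediate_outcome(HYP, 20.0, 30, 0.5) == 5.0

    def test_worked_example(self):
        r1 = solve_immediate_outcome(HYP, 20.0, 30, 0.7)
        assert r1 == pytest.approx(5 + np.log(7 / 3) / 0.4, abs=1e-10)
        # and the inversion round-trips through the choice link
        v2 = discount_factor(HYP, 30) * 20.0
        assert immediate_choice_prob(0.4, r1, v2) == pytest.approx(0.7, abs=1e-12)

    @pytest.mark.parametrize("p1", [0.0, 1.0, -0.1, 1.7])
    def test_degenerate_probability_rejected(self, p1):
        with pytest.raises(ValueError):
            solve_immediate_outcome(HYP, 20.0, 30, p1)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError):
            solve_immediate_outcome(
                ModelParams("hyperbolic", kappa=0.1, beta=0.0), 20.0, 30, 0.3)

    @given(
        p_lo=st.floats(0.02, 0.97),
        dp=st.floats(0.005, 0.02),
        sign=st.sampled_from([1.0, -1.0]),
    )
    def test_strictly_increasing_in_target_probability(self, p_lo, dp, sign):
        r_lo = solve_immediate_outcome(HYP, sign * 20.0, 30, p_lo)
        r_hi = solve_immediate_outcome(HYP, sign * 20.0, 30, p_lo + dp)
        assert r_hi > r_lo

    def test_offset_constant_across_delays(self):
        """The immediate-minus-discounted-value offset depends only on the
        target probability and beta, not on the delay."""
        offsets = []
        for D in (2, 7, 30, 90, 180):
            v2 = discount_factor(HYP, D) * 20.0
            offsets.append(solve_immediate_outcome(HYP, 20.0, D, 0.7) - v2)
        assert np.ptp(offsets) < 1e-10

    def test_smaller_beta_needs_larger_offsets(self):
        lo = ModelParams("hyperbolic", kappa=0.1, beta=0.1)
        hi = ModelParams("hyperbolic", kappa=0.1, beta=0.4)
        off = lambda p: (solve_immediate_outcome(p, 20.0, 30, 0.7)
                         - discount_factor(p, 30) * 20.0)
        assert off(lo) > off(hi)


class TestGenerateRunA:
    def test_initial_grid_size(self):
        trials = generate_run_a(EXP1_RUN_A, seed=0)
        assert len(trials) == 160
        assert (trials.run == "A").all()
        assert set(trials.condition) == {"reward", "loss"}

    def test_indifference_point_values(self):
        trials = generate_run_a(EXP1_RUN_A, seed=0)
        row = trials[(trials.hypothetical_kappa == 0.2) & (trials.delay_days == 90)
                     & (trials.r2 == 10)]
        assert row.r1.to_list() == [pytest.approx(0.53)]
        # loss mirrors reward with negated outcomes
        row_l = trials[(trials.hypothetical_kappa == 0.1) & (trials.delay_days == 30)
                       & (trials.r2 == -20)]
        assert row_l.r1.to_list() == [pytest.approx(-5.00)]

    def test_per_condition_delay_overrides(self):
        trials = generate_run_a(EXP3_RUN_A, seed=0)
        assert set(trials[trials.condition == "loss"].delay_days) == {30, 90, 180, 365, 1095}
        assert set(trials[trials.condition == "reward"].delay_days) == {7, 30, 90, 180, 365}

    def test_order_randomized_but_reproducible(self):
        t1 = generate_run_a(EXP1_RUN_A, seed=7)
        t2 = generate_run_a(EXP1_RUN_A, seed=7)
        t3 = generate_run_a(EXP1_RUN_A, seed=8)
        assert t1.equals(t2)
        assert not t1.r1.equals(t3.r1)
        # same multiset of trials regardless of seed
        key = ["condition", "r1", "r2", "delay_days"]
        assert t1[key].sort_values(key).reset_index(drop=True).equals(
            t3[key].sort_values(key).reset_index(drop=True))


class TestResolveAtypical:
    CFG = run_b_config_for(EXP1_RUN_A)

    def test_valid_trial_untouched(self):
        trial = Trial("reward", 5.0, 20.0, 30, target_p1=0.5)
        out = resolve_atypical_trial(trial, HYP, self.CFG)
        assert (out.r1, out.delay_days, out.adjusted) == (5.0, 30, False)

    def test_sign_violation_falls_back_to_one_penny(self):
        # beta so small the negative offset cannot be absorbed at any delay
        params = ModelParams("hyperbolic", kappa=0.6, beta=0.01)
        r1 = penny_round(solve_immediate_outcome(params, 2.0, 180, 0.3))
        assert r1 < 0
        out = resolve_atypical_trial(Trial("reward", r1, 2.0, 180, target_p1=0.3),
                                     params, self.CFG)
        assert out.r1 == 0.01
        assert out.adjusted
        # loss mirror
        r1_l = penny_round(solve_immediate_outcome(params, -2.0, 180, 0.7))
        out_l = resolve_atypical_trial(Trial("loss", r1_l, -2.0, 180, target_p1=0.7),
                                       params, self.CFG)
        assert out_l.r1 == -0.01

    def test_equal_outcomes_nudged_one_penny(self):
        zero_discount = ModelParams("hyperbolic", kappa=0.0, beta=1.0)
        cfg = RunBConfig(target_probs=(0.5,), delays=(30,), delayed_outcomes=(5,))
        out = resolve_atypical_trial(Trial("reward", 5.0, 5.0, 30, target_p1=0.5),
                                     zero_discount, cfg)
        assert out.r1 == pytest.approx(4.99)
        out_l = resolve_atypical_trial(Trial("loss", -5.0, -5.0, 30, target_p1=0.5),
                                       zero_discount, cfg)
        assert out_l.r1 == pytest.approx(-4.99)

    def test_delay_sweep_resolves_when_possible(self):
        # shrinking the delay raises the discounted value until r1 > 0
        params = ModelParams("hyperbolic", kappa=0.6, beta=0.05, )
        candidate = penny_round(solve_immediate_outcome(params, 2.0, 180, 0.3))
        assert candidate < 0
        out = resolve_atypical_trial(Trial("reward", candidate, 2.0, 180, target_p1=0.3),
                                     params, self.CFG)
        assert out.adjusted
        assert out.is_valid()
        if out.delay_days > self.CFG.sweep_bounds("reward")[0]:
            # the sweep stopped at the first valid delay: one day longer is atypical
            previous = penny_round(
                solve_immediate_outcome(params, 2.0, out.delay_days + 1, 0.3))
            assert previous <= 0

    def test_requires_target_probability(self):
        with pytest.raises(ValueError):
            resolve_atypical_trial(Trial("reward", 1.0, 2.0, 30), HYP, self.CFG)

    @given(
        kappa=st.floats(1e-4, 5.0),
        beta=st.floats(0.02, 50.0),
        p1=st.sampled_from([0.3, 0.5, 0.7]),
        mag=st.sampled_from([2.0, 5.0, 10.0, 20.0]),
        delay=st.sampled_from([2, 7, 30, 90, 180]),
        cond=st.sampled_from(["reward", "loss"]),
    )
    def test_resolution_always_yields_valid_trials(self, kappa, beta, p1, mag, delay, cond):
        params = ModelParams("hyperbolic", kappa=kappa, beta=beta)
        r2 = mag if cond == "reward" else -mag
        r1 = penny_round(solve_immediate_outcome(params, r2, delay, p1))
        out = resolve_atypical_trial(Trial(cond, r1, r2, delay, target_p1=p1),
                                     params, self.CFG)
        assert out.is_valid()


class TestGenerateRunB:
    FITS = {
        "reward": ModelParams("hyperbolic", kappa=0.08, beta=1.2),
        "loss": ModelParams("hyperbolic", kappa=0.04, beta=0.9),
    }

    def test_initial_grid_size(self):
        trials = generate_run_b(self.FITS, run_b_config_for(EXP1_RUN_A), seed=1)
        assert len(trials) == 120
        assert (trials.run == "B").all()
        assert set(trials.target_p1) == {0.3, 0.5, 0.7}

    def test_round_trip_identity_on_unadjusted_trials(self):
        cfg = run_b_config_for(EXP1_RUN_A)
        raw = generate_run_b(self.FITS, cfg, seed=1, round_to_penny=False, resolve=False)
        for row in raw.itertuples():
            params = self.FITS[row.condition]
            v2 = discount_factor(params, row.delay_days) * row.r2
            p = immediate_choice_prob(params.get("beta"), row.r1, v2)
            assert p == pytest.approx(row.target_p1, abs=1e-12)

    def test_all_emitted_trials_are_well_formed(self):
        pathological = {
            "reward": ModelParams("hyperbolic", kappa=5.0, beta=0.03),
            "loss": ModelParams("hyperbolic", kappa=5.0, beta=0.03),
        }
        trials = generate_run_b(pathological, run_b_config_for(EXP2_RUN_A), seed=2)
        for row in trials.itertuples():
            t = Trial(row.condition, row.r1, row.r2, row.delay_days,
                      target_p1=row.target_p1)
            assert t.is_valid()

    def test_zero_beta_raises_with_guidance(self):
        bad = {"reward": ModelParams("hyperbolic", kappa=0.1, beta=0.0),
               "loss": ModelParams("hyperbolic", kappa=0.1, beta=0.0)}
        with pytest.raises(ValueError, match="beta"):
            generate_run_b(bad, run_b_config_for(EXP1_RUN_A))

    def test_deterministic_given_seed(self):
        cfg = run_b_config_for(EXP2_RUN_A)
        assert generate_run_b(self.FITS, cfg, seed=9).equals(
            generate_run_b(self.FITS, cfg, seed=9))
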