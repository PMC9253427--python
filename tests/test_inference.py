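"""Choice link, likelihood, ML fitting and prediction summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from discount_design import (
    ChoiceDataset,
    FitConfig,
    ModelParams,
    cross_run_model_comparison,
    fit_mle,
    immediate_choice_prob,
    log_likelihood,
    predicted_probability_summary,
)
from discount_design.inference import _observed_choice_probs

from conftest import make_dataset, record


class TestChoiceLink:
    def test_indifference_gives_half(self):
        for beta in (0.0, 0.1, 7.0, 100.0):
            assert immediate_choice_prob(beta, 5.0, 5.0) == 0.5

    def test_zero_beta_is_random_choice(self):
        assert immediate_choice_prob(0.0, -3.0, 40.0) == 0.5

    def test_closed_form_value(self):
        assert immediate_choice_prob(0.1, 5.0, 15.0) == pytest.approx(
            1 / (1 + np.e), abs=1e-10
        )

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            immediate_choice_prob(-0.1, 1.0, 2.0)

    def test_overflow_guarded(self):
        assert immediate_choice_prob(100.0, -1e6, 1e6) == pytest.approx(0.0)
        assert immediate_choice_prob(100.0, 1e6, -1e6) == pytest.approx(1.0)

    @given(
        beta=st.floats(0.01, 100),
        d1=st.floats(-30, 30),
        d2=st.floats(-30, 30),
    )
    def test_strictly_decreasing_in_value_difference(self, beta, d1, d2):
        lo, hi = sorted((d1, d2))
        p_lo = immediate_choice_prob(beta, 0.0, lo)
        p_hi = immediate_choice_prob(beta, 0.0, hi)
        assert p_hi <= p_lo
        if hi - lo > 1e-6 and abs(beta * hi) < 500 and abs(beta * lo) < 500:
            assert p_hi < p_lo


class TestLogLikelihood:
    def test_single_record_hand_computed(self):
        # hyperbolic kappa=0.1, D=30: factor 0.25, r2=60 -> v2=15; with r1=5
        # and beta=0.1 the immediate choice has p = 1/(1+e) = 0.26894 and
        # log-likelihood ln(0.26894) = -1.31326.
        p = ModelParams("hyperbolic", kappa=0.1, beta=0.1)
        ds = make_dataset([record("reward", 5.0, 60.0, 30, "immediate")])
        assert log_likelihood(p, ds) == pytest.approx(-1.31326, abs=1e-5)

    def test_empty_dataset_scores_zero(self, hyperbolic_params):
        assert log_likelihood(hyperbolic_params, make_dataset([])) == 0.0

    def test_missing_records_excluded(self, hyperbolic_params):
        responded = make_dataset([record("reward", 2.0, 20.0, 30, "delayed")])
        with_missing = make_dataset(
            [
                record("reward", 2.0, 20.0, 30, "delayed"),
                record("reward", 9.0, 10.0, 90, "missing"),
            ]
        )
        assert log_likelihood(hyperbolic_params, with_missing) == pytest.approx(
            log_likelihood(hyperbolic_params, responded), abs=1e-14
        )

    def test_invalid_params_raise(self, reward_dataset):
        with pytest.raises(ValueError):
            log_likelihood(ModelParams("exponential", kappa=1.5, beta=1.0), reward_dataset)


class TestFitMle:
    def test_all_delayed_pushes_kappa_to_zero(self):
        recs = [record("reward", r1, 20.0, D, "delayed")
                for D in (2, 7, 30, 90) for r1 in (1.0, 5.0, 10.0)]
        fit = fit_mle("hyperbolic", make_dataset(recs), FitConfig(seed=3))
        assert fit.params.kappa <= 1e-4
        assert fit.at_boundary["kappa"] or fit.params.kappa < 1e-5

    def test_deterministic_given_seed(self, reward_dataset):
        cfg = FitConfig(seed=11)
        f1 = fit_mle("hyperboloid", reward_dataset, cfg)
        f2 = fit_mle("hyperboloid", reward_dataset, cfg)
        assert f1.log_lik == f2.log_lik
        assert np.array_equal(f1.params.free_values(), f2.params.free_values())
        assert f1.at_boundary == f2.at_boundary

    def test_requires_non_missing_records(self):
        ds = make_dataset([record("reward", 1.0, 5.0, 7, "missing")])
        with pytest.raises(ValueError):
            fit_mle("hyperbolic", ds)

    def test_matches_modal_generator_near_grid_optimum(self):
        """Fitting modal choices of a hyperbolic agent reaches (within 1e-3)
        the best log-likelihood on a dense (kappa, beta) grid."""
        from discount_design import EXP1_RUN_A, generate_run_a, modal_choice_dataset

        agent = ModelParams("hyperbolic", kappa=0.1, beta=5.0)
        trials = generate_run_a(EXP1_RUN_A, seed=0)
        ds = modal_choice_dataset(agent, trials[trials.condition == "reward"])
        fit = fit_mle("hyperbolic", ds, FitConfig(seed=0))
        kappas = np.concatenate(
            [[0.0], np.exp(np.linspace(np.log(1e-6), np.log(10), 120)).clip(max=10.0)])
        betas = np.concatenate(
            [[0.0], np.exp(np.linspace(np.log(0.01), np.log(100), 120)).clip(max=100.0)])
        best = max(
            log_likelihood(ModelParams("hyperbolic", kappa=k, beta=b), ds)
            for k in kappas for b in betas
        )
        assert fit.log_lik >= best - 1e-3

    def test_nested_model_never_fits_worse(self, reward_dataset):
        cfg = FitConfig(seed=0)
        ll_hyp = fit_mle("hyperbolic", reward_dataset, cfg).log_lik
        ll_mh = fit_mle("modified_hyperboloid", reward_dataset, cfg).log_lik
        assert ll_mh >= ll_hyp - 1e-6


class TestPredictionSummary:
    def test_arithmetic(self):
        p = ModelParams("hyperbolic", kappa=0.0, beta=100.0)
        # kappa=0 -> v2=r2 > r1 -> p(imm) ~ 0 -> delayed predicted ~certainly
        ds = make_dataset([record("reward", 1.0, 20.0, 30, "delayed"),
                           record("reward", 1.0, 20.0, 90, "delayed")])
        s = predicted_probability_summary(p, ds)
        assert s.p_hat == pytest.approx(1.0, abs=1e-6)
        assert s.pe == pytest.approx(0.0, abs=1e-6)
        assert s.pe == 1 - s.p_hat

    def test_mean_of_observed_probabilities(self, reward_dataset, hyperbolic_params):
        s = predicted_probability_summary(hyperbolic_params, reward_dataset)
        probs = _observed_choice_probs(hyperbolic_params, reward_dataset)
        assert s.p_hat == pytest.approx(float(probs.mean()), abs=1e-12)
        assert 0 <= s.p_hat <= 1

    def test_weighted_variant_averages_class_means(self):
        # three immediate-observed records predicted at 0.8, two delayed at 0.6, 0.4
        beta = 1.0
        def r1_for(p_imm, v2):
            return v2 + np.log(p_imm / (1 - p_imm)) / beta
        p = ModelParams("hyperbolic", kappa=0.0, beta=beta)  # v2 = r2
        recs = [record("reward", round(r1_for(0.8, 20.0), 10), 20.0, 30, "immediate")
                for _ in range(3)]
        recs += [record("reward", round(r1_for(1 - 0.6, 20.0), 10), 20.0, 30, "delayed"),
                 record("reward", round(r1_for(1 - 0.4, 20.0), 10), 20.0, 30, "delayed")]
        s = predicted_probability_summary(p, make_dataset(recs))
        assert s.p_hat_weighted == pytest.approx(0.5 * (0.8 + 0.5), abs=1e-9)
        assert s.p_hat == pytest.approx((3 * 0.8 + 0.6 + 0.4) / 5, abs=1e-9)
        assert not s.weighted_fallback

    def test_single_class_falls_back(self, hyperbolic_params):
        ds = make_dataset([record("reward", 1.0, 20.0, 30, "delayed")])
        s = predicted_probability_summary(hyperbolic_params, ds)
        assert s.weighted_fallback
        assert s.p_hat_weighted == s.p_hat

    def test_empty_raises(self, hyperbolic_params):
        with pytest.raises(ValueError):
            predicted_probability_summary(hyperbolic_params, make_dataset([]))


class TestCrossRunComparison:
    def test_identical_runs_give_symmetric_directions(self, reward_records):
        a = make_dataset(reward_records, run="A")
        b = make_dataset(reward_records, run="B")
        table = cross_run_model_comparison(a, b, ["hyperbolic", "exponential"],
                                           FitConfig(seed=5))
        for _, row in table.iterrows():
            assert row.p_hat_a_to_b == pytest.approx(row.p_hat_b_to_a, abs=1e-9)

    def test_single_model_table(self, reward_records):
        a = make_dataset(reward_records, run="A")
        b = make_dataset(reward_records, run="B")
        table = cross_run_model_comparison(a, b, ["hyperbolic"], FitConfig(seed=5))
        assert len(table) == 1
        assert np.isfinite(table.p_hat_a_to_b.iloc[0])
        assert np.isfinite(table.p_hat_b_to_a.iloc[0])

    def test_sorted_by_avg_with_parsimony_ties(self, reward_records):
        a = make_dataset(reward_records, run="A")
        b = make_dataset(reward_records, run="B")
        table = cross_run_model_comparison(
            a, b, ["double_exponential", "hyperbolic", "hyperboloid"], FitConfig(seed=5))
        avgs = table.p_hat_avg.to_numpy()
        assert np.all(np.diff(avgs) <= 1e-12)

    def test_mismatched_subjects_rejected(self, reward_records):
        a = make_dataset(reward_records, subject_id="s0")
        b = make_dataset(reward_records, subject_id="s1")
        with pytest.raises(ValueError):
            cross_run_model_comparison(a, b, ["hyperbolic"])
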