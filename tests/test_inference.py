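"""Priors, the MAP objective, fitting, BIC, and model comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from riskrl import inference, models, recovery, sessions, task


class TestPriors:
    def test_beta22_at_half_is_log_three_halves(self):
        prior = inference.default_priors("RSTD")["alpha_pos"]
        assert prior.logpdf(0.5) == pytest.approx(math.log(1.5), rel=1e-12)

    def test_rate_prior_vanishes_at_bounds(self):
        prior = inference.default_priors("TD")["alpha"]
        assert prior.logpdf(0.0) == -math.inf
        assert prior.logpdf(1.0) == -math.inf

    def test_gamma_shape_scale_closed_form(self):
        # Gamma(shape 2, scale 3) density at 6: 6 e^-2 / 9
        prior = inference.default_priors("TD")["beta"]
        assert prior.logpdf(6.0) == pytest.approx(math.log(6.0 * math.exp(-2.0) / 9.0), rel=1e-12)

    @pytest.mark.parametrize("x", [0.05, 0.3, 0.5, 0.77, 0.99])
    def test_beta_prior_matches_scipy(self, x):
        prior = inference.PriorSpec("beta", 2.0, 2.0, 0.0, 1.0)
        assert prior.logpdf(x) == pytest.approx(stats.beta.logpdf(x, 2, 2), rel=1e-12)

    @pytest.mark.parametrize("x", [0.1, 1.0, 3.0, 12.0, 29.0])
    def test_gamma_prior_matches_scipy(self, x):
        prior = inference.PriorSpec("gamma", 2.0, 3.0, 1e-6, 30.0)
        assert prior.logpdf(x) == pytest.approx(stats.gamma.logpdf(x, 2, scale=3), rel=1e-12)

    def test_shape_rate_convention_switch(self):
        rate_version = inference.PriorSpec("gamma", 2.0, 3.0, 1e-6, 30.0, gamma_rate=True)
        assert rate_version.logpdf(2.0) == pytest.approx(
            stats.gamma.logpdf(2.0, 2, scale=1 / 3), rel=1e-12
        )

    def test_prior_modes(self):
        priors = inference.default_priors("Utility")
        assert priors["alpha"].mode == pytest.approx(0.5)
        assert priors["beta"].mode == pytest.approx(3.0)
        assert priors["rho"].mode == pytest.approx(0.75)

    def test_log_prior_sums_over_free_parameters(self):
        params = models.ModelParams("RSTD", alpha_pos=0.5, alpha_neg=0.5, beta=6.0)
        expected = 2 * math.log(1.5) + math.log(6.0 * math.exp(-2.0) / 9.0)
        assert inference.log_prior(params) == pytest.approx(expected, rel=1e-12)


def reference_nll(params, session):
    """Independent likelihood route: explicit replay via the scalar update
    and softmax functions, no shared code with the compiled kernel."""
    state = models.initialize_values(task.build_machines())
    nll = 0.0
    for spec, rec in zip(session.sequence, session.records):
        if rec.missed:
            continue
        if spec.is_free_choice:
            unchosen = [m for m in spec.offered if m != rec.chosen][0]
            p = models.choice_prob(params.beta, state.q[rec.chosen], state.q[unchosen])
            nll -= math.log(p)
        agency = "free" if spec.is_free_choice else "forced"
        state, _ = models.update_value(params, state, rec.chosen, rec.reward, agency)
    return nll


class TestLikelihood:
    def test_kernel_agrees_with_reference_replay(self, rstd_session):
        rng = np.random.default_rng(7)
        for _ in range(10):
            for name in ("TD", "RSTD", "FourLR", "Utility"):
                params = recovery.draw_uniform_params(name, rng)
                fast = inference.negative_log_likelihood(params, rstd_session)
                slow = reference_nll(params, rstd_session)
                assert fast == pytest.approx(slow, abs=1e-10)

    def test_zero_learning_gives_108_log2(self, rstd_session):
        params = models.ModelParams("TD", alpha=0.0, beta=5.0)
        assert inference.negative_log_likelihood(params, rstd_session) == pytest.approx(
            108 * math.log(2), rel=1e-12
        )

    def test_posterior_is_likelihood_minus_log_prior(self, rstd_session):
        params = models.ModelParams("RSTD", alpha_pos=0.4, alpha_neg=0.2, beta=8.0)
        nlp = inference.negative_log_posterior(params, rstd_session)
        nll = inference.negative_log_likelihood(params, rstd_session)
        assert nlp == pytest.approx(nll - inference.log_prior(params), rel=1e-12)

    def test_single_confident_choice_costs_little(self):
        """One free choice of a much higher-valued option with high beta
        contributes nearly zero likelihood cost."""
        seq = task.TrialSequence(
            (
                task.TrialSpec(1, 1, "forced", ("D80",), "left"),
                task.TrialSpec(2, 1, "test", ("D80", "D20"), None),
            ),
            seed=0,
        )
        records = (
            task.ChoiceRecord(1, "D80", 80),
            task.ChoiceRecord(2, "D80", 80),
        )
        session = sessions.Session(seq, records)
        params = models.ModelParams("TD", alpha=1.0, beta=30.0)
        # after the forced win, Q(D80)=1 vs Q(D20)=0.5: cost = ln(1 + e^-15)
        assert inference.negative_log_likelihood(params, session) < 1e-6

    def test_inconsistent_choice_rejected(self, sequence_seed1):
        records = []
        for spec in sequence_seed1:
            chosen = spec.offered[0]
            records.append(task.ChoiceRecord(spec.index, chosen, 20))
        bad = list(records)
        idx = next(i for i, s in enumerate(sequence_seed1) if s.trial_type == "test")
        unoffered = next(
            m for m in sessions.MACHINE_INDEX if m not in sequence_seed1.trials[idx].offered
        )
        bad[idx] = task.ChoiceRecord(sequence_seed1.trials[idx].index, unoffered, 20)
        with pytest.raises(ValueError, match="offered"):
            sessions.Session(sequence_seed1, tuple(bad))


class TestFitMap:
    def test_determinism(self, rstd_session):
        a = inference.fit_map("RSTD", rstd_session, n_restarts=4, seed=9)
        b = inference.fit_map("RSTD", rstd_session, n_restarts=4, seed=9)
        assert a.map_params == b.map_params
        assert a.neg_log_posterior == b.neg_log_posterior
        assert a.restart_objectives == b.restart_objectives

    def test_best_restart_selected(self, rstd_session):
        fit = inference.fit_map("RSTD", rstd_session, n_restarts=6, seed=2)
        assert fit.neg_log_posterior == pytest.approx(min(fit.restart_objectives))

    def test_prior_modes_recovered_without_data(self):
        """With only forced trials (no free choices) the MAP sits at the
        prior modes: alpha 0.5, beta 3."""
        specs, records = [], []
        for i, m in enumerate(["D20", "D40", "D80", "P40", "P80"] * 3, start=1):
            specs.append(task.TrialSpec(i, 1, "forced", (m,), "left"))
            records.append(task.ChoiceRecord(i, m, 20))
        session = sessions.Session(task.TrialSequence(tuple(specs), 0), tuple(records))
        assert session.n_modeled_choices == 0
        fit = inference.fit_map("TD", session, n_restarts=3, seed=0)
        assert fit.map_params.alpha == pytest.approx(0.5, abs=1e-3)
        assert fit.map_params.beta == pytest.approx(3.0, abs=1e-2)
        assert math.isnan(fit.bic)

    def test_grid_oracle_small(self, rstd_session):
        """The optimizer matches a dense grid argmin of the same objective."""
        params = models.ModelParams("TD", alpha=0.3, beta=8.0)
        seq = task.generate_trial_sequence(77)
        session = recovery.simulate_agent("TD", params, seq, seed=78)
        alphas = np.linspace(0.02, 0.98, 25)
        betas = np.linspace(0.5, 29.5, 20)
        best = (math.inf, None, None)
        for a in alphas:
            for b in betas:
                p = models.ModelParams("TD", alpha=a, beta=b)
                nlp = inference.negative_log_posterior(p, session)
                if nlp < best[0]:
                    best = (nlp, a, b)
        fit = inference.fit_map("TD", session, n_restarts=5, seed=1)
        assert fit.neg_log_posterior <= best[0] + 1e-6
        assert abs(fit.map_params.alpha - best[1]) <= (alphas[1] - alphas[0])
        assert abs(fit.map_params.beta - best[2]) <= (betas[1] - betas[0])

    def test_symmetric_generator_recovers_near_zero_ai(self):
        """RSTD fit to TD-generated data: median |AI| stays small."""
        rng = np.random.default_rng(42)
        ais = []
        for i in range(30):
            alpha = rng.uniform(0.2, 0.8)
            params = models.ModelParams("RSTD", alpha_pos=alpha, alpha_neg=alpha, beta=6.0)
            seq = task.generate_trial_sequence(3000 + i)
            session = recovery.simulate_agent("RSTD", params, seq, seed=4000 + i)
            fit = inference.fit_map("RSTD", session, n_restarts=5, seed=i)
            ais.append(abs(fit.asymmetry_index))
        assert np.median(ais) < 0.15


class TestBic:
    def test_closed_form(self):
        fit = inference.FitResult(
            model_name="RSTD",
            map_params=models.ModelParams("RSTD", alpha_pos=0.5, alpha_neg=0.5, beta=5.0),
            neg_log_posterior=0.0,
            log_likelihood_at_map=-74.861,
            n_modeled_choices=108,
            bic=math.nan,
            asymmetry_index=0.0,
            n_restarts=1,
            converged=True,
        )
        assert inference.compute_bic(fit) == pytest.approx(149.722 + 3 * math.log(108), abs=1e-3)

    def test_parameter_penalty(self):
        kwargs = dict(
            neg_log_posterior=0.0, log_likelihood_at_map=-74.861,
            n_modeled_choices=108, bic=math.nan, asymmetry_index=None,
            n_restarts=1, converged=True,
        )
        td = inference.FitResult(
            "TD", models.ModelParams("TD", alpha=0.5, beta=5.0), **kwargs
        )
        rstd = inference.FitResult(
            "RSTD", models.ModelParams("RSTD", alpha_pos=0.5, alpha_neg=0.5, beta=5.0), **kwargs
        )
        assert inference.compute_bic(rstd) - inference.compute_bic(td) == pytest.approx(
            math.log(108), rel=1e-12
        )

    def test_zero_choices_rejected(self):
        fit = inference.FitResult(
            "TD", models.ModelParams("TD", alpha=0.5, beta=5.0), 0.0, 0.0, 0,
            math.nan, None, 1, True,
        )
        with pytest.raises(ValueError):
            inference.compute_bic(fit)


class TestModelComparison:
    def test_winner_requires_margin(self):
        comp = inference.ModelComparison()
        comp.add("RSTD", np.array([100.0, 110.0, 120.0]))
        comp.add("TD", np.array([104.0, 113.0, 122.0]))
        assert comp.winner() is None  # median gap 3 <= 6
        comp.add("FourLR", np.array([150.0, 160.0, 170.0]))
        assert comp.winner() is None  # runner-up still within 6
        comp2 = inference.ModelComparison()
        comp2.add("RSTD", np.array([100.0, 110.0, 120.0]))
        comp2.add("TD", np.array([120.0, 130.0, 125.0]))
        assert comp2.winner() == "RSTD"

    def test_delta_bic_zero_for_best(self):
        comp = inference.ModelComparison()
        comp.add("A", np.array([10.0, 12.0]))
        comp.add("B", np.array([20.0, 22.0]))
        assert comp.delta_bic()["A"] == 0.0
        assert comp.delta_bic()["B"] == pytest.approx(10.0)


class TestExplicitPrediction:
    def _records(self, alpha_pos, alpha_neg, noise_sd, seed=0, n=60):
        """Prediction stream from a hand-rolled agent with known rates."""
        rng = np.random.default_rng(seed)
        values = {"A": 0.5, "B": 0.5}
        records = []
        cats = rng.permuted(["A", "B"] * (n // 2 + 1))[:n]
        for t, cat in enumerate(cats, start=1):
            mean = 0.65 if cat == "A" else 0.35
            shown = float(np.clip(rng.normal(mean, 0.17), 0, 1))
            stated = values[cat] + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            delta = shown - values[cat]
            rate = alpha_pos if delta > 0 else alpha_neg
            records.append(
                inference.PredictionRecord(t, cat, shown, float(np.clip(stated, 0, 1)), delta)
            )
            values[cat] += rate * delta
        return records

    def test_noiseless_recovery(self):
        records = self._records(0.6, 0.2, noise_sd=0.0, seed=5)
        fit = inference.fit_explicit_prediction(records, n_restarts=5, seed=1)
        assert fit.map_params.alpha_pos == pytest.approx(0.6, abs=0.05)
        assert fit.map_params.alpha_neg == pytest.approx(0.2, abs=0.05)
        assert not fit.unidentifiable

    def test_zero_pe_stream_flagged_unidentifiable(self):
        records = [
            inference.PredictionRecord(t, "A" if t % 2 else "B", 0.5, 0.5) for t in range(1, 21)
        ]
        fit = inference.fit_explicit_prediction(records, n_restarts=2, seed=0)
        assert fit.unidentifiable
        assert fit.neg_log_posterior == pytest.approx(0.0, abs=1e-12)

    def test_too_few_trials_per_category_rejected(self):
        records = [inference.PredictionRecord(1, "A", 0.5, 0.5), inference.PredictionRecord(2, "B", 0.5, 0.5)]
        with pytest.raises(ValueError):
            inference.fit_explicit_prediction(records)

    def test_symmetric_generator_gives_near_zero_mean_ai(self):
        from riskrl import synth

        data = synth.generate_prediction_dataset(
            40, n_trials=40, seed=9, category_means=(0.5, 0.5)
        )
        ais = [
            inference.fit_explicit_prediction(recs, n_restarts=3, seed=sid).asymmetry_index
            for sid, recs in data.items()
        ]
        assert abs(float(np.mean(ais))) < 0.12
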