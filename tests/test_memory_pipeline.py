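"""Memory scoring, PE annotation, and the memory regressions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskrl import inference, memory, models, sessions, synth, task


def make_records(n_old, n_old_said_old, n_new, n_new_said_old, subject_id=1):
    records = []
    mem_trial = 1
    for i in range(n_old):
        said_old = i < n_old_said_old
        records.append(
            memory.MemoryRecord(
                subject_id, f"img_{i:03d}", True, 1 if said_old else 4, mem_trial, trial=i + 1
            )
        )
        mem_trial += 1
    for i in range(n_new):
        said_old = i < n_new_said_old
        records.append(
            memory.MemoryRecord(subject_id, f"foil_{i:03d}", False, 2 if said_old else 3, mem_trial)
        )
        mem_trial += 1
    return records


class TestSignalDetection:
    def test_hit_rate_example(self):
        sd = memory.signal_detection(make_records(100, 54, 100, 24))
        assert sd.hit_rate == pytest.approx(0.54)
        assert sd.false_alarm_rate == pytest.approx(0.24)

    def test_d_prime_quantile_closed_form(self):
        # hit .8, fa .2 with 200 items each: d' = z(.8) - z(.2) = 2 * 0.8416
        sd = memory.signal_detection(make_records(200, 160, 200, 40))
        expected = stats.norm.ppf(0.8) - stats.norm.ppf(0.2)
        assert sd.d_prime == pytest.approx(expected, abs=1e-10)
        assert sd.d_prime == pytest.approx(1.683, abs=1e-3)

    def test_equal_rates_give_zero(self):
        sd = memory.signal_detection(make_records(50, 20, 50, 20))
        assert sd.d_prime == pytest.approx(0.0, abs=1e-12)

    def test_extreme_rates_corrected(self):
        sd = memory.signal_detection(make_records(50, 50, 50, 0))
        assert math.isfinite(sd.d_prime)
        expected = stats.norm.ppf(1 - 1 / 100) - stats.norm.ppf(1 / 100)
        assert sd.d_prime == pytest.approx(expected, abs=1e-10)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            memory.signal_detection(make_records(10, 5, 0, 0))

    def test_binarization_boundary(self):
        rec = memory.MemoryRecord(1, "x", True, 2, 1, trial=1)
        assert rec.said_old and rec.correct
        rec = memory.MemoryRecord(1, "x", True, 3, 1, trial=1)
        assert not rec.said_old and not rec.correct


class TestAnnotateWithPe:
    def test_first_forced_win_delta(self, machine_by_id):
        """A first-trial forced P80 win has delta = 1 - 0.5 = +0.5."""
        seq = task.TrialSequence(
            (task.TrialSpec(1, 1, "forced", ("P80",), "left"),), seed=0
        )
        session = sessions.Session(seq, (task.ChoiceRecord(1, "P80", 80),))
        params = models.ModelParams("RSTD", alpha_pos=0.4, alpha_neg=0.2, beta=5.0)
        fit = inference.FitResult("RSTD", params, 0.0, 0.0, 0, math.nan, 0.5, 1, True)
        recs = [memory.MemoryRecord(1, "img_001", True, 1, 1, trial=1)]
        trace, enriched = memory.annotate_with_pe(fit, session, recs)
        assert enriched[0].pe == pytest.approx(0.5)
        assert enriched[0].pe_valence == 1
        assert enriched[0].agency == "forced"
        assert enriched[0].machine_type == "probabilistic"

    def test_symmetric_rstd_trace_matches_td_replay(self, rstd_session):
        rstd = models.ModelParams("RSTD", alpha_pos=0.3, alpha_neg=0.3, beta=5.0)
        td = models.ModelParams("TD", alpha=0.3, beta=5.0)
        t1 = sessions.replay(rstd, rstd_session)
        t2 = sessions.replay(td, rstd_session)
        assert [(s.trial, s.delta, s.q_post) for s in t1] == [
            (s.trial, s.delta, s.q_post) for s in t2
        ]

    def test_unlinked_image_rejected(self, rstd_session):
        params = models.ModelParams("RSTD", alpha_pos=0.4, alpha_neg=0.2, beta=5.0)
        fit = inference.FitResult("RSTD", params, 0.0, 0.0, 108, math.nan, 0.3, 1, True)
        recs = [memory.MemoryRecord(1, "img_999", True, 1, 1, trial=999)]
        with pytest.raises(ValueError, match="trial 999"):
            memory.annotate_with_pe(fit, rstd_session, recs)

    def test_unvalenced_fit_rejected(self, rstd_session):
        params = models.ModelParams("TD", alpha=0.4, beta=5.0)
        fit = inference.FitResult("TD", params, 0.0, 0.0, 108, math.nan, None, 1, True)
        with pytest.raises(ValueError):
            memory.annotate_with_pe(fit, rstd_session, [])

    def test_long_run_deterministic_pe_shrinks(self, fitted_cohort):
        """|PE| on late deterministic-machine trials is smaller than early.

        D80 pays 1.0 against the 0.5 initialization, so its early PEs are
        large and decay as its value converges. (D40's payoff equals the
        initialization, so its PE is zero throughout — no decay to observe.)
        """
        subj = fitted_cohort[0]
        trace = sessions.replay(subj.fit.map_params, subj.session)
        det = [s for s in trace if s.chosen == "D80"]
        early = np.mean([abs(s.delta) for s in det[:3]])
        late = np.mean([abs(s.delta) for s in det[-3:]])
        assert late < early


class TestBuildMemoryTable:
    def test_columns_and_zscoring(self, fitted_cohort):
        table = memory.build_memory_table(fitted_cohort)
        assert len(table) == 8 * 183
        for col in ("ai_z", "pe_valence_z", "pe_mag_z", "age_z", "fa_rate_z", "mem_trial_z"):
            assert table[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert table[col].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert (table["age_z2"] == table["age_z"] ** 2).all()
        assert set(table["correct"].unique()) <= {0, 1}

    def test_subject_without_fit_excluded(self, fitted_cohort):
        crippled = list(fitted_cohort)
        clone = synth.SubjectData(
            subject_id=99, age=20.0, true_params=None,
            session=crippled[0].session, memory_records=crippled[0].memory_records,
            fa_rate=0.2, fit=None,
        )
        table = memory.build_memory_table(crippled + [clone])
        assert 99 not in set(table["subject_id"])

    def test_foils_contribute_no_rows(self, fitted_cohort):
        table = memory.build_memory_table(fitted_cohort)
        assert table["pe"].notna().all()

    def test_within_subject_zscoring_switch(self, fitted_cohort):
        table = memory.build_memory_table(fitted_cohort, z_within_subject=True)
        for _, group in table.groupby("subject_id"):
            assert group["pe_mag_z"].mean() == pytest.approx(0.0, abs=1e-10)


class TestMemoryGlmm:
    def test_strong_effect_recovered_on_small_cohort(self, fitted_cohort):
        table = memory.build_memory_table(fitted_cohort)
        result = memory.fit_memory_glmm(table)
        assert result.converged
        assert result.ladder_log[-1].endswith("converged")
        mag = result.term("pe_mag_z")
        assert mag["estimate"] > 0  # generator's b_mag = 0.2
        trial = result.term("mem_trial_z")
        assert trial["estimate"] < 0  # generator's b_trial = -0.2
        assert np.allclose(
            result.coefficients["odds_ratio"], np.exp(result.coefficients["estimate"])
        )

    def test_single_level_outcome_flagged_as_separation(self, fitted_cohort):
        table = memory.build_memory_table(fitted_cohort)
        table = table.assign(correct=1)
        result = memory.fit_memory_glmm(table)
        assert result.separation
        assert not result.converged
        assert result.coefficients.empty

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            memory.fit_memory_glmm(pd.DataFrame())


def _toy_result(coeffs: dict) -> memory.MemoryRegressionResult:
    frame = pd.DataFrame(
        {
            "term": list(coeffs),
            "estimate": list(coeffs.values()),
            "se": [0.1] * len(coeffs),
            "z": [c / 0.1 for c in coeffs.values()],
            "p": [0.5] * len(coeffs),
            "odds_ratio": np.exp(list(coeffs.values())),
            "ci_low": [0.0] * len(coeffs),
            "ci_high": [0.0] * len(coeffs),
        }
    )
    return memory.MemoryRegressionResult(
        coefficients=frame, random_structure="toy", n_observations=0,
        converged=True, cov_params=np.zeros((len(coeffs), len(coeffs))),
    )


class TestMarginalMeans:
    def test_all_zero_coefficients_predict_half(self):
        result = _toy_result({"Intercept": 0.0, "pe_mag_z": 0.0})
        grid = memory.marginal_means(result)
        assert (grid["prob"] == 0.5).all()

    def test_monotone_in_magnitude(self):
        result = _toy_result({"Intercept": 0.0, "pe_mag_z": 0.4})
        grid = memory.marginal_means(result, ai_levels=(0.0,), magnitude_levels=(-1.0, 0.0, 1.0))
        for _, sub in grid.groupby("pe_valence"):
            probs = sub.sort_values("pe_mag")["prob"].to_numpy()
            assert np.all(np.diff(probs) > 0)

    def test_interaction_sign_structure(self):
        """With b_int > 0 the magnitude slope for positive-PE items grows
        with AI; for negative-PE items it shrinks."""
        result = _toy_result({"Intercept": 0.0, "ai_z:pe_valence_z:pe_mag_z": 0.3})
        grid = memory.marginal_means(result, ai_levels=(-1.0, 1.0), magnitude_levels=(-1.0, 1.0))

        def slope(ai, val):
            sub = grid[(grid["ai"] == ai) & (grid["pe_valence"] == val)].sort_values("pe_mag")
            return sub["prob"].iloc[-1] - sub["prob"].iloc[0]

        assert slope(1.0, 1.0) > slope(-1.0, 1.0)
        assert slope(1.0, -1.0) < slope(-1.0, -1.0)

    def test_failed_fit_rejected(self):
        result = _toy_result({"Intercept": 0.0})
        result.converged = False
        with pytest.raises(ValueError):
            memory.marginal_means(result)


class TestGeneratorStructure:
    def test_probabilistic_machine_memory_advantage(self, small_cohort):
        """With b_mag > 0, probabilistic outcomes (larger |PE|) are better
        remembered than deterministic ones — a model-implied property."""
        hit_prob, hit_det = [], []
        for subj in small_cohort:
            trace = sessions.replay(subj.true_params, subj.session).by_trial()
            for rec in subj.memory_records:
                if not rec.truly_old:
                    continue
                chosen = trace[rec.trial].chosen
                (hit_prob if chosen.startswith("P") else hit_det).append(rec.said_old)
        assert np.mean(hit_prob) > np.mean(hit_det)

    def test_three_way_estimate_monotone_in_generating_coefficient(self):
        """The estimated AI x valence x magnitude interaction grows with the
        generating b_int across {0, 0.1, 0.2}."""
        estimates = []
        for b_int in (0.0, 0.1, 0.2):
            cohort = synth.generate_cohort(
                synth.CohortConfig(n_subjects=40, seed=55, memory=synth.MemoryCoefs(b_int=b_int))
            )
            for s in cohort:
                s.fit = inference.fit_map("RSTD", s.session, n_restarts=5, seed=500 + s.subject_id)
                _, s.memory_records = memory.annotate_with_pe(s.fit, s.session, s.memory_records)
            result = memory.fit_memory_glmm(memory.build_memory_table(cohort))
            estimates.append(float(result.term("ai_z:pe_valence_z:pe_mag_z")["estimate"]))
        assert estimates[0] < estimates[1] < estimates[2]


class TestSubsetAnalyses:
    def test_probabilistic_subset_and_agency_model(self, fitted_cohort):
        table = memory.build_memory_table(fitted_cohort)
        results = memory.subset_analyses(table)
        assert results["probabilistic_only"].converged
        assert results["agency"].converged
        agency_terms = set(results["agency"].coefficients["term"])
        assert any("agency_free" in t for t in agency_terms)

    def test_deterministic_pe_magnitude_compressed(self, fitted_cohort):
        """Deterministic outcomes stop surprising once learned, so their
        |PE| variance is below the probabilistic machines'."""
        table = memory.build_memory_table(fitted_cohort)
        det = table[table["machine_type"] == "deterministic"]["pe_mag"]
        prob = table[table["machine_type"] == "probabilistic"]["pe_mag"]
        assert det.var() < prob.var()

    def test_empty_subset_rejected(self, fitted_cohort):
        table = memory.build_memory_table(fitted_cohort)
        with pytest.raises(ValueError):
            memory.subset_analyses(table[table["machine_type"] == "nope"])
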