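"""Discrimination, calibration and cross-validation checks."""

import numpy as np
import pandas as pd
import pytest

from erisk.absolute_risk import project_risks
from erisk.validation import (
    calibration_deciles,
    crossvalidate_5fold,
    cstatistic_5yr,
    expected_observed,
    external_validation,
)

from conftest import reduced_cohort, reduced_spec, reduced_truth


def _mini_cohort(times, events, cause="er_pos"):
    n = len(times)
    return pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "entry_age": np.full(n, 50.0),
            "exit_age": 50.0 + np.asarray(times, dtype=float),
            "event": [cause if e else "censored" for e in events],
            "menopausal_status": ["post"] * n,
        }
    )


class TestCStatistic:
    def test_perfect_ranking_gives_one(self):
        cohort = _mini_cohort([1, 2, 6, 7], [1, 1, 0, 0])
        c, _ = cstatistic_5yr([0.9, 0.8, 0.1, 0.2], cohort, "er_pos", n_bootstrap=0)
        assert c == 1.0

    def test_constant_risk_gives_half(self):
        cohort = _mini_cohort([1, 2, 6, 7], [1, 1, 0, 0])
        c, _ = cstatistic_5yr([0.3] * 4, cohort, "er_pos", n_bootstrap=0)
        assert c == 0.5

    def test_matches_exhaustive_pair_enumeration(self):
        """8-subject fixture with censoring vs a brute-force comparable-pairs oracle."""
        times = [1.0, 2.5, 3.0, 3.0, 4.5, 2.0, 6.0, 7.0]
        events = [1, 1, 0, 1, 0, 0, 0, 0]  # subject 5 censored early
        risks = np.array([0.8, 0.3, 0.5, 0.5, 0.2, 0.6, 0.4, 0.1])
        cohort = _mini_cohort(times, events)
        c, _ = cstatistic_5yr(risks, cohort, "er_pos", n_bootstrap=0)

        t = np.minimum(np.asarray(times), 5.0)
        case = np.asarray(events, dtype=bool) & (np.asarray(times) <= 5.0)
        num = den = 0.0
        for i in range(8):
            if not case[i]:
                continue
            for j in range(8):
                if j == i:
                    continue
                # comparable: j at risk beyond t_i, or censored exactly at t_i
                if t[j] < t[i] or (t[j] == t[i] and case[j]):
                    continue
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
        assert c == pytest.approx(num / den)

    def test_invariant_under_monotone_transform(self, small_cohort):
        truth = reduced_truth()
        risks = project_risks(truth.tumor, truth.competing, small_cohort)["risk_er_pos"]
        c1, _ = cstatistic_5yr(risks, small_cohort, "er_pos", n_bootstrap=0)
        c2, _ = cstatistic_5yr(np.sqrt(risks), small_cohort, "er_pos", n_bootstrap=0)
        c3, _ = cstatistic_5yr(np.log(risks + 1e-12), small_cohort, "er_pos", n_bootstrap=0)
        assert c1 == pytest.approx(c2, abs=1e-12)
        assert c1 == pytest.approx(c3, abs=1e-12)

    def test_no_comparable_pairs_is_an_error(self):
        cohort = _mini_cohort([6, 7], [0, 0])
        with pytest.raises(ValueError):
            cstatistic_5yr([0.1, 0.2], cohort, "er_pos", n_bootstrap=0)


class TestExpectedObserved:
    def test_hand_arithmetic_of_ci(self):
        # E=110 over O=100: CI = 1.10 * exp(+-1.96/10)
        n = 100
        cohort = _mini_cohort(np.full(n, 1.0), np.ones(n))
        risks = np.full(n, 1.10)
        eo, (lo, hi) = expected_observed(risks, cohort, "er_pos")
        assert eo == pytest.approx(1.10)
        assert lo == pytest.approx(1.10 * np.exp(-0.196), abs=1e-3)
        assert hi == pytest.approx(1.10 * np.exp(0.196), abs=1e-3)

    def test_linearity_in_expected(self):
        cohort = _mini_cohort([1, 2, 6], [1, 1, 0])
        risks = np.array([0.5, 0.3, 0.2])
        eo1, _ = expected_observed(risks, cohort, "er_pos")
        eo2, _ = expected_observed(2 * risks, cohort, "er_pos")
        assert eo2 == pytest.approx(2 * eo1)

    def test_zero_observed_events_is_an_error(self):
        cohort = _mini_cohort([6, 7], [0, 0])
        with pytest.raises(ValueError):
            expected_observed([0.1, 0.1], cohort, "er_pos")

    def test_self_calibrated_input_gives_unity(self):
        # predicted risks equal to the empirical event frequency
        n = 200
        events = np.zeros(n)
        events[:40] = 1
        cohort = _mini_cohort(np.where(events, 1.0, 6.0), events)
        eo, _ = expected_observed(np.full(n, 0.2), cohort, "er_pos")
        assert eo == pytest.approx(1.0)


class TestCalibrationDeciles:
    def test_decile_sizes_partition_subjects(self):
        n = 100
        cohort = _mini_cohort(np.full(n, 6.0), np.zeros(n))
        rng = np.random.default_rng(0)
        table = calibration_deciles(rng.uniform(0, 1, n), cohort, "er_pos")
        assert list(table["n"]) == [10] * 10
        assert table["n_events"].sum() == 0

    def test_self_calibrated_cohort_within_3se(self):
        truth = reduced_truth(gompertz=None, unknown_er_prob=0.0)
        cohort = reduced_cohort(60_000, seed=51, truth=truth)
        risks = project_risks(truth.tumor, None, cohort)["risk_er_pos"].to_numpy()
        table = calibration_deciles(risks, cohort, "er_pos")
        for _, row in table.iterrows():
            se = np.sqrt(max(row["mean_predicted"] * (1 - row["mean_predicted"]), 1e-12) / row["n"])
            assert abs(row["mean_predicted"] - row["observed"]) < 3 * se + 1e-12

    def test_inflated_risks_overpredict_in_every_decile(self):
        truth = reduced_truth(gompertz=None, unknown_er_prob=0.0)
        cohort = reduced_cohort(60_000, seed=52, truth=truth)
        risks = 1.5 * project_risks(truth.tumor, None, cohort)["risk_er_pos"].to_numpy()
        table = calibration_deciles(risks, cohort, "er_pos")
        assert (table["mean_predicted"] > table["observed"]).all()


class TestCrossValidation:
    def test_every_subject_predicted_once_and_metrics_sane(self, small_cohort):
        report = crossvalidate_5fold(small_cohort, reduced_spec(), seed=4, n_bootstrap=25)
        oof = report.oof_risks
        assert len(oof) == len(small_cohort)
        assert oof["risk_er_pos"].notna().all()
        assert sorted(oof["fold"].unique()) == [0, 1, 2, 3, 4]
        cv = report.overall["er_pos"]
        assert 0.5 < cv.c_statistic < 1.0
        assert cv.c_ci[0] <= cv.c_statistic <= cv.c_ci[1]
        # well-specified model evaluated on its own population: E/O near 1
        assert 0.8 < cv.e_over_o < 1.25

    def test_cv_close_to_apparent_c(self):
        from erisk.hazards import fit_gompertz, fit_piecewise, split_person_time

        cohort = reduced_cohort(60_000, seed=15)
        spec = reduced_spec()
        report = crossvalidate_5fold(cohort, spec, seed=5, n_bootstrap=0)
        model = fit_piecewise(split_person_time(cohort, spec.cutoffs), spec)
        gomp = fit_gompertz(cohort)
        apparent = project_risks(model, gomp, cohort)["risk_er_pos"]
        c_app, _ = cstatistic_5yr(apparent, cohort, "er_pos", n_bootstrap=0)
        assert abs(report.overall["er_pos"].c_statistic - c_app) < 0.02

    def test_stratum_elimination_reduces_c_under_real_country_effects(self):
        truth = reduced_truth(with_stratum=True, stratum_loghr=0.5)
        cohort = reduced_cohort(25_000, seed=6, truth=truth, with_stratum=True)
        spec = reduced_spec(with_stratum=True)
        full = crossvalidate_5fold(cohort, spec, seed=7, n_bootstrap=0)
        nostrat = crossvalidate_5fold(
            cohort, spec, seed=7, n_bootstrap=0, eliminate_stratum=True
        )
        assert (
            nostrat.overall["er_pos"].c_statistic < full.overall["er_pos"].c_statistic
        )


class TestExternalValidation:
    def test_recalibrated_projection_is_mean_calibrated(self):
        from erisk.hazards import fit_piecewise, split_person_time

        spec = reduced_spec()
        source = reduced_cohort(40_000, seed=8)
        target = reduced_cohort(40_000, seed=9)
        model = fit_piecewise(split_person_time(source, spec.cutoffs), spec)
        report = external_validation(model, target, seed=10, n_bootstrap=0)
        for cause in ("er_pos", "er_neg"):
            eo = report.overall[cause].e_over_o
            o = report.overall[cause].deciles["n_events"].sum()
            assert abs(eo - 1.0) < 3 / np.sqrt(o)
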