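"""Episode splitting, piecewise MLE vs Poisson-GLM oracle, Gompertz, LRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from erisk.coding import Covariate, EVENT_CENSORED
from erisk.hazards import fit_gompertz, fit_piecewise, lrt_heterogeneity, split_person_time
from erisk.models import GompertzModel, ModelSpec, PiecewiseHazardModel
from erisk.synthetic import TrueModel, simulate_outcomes

from conftest import reduced_cohort, reduced_spec, reduced_truth


class TestSplitPersonTime:
    def test_hand_fixture_two_bands(self):
        df = pd.DataFrame(
            {"subject_id": [0], "entry_age": [48.0], "exit_age": [53.0], "event": ["er_pos"]}
        )
        eps = split_person_time(df, (45.0, 50.0, 55.0))
        assert list(eps["exposure"]) == [2.0, 3.0]
        assert list(eps["band"]) == [1, 2]
        assert list(eps["event"]) == [EVENT_CENSORED, "er_pos"]

    def test_single_band_event(self):
        df = pd.DataFrame(
            {"subject_id": [0], "entry_age": [46.0], "exit_age": [47.0], "event": ["er_pos"]}
        )
        eps = split_person_time(df, (45.0, 50.0))
        assert len(eps) == 1
        assert eps["exposure"].iloc[0] == pytest.approx(1.0)
        assert eps["event"].iloc[0] == "er_pos"

    @given(st.integers(0, 2**31 - 1))
    def test_exposure_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        entry = rng.uniform(40, 70, n)
        df = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "entry_age": entry,
                "exit_age": entry + rng.uniform(0.01, 25, n),
                "event": rng.choice(["er_pos", "er_neg", "competing", "censored"], n),
            }
        )
        eps = split_person_time(df, (45.0, 50.0, 55.0, 60.0, 65.0, 70.0, 75.0))
        total = eps.groupby("subject_id")["exposure"].sum()
        np.testing.assert_allclose(
            total.to_numpy(), (df["exit_age"] - df["entry_age"]).to_numpy(), atol=1e-6
        )
        # exactly one event row per non-censored subject
        n_events = (eps["event"] != EVENT_CENSORED).sum()
        assert n_events == (df["event"] != EVENT_CENSORED).sum()


def _tiny_fixture(n=50, seed=1):
    """Small two-band cohort with one binary covariate and both causes."""
    rng = np.random.default_rng(seed)
    entry = rng.uniform(45, 60, n)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "entry_age": entry,
            "exit_age": entry + rng.uniform(1, 15, n),
            "event": rng.choice(
                ["er_pos", "er_neg", "censored"], n, p=[0.3, 0.2, 0.5]
            ),
            "grp": rng.choice(np.array(["a", "b"], dtype=object), n),
        }
    )
    grp = Covariate("grp", categories=("a", "b"))
    spec = ModelSpec(covariates=(grp,), shared={"grp": False}, cutoffs=(55.0,))
    return df, spec


class TestFitPiecewise:
    def test_single_cell_rate_is_events_over_persontime(self):
        # one band, no covariates: MLE is d/T exactly
        df = pd.DataFrame(
            {
                "subject_id": np.arange(20),
                "entry_age": np.full(20, 50.0),
                "exit_age": np.full(20, 100.0),
                "event": ["er_pos"] * 10 + ["er_neg"] * 10,
            }
        )
        spec = ModelSpec(covariates=(), shared={}, cutoffs=())
        model = fit_piecewise(split_person_time(df, spec.cutoffs), spec)
        assert np.exp(model.params["base:er_pos:0"]) == pytest.approx(10 / 1000.0, rel=1e-9)
        assert np.exp(model.params["base:er_neg:0"]) == pytest.approx(10 / 1000.0, rel=1e-9)

    def test_matches_poisson_glm_oracle(self):
        """Stacked piecewise MLE equals an independent GLM fit on the episodes."""
        import statsmodels.api as sm

        df, spec = _tiny_fixture()
        eps = split_person_time(df, spec.cutoffs)
        model = fit_piecewise(eps, spec)

        # oracle: hand-built stacked Poisson design with log-exposure offset
        rows, ys, offs = [], [], []
        for cause in ("er_pos", "er_neg"):
            for _, ep in eps.iterrows():
                rec = {}
                for b in range(2):
                    rec[f"base:{cause}:{b}"] = 1.0 * (ep["band"] == b)
                    rec[f"base:{'er_neg' if cause == 'er_pos' else 'er_pos'}:{b}"] = 0.0
                rec[f"{cause}:grp=b"] = 1.0 * (ep["grp"] == "b")
                other = "er_neg" if cause == "er_pos" else "er_pos"
                rec[f"{other}:grp=b"] = 0.0
                rows.append(rec)
                ys.append(1.0 * (ep["event"] == cause))
                offs.append(np.log(ep["exposure"]))
        X = pd.DataFrame(rows).fillna(0.0)
        fit = sm.GLM(
            np.array(ys), X, family=sm.families.Poisson(), offset=np.array(offs)
        ).fit()
        for name in X.columns:
            assert model.params[name] == pytest.approx(fit.params[name], abs=1e-6)

    def test_sharing_constraint_never_increases_loglik(self, small_cohort):
        spec_free = reduced_spec()
        spec_con = reduced_spec(share_height=True)
        eps = split_person_time(small_cohort, spec_free.cutoffs)
        ll_free = fit_piecewise(eps, spec_free).loglik
        ll_con = fit_piecewise(eps, spec_con).loglik
        assert ll_con <= ll_free + 1e-8

    def test_shared_coefficient_identical_across_causes(self, small_cohort):
        spec = reduced_spec(share_height=True)
        model = fit_piecewise(split_person_time(small_cohort, spec.cutoffs), spec)
        # one parameter serves both causes: bit-identical by construction
        lp_pos = model.linear_predictor(small_cohort.head(50), "er_pos")
        lp_neg = model.linear_predictor(small_cohort.head(50), "er_neg")
        np.testing.assert_array_equal(lp_pos, lp_neg)

    def test_empty_cell_pinned_with_warning(self):
        rng = np.random.default_rng(3)
        n = 30
        entry = rng.uniform(45, 52, n)
        df = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "entry_age": entry,
                # nobody reaches band 1 (ages above 55)
                "exit_age": np.minimum(entry + rng.uniform(0.5, 10, n), 54.0),
                "event": rng.choice(["er_pos", "er_neg", "censored"], n, p=[0.3, 0.2, 0.5]),
                "grp": rng.choice(np.array(["a", "b"], dtype=object), n),
            }
        )
        grp = Covariate("grp", categories=("a", "b"))
        spec = ModelSpec(covariates=(grp,), shared={"grp": False}, cutoffs=(55.0,))
        with pytest.warns(RuntimeWarning, match="pinned"):
            model = fit_piecewise(split_person_time(df, spec.cutoffs), spec)
        assert model.params["base:er_pos:1"] == -30.0


class TestFitGompertz:
    def test_exponential_limit_rate(self):
        rng = np.random.default_rng(0)
        n = 2000
        entry = rng.uniform(40, 70, n)
        fu = rng.uniform(1, 10, n)
        df = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "entry_age": entry,
                "exit_age": entry + fu,
                "event": rng.choice(["competing", "censored"], n, p=[0.1, 0.9]),
            }
        )
        g = fit_gompertz(df, gamma_bounds=(-1e-12, 1e-12))
        d = (df["event"] == "competing").sum()
        t = fu.sum()
        assert np.exp(g.alpha) == pytest.approx(d / t, rel=1e-6)

    def test_parameter_recovery(self):
        truth = GompertzModel(alpha=np.log(1e-4), gamma=0.1)
        rng = np.random.default_rng(1)
        n = 100_000
        entry = rng.uniform(40, 70, n)
        t_event = truth.inverse_time(entry, rng.exponential(size=n))
        t_cens = entry + rng.uniform(5, 20, n)
        exit_ = np.minimum(t_event, t_cens)
        df = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "entry_age": entry,
                "exit_age": exit_,
                "event": np.where(t_event < t_cens, "competing", "censored"),
            }
        )
        g = fit_gompertz(df)
        se_a, se_g = np.sqrt(np.diag(g.cov))
        assert abs(g.alpha - np.log(1e-4)) < 3 * se_a
        assert abs(g.gamma - 0.1) < 3 * se_g
        # positive slope: hazard is monotone increasing in age
        assert g.hazard(70) > g.hazard(50)


class TestLRT:
    def test_statistic_definition_and_df(self, small_cohort):
        spec_free = reduced_spec()
        spec_con = reduced_spec(share_height=True)
        eps = split_person_time(small_cohort, spec_free.cutoffs)
        free = fit_piecewise(eps, spec_free)
        con = fit_piecewise(eps, spec_con)
        stat, df, p = lrt_heterogeneity(free, con)
        assert stat == pytest.approx(2 * (free.loglik - con.loglik))
        assert df == 1
        assert 0.0 <= p <= 1.0

    def test_non_nested_specs_rejected(self, small_cohort):
        spec_free = reduced_spec()
        eps = split_person_time(small_cohort, spec_free.cutoffs)
        free = fit_piecewise(eps, spec_free)
        with pytest.raises(ValueError, match="nested|nothing"):
            lrt_heterogeneity(free, free)
        # reversed nesting direction is an error too
        con = fit_piecewise(eps, reduced_spec(share_height=True))
        with pytest.raises(ValueError, match="nested"):
            lrt_heterogeneity(con, free)

    def test_power_against_true_height_heterogeneity(self):
        # ER+ HR 1.19 vs ER− HR 1.00 per 10 cm is detectable at large n
        truth = reduced_truth(height_hr=(1.19, 1.00), gompertz=None, unknown_er_prob=0.0)
        df = reduced_cohort(200_000, seed=21, truth=truth)
        eps = split_person_time(df, truth.tumor.spec.cutoffs)
        free = fit_piecewise(eps, reduced_spec())
        con = fit_piecewise(eps, reduced_spec(share_height=True))
        stat, dof, p = lrt_heterogeneity(free, con)
        assert p < 0.05
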