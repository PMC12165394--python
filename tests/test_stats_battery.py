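import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdgait.io_model import AnalysisConfig, ValidationError
from pdgait.stats_battery import (
    NormalityResult,
    choose_method,
    correlate,
    manova,
    ols_fit,
    run_correlation_battery,
    run_full_battery,
    shapiro_wilk,
    vif,
)
from pdgait.synthetic_data import CohortSimParams, simulate_cohort


def normal_flag(flag):
    return NormalityResult(variable="v", W=0.95, p_value=0.5 if flag else 0.01, normal=flag)


class TestShapiroWilk:
    def test_equally_spaced_triple_has_unit_w(self):
        res = shapiro_wilk(np.array([1.0, 2.0, 3.0]))
        assert res.W == pytest.approx(1.0, abs=1e-3)

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(12)
        res = shapiro_wilk(rng.exponential(size=50))
        assert res.p_value < 0.05 and not res.normal

    def test_gaussian_sample_passes(self):
        rng = np.random.default_rng(3)
        assert shapiro_wilk(rng.normal(size=50)).normal

    def test_small_and_constant_samples_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            shapiro_wilk(np.full(10, 3.3))


class TestGating:
    @pytest.mark.parametrize(
        "nx, ny, expected",
        [
            (True, True, "pearson"),
            (False, True, "spearman"),
            (True, False, "spearman"),
            (False, False, "spearman"),
        ],
    )
    def test_pearson_only_when_both_normal(self, nx, ny, expected):
        assert choose_method(normal_flag(nx), normal_flag(ny)) == expected


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        res = correlate(np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8]), "pearson")
        assert res.r == pytest.approx(1.0)

    def test_monotone_cubic_spearman(self):
        res = correlate(np.array([1.0, 2, 3, 4]), np.array([1.0, 8, 27, 64]), "spearman")
        assert res.r == pytest.approx(1.0)

    def test_fisher_ci_against_hand_evaluation(self):
        # r = 0.6, n = 19: tanh(atanh(0.6) +/- 1.96/sqrt(16))
        rng = np.random.default_rng(0)
        # construct a sample with exact r = 0.6 via Gram-Schmidt
        x = rng.standard_normal(19)
        e = rng.standard_normal(19)
        xc = (x - x.mean()) / x.std()
        ec = e - e.mean()
        ec -= (ec @ xc) / (xc @ xc) * xc
        ec /= ec.std()
        y = 0.6 * xc + np.sqrt(1 - 0.36) * ec
        res = correlate(xc, y, "pearson")
        assert res.r == pytest.approx(0.6, abs=1e-12)
        z = np.arctanh(0.6)
        crit = sps.norm.ppf(0.975)
        assert res.ci_lower == pytest.approx(np.tanh(z - crit / 4), abs=1e-9)
        assert res.ci_upper == pytest.approx(np.tanh(z + crit / 4), abs=1e-9)
        assert (round(res.ci_lower, 2), round(res.ci_upper, 2)) == (0.20, 0.83)

    def test_pairwise_complete_handling(self):
        x = np.array([1.0, 2, 3, 4, np.nan, 6])
        y = np.array([2.0, 4, 6, 8, 10, np.nan])
        res = correlate(x, y, "pearson")
        assert res.n == 4 and res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            correlate(np.ones(10), np.arange(10.0), "pearson")


class TestBattery:
    def test_full_cohort_yields_57_rows(self, config):
        cohort, _ = simulate_cohort(CohortSimParams(n=19, seed=2))
        rows = run_correlation_battery(cohort, config)
        assert len(rows) == 57
        assert {r.method for r in rows} <= {"pearson", "spearman"}

    def test_skewed_predictor_routes_through_spearman(self, config):
        cohort, truth = simulate_cohort(CohortSimParams(n=19, seed=14))
        ri = shapiro_wilk(cohort["response_inhibition"].to_numpy())
        rows = run_correlation_battery(cohort, config)
        ri_rows = [r for r in rows if r.predictor == "response_inhibition"]
        if not ri.normal:
            assert all(r.method == "spearman" for r in ri_rows)

    def test_strong_correlation_recovered_at_large_n(self, config):
        from pdgait.io_model import REGISTRY_COLUMNS

        cols = list(REGISTRY_COLUMNS)
        C = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        C.loc["working_memory", "dt_velocity"] = 0.65
        C.loc["dt_velocity", "working_memory"] = 0.65
        cohort, _ = simulate_cohort(CohortSimParams(n=2000, seed=7, correlation=C))
        rows = run_correlation_battery(cohort, config)
        row = next(r for r in rows if r.predictor == "working_memory"
                   and r.dependent == "dt_velocity")
        assert row.r == pytest.approx(0.65, abs=0.03)

    def test_constant_column_recorded_as_row_failure(self, config):
        cohort, _ = simulate_cohort(CohortSimParams(n=19, seed=2))
        cohort["dt_velocity"] = np.nan
        cohort.loc[cohort.index[:4], "dt_velocity"] = 1.0  # constant, n=4
        norm = {c: shapiro_wilk(cohort[c].to_numpy(), c)
                for c in cohort.columns if c != "dt_velocity"}
        norm["dt_velocity"] = normal_flag(True)
        rows = run_correlation_battery(cohort, config, norm)
        failed = [r for r in rows if r.dependent == "dt_velocity"]
        assert len(failed) == 3 and all(np.isnan(r.r) and r.note for r in failed)


class TestOLS:
    def test_exact_linear_relation(self):
        wm = np.array([3.0, 4, 5, 6, 7, 4.5])
        X = pd.DataFrame({"working_memory": wm})
        res = ols_fit(X, 2.0 * wm + 1.0)
        b = {t.term: t.B for t in res.terms}
        assert b["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert b["working_memory"] == pytest.approx(2.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["ri", "wm", "mr"])
        y = rng.normal(size=10)
        res = ols_fit(X, y)
        design = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose([t.B for t in res.terms], beta, atol=1e-10)

    def test_null_design_has_small_r2(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(2000, 3)), columns=["ri", "wm", "mr"])
        y = rng.normal(size=2000)
        res = ols_fit(X, y)
        assert res.r_squared < 0.01
        for t in res.terms[1:]:
            assert abs(t.B) < 4 * t.SE

    def test_rank_deficiency_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"wm": x, "wm_copy": 2 * x})
        with pytest.raises(ValidationError, match="wm"):
            ols_fit(X, x + 1.0)

    def test_ci_contains_coefficient(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["ri", "wm", "mr"])
        y = X["wm"].to_numpy() + rng.normal(size=30)
        res = ols_fit(X, y)
        for t in res.terms:
            assert t.ci_lower <= t.B <= t.ci_upper
        assert res.adj_r_squared <= res.r_squared


class TestVIF:
    def test_orthogonal_predictors_give_unity(self):
        # exactly orthogonal, centered columns
        X = pd.DataFrame({
            "a": [1.0, 1, -1, -1],
            "b": [1.0, -1, 1, -1],
            "c": [1.0, -1, -1, 1],
        })
        for res in vif(X):
            assert res.vif == pytest.approx(1.0, abs=1e-12)

    def test_half_correlated_pair(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        e = rng.standard_normal(50)
        xc = (x - x.mean()) / x.std()
        ec = e - e.mean()
        ec -= (ec @ xc) / (xc @ xc) * xc
        ec /= ec.std()
        y = 0.5 * xc + np.sqrt(0.75) * ec
        res = vif(pd.DataFrame({"a": xc, "b": y}))
        for r in res:
            assert r.vif == pytest.approx(1.0 / (1.0 - 0.25), abs=1e-9)

    def test_duplicated_column_reports_infinite(self):
        x = np.arange(8.0)
        res = vif(pd.DataFrame({"a": x, "b": x, "c": np.cos(x)}))
        assert np.isinf(res[0].vif) and np.isinf(res[1].vif)


class TestMANOVA:
    def test_single_response_wilks_equals_one_minus_r2(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=["ri", "wm", "mr"])
        y = X["wm"].to_numpy() * 0.7 + rng.normal(size=25)
        res = manova(X, pd.DataFrame({"y": y}))
        ols = ols_fit(pd.DataFrame({"wm": X["wm"]}), y)
        # per-term Wilks for wm in the full model vs the partial R2 identity:
        # compare overall fit via the single-predictor case instead
        res1 = manova(pd.DataFrame({"wm": X["wm"]}), pd.DataFrame({"y": y}))
        wilks = next(s for s in res1.terms[1].statistics if s.name == "wilks_lambda")
        assert wilks.value == pytest.approx(1.0 - ols.r_squared, abs=1e-10)

    def test_single_predictor_single_response_matches_ols_t_test(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=22)
        y = 0.5 * x + rng.normal(size=22)
        res = manova(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        ols = ols_fit(pd.DataFrame({"x": x}), y)
        slope_p = next(t for t in ols.terms if t.term == "x").p_value
        for stat in res.terms[1].statistics:
            assert stat.p_value == pytest.approx(slope_p, abs=1e-8)

    def test_one_df_terms_share_f_and_p_across_statistics(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(19, 3)), columns=["ri", "wm", "mr"])
        Y = pd.DataFrame(rng.normal(size=(19, 7)),
                         columns=[f"y{i}" for i in range(7)])
        res = manova(X, Y)
        for term in res.terms:
            fs = [s.F for s in term.statistics]
            ps = [s.p_value for s in term.statistics]
            np.testing.assert_allclose(fs, fs[0], atol=1e-8)
            np.testing.assert_allclose(ps, ps[0], atol=1e-8)

    def test_study_sized_dfs(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(19, 3)), columns=["ri", "wm", "mr"])
        Y = pd.DataFrame(rng.normal(size=(19, 7)), columns=[f"y{i}" for i in range(7)])
        res = manova(X, Y)
        wilks = res.terms[0].statistics[0]
        assert (wilks.df_num, wilks.df_den) == (7.0, 9.0)

    def test_matches_statsmodels_reference(self):
        from statsmodels.multivariate.manova import MANOVA as SMManova

        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        Y = pd.DataFrame(rng.normal(size=(30, 4)) + 0.8 * X[["a"]].to_numpy(),
                         columns=[f"y{i}" for i in range(4)])
        mine = manova(X, Y)
        ref = SMManova(Y.to_numpy(), np.column_stack([np.ones(30), X.to_numpy()]))
        contrasts = [(t, np.eye(4)[[j]]) for j, t in enumerate(["intercept", "a", "b", "c"])]
        res = ref.mv_test(contrasts)
        name_map = {
            "wilks_lambda": "Wilks' lambda",
            "pillai_trace": "Pillai's trace",
            "hotelling_lawley_trace": "Hotelling-Lawley trace",
            "roys_greatest_root": "Roy's greatest root",
        }
        for term in mine.terms:
            tbl = res.results[term.term]["stat"]
            for st in term.statistics:
                row = tbl.loc[name_map[st.name]]
                assert st.value == pytest.approx(row["Value"], abs=1e-8)
                assert st.F == pytest.approx(row["F Value"], abs=1e-6)
                assert st.p_value == pytest.approx(row["Pr > F"], abs=1e-8)

    def test_undersized_problem_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        Y = pd.DataFrame(rng.normal(size=(8, 7)), columns=[f"y{i}" for i in range(7)])
        with pytest.raises(ValidationError):
            manova(X, Y)


class TestFullBattery:
    def test_report_shape_for_study_cohort(self, config):
        cohort, _ = simulate_cohort(CohortSimParams(n=19, seed=3))
        rep = run_full_battery(cohort, config)
        assert len(rep.normality) == 22
        assert len(rep.correlations) == 57
        assert len(rep.ols) == 19
        assert [m.block for m in rep.manova] == ["tug", "walk_st", "walk_dt"]
        assert len(rep.vif) == 3
        assert all(v.vif < 2.7 for v in rep.vif)  # collinearity screen passes

    def test_deterministic_given_inputs(self, config):
        cohort, _ = simulate_cohort(CohortSimParams(n=19, seed=3))
        a = run_full_battery(cohort, config)
        b = run_full_battery(cohort.copy(), config)
        assert [r.r for r in a.correlations] == [r.r for r in b.correlations]
        assert [r.r_squared for r in a.ols] == [r.r_squared for r in b.ols]

    def test_all_missing_column_dropped(self, config):
        cohort, _ = simulate_cohort(CohortSimParams(n=19, seed=3))
        cohort["dt_velocity"] = np.nan
        rep = run_full_battery(cohort, config)
        assert len(rep.normality) == 21
        assert len(rep.correlations) == 54
        assert all(r.dependent != "dt_velocity" for r in rep.correlations)
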