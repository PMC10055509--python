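import numpy as np
import pandas as pd
import pytest

import neurosgm as ns
from neurosgm.cohort import PARAM_REPORT_COLUMNS, cohort_mean_parameters
from neurosgm.fitting import _subject_seed


class TestCohensD:
    def test_identical_groups_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ns.cohens_d(x, x) == 0.0

    def test_hand_computed_value(self):
        # means 1 and 0; sample variances 2 and 2 -> pooled SD sqrt(2)
        d = ns.cohens_d([0.0, 2.0], [-1.0, 1.0])
        assert d == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(1.0, size=25)
        assert ns.cohens_d(x + 7.0, y + 7.0) == pytest.approx(
            ns.cohens_d(x, y), abs=1e-12)

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(RuntimeWarning, match="pooled SD"):
            assert np.isnan(ns.cohens_d([1.0, 1.0], [2.0, 2.0]))


class TestKsGroupTest:
    def test_identical_multisets_have_zero_statistic(self):
        x = np.arange(10.0)
        stat, p = ns.ks_group_test(x, x)
        assert stat == 0.0

    def test_shifted_uniforms_detected(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 500)
        y = rng.uniform(0.5, 1.5, 500)
        stat, p = ns.ks_group_test(x, y)
        assert p < 1e-3
        assert 0.0 <= stat <= 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ns.ks_group_test([1, 2, 3], [1, 2, 3, 4, 5])


def _toy_table(outcome, group, age, mmse=None):
    n = len(outcome)
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "group": group,
        "age": age,
        "tau_G_ms": outcome,
        "mmse": mmse if mmse is not None else [np.nan] * n,
    })


class TestAdjustedGroupCompare:
    def test_identical_group_values_give_null(self):
        # each patient row duplicates a control row exactly, so the group
        # coefficient is 0 by symmetry (age deliberately not collinear
        # with the outcome)
        vals = [4.0, 5.0, 6.0] * 2
        table = _toy_table(vals, ["control"] * 3 + ["AD"] * 3,
                           [70.0, 60.0, 65.0] * 2)
        row = ns.adjusted_group_compare(table, "tau_G_ms")
        assert row.t_stat == pytest.approx(0.0, abs=1e-10)
        assert row.cohens_d == pytest.approx(0.0, abs=1e-12)
        assert row.p_adjusted == 1.0

    def test_orthogonal_age_leaves_means_unchanged(self):
        # age is balanced across groups and uncorrelated with the outcome
        table = _toy_table([1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                           ["control"] * 3 + ["AD"] * 3,
                           [60.0, 65.0, 70.0, 60.0, 65.0, 70.0])
        row = ns.adjusted_group_compare(table, "tau_G_ms")
        assert row.mean_control == pytest.approx(1.0, abs=1e-10)
        assert row.mean_ad == pytest.approx(2.0, abs=1e-10)

    def test_coefficients_match_normal_equations(self):
        # independent oracle: solve (X^T X) beta = X^T y explicitly
        outcome = [3.1, 4.0, 2.7, 5.5, 6.1, 5.0]
        group = ["control"] * 3 + ["AD"] * 3
        age = [61.0, 64.0, 72.0, 58.0, 66.0, 70.0]
        table = _toy_table(outcome, group, age)
        row = ns.adjusted_group_compare(table, "tau_G_ms")
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1], age])
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(outcome))
        age_bar = np.mean(age)
        assert row.mean_control == pytest.approx(beta[0] + beta[2] * age_bar)
        assert row.mean_ad == pytest.approx(
            beta[0] + beta[1] + beta[2] * age_bar)

    def test_constant_age_falls_back_to_unadjusted(self):
        table = _toy_table([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                           ["control"] * 3 + ["AD"] * 3, [65.0] * 6)
        with pytest.warns(RuntimeWarning, match="constant"):
            row = ns.adjusted_group_compare(table, "tau_G_ms")
        assert not row.age_adjusted

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(1)
        table = _toy_table(rng.normal(size=30),
                           ["control"] * 15 + ["AD"] * 15,
                           rng.normal(65, 8, 30))
        row = ns.adjusted_group_compare(table, "tau_G_ms", m_tests=7)
        assert row.p_adjusted >= row.p_raw
        assert row.p_adjusted <= 1.0
        assert row.ci_control[0] <= row.mean_control <= row.ci_control[1]


class TestRegressCognition:
    def test_exact_linear_outcome_fits_perfectly(self):
        rng = np.random.default_rng(4)
        tau = rng.uniform(5, 30, 20)
        table = _toy_table(tau, ["AD"] * 20, rng.normal(65, 5, 20),
                           mmse=30.0 - 0.5 * tau)
        rep = ns.regress_cognition(table, "mmse", ["tau_G_ms"])
        assert rep["model_r"] == pytest.approx(1.0, abs=1e-8)
        assert rep["coefficients"]["tau_G_ms"]["slope"] == pytest.approx(-0.5)

    def test_coefficients_match_normal_equations(self):
        tau = [6.0, 9.0, 14.0, 21.0, 27.0]
        mmse = [28.0, 25.0, 26.0, 20.0, 18.0]
        table = _toy_table(tau, ["AD"] * 5, [65.0] * 5, mmse=mmse)
        rep = ns.regress_cognition(table, "mmse", ["tau_G_ms"])
        X = np.column_stack([np.ones(5), tau])
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(mmse))
        assert rep["coefficients"]["tau_G_ms"]["slope"] == pytest.approx(
            beta[1], abs=1e-10)

    def test_underdetermined_model_rejected(self):
        table = _toy_table([6.0, 9.0], ["AD"] * 2, [65.0, 70.0],
                           mmse=[28.0, 25.0])
        with pytest.raises(ValueError, match="predictors"):
            ns.regress_cognition(table, "mmse", ["tau_G_ms"])


def _feature_table(n_per_group, rng, separation=0.0, informative="f0"):
    cols = ["f0", "f1", "f2"]
    data = {c: rng.standard_normal(2 * n_per_group) for c in cols}
    group = ["control"] * n_per_group + ["AD"] * n_per_group
    data[informative][n_per_group:] += separation
    df = pd.DataFrame(data)
    df["group"] = group
    df["age"] = rng.normal(65, 8, 2 * n_per_group)
    return df


class TestClassifyGroups:
    def test_separable_groups_classified_reliably(self):
        rng = np.random.default_rng(0)
        df = _feature_table(30, rng, separation=3.0)
        report = ns.classify_groups(
            df, ["f0", "f1", "f2"],
            ns.ClassifyConfig(repeats=2, n_estimators=25,
                              max_depth_grid=(None, 3), seed=1))
        assert report.auroc_mean >= 0.9
        assert report.importance_order()[0] == "f0"
        assert sum(report.feature_importances.values()) == pytest.approx(1.0)

    def test_metrics_bounded_and_confusion_pooled(self):
        rng = np.random.default_rng(3)
        df = _feature_table(20, rng, separation=1.0)
        cfg = ns.ClassifyConfig(repeats=1, n_estimators=15,
                                max_depth_grid=(None, 2), seed=5)
        report = ns.classify_groups(df, ["f0", "f1"], cfg)
        for v in (report.auroc_mean, report.accuracy, report.precision,
                  report.recall, report.f1):
            assert 0.0 <= v <= 1.0
        assert report.confusion.sum() == cfg.repeats * len(df)

    def test_feature_column_order_invariance(self):
        # trees are order-free in principle; with a fixed seed the random
        # feature subsampling ties break differently, so the check is
        # statistical, not bitwise
        rng = np.random.default_rng(7)
        df = _feature_table(20, rng, separation=2.0)
        cfg = ns.ClassifyConfig(repeats=2, n_estimators=25,
                                max_depth_grid=(None, 3), seed=9)
        a = ns.classify_groups(df, ["f0", "f1", "f2"], cfg)
        b = ns.classify_groups(df, ["f2", "f0", "f1"], cfg)
        assert a.auroc_mean == pytest.approx(b.auroc_mean, abs=0.08)
        assert a.importance_order()[0] == b.importance_order()[0] == "f0"

    def test_monotone_feature_rescaling_invariance(self):
        rng = np.random.default_rng(11)
        df = _feature_table(20, rng, separation=2.0)
        cfg = ns.ClassifyConfig(repeats=2, n_estimators=25,
                                max_depth_grid=(None, 3), seed=13)
        a = ns.classify_groups(df, ["f0", "f1"], cfg)
        df2 = df.copy()
        df2["f0"] = np.exp(df2["f0"])  # strictly monotone transform
        b = ns.classify_groups(df2, ["f0", "f1"], cfg)
        assert a.auroc_mean == pytest.approx(b.auroc_mean, abs=0.08)


class TestParameterAblation:
    @pytest.fixture(scope="class")
    def ablation_setup(self, coarse_grid):
        graph = ns.synth_connectome(6, seed=17)
        base = ns.SGMParameters()
        subjects = {}
        truths = {}
        for i, tg in enumerate((0.008, 0.022)):
            p = base.replace(tau_G=tg)
            truths[f"s{i}"] = p
            subjects[f"s{i}"] = ns.synth_subject_spectrum(
                p, graph, coarse_grid, noise_db=0.5, seed=30 + i)
        mean_params = base.replace(tau_G=0.015)
        return graph, subjects, mean_params

    def test_stage_structure_and_final_stage_matches_full_fit(
            self, ablation_setup):
        graph, subjects, mean_params = ablation_setup
        order = ["tau_G", "tau_e", "tau_i", "g_ei", "g_ii", "alpha", "speed"]
        config = ns.FitConfig(maxiter=2, seed=19)
        result = ns.parameter_ablation(subjects, graph, mean_params, order,
                                       config)
        assert len(result.stages) == 8
        assert result.stages[0][0] == ()
        assert result.stages[-1][0] == tuple(order)
        # the all-free stage equals an independent full fit with shared seeds
        sid = sorted(subjects)[0]
        sub_cfg = ns.FitConfig(maxiter=2, seed=_subject_seed(19, sid))
        full = ns.fit_subject(subjects[sid], graph, sub_cfg)
        row = result.per_subject
        final = row[(row["id"] == sid) & (row["n_free"] == 7)].iloc[0]
        assert final["objective"] == pytest.approx(full.objective, abs=1e-12)

    def test_incomplete_importance_order_rejected(self, ablation_setup):
        graph, subjects, mean_params = ablation_setup
        with pytest.raises(ValueError, match="seven"):
            ns.parameter_ablation(subjects, graph, mean_params,
                                  ["tau_G"], ns.FitConfig(maxiter=2))


def test_cohort_mean_parameters_converts_units():
    fits = pd.DataFrame({
        "tau_G_ms": [10.0, 20.0], "tau_e_ms": [10.0, 14.0],
        "tau_i_ms": [8.0, 12.0], "g_ei": [0.2, 0.4], "g_ii": [0.5, 0.7],
        "alpha": [0.8, 1.0], "speed": [8.0, 12.0],
    })
    p = cohort_mean_parameters(fits)
    assert p.tau_G == pytest.approx(0.015)
    assert p.speed == pytest.approx(10.0)
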