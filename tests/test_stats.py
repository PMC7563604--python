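"""Rank tests, ROC analysis, DeLong comparison, and the prediction model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cystexture as ct
from cystexture.stats import holm_adjust, truncate2


class TestMannWhitney:
    def test_tiny_exact_case(self):
        res = ct.mann_whitney_u([1, 2], [3, 4])
        assert res.u == 0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_identical_multisets_are_symmetric(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        res = ct.mann_whitney_u(x, list(x))
        assert res.u == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == 1.0

    def test_all_values_identical_degenerate(self):
        res = ct.mann_whitney_u([5.0] * 6, [5.0] * 4)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(25):
            x = rng.standard_normal(rng.integers(3, 9))
            y = rng.standard_normal(rng.integers(3, 9))
            res = ct.mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.u == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_agrees_with_scipy_asymptotic(self, rng):
        for _ in range(25):
            x = rng.standard_normal(20)
            y = rng.standard_normal(15) + 0.5
            res = ct.mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert res.method == "normal-approx"
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_force_normal_approximation(self):
        res = ct.mann_whitney_u([1, 2, 2, 3], [2, 4, 5])
        assert res.method == "normal-approx"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ct.mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = ct.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.h == pytest.approx(16 * 12 / 42, rel=1e-12)  # 4.5714...

    def test_identical_groups(self):
        res = ct.kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res.h == 0.0 and res.p_value == 1.0

    def test_two_group_case_tracks_mann_whitney(self, rng):
        diffs = []
        for _ in range(100):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10) + rng.uniform(-1, 1)
            p_kw = ct.kruskal_wallis([x, y]).p_value
            p_mw = ct.mann_whitney_u(x, y).p_value
            diffs.append(abs(p_kw - p_mw))
        assert max(diffs) < 0.05  # chi-square vs exact/continuity differences only

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            ct.kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            ct.kruskal_wallis([[1.0], []])


class TestRocAnalyze:
    def test_perfect_separation(self):
        res = ct.roc_analyze([1, 2, 3, 4, 5], ["b", "b", "b", "m", "m"], positive="m")
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.direction == "greater"
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_interleaved_enumerated_case(self):
        # benign {1,3}, malignant {2,4}: AUC = 3/4; J = 0.5 at two cutoffs;
        # the higher-specificity tie-break selects the cutoff between 3 and 4
        res = ct.roc_analyze([1, 3, 2, 4], ["b", "b", "m", "m"], positive="m")
        assert res.auc == pytest.approx(0.75)
        assert res.youden_j == pytest.approx(0.5)
        assert res.cutoff_value == pytest.approx(3.5)
        assert res.sensitivity == pytest.approx(0.5)
        assert res.specificity == pytest.approx(1.0)

    def test_orientation_flips_low_auc_marker(self):
        # marker lower in positives: direction less_equal, AUC reported >= 0.5
        res = ct.roc_analyze([5, 4, 3, 1, 2], ["b", "b", "b", "m", "m"], positive="m")
        assert res.direction == "less_equal"
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_clopper_pearson_8_of_13(self):
        lo, hi = ct.clopper_pearson(8, 13)
        assert round(lo * 100, 1) == 31.6
        assert round(hi * 100, 1) == 86.1

    def test_clopper_pearson_edge_counts(self):
        lo, hi = ct.clopper_pearson(0, 10)
        assert lo == 0.0 and 0 < hi < 0.35
        lo, hi = ct.clopper_pearson(10, 10)
        assert hi == 1.0 and lo > 0.65

    def test_auc_u_identity_and_j_consistency(self, rng):
        for _ in range(100):
            n1, n0 = rng.integers(4, 15), rng.integers(4, 15)
            scores = np.concatenate([rng.standard_normal(n0), rng.standard_normal(n1) + 1])
            labels = np.array([0] * n0 + [1] * n1)
            res = ct.roc_analyze(scores, labels)
            u = ct.mann_whitney_u(scores[labels == 1], scores[labels == 0]).u
            auc_u = u / (n1 * n0)
            assert res.auc == pytest.approx(max(auc_u, 1 - auc_u), abs=1e-12)
            assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1, abs=1e-12)
            assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ct.roc_analyze([1, 2, 3], [1, 1, 1])

    def test_truncation_helper(self):
        assert truncate2(0.4821) == 0.48
        assert truncate2(0.7795) == 0.77
        assert truncate2(0.6462) == 0.64


class TestDeLong:
    def test_identical_curves(self, rng):
        s = rng.standard_normal(20)
        labels = np.array([0, 1] * 10)
        res = ct.delong_compare(s, s.copy(), labels)
        assert res.auc_difference == 0.0
        assert res.p_value == 1.0

    def test_antisymmetry(self, rng):
        labels = np.array([0] * 12 + [1] * 10)
        a = rng.standard_normal(22) + labels
        b = 0.6 * a + rng.standard_normal(22)
        fwd = ct.delong_compare(a, b, labels)
        rev = ct.delong_compare(b, a, labels)
        assert fwd.auc_difference == pytest.approx(-rev.auc_difference)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.z_statistic == pytest.approx(-rev.z_statistic)

    def test_matches_pROC_reference(self):
        """z, p and the AUC CI agree with R's pROC DeLong implementation."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(2)
        n, n_pos = 30, 13
        labels = np.zeros(n, dtype=int)
        labels[:n_pos] = 1
        z = rng.standard_normal(n) + labels
        a = z + 0.8 * rng.standard_normal(n)
        b = z + 0.8 * rng.standard_normal(n)
        res = ct.delong_compare(a, b, labels, positive=1)
        roc = ct.roc_analyze(a, labels, positive=1)
        rcode = (
            'suppressMessages(library(pROC));'
            f'y<-c({",".join(map(str, labels))});'
            f'a<-c({",".join("%.12f" % v for v in a)});'
            f'b<-c({",".join("%.12f" % v for v in b)});'
            'ra<-roc(y,a,quiet=TRUE,direction="<");rb<-roc(y,b,quiet=TRUE,direction="<");'
            't<-roc.test(ra,rb,method="delong",paired=TRUE);ci<-ci.auc(ra,method="delong");'
            'cat(sprintf("%.10f %.10f %.10f %.10f %.10f",t$statistic,t$p.value,'
            'auc(ra),ci[1],ci[3]))'
        )
        proc = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"pROC unavailable: {proc.stderr[-200:]}")
        z_r, p_r, auc_r, lo_r, hi_r = map(float, proc.stdout.split())
        assert res.z_statistic == pytest.approx(z_r, abs=1e-8)
        assert res.p_value == pytest.approx(p_r, abs=1e-8)
        assert roc.auc == pytest.approx(auc_r, abs=1e-10)
        assert roc.auc_ci[0] == pytest.approx(lo_r, abs=1e-8)
        assert roc.auc_ci[1] == pytest.approx(hi_r, abs=1e-8)

    def test_length_mismatch_and_single_class(self):
        with pytest.raises(ValueError):
            ct.delong_compare([1, 2], [1, 2, 3], [0, 1, 1])
        with pytest.raises(ValueError):
            ct.delong_compare([1, 2], [2, 1], [1, 1])


class TestLinearProbabilityModel:
    def test_hand_computed_single_predictor(self):
        # Sxy = 2, Sxx = 5, Syy = 1 -> slope 0.4, intercept -0.5, R2 = 0.8
        model = ct.LinearProbabilityModel().fit(
            np.array([[1.0], [2.0], [3.0], [4.0]]), np.array([0, 0, 1, 1])
        )
        assert model.coef_[0] == pytest.approx(0.4)
        assert model.intercept_ == pytest.approx(-0.5)
        assert model.r_squared_ == pytest.approx(0.8)
        assert model.multiple_correlation_ == pytest.approx(np.sqrt(0.8))
        assert model.vif_[0] == 1.0
        np.testing.assert_allclose(
            model.predict(np.array([[1.0], [4.0]])), [-0.1, 1.1], atol=1e-12
        )

    def test_orthogonal_predictors_have_unit_vif(self):
        x1 = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        x2 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        y = np.array([1, 0, 1, 0, 1, 0, 0, 0])
        model = ct.LinearProbabilityModel().fit(np.column_stack([x1, x2]), y)
        np.testing.assert_allclose(model.vif_, [1.0, 1.0], atol=1e-9)

    def test_exact_collinearity_names_column(self, rng):
        x1 = rng.standard_normal(12)
        X = pd.DataFrame({"alpha": x1, "beta": 2.0 * x1})
        with pytest.raises(ValueError, match="beta"):
            ct.LinearProbabilityModel().fit(X, rng.integers(0, 2, 12))

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="n >"):
            ct.LinearProbabilityModel().fit(np.ones((4, 2)), [0, 1, 0, 1])

    def test_string_labels_and_fitted_scores(self, rng):
        X = pd.DataFrame({"f": rng.standard_normal(15)})
        y = np.array(["benign"] * 8 + ["malignant"] * 7)
        model = ct.fit_prediction_model(X, ["f"], y)
        np.testing.assert_allclose(model.fitted_scores_, model.predict(X), atol=1e-12)
        assert 0.0 <= model.r_squared_ <= 1.0
        assert model.vif_[0] >= 1.0


def _toy_table(rng, n_per=14, label_feature=False):
    groups = ["benign"] * n_per + ["malignant"] * n_per
    subtypes = (
        ["functional_cyst"] * (n_per // 2) + ["serous_cystadenoma"] * (n_per - n_per // 2)
        + ["clear_cell_carcinoma"] * (n_per // 2) + ["serous_carcinoma"] * (n_per - n_per // 2)
    )
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(2 * n_per)],
        "group": groups,
        "subtype": subtypes,
        "noise1": rng.standard_normal(2 * n_per),
        "noise2": rng.standard_normal(2 * n_per),
    })
    if label_feature:
        df["oracle"] = (np.array(groups) == "malignant") + 0.01 * rng.standard_normal(2 * n_per)
    return df


class TestRunFullAnalysis:
    def test_structural_counts_on_default_cohort(self, default_cohort_table):
        report = ct.run_full_analysis(default_cohort_table)
        assert report["n_subjects"] == 28
        assert report["n_benign"] == 15 and report["n_malignant"] == 13
        assert len(report["kruskal_wallis"]) == 24
        assert len(report["mann_whitney"]) == 24
        assert set(report["group_medians"]) == set(report["significant_features"])
        assert report["schema_version"]

    def test_label_like_feature_dominates(self, rng):
        df = _toy_table(rng, label_feature=True)
        report = ct.run_full_analysis(df)
        assert "oracle" in report["significant_features"]
        assert report["roc"]["oracle"]["auc"] == 1.0
        assert "oracle" in report["prediction_model"]["predictors"]
        assert "prediction_model" in report["roc"]

    def test_empty_screen_skips_model_gracefully(self, rng):
        # alpha below the smallest p the screen can produce at this n
        report = ct.run_full_analysis(_toy_table(rng), alpha=1e-8)
        assert report["significant_features"] == []
        assert report["prediction_model"] is None
        assert report["roc"] == {} and report["delong"] == {}
        assert "note" in report

    def test_alpha_boundary_is_strict(self):
        # 3 vs 3 perfectly separated: exact two-sided p = 2/20 = 0.1 exactly;
        # the screen requires p strictly below alpha
        df = pd.DataFrame({
            "subject_id": list("abcdef"),
            "group": ["benign"] * 3 + ["malignant"] * 3,
            "subtype": ["functional_cyst"] * 3 + ["serous_carcinoma"] * 3,
            "sep": [1.0, 2.0, 3.0, 11.0, 12.0, 13.0],
        })
        at_boundary = ct.run_full_analysis(df, alpha=0.1)
        assert at_boundary["mann_whitney"]["sep"]["p"] == pytest.approx(0.1)
        assert at_boundary["significant_features"] == []
        above = ct.run_full_analysis(df, alpha=0.11)
        assert above["significant_features"] == ["sep"]

    def test_holm_adjustment_screen(self, rng):
        df = _toy_table(rng, label_feature=True)
        report = ct.run_full_analysis(df, holm=True)
        assert all("p_holm" in v for v in report["mann_whitney"].values())
        assert "oracle" in report["significant_features"]

    def test_delong_table_covers_all_pairs(self, rng):
        df = _toy_table(rng, label_feature=True)
        df["oracle2"] = df["oracle"] + 0.05 * rng.standard_normal(len(df))
        report = ct.run_full_analysis(df)
        k = len(report["significant_features"]) + 1  # + prediction model
        assert len(report["delong"]) == k * (k - 1) // 2


def test_holm_adjust_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(0, 1, 20)
    ref = multipletests(p, method="holm")[1]
    np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)
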