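"""SVM decision function, cross-validation, ROC and contingency statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from curvecad.balance import LabeledTable
from curvecad.model_eval import (
    SvmModel,
    chi_square_2x2,
    decision_value,
    decision_values,
    feature_change,
    kfold_cv,
    malignance_rate,
    predict,
    roc_auc,
    train_svm,
)


def gaussian_clouds(rng, n_per_class=100, d=2, sep=10.0):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n_per_class, d)),
        rng.normal(sep, 1.0, size=(n_per_class, d)),
    ])
    y = np.array(["benign"] * n_per_class + ["malignant"] * n_per_class)
    return X, y


def brute_force_decision(model, x):
    z = (np.asarray(x, float) - model.scale_mean) / model.scale_sd
    total = model.bias
    for alpha, sv in zip(model.alphas, model.support_vectors):
        total += alpha * np.exp(-model.gamma * float(((sv - z) ** 2).sum()))
    return total


class TestTrainSvm:
    def test_separable_clouds_fit_perfectly(self, rng):
        X, y = gaussian_clouds(rng)
        model = train_svm((X, y))
        assert (predict(model, X) == y).mean() >= 0.99

    def test_duplicating_rows_preserves_decision_function(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=50)
        m1 = train_svm((X, y), C=10.0, gamma=0.5)
        m2 = train_svm((np.vstack([X, X]), np.concatenate([y, y])), C=10.0, gamma=0.5)
        probe = rng.normal(5.0, 4.0, size=(40, 2))
        np.testing.assert_allclose(
            decision_values(m1, probe), decision_values(m2, probe), atol=1e-6
        )

    def test_flipping_labels_negates_decisions(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=50)
        flipped = np.where(y == "benign", "malignant", "benign")
        m1 = train_svm((X, y), C=2.0, gamma=0.3)
        m2 = train_svm((X, flipped), C=2.0, gamma=0.3)
        probe = rng.normal(5.0, 4.0, size=(40, 2))
        np.testing.assert_allclose(
            decision_values(m1, probe), -decision_values(m2, probe), atol=1e-6
        )

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            train_svm((X, ["benign"] * 10))


class TestDecisionFunction:
    def test_support_vectors_sit_on_the_margin(self):
        # hard-margin 4-point toy problem: all points are support vectors
        X = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
        y = np.array(["benign", "benign", "malignant", "malignant"])
        model = train_svm((X, y), C=1e6, gamma=0.5)
        for x, lab in zip(X, y):
            f = decision_value(model, x)
            assert abs(f) >= 1.0 - 1e-6
            assert (f > 0) == (lab == "malignant")

    def test_symmetric_two_point_problem_has_zero_bias(self):
        X = np.array([[1.0, 2.0], [-1.0, -2.0]])
        y = np.array(["malignant", "benign"])
        model = train_svm((X, y), C=1e6, gamma=1.0)
        assert decision_value(model, np.zeros(2)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_kernel_sum(self, rng):
        for _ in range(5):
            s, d = int(rng.integers(2, 8)), int(rng.integers(2, 5))
            model = SvmModel(
                support_vectors=rng.normal(size=(s, d)),
                alphas=rng.normal(size=s),
                bias=float(rng.normal()),
                gamma=float(rng.uniform(0.1, 2.0)),
                C=1.0,
                scale_mean=rng.normal(size=d),
                scale_sd=rng.uniform(0.5, 2.0, size=d),
                classes=["benign", "malignant"],
            )
            x = rng.normal(size=d)
            assert decision_value(model, x) == pytest.approx(
                brute_force_decision(model, x), abs=1e-10
            )

    def test_matches_sklearn_decision_function(self, rng):
        from sklearn.svm import SVC

        X, y = gaussian_clouds(rng, n_per_class=40, sep=3.0)
        model = train_svm((X, y), C=1.5, gamma=0.2)
        Z = (X - model.scale_mean) / model.scale_sd
        clf = SVC(C=1.5, kernel="rbf", gamma=0.2, tol=1e-7).fit(Z, y)
        np.testing.assert_allclose(
            decision_values(model, X), clf.decision_function(Z), atol=1e-8
        )

    def test_dimension_mismatch_rejected(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=20)
        model = train_svm((X, y))
        with pytest.raises(ValueError):
            decision_value(model, np.zeros(5))

    def test_model_json_round_trip(self, rng, tmp_path):
        X, y = gaussian_clouds(rng, n_per_class=30)
        model = train_svm((X, y))
        model.to_json(tmp_path / "m.json")
        loaded = SvmModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(
            decision_values(model, X), decision_values(loaded, X)
        )


class TestKfoldCv:
    def test_separable_data_scores_high(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=60)
        res = kfold_cv((X, y), k=5, grouping="roi", seed=0)
        assert res["mean_accuracy"] >= 0.95

    def test_leave_one_out_fold_arithmetic(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=5)
        res = kfold_cv((X, y), k=10, grouping="roi", seed=0)
        assert len(res["fold_accuracies"]) == 10
        counts = np.bincount(res["fold_assignment"])
        assert (counts == 1).all()

    def test_same_seed_same_folds(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=30)
        a = kfold_cv((X, y), k=5, grouping="roi", seed=3)
        b = kfold_cv((X, y), k=5, grouping="roi", seed=3)
        np.testing.assert_array_equal(a["fold_assignment"], b["fold_assignment"])

    def test_patient_grouping_keeps_rois_together(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=30)
        groups = np.repeat(np.arange(20), 3)  # 3 ROIs per patient
        res = kfold_cv((X, y), k=4, grouping="patient", groups=groups, seed=1)
        for g in np.unique(groups):
            assert len(set(res["fold_assignment"][groups == g])) == 1

    def test_k_larger_than_n_rejected(self, rng):
        X, y = gaussian_clouds(rng, n_per_class=3)
        with pytest.raises(ValueError):
            kfold_cv((X, y), k=7, grouping="roi")


class TestMalignanceRate:
    @pytest.mark.parametrize(
        "preds,expected",
        [
            (["malignant"] * 7 + ["benign"] * 3, 0.7),
            (["benign"] * 4, 0.0),
            (["malignant"] * 5, 1.0),
        ],
    )
    def test_fraction_of_malignant_calls(self, preds, expected):
        assert malignance_rate(preds) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            malignance_rate([])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], ["malignant", "malignant", "benign", "benign"])
        assert res["auc"] == pytest.approx(1.0)

    def test_three_of_four_concordant_pairs(self):
        res = roc_auc([0.8, 0.4, 0.6, 0.2], ["malignant", "malignant", "benign", "benign"])
        assert res["auc"] == pytest.approx(0.75)

    def test_identical_scores_give_half(self):
        res = roc_auc([0.5, 0.5, 0.5, 0.5], ["malignant", "malignant", "benign", "benign"])
        assert res["auc"] == pytest.approx(0.5)

    def test_roc_is_monotone(self, rng):
        scores = rng.uniform(size=30)
        labels = np.where(rng.uniform(size=30) < 0.5, "malignant", "benign")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "malignant", "benign"
        res = roc_auc(scores, labels)
        fprs = [p[0] for p in res["roc"]]
        tprs = [p[1] for p in res["roc"]]
        assert all(a <= b + 1e-12 for a, b in zip(fprs, fprs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tprs, tprs[1:]))

    def test_auc_equals_mann_whitney_u(self, rng):
        """Trapezoid AUC == U / (n+ n-) including ties, on random score sets."""
        for _ in range(50):
            n_pos, n_neg = int(rng.integers(3, 20)), int(rng.integers(3, 20))
            # discrete scores force ties across and within classes
            pos = rng.integers(0, 6, size=n_pos) / 5.0
            neg = rng.integers(0, 6, size=n_neg) / 5.0
            res = roc_auc(
                np.concatenate([pos, neg]),
                ["malignant"] * n_pos + ["benign"] * n_neg,
            )
            u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert res["auc"] == pytest.approx(u / (n_pos * n_neg), abs=1e-10)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.7], ["malignant", "malignant"])


class TestChiSquare:
    def test_smoking_contingency_statistic(self):
        stat, df, p = chi_square_2x2([[64, 42], [107, 105]])
        assert stat == pytest.approx(2.79, abs=0.01)
        assert df == 1
        assert p == pytest.approx(0.0949, abs=0.001)

    def test_sex_contingency_statistic(self):
        stat, _, p = chi_square_2x2([[48, 58], [85, 127]])
        assert stat == pytest.approx(0.78, abs=0.01)
        assert p == pytest.approx(0.3766, abs=0.001)

    def test_independent_table_is_zero(self):
        stat, _, p = chi_square_2x2([[50, 50], [50, 50]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [10, 20]])

    def test_agrees_with_permutation_null(self, rng):
        """Asymptotic p close to a 10^4-draw permutation estimate."""
        table = np.array([[60, 80], [95, 70]], dtype=float)
        stat, _, p_asym = chi_square_2x2(table)
        row, col = table.sum(axis=1), table.sum(axis=0)
        n = table.sum()
        a = rng.hypergeometric(row[0], row[1], col[0], size=10_000)
        # reconstruct each permuted table's chi-square statistic
        b = col[0] - a
        c = row[0] - a
        d = row[1] - b
        expected = np.outer(row, col) / n
        stats_perm = (
            (a - expected[0, 0]) ** 2 / expected[0, 0]
            + (c - expected[0, 1]) ** 2 / expected[0, 1]
            + (b - expected[1, 0]) ** 2 / expected[1, 0]
            + (d - expected[1, 1]) ** 2 / expected[1, 1]
        )
        p_perm = float((stats_perm >= stat - 1e-12).mean())
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 10_000)
        assert abs(p_asym - p_perm) < mc_err + 0.01


class TestFeatureChange:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "scan_index", "label", "s1_w0_stddev"]
        )

    def test_identical_scans_give_zero_delta(self):
        df = self.frame([("p1", 0, "benign", 2.0), ("p1", 1, "benign", 2.0)])
        per_patient, _ = feature_change(df)
        assert per_patient["delta"].iloc[0] == 0.0

    def test_delta_is_last_minus_first_of_scan_means(self):
        df = self.frame([
            ("p1", 0, "benign", 1.0), ("p1", 0, "benign", 3.0),  # scan mean 2
            ("p1", 1, "benign", 5.0),
        ])
        per_patient, summary = feature_change(df)
        assert per_patient["delta"].iloc[0] == pytest.approx(3.0)
        assert summary.set_index("label").loc["benign", "mean_delta"] == pytest.approx(3.0)

    def test_single_scan_patient_excluded_with_warning(self, caplog):
        df = self.frame([
            ("p1", 0, "benign", 1.0), ("p1", 1, "benign", 2.0),
            ("p2", 0, "malignant", 4.0),
        ])
        with caplog.at_level("WARNING", logger="curvecad.model_eval"):
            per_patient, _ = feature_change(df)
        assert list(per_patient["patient_id"]) == ["p1"]
        assert any("single scan" in rec.message for rec in caplog.records)

    def test_all_single_scan_rejected(self):
        df = self.frame([("p1", 0, "benign", 1.0)])
        with pytest.raises(ValueError):
            feature_change(df)
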