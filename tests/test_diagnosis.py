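import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thyrotype.core_io import ExpressionMatrix, log2_transform, rng_for
from thyrotype.diagnosis import (
    differential_expression,
    evaluate_classifiers,
    rfe_signature,
    stratified_split,
)


def _labelled_matrix(values: np.ndarray, labels: list[str]):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    m = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    return m, pd.Series(labels, index=samples)


class TestDifferentialExpression:
    def test_null_false_positive_rate_calibrated(self):
        rng = rng_for(22, "test_de_null")
        values = rng.uniform(1, 10, size=(500, 40))
        m, labels = _labelled_matrix(values, ["PTC"] * 20 + ["BTN"] * 20)
        res = differential_expression(m, labels)
        fpr = float((res.p_value < 0.05).mean())
        assert 0.03 <= fpr <= 0.07

    def test_known_fold_change_and_minimal_p(self):
        values = np.vstack([[8.0] * 5 + [2.0] * 5])
        m, labels = _labelled_matrix(values, ["PTC"] * 5 + ["BTN"] * 5)
        res = differential_expression(m, labels)
        assert res.loc["g0", "log2fc"] == pytest.approx(np.log2(9.0 / 3.0))
        # smallest attainable two-sided p for 5 vs 5 complete separation
        exact = stats.mannwhitneyu(
            values[0, :5], values[0, 5:], alternative="two-sided", method="exact"
        ).pvalue
        assert res.loc["g0", "p_value"] <= 4 * exact  # normal approx in same regime
        assert res.loc["g0", "changed"]

    def test_constant_gene_not_flagged(self):
        values = np.vstack([np.full(12, 3.0), np.r_[np.full(6, 9.0), np.full(6, 1.0)]])
        m, labels = _labelled_matrix(values, ["PTC"] * 6 + ["BTN"] * 6)
        res = differential_expression(m, labels)
        assert not res.loc["g0", "changed"]
        assert res.loc["g0", "p_value"] == 1.0

    def test_direction_consistent_with_fold_change(self, diagnosis7):
        expr, labels, _ = diagnosis7
        res = differential_expression(expr, labels)
        up = res.direction == "up"
        assert (res.loc[up, "log2fc"] >= 0).all()
        assert (res.loc[~up, "log2fc"] < 0).all()


class TestStratifiedSplit:
    def test_exact_proportions(self):
        samples = [f"p{i}" for i in range(100)] + [f"b{i}" for i in range(50)]
        labels = pd.Series(["PTC"] * 100 + ["BTN"] * 50, index=samples)
        train, test = stratified_split(samples, labels, 0.2, seed=1)
        assert labels[test].value_counts().to_dict() == {"PTC": 20, "BTN": 10}

    def test_partition_property(self):
        samples = [f"s{i}" for i in range(40)]
        labels = pd.Series(["PTC"] * 25 + ["BTN"] * 15, index=samples)
        train, test = stratified_split(samples, labels, 0.3, seed=2)
        assert sorted(train + test) == sorted(samples)
        assert not set(train) & set(test)

    def test_same_seed_same_split(self):
        samples = [f"s{i}" for i in range(30)]
        labels = pd.Series(["PTC"] * 20 + ["BTN"] * 10, index=samples)
        assert stratified_split(samples, labels, 0.2, seed=3) == stratified_split(
            samples, labels, 0.2, seed=3
        )

    def test_bad_fraction_rejected(self):
        samples = [f"s{i}" for i in range(10)]
        labels = pd.Series(["PTC"] * 5 + ["BTN"] * 5, index=samples)
        with pytest.raises(ValueError):
            stratified_split(samples, labels, 1.5)


class TestRFESignature:
    def test_two_candidates_path_has_sizes_two_and_one(self):
        rng = rng_for(23, "test_rfe_two")
        n = 40
        y = ["PTC"] * 20 + ["BTN"] * 20
        values = np.clip(
            np.vstack(
                [np.where(np.array(y) == "PTC", 5.0, 1.0) + rng.normal(0, 0.5, n),
                 rng.uniform(1, 2, n)]
            ),
            0.0,
            None,
        )
        m, labels = _labelled_matrix(values, y)
        model = rfe_signature(m, labels, ["g0", "g1"], folds=(4,), seed=0)
        assert sorted(model.cv_path["size"].tolist()) == [1, 2]

    def test_same_seed_same_panel_and_coefficients(self, diagnosis7):
        expr, labels, _ = diagnosis7
        log2m = log2_transform(expr)
        sub = log2m.subset_samples(log2m.samples[::4])
        lab = labels[sub.samples]
        a = rfe_signature(sub, lab, expr.genes[:30], folds=(4,), seed=5)
        b = rfe_signature(sub, lab, expr.genes[:30], folds=(4,), seed=5)
        assert a.panel == b.panel
        pd.testing.assert_series_equal(a.coefficients, b.coefficients)

    def test_no_leakage_from_test_samples(self, diagnosis7):
        """Perturbing held-out samples must not change the trained model."""
        expr, labels, _ = diagnosis7
        log2m = log2_transform(expr)
        train_ids, test_ids = stratified_split(expr.samples, labels, 0.2, seed=7)
        train_m = log2m.subset_samples(train_ids)
        model_a = rfe_signature(train_m, labels[train_ids], expr.genes[:40], folds=(4,), seed=7)
        # plant an artifact in the test split only, re-run the training path
        poisoned = log2m.data.copy()
        poisoned.loc[:, test_ids] = 999.0
        train_again = ExpressionMatrix(poisoned[train_ids])
        model_b = rfe_signature(
            ExpressionMatrix(train_again.data), labels[train_ids], expr.genes[:40],
            folds=(4,), seed=7,
        )
        assert model_a.panel == model_b.panel
        pd.testing.assert_series_equal(model_a.coefficients, model_b.coefficients)


class TestEvaluateClassifiers:
    def _separable(self, seed=24):
        rng = rng_for(seed, "test_eval_sep")
        n = 60
        y = ["PTC"] * 30 + ["BTN"] * 30
        values = np.clip(
            np.vstack(
                [np.where(np.array(y) == "PTC", 8.0, 2.0) + rng.normal(0, 0.3, n),
                 rng.uniform(1, 2, n)]
            ),
            0.0,
            None,
        )
        return _labelled_matrix(values, y)

    def test_perfect_separation_gives_auc_one(self):
        m, labels = self._separable()
        train_ids, test_ids = stratified_split(m.samples, labels, 0.3, seed=0)
        model = rfe_signature(
            m.subset_samples(train_ids), labels[train_ids], ["g0", "g1"], folds=(4,), seed=0
        )
        res = evaluate_classifiers(
            model, m.subset_samples(train_ids), labels[train_ids],
            m.subset_samples(test_ids), labels[test_ids], classifiers=("LR",), seed=0,
        )
        assert res["LR"]["test_auc"] == 1.0

    def test_shuffled_labels_give_chance_auc(self):
        rng = rng_for(25, "test_eval_null")
        n = 60
        y = list(rng.permutation(["PTC"] * 30 + ["BTN"] * 30))
        values = rng.uniform(1, 10, size=(5, n))
        m, labels = _labelled_matrix(values, y)
        train_ids, test_ids = stratified_split(m.samples, labels, 0.5, seed=1)
        model = rfe_signature(
            m.subset_samples(train_ids), labels[train_ids], m.genes, folds=(4,), seed=1
        )
        res = evaluate_classifiers(
            model, m.subset_samples(train_ids), labels[train_ids],
            m.subset_samples(test_ids), labels[test_ids], classifiers=("LR",), seed=1,
        )
        assert abs(res["LR"]["test_auc"] - 0.5) <= 0.25

    def test_trapezoid_auc_equals_mann_whitney_identity(self):
        from sklearn.metrics import auc, roc_curve

        rng = rng_for(26, "test_auc_identity")
        scores = rng.normal(size=200)
        y = rng.uniform(size=200) < 0.4
        fpr, tpr, _ = roc_curve(y, scores)
        trap = auc(fpr, tpr)
        u = stats.mannwhitneyu(scores[y], scores[~y], alternative="two-sided").statistic
        assert trap == pytest.approx(u / (y.sum() * (~y).sum()), abs=1e-12)

    def test_unknown_classifier_rejected(self):
        m, labels = self._separable()
        train_ids, test_ids = stratified_split(m.samples, labels, 0.3, seed=0)
        model = rfe_signature(
            m.subset_samples(train_ids), labels[train_ids], ["g0", "g1"], folds=(4,), seed=0
        )
        with pytest.raises(ValueError, match="unknown classifier"):
            evaluate_classifiers(
                model, m.subset_samples(train_ids), labels[train_ids],
                m.subset_samples(test_ids), labels[test_ids], classifiers=("DNN",), seed=0,
            )
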