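"""Classifier grid: normalization contract, CV, metrics, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petctrad.modeling import (
    FAMILIES,
    bootstrap_ci,
    evaluate_metrics,
    rank_auc,
    run_grid,
    stratified_kfold,
    train_classifier,
    zscore_fit_apply,
)


class TestZScore:
    def test_train_block_standardized(self, rng):
        X = rng.normal(3, 5, size=(50, 4))
        (Z,), params = zscore_fit_apply(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_external_uses_train_params(self, rng):
        X = rng.normal(0, 1, size=(50, 3))
        E = rng.normal(5, 1, size=(20, 3))
        (Ztr, Zext), params = zscore_fit_apply(X, E)
        assert Zext.mean() > 1.0  # shifted external stays shifted
        np.testing.assert_allclose(Zext, (E - params["mean"]) / params["sd"])

    def test_constant_column_flagged_and_centered(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        (Z,), params = zscore_fit_apply(X)
        assert params["constant"][0] and not params["constant"][1]
        np.testing.assert_allclose(Z[:, 0], 0.0)


class TestStratifiedKFold:
    def test_balanced_folds(self):
        y = np.array([0, 1] * 50)
        folds = stratified_kfold(y, 5, seed=3)
        for f in range(5):
            sel = folds == f
            assert sel.sum() == 20
            assert y[sel].sum() == 10

    def test_partition_exact_and_deterministic(self, rng):
        y = rng.integers(0, 2, 97)
        while min(np.bincount(y)) < 5:
            y = rng.integers(0, 2, 97)
        f1 = stratified_kfold(y, 5, seed=11)
        f2 = stratified_kfold(y, 5, seed=11)
        np.testing.assert_array_equal(f1, f2)
        assert set(f1) == {0, 1, 2, 3, 4}

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0, 0, 0, 0, 1, 1]), 5)


class TestClassifiers:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_toy_fits(self, family):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        model = train_classifier(X, y, family, seed=0)
        proba = model.predict_proba(X)[:, 1]
        assert ((proba > 0.5) == y).mean() == 1.0

    def test_deterministic_families_seed_independent(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        for family in ("lda", "knn"):
            p1 = train_classifier(X, y, family, seed=1).predict_proba(X)
            p2 = train_classifier(X, y, family, seed=99).predict_proba(X)
            np.testing.assert_allclose(p1, p2)

    def test_unknown_family_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.normal(size=(10, 2)), np.array([0, 1] * 5), "boosted_ferns")

    def test_shuffled_labels_give_chance_auc(self):
        """Permutation null: CV AUC ~ 0.5 for a fast subset of families."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 5))
        y = rng.permutation([0, 1] * 50)
        folds = stratified_kfold(y, 5, seed=0)
        for family in ("logistic", "lda", "naive_bayes", "knn"):
            oof = np.empty(100)
            for f in range(5):
                tr, te = folds != f, folds == f
                m = train_classifier(X[tr], y[tr], family, seed=0)
                oof[te] = m.predict_proba(X[te])[:, 1]
            assert 0.3 < rank_auc(oof, y) < 0.7


class TestMetrics:
    def test_perfect_scores(self):
        r = evaluate_metrics(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0 and r.accuracy == 1.0 and r.sensitivity == 1.0

    def test_flipped_scores_auc_zero(self):
        r = evaluate_metrics(np.array([0.1, 0.2, 0.9, 0.8]), np.array([1, 1, 0, 0]))
        assert r.auc == 0.0

    def test_rank_formula_example(self):
        # scores {0.9, 0.8, 0.4, 0.3}, labels {1, 1, 0, 1}: one negative,
        # ranked above exactly 2 of 3 positives -> AUC = 2/3
        auc = rank_auc(np.array([0.9, 0.8, 0.4, 0.3]), np.array([1, 1, 0, 1]))
        assert auc == pytest.approx(2 / 3)

    def test_rank_auc_equals_trapezoid_on_tiefree_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.permutation(np.linspace(0, 1, 60))
        y = rng.integers(0, 2, 60)
        y[:3] = [0, 1, 0]
        assert rank_auc(scores, y) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_confusion_identities(self, tp, fp, fn, tn):
        """accuracy/sens/spec/ppv/npv identities hold for any confusion matrix."""
        if tp + fn == 0 or tn + fp == 0:
            return
        scores = np.concatenate(
            [np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
        )
        labels = np.concatenate([np.ones(tp + fn), np.zeros(fp + tn)]).astype(int)
        r = evaluate_metrics(scores, labels)
        assert (r.tp, r.fp, r.fn, r.tn) == (tp, fp, fn, tn)
        total = tp + fp + fn + tn
        assert r.accuracy == pytest.approx((tp + tn) / total)
        assert r.sensitivity == pytest.approx(tp / (tp + fn))
        assert r.specificity == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert r.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert r.npv == pytest.approx(tn / (tn + fn))
        assert 0.0 <= r.auc <= 1.0


class TestBootstrap:
    def test_all_correct_gives_degenerate_ci(self):
        y = np.array([1] * 10 + [0] * 10)
        s = y.astype(float)
        lo, hi = bootstrap_ci(lambda sc, yy: ((sc >= 0.5) == yy).mean(), s, y, B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_ci_contains_point_estimate(self, rng):
        y = np.array([0, 1] * 50)
        s = np.clip(y + rng.normal(0, 0.4, 100), 0, 1)
        acc = lambda sc, yy: ((sc >= 0.5) == yy).mean()
        lo, hi = bootstrap_ci(acc, s, y, B=500, seed=1)
        assert lo <= acc(s, y) <= hi

    def test_width_matches_binomial_approximation(self, rng):
        n, p_correct = 200, 0.9
        y = np.array([0, 1] * (n // 2))
        correct = rng.random(n) < p_correct
        s = np.where(correct, y, 1 - y).astype(float)
        acc = lambda sc, yy: ((sc >= 0.5) == yy).mean()
        lo, hi = bootstrap_ci(acc, s, y, B=2000, seed=2)
        a = acc(s, y)
        expected_width = 2 * 1.96 * np.sqrt(a * (1 - a) / n)
        assert (hi - lo) == pytest.approx(expected_width, rel=0.30)

    def test_small_B_warns(self):
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning):
            bootstrap_ci(lambda s, yy: s.mean(), y.astype(float), y, B=50, seed=0)


class TestRunGrid:
    def _table(self, rng, n=120, informative=True):
        y = np.array([0, 1] * (n // 2))
        site = np.array(["internal"] * (3 * n // 4) + ["external"] * (n // 4))
        data = {}
        for i in range(4):
            data[f"PET_original_firstorder_F{i}"] = rng.normal(size=n) + (
                1.5 * y if informative and i == 0 else 0
            )
            data[f"CT_original_firstorder_F{i}"] = rng.normal(size=n)
        table = pd.DataFrame(data)
        table["label"], table["site"] = y, site
        return table

    def test_report_shape_and_best_cell(self, rng):
        table = self._table(rng)
        sets = {
            "PET_TIF": [c for c in table.columns if c.startswith("PET")],
            "CT_TIF": [c for c in table.columns if c.startswith("CT")],
        }
        result = run_grid(table, sets, families=("logistic", "lda"), seed=0)
        assert len(result.rows) == 4
        assert result.best[0] == "PET_TIF"  # planted signal is PET-side
        assert result.best_internal.auc > 0.8

    def test_failed_cell_recorded_not_fatal(self, rng):
        table = self._table(rng)
        sets = {"bad": ["PET_original_firstorder_F0"], "ok": ["PET_original_firstorder_F0"]}
        table_bad = table.copy()
        result = run_grid(table_bad, sets, families=("logistic",), seed=0)
        assert len(result.rows) == 2

    def test_paper_mode_runs(self, rng):
        table = self._table(rng)
        sets = {"PET_TIF": [c for c in table.columns if c.startswith("PET")]}
        result = run_grid(table, sets, families=("logistic",), seed=0, mode="paper")
        assert result.best_internal.auc > 0.7
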