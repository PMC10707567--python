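"""Cross-validation protocols, metrics, RFE baseline, ablation harness."""

import numpy as np
import pytest

from maacnn.evaluation import (ABLATION_ARMS, ConfusionCounts,
                               UndefinedMetricWarning, ablation_suite, auc,
                               loocv, metrics, rfe_baseline, stratified_kfold,
                               train_maacnn)


def oracle_auc(labels, scores):
    """Brute-force Mann-Whitney: concordant pairs count 1, ties 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedKFold:
    def test_perfect_stratification(self):
        y = np.array([0] * 10 + [1] * 10)
        folds = stratified_kfold(y, 10, seed=0)
        for f in folds:
            assert len(f) == 2 and y[f].sum() == 1

    def test_partition_property(self, rng):
        y = rng.integers(0, 2, size=47)
        while min((y == 0).sum(), (y == 1).sum()) < 5:
            y = rng.integers(0, 2, size=47)
        folds = stratified_kfold(y, 5, seed=3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(47))  # disjoint cover

    def test_cohort_scale_fold_sizes(self):
        """419 positives / 530 controls in 10 folds: sizes 94-95, 41-42 ASD."""
        y = np.array([1] * 419 + [0] * 530)
        folds = stratified_kfold(y, 10, seed=1)
        assert {len(f) for f in folds} <= {94, 95}
        assert {int(y[f].sum()) for f in folds} <= {41, 42}

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            stratified_kfold(np.array([0] * 20 + [1] * 3), 5, seed=0)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert m == {"ACC": 1.0, "SEN": 1.0, "SPEC": 1.0}

    def test_direct_formula_evaluation(self):
        m = metrics(ConfusionCounts(TP=3, FN=1, TN=4, FP=2))
        assert m["SEN"] == pytest.approx(0.75)
        assert m["SPEC"] == pytest.approx(2 / 3)
        assert m["ACC"] == pytest.approx(0.7)

    def test_random_counts_match_formula_oracle(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            m = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert m["ACC"] == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert m["SEN"] == pytest.approx(tp / (tp + fn))
            assert m["SPEC"] == pytest.approx(tn / (tn + fp))

    def test_undefined_denominators_warn_not_crash(self):
        with pytest.warns(UndefinedMetricWarning):
            m = metrics(ConfusionCounts(TP=0, FN=0, TN=3, FP=1))
        assert m["SEN"] is None and m["SPEC"] is not None

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts())
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=1)

    def test_total_invariant(self):
        c = ConfusionCounts.from_predictions([0, 1, 1, 0, 1], [1, 1, 0, 0, 1])
        assert c.total == 5


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([1, 0], [0.9, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_hand_set_scores_match_pair_oracle(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.8, 0.4, 0.6, 0.6, 0.3, 0.5]
        assert auc(labels, scores) == pytest.approx(oracle_auc(labels, scores))

    def test_random_score_sets_match_pair_oracle(self, rng):
        for _ in range(25):
            labels = rng.integers(0, 2, size=12)
            if len(set(labels)) < 2:
                continue
            scores = np.round(rng.random(12), 1)  # coarse grid forces ties
            assert auc(labels, scores) == pytest.approx(
                oracle_auc(labels, scores), abs=1e-12)

    def test_single_class_returns_none_with_warning(self):
        with pytest.warns(UndefinedMetricWarning):
            assert auc([1, 1, 1], [0.1, 0.2, 0.3]) is None


class TestRFE:
    def test_target_one_less_removes_exactly_one(self, rng):
        x = rng.standard_normal((40, 10))
        y = rng.integers(0, 2, size=40)
        sel = rfe_baseline(x, y, target_dim=9)
        assert len(sel) == 9

    def test_planted_signal_recovery(self, rng):
        """Features 0-4 carry all the class signal; RFE to 5 recovers them."""
        n = 200
        y = np.repeat([0, 1], n // 2)
        x = rng.standard_normal((n, 30))
        x[:, :5] += 2.0 * y[:, None]
        assert rfe_baseline(x, y, target_dim=5).tolist() == [0, 1, 2, 3, 4]

    def test_deterministic(self, rng):
        x = rng.standard_normal((50, 20))
        y = rng.integers(0, 2, size=50)
        np.testing.assert_array_equal(rfe_baseline(x, y, 6, seed=4),
                                      rfe_baseline(x, y, 6, seed=4))

    def test_target_dim_bounds(self, rng):
        x = rng.standard_normal((10, 5))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            rfe_baseline(x, y, 5)
        with pytest.raises(ValueError):
            rfe_baseline(x, y, 0)


class TestCrossValidation:
    def test_same_seed_identical_report_digests(self, separable_views, test_config):
        y = np.repeat([0, 1], 40)
        r1 = train_maacnn(separable_views, y, test_config, seed=3)
        r2 = train_maacnn(separable_views, y, test_config, seed=3)
        assert r1.digest() == r2.digest()
        assert r1.leakage["n_violations"] == 0

    def test_fold_mean_equals_mean_of_folds(self, separable_views, test_config):
        y = np.repeat([0, 1], 40)
        rep = train_maacnn(separable_views, y, test_config, seed=5)
        accs = [f["ACC"] for f in rep.folds]
        assert rep.mean["ACC"] == pytest.approx(np.mean(accs), abs=1e-9)
        assert rep.aggregation == "fold-mean"

    def test_misaligned_subjects_rejected(self, separable_views, test_config):
        y = np.repeat([0, 1], 40)
        bad = {k: (v if i == 0 else v.iloc[::-1]) for i, (k, v)
               in enumerate(separable_views.items())}
        with pytest.raises(ValueError, match="misalignment|subject"):
            train_maacnn(bad, y, test_config, seed=0)

    def test_loocv_toy_separable(self, separable_views, test_config):
        """20-subject LOOCV on one informative view: 20 singleton folds,
        pooled counts total 20, accuracy >= 0.8."""
        name = next(iter(separable_views))
        sub = separable_views[name].iloc[list(range(10)) + list(range(40, 50))]
        y = np.repeat([0, 1], 10)
        rep = loocv({name: sub}, y, test_config, seed=2)
        assert rep.protocol == "LOOCV" and rep.aggregation == "pooled"
        assert len(rep.folds) == 20
        assert all(len(f["test_indices"]) == 1 for f in rep.folds)
        counts = rep.pooled["counts"]
        assert sum(counts.values()) == 20
        assert rep.mean["ACC"] >= 80.0

    def test_loocv_needs_three_subjects(self, separable_views, test_config):
        name = next(iter(separable_views))
        with pytest.raises(ValueError):
            loocv({name: separable_views[name].iloc[:2]}, [0, 1], test_config)


class TestAblation:
    def test_four_arms_shared_folds(self, separable_views, test_config):
        y = np.repeat([0, 1], 40)
        rows = ablation_suite(separable_views, y, test_config, seed=9)
        assert [r["arm"] for r in rows] == list(ABLATION_ARMS)
        assert len({r["fold_digest"] for r in rows}) == 1
        assert all(r["leakage_violations"] == 0 for r in rows)
        by_arm = {r["arm"]: r for r in rows}
        # signal is planted in every view: fusing all views should not lose
        # to the single-view CNN arm
        assert by_arm["full"]["ACC"] >= by_arm["cnn"]["ACC"] - 1e-9

    def test_needs_two_views(self, separable_views, test_config):
        name = next(iter(separable_views))
        with pytest.raises(ValueError, match=">= 2 views"):
            ablation_suite({name: separable_views[name]},
                           np.repeat([0, 1], 40), test_config)
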