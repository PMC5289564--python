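"""Evaluation machinery: metrics vs brute-force oracles, CV partition
properties, the corrected resampled t-test, and the attribute filters."""

import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from tunasonar import evalstats as ev
from tunasonar.synthgen import make_feature_table


def cm_metrics_bruteforce(cm: ev.ConfusionMatrix):
    """Recompute metrics by materialising label vectors and using an
    independent library route (sklearn) plus explicit pair counting."""
    y = [1] * (cm.tp + cm.fn) + [0] * (cm.tn + cm.fp)
    p = [1] * cm.tp + [0] * cm.fn + [0] * cm.tn + [1] * cm.fp
    return cohen_kappa_score(y, p)


def auc_pair_counting(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_all_correct_positives(self):
        cm = ev.confusion([1] * 10, [1] * 10)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 0, 0, 0)

    def test_hand_counted_example(self):
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        p = [1, 1, 1, 0, 0, 0, 1, 1]
        cm = ev.confusion(y, p)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 1, 2, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion([], [])
        with pytest.raises(ValueError):
            ev.confusion([1, 0], [1])

    def test_sensitivity_specificity_worked_cases(self):
        assert ev.sensitivity(ev.ConfusionMatrix(40, 0, 10, 0)) == 0.8
        assert ev.specificity(ev.ConfusionMatrix(0, 0, 0, 30)) == 1.0
        assert ev.sensitivity(ev.ConfusionMatrix(0, 0, 10, 5)) == 0.0

    def test_undefined_denominators_warn(self):
        with pytest.warns(UserWarning):
            assert math.isnan(ev.sensitivity(ev.ConfusionMatrix(0, 3, 0, 5)))
        with pytest.warns(UserWarning):
            assert math.isnan(ev.specificity(ev.ConfusionMatrix(3, 0, 5, 0)))

    def test_kappa_worked_example(self):
        # p_o = 0.7, p_e = 0.5 -> Kappa = 0.4
        cm = ev.ConfusionMatrix(tp=40, fp=20, fn=10, tn=30)
        assert ev.kappa(cm) == pytest.approx(0.4, abs=1e-12)

    def test_kappa_perfect_and_chance(self):
        assert ev.kappa(ev.ConfusionMatrix(10, 0, 0, 10)) == 1.0
        assert ev.kappa(ev.ConfusionMatrix(25, 25, 25, 25)) == 0.0

    def test_kappa_degenerate_agreement(self):
        with pytest.warns(UserWarning):
            assert ev.kappa(ev.ConfusionMatrix(10, 0, 0, 0)) == 0.0

    def test_metrics_match_oracles_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + fn == 0 or tn + fp == 0 or tp + fp + fn + tn == 0:
                continue
            cm = ev.ConfusionMatrix(tp, fp, fn, tn)
            assert ev.sensitivity(cm) == pytest.approx(tp / (tp + fn),
                                                       abs=1e-12)
            assert ev.specificity(cm) == pytest.approx(tn / (tn + fp),
                                                       abs=1e-12)
            if len({tp + fn > 0, True}) and not (fp + tp == 0 and fn + tn == 0):
                expected = cm_metrics_bruteforce(cm)
                assert ev.kappa(cm) == pytest.approx(expected, abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        assert ev.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example_three_of_four_pairs(self):
        assert ev.auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert ev.auc([0.5] * 8, [1, 1, 1, 0, 0, 0, 1, 0]) == 0.5

    def test_one_class_absent_is_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(ev.auc([0.1, 0.2], [1, 1]))

    def test_matches_pair_counting_and_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            got = ev.auc(scores, labels)
            assert got == pytest.approx(auc_pair_counting(scores, labels),
                                        abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        base = ev.auc(scores, labels)
        assert ev.auc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert ev.auc(np.log(scores + 1e-9), labels) == pytest.approx(base)


class TestCorrectedResampledTTest:
    def test_all_zero_diffs(self):
        assert ev.corrected_resampled_ttest([0.0] * 10, 50, 50) == (0.0, 1.0)

    def test_formula_matches_direct_evaluation(self):
        diffs = [0.02, 0.00, 0.01, -0.01, 0.03, 0.01, 0.00, 0.02, 0.01, 0.01]
        j = len(diffs)
        mean = sum(diffs) / j
        s2 = sum((d - mean) ** 2 for d in diffs) / (j - 1)
        expected_t = mean / math.sqrt((1 / j + 1.0) * s2)  # n_test = n_train
        t, p = ev.corrected_resampled_ttest(diffs, 100, 100)
        assert t == pytest.approx(expected_t, abs=1e-12)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), j - 1))

    def test_larger_test_fraction_shrinks_t(self):
        diffs = [0.02, 0.01, 0.03, 0.00, 0.02]
        t1, _ = ev.corrected_resampled_ttest(diffs, 100, 50)
        t2, _ = ev.corrected_resampled_ttest(diffs, 100, 100)
        assert abs(t2) < abs(t1)

    def test_zero_variance_nonzero_mean(self):
        t, p = ev.corrected_resampled_ttest([0.05] * 6, 10, 10)
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_too_few_diffs_rejected(self):
        with pytest.raises(ValueError):
            ev.corrected_resampled_ttest([0.1], 10, 10)


class TestCrossValidation:
    def test_5x2_partitions_disjoint_exhaustive_balanced(self):
        labels = np.r_[np.ones(30, int), np.zeros(70, int)]
        parts = ev.make_5x2_partitions(labels, seed=0)
        assert len(parts) == 10
        for rep in range(5):
            (r0, f0, tr0, te0), (r1, f1, tr1, te1) = parts[2 * rep:2 * rep + 2]
            assert set(te0) | set(te1) == set(range(100))
            assert set(te0).isdisjoint(te1)
            assert abs(len(te0) - len(te1)) <= 1
            assert set(tr0) == set(te1) and set(tr1) == set(te0)

    def test_same_seed_same_partitions(self):
        labels = np.r_[np.ones(20, int), np.zeros(30, int)]
        a = ev.make_5x2_partitions(labels, seed=5)
        b = ev.make_5x2_partitions(labels, seed=5)
        for (_, _, tra, tea), (_, _, trb, teb) in zip(a, b):
            assert (tra == trb).all() and (tea == teb).all()

    def test_majority_dummy_on_balanced_table(self, small_table):
        # a majority-class dummy has Kappa ~ 0 and AUC = 0.5 by the ties rule
        table = make_feature_table(50, 50, seed=3)
        records = ev.five_by_two_cv(table, "majority", seed=3)
        assert len(records) == 10
        for r in records:
            assert abs(r.kappa) < 0.2
            assert r.auc == 0.5
            assert abs(r.accuracy - 0.5) < 0.2

    def test_repeated_kfold_record_count_and_partitions(self, small_table):
        report = ev.repeated_kfold(small_table, "tree", runs=3, k=10, seed=0)
        assert len(report.folds) == 30
        sizes = [f.n_test for f in report.folds[:10]]
        assert sum(sizes) == len(small_table.df)
        assert max(sizes) - min(sizes) <= 1

    def test_separable_table_rf_auc(self, small_table):
        report = ev.repeated_kfold(small_table, "rf", runs=1, k=10, seed=1)
        assert report.auc >= 0.99
        assert report.summary()["classifier"] == "rf"

    def test_leave_one_out_fold_sizes(self):
        table = make_feature_table(10, 10, seed=4)
        report = ev.repeated_kfold(table, "tree", runs=1, k=2, seed=0)
        assert len(report.folds) == 2

    def test_balance_applied_inside_training_fold_only(self, small_table):
        recs_plain = ev.five_by_two_cv(small_table, "tree", seed=7)
        recs_smote = ev.five_by_two_cv(small_table, "tree", seed=7,
                                       balance="smote")
        # test folds are identical: same sizes regardless of balancing
        assert [r.n_test for r in recs_plain] == \
            [r.n_test for r in recs_smote]

    def test_identical_seeds_identical_reports(self, small_table):
        a = ev.repeated_kfold(small_table, "tree", runs=2, k=5, seed=9)
        b = ev.repeated_kfold(small_table, "tree", runs=2, k=5, seed=9)
        assert [f.accuracy for f in a.folds] == [f.accuracy for f in b.folds]


class TestFeatureRanking:
    def test_label_copy_feature_ranks_first(self):
        table = make_feature_table(40, 60, seed=6)
        df = table.df.copy()
        df["Area"] = table.labels().astype(float)  # Area := the label
        # scramble the other informative size features so only Area is a
        # perfect predictor
        rng = np.random.default_rng(0)
        for col in ("Major", "Minor", "Feret", "MinFeret", "Perimeter",
                    "Width", "Height", "BX", "BY"):
            df[col] = rng.permutation(df[col].to_numpy())
        scrambled = type(table)(df)
        for method in ("chi2", "infogain", "svm_weight"):
            ranking = ev.rank_features(scrambled, method)
            assert ranking[0][0] == "Area", method

    def test_permuted_feature_has_no_infogain(self):
        table = make_feature_table(50, 50, seed=7)
        df = table.df.copy()
        rng = np.random.default_rng(1)
        df["Solidity"] = rng.permutation(df["Solidity"].to_numpy())
        scores = dict(ev.rank_features(type(table)(df), "infogain"))
        assert scores["Solidity"] == pytest.approx(0.0, abs=0.05)

    def test_chi2_matches_hand_computed_contingency(self):
        # binary feature vs binary class: Pearson chi2 by hand
        from tunasonar.evalstats import chi2_score

        x = np.array([0.0] * 30 + [1.0] * 30)
        y = np.array([0] * 25 + [1] * 5 + [0] * 10 + [1] * 20)
        # contingency: [[25, 5], [10, 20]]
        n = 60.0
        expected = 0.0
        obs = np.array([[25, 5], [10, 20]], float)
        row = obs.sum(1)
        col = obs.sum(0)
        for i in range(2):
            for j in range(2):
                e = row[i] * col[j] / n
                expected += (obs[i, j] - e) ** 2 / e
        assert chi2_score(x, y) == pytest.approx(expected)

    def test_constant_feature_scores_zero(self):
        from tunasonar.evalstats import chi2_score, infogain_score

        x = np.full(50, 3.0)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        assert chi2_score(x, y) == 0.0
        assert infogain_score(x, y) == 0.0


class TestStepwise:
    @staticmethod
    def noise_table(n=150, n_informative=1, seed=0):
        """A table where only the first ``n_informative`` descriptor columns
        carry class signal; the rest are pure noise."""
        from tunasonar.balance import TrainingTable
        from tunasonar.morphfeatures import FEATURE_COLUMNS
        import pandas as pd

        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        data = {"Blob_ID": [f"b{i}" for i in range(n)]}
        for j, col in enumerate(FEATURE_COLUMNS):
            if j < n_informative:
                data[col] = y * 2.0 + rng.normal(0, 0.5, n)
            else:
                data[col] = rng.normal(0, 1, n)
        data["Class"] = np.where(y == 1, "tuna", "no-tuna")
        return TrainingTable(pd.DataFrame(data))

    def test_informative_feature_recovered(self):
        hits = 0
        for seed in range(30):
            table = self.noise_table(seed=seed)
            sel = ev.stepwise_select(table)
            hits += "Area" in sel  # Area is the informative column
        assert hits >= 27  # >= 90% recovery over seeds

    def test_pure_noise_selects_almost_nothing(self):
        sizes = [len(ev.stepwise_select(self.noise_table(n_informative=0,
                                                         seed=s)))
                 for s in range(10)]
        assert np.mean(sizes) <= 2.0

    def test_single_feature_table(self):
        table = self.noise_table(n_informative=1, seed=1)
        sel = ev.stepwise_select(table, columns=["Area"])
        assert sel == ["Area"]
        noise = self.noise_table(n_informative=0, seed=1)
        assert ev.stepwise_select(noise, columns=["Area"]) in ([], ["Area"])


class TestExperiments:
    def test_experiment1_grid_shape_and_full_row(self, small_table):
        grid = ev.run_experiment1(
            small_table, seed=0, backend_kwargs={"n_estimators": 15})
        assert len(grid) == 29
        assert set(grid["selector"]) == {"full", "chi2", "infogain",
                                         "svm_weight", "stepwise"}
        full = grid[grid["selector"] == "full"].iloc[0]
        assert full["t"] == 0.0 and full["p"] == 1.0
        sizes = sorted(grid[grid["selector"] == "chi2"]["n_features"])
        assert sizes == list(range(3, 20, 2))

    def test_experiment2_grid_and_smote_sensitivity(self):
        table = make_feature_table(40, 160, seed=12)
        grid = ev.run_experiment2(
            table, backends=("tree", "knn"), runs=1, k=5, seed=0,
            backend_kwargs=None)
        assert len(grid) == 6
        for (ds, name), report in grid.items():
            assert report.dataset == ds and report.classifier == name
            assert len(report.folds) == 5
        # balanced training folds should not hurt sensitivity on
        # separable data
        for name in ("tree", "knn"):
            assert grid[("SMOTE", name)].sensitivity >= \
                grid[("TOTAL", name)].sensitivity - 0.05

    def test_experiment2_determinism(self):
        table = make_feature_table(30, 90, seed=13)
        g1 = ev.run_experiment2(table, backends=("tree",), runs=1, k=5,
                                seed=4)
        g2 = ev.run_experiment2(table, backends=("tree",), runs=1, k=5,
                                seed=4)
        a = [f.accuracy for f in g1[("SPREAD", "tree")].folds]
        b = [f.accuracy for f in g2[("SPREAD", "tree")].folds]
        assert a == b
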