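"""SVM evaluation harness: folds, grid search, metrics, t-test."""

import numpy as np
import pytest
from scipy import stats

import densitex as dx
from densitex import evaluate as ev

# Pooled 4-class and binary confusion matrices from the reference
# mammographic evaluation of these descriptors; metric worked examples.
ISO_MLBP_4CLASS = np.array([[128, 5, 2, 1],
                            [18, 108, 19, 1],
                            [8, 1, 84, 6],
                            [0, 0, 2, 26]])
ISO_4CLASS = np.array([[119, 9, 5, 3],
                       [24, 91, 26, 5],
                       [15, 5, 72, 7],
                       [0, 1, 7, 20]])
MLBP_BINARY = np.array([[259, 23], [10, 117]])
ISO_BINARY = np.array([[253, 29], [15, 112]])
ISO_MLBP_BINARY = np.array([[262, 20], [9, 118]])


class TestStratifiedKFold:
    def test_balanced_small_case(self):
        y = np.repeat(["I", "II", "III", "IV"], 5)
        folds = dx.stratified_kfold(y, k=5, seed=0)
        for f in range(5):
            labels, counts = np.unique(y[folds == f], return_counts=True)
            assert len(labels) == 4 and (counts == 1).all()

    def test_partition_properties(self, rng):
        y = rng.choice(["a", "b", "c"], size=47, p=[0.5, 0.3, 0.2])
        folds = dx.stratified_kfold(y, k=5, seed=3)
        assert folds.shape == y.shape
        assert set(np.unique(folds)) == set(range(5))
        for cls in "abc":
            per_fold = [np.sum((y == cls) & (folds == f)) for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(dx.InvalidInputError):
            dx.stratified_kfold(np.array(["a"] * 10 + ["b"] * 3), k=5)


class TestGridSearch:
    def test_grid_sizes(self):
        assert len(ev.rbf_grid()) == 64  # 8 gamma x 8 C decade steps
        assert len(ev.default_grid()) == 64 + 64 * 6 + 64

    def test_config_bounds_enforced(self):
        with pytest.raises(dx.InvalidInputError):
            dx.SVMConfig(C=1e5)
        with pytest.raises(dx.InvalidInputError):
            dx.SVMConfig(gamma=1e-5)
        with pytest.raises(dx.InvalidInputError):
            dx.SVMConfig(kernel="linear")

    def test_separable_blobs_reach_perfect_inner_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (12, 2)),
                       rng.normal(8, 0.3, (12, 2))])
        y = np.array(["a"] * 12 + ["b"] * 12)
        config, score = dx.grid_search_svm(X, y, grid=ev.rbf_grid(),
                                           seed=0, return_score=True)
        assert score == 1.0

    def test_selection_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(24, 3))
        y = np.array(["a", "b", "c"] * 8)
        base = dx.grid_search_svm(X, y, grid=ev.rbf_grid(), seed=5)
        perm = rng.permutation(24)
        shuffled = dx.grid_search_svm(X[perm], y[perm], grid=ev.rbf_grid(),
                                      seed=5)
        assert base == shuffled

    def test_single_class_rejected(self, rng):
        with pytest.raises(dx.InvalidInputError):
            dx.grid_search_svm(rng.normal(size=(10, 2)), np.array(["a"] * 10))


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(3 * i, 1.0, (50, 6)) for i in range(4)])
    y = np.repeat(["I", "II", "III", "IV"], 50)
    return X, y


class TestCrossValidate:
    def test_well_separated_classes_classified(self, separated):
        X, y = separated
        res = dx.cross_validate(X, y, seed=1, grid=ev.rbf_grid())
        assert res.accuracy >= 0.95
        assert res.confusion.sum() == len(y)  # every sample tested once

    def test_deterministic_and_consistent(self, separated):
        X, y = separated
        a = dx.cross_validate(X, y, seed=2, grid=ev.rbf_grid())
        b = dx.cross_validate(X, y, seed=2, grid=ev.rbf_grid())
        assert a.to_dict() == b.to_dict()
        # pooled accuracy is the fold-size-weighted mean of fold accuracies
        folds = dx.stratified_kfold(y, k=5, seed=2)
        sizes = np.bincount(folds)
        weighted = np.average(a.fold_accuracies, weights=sizes)
        assert a.accuracy == pytest.approx(weighted, abs=1e-12)
        assert a.accuracy == pytest.approx(
            dx.compute_metrics(a.confusion).accuracy, abs=1e-12)


class TestMetrics:
    @pytest.mark.parametrize("cm,printed", [
        (ISO_MLBP_4CLASS, 84.6), (ISO_4CLASS, 73.8),
        (MLBP_BINARY, 91.9), (ISO_BINARY, 89.2), (ISO_MLBP_BINARY, 92.9),
    ])
    def test_reported_accuracies_recovered(self, cm, printed):
        assert round(100 * dx.compute_metrics(cm).accuracy, 1) == printed

    def test_perfect_matrix(self):
        m = dx.compute_metrics(np.diag([10, 20, 5]))
        assert m.accuracy == 1.0 and m.kappa == 1.0 and m.f1_weighted == 1.0

    def test_kappa_matches_marginal_formula(self, rng):
        cm = rng.integers(0, 30, size=(4, 4))
        cm[0, 0] += 5
        total = cm.sum()
        p_o = np.trace(cm) / total
        p_e = (cm.sum(1) * cm.sum(0)).sum() / total**2
        oracle = (p_o - p_e) / (1 - p_e)
        assert dx.compute_metrics(cm).kappa == pytest.approx(oracle, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(dx.InvalidInputError):
            dx.compute_metrics(np.zeros((3, 3)))


class TestPairedTTest:
    def test_degenerate_rules(self):
        assert dx.paired_ttest([0.7, 0.8, 0.9], [0.7, 0.8, 0.9]) == 1.0
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        assert dx.paired_ttest(a + 0.1, a) == 0.0

    def test_matches_textbook_formula(self, rng):
        a, b = rng.random(5), rng.random(5)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        oracle = 2 * stats.t.sf(abs(t), df=4)
        assert dx.paired_ttest(a, b) == pytest.approx(oracle, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(dx.InvalidInputError):
            dx.paired_ttest([0.1], [0.2])


class TestBinarize:
    def test_mapping(self):
        out = dx.binarize_labels(np.array(["I", "II", "III", "IV"]))
        assert list(out) == ["low", "low", "high", "high"]
        assert set(dx.binarize_labels(np.array(["I", "I"]))) == {"low"}

    def test_reported_class_sizes_collapse(self):
        labels = np.repeat(["I", "II", "III", "IV"], [136, 146, 99, 28])
        binary = dx.binarize_labels(labels)
        assert (binary == "low").sum() == 282
        assert (binary == "high").sum() == 127

    def test_unknown_label_rejected(self):
        with pytest.raises(dx.InvalidInputError):
            dx.binarize_labels(np.array(["I", "V"]))
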