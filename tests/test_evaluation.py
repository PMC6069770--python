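"""Fold construction, metric definitions, CV driver and cross-technology mode."""

import numpy as np
import pytest

from m16s.evaluation import (
    MetricsReport,
    compute_metrics,
    cross_technology_eval,
    cross_validate,
    make_folds,
)
from m16s.rdp_nb import NaiveBayesClassifier


def confusion_matrix_metrics(y_true, y_pred):
    """Independent macro metrics from an explicit confusion matrix."""
    classes = sorted(set(y_true))
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes) + 1))
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx.get(p, len(classes))] += 1
    precisions, recalls, f1s = [], [], []
    for i in range(len(classes)):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    acc = sum(cm[i, i] for i in range(len(classes))) / len(y_true)
    return {
        "accuracy": 100 * acc,
        "precision": 100 * float(np.mean(precisions)),
        "recall": 100 * float(np.mean(recalls)),
        "f1": 100 * float(np.mean(f1s)),
    }


class _MajorityClassifier:
    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.label = vals[counts.argmax()]
        return self

    def predict(self, X):
        return np.full(len(X), self.label)


class TestMakeFolds:
    def test_equal_fold_sizes(self):
        labels = np.repeat(list("abcd"), 25)
        folds = make_folds(labels, n_folds=10, seed=0)
        sizes = [len(folds.test_indices(f)) for f in range(10)]
        assert sizes == [10] * 10

    def test_stratification(self):
        labels = np.repeat(list("wxyz"), 10)
        folds = make_folds(labels, n_folds=10, seed=1)
        for f in range(10):
            fold_labels = labels[folds.test_indices(f)]
            assert sorted(fold_labels) == ["w", "x", "y", "z"]

    def test_partition_property(self):
        labels = np.repeat([0, 1, 2], 17)
        folds = make_folds(labels, n_folds=5, seed=2)
        all_test = np.concatenate([folds.test_indices(f) for f in range(5)])
        assert sorted(all_test) == list(range(len(labels)))

    def test_small_class_warns_not_errors(self):
        labels = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.warns(UserWarning):
            make_folds(labels, n_folds=5, seed=0)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 1]), n_folds=5)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c", "a"])
        m = compute_metrics(y, y)
        assert all(m[k] == 100.0 for k in m)

    def test_constant_predictor_on_balanced_classes(self):
        y_true = np.repeat(list("abcd"), 10)
        y_pred = np.full(40, "a")
        m = compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(25.0)
        assert m["recall"] == pytest.approx(25.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros(3), np.zeros(4))

    def test_agrees_with_confusion_matrix_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(2, 6))
            y_true = rng.integers(k, size=n).astype(str)
            y_pred = rng.integers(k + 1, size=n).astype(str)  # may predict unseen class
            ours = compute_metrics(y_true, y_pred)
            oracle = confusion_matrix_metrics(list(y_true), list(y_pred))
            for key in ours:
                assert ours[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_macro_f1_bounded_by_per_class_f1(self):
        rng = np.random.default_rng(6)
        from sklearn.metrics import f1_score
        for _ in range(20):
            y_true = rng.integers(3, size=40).astype(str)
            y_pred = rng.integers(3, size=40).astype(str)
            macro = compute_metrics(y_true, y_pred)["f1"] / 100
            per_class = f1_score(y_true, y_pred, labels=sorted(set(y_true)),
                                 average=None, zero_division=0)
            assert per_class.min() - 1e-12 <= macro <= per_class.max() + 1e-12


class TestCrossValidate:
    def test_nb_on_separable_fixture(self, clean_reads):
        seqs = [r.seq for r in clean_reads]
        labels = np.array([r.lineage.genus for r in clean_reads])
        report = cross_validate(seqs, labels, NaiveBayesClassifier, n_folds=5, seed=0)
        assert report.mean("accuracy") >= 90.0
        assert report.std("accuracy") >= 0.0
        assert report.n_folds == 5

    def test_identical_seed_identical_report(self, clean_reads):
        seqs = [r.seq for r in clean_reads[:200]]
        labels = np.array([r.lineage.genus for r in clean_reads[:200]])
        a = cross_validate(seqs, labels, NaiveBayesClassifier, n_folds=3, seed=4)
        b = cross_validate(seqs, labels, NaiveBayesClassifier, n_folds=3, seed=4)
        assert a.per_fold == b.per_fold

    def test_two_folds_two_entries(self):
        X = np.random.default_rng(0).random((10, 4))
        y = np.array(list("ababababab"))
        report = cross_validate(X, y, _MajorityClassifier, n_folds=2, seed=0)
        assert report.n_folds == 2

    def test_no_leakage_of_test_normalization(self):
        # estimator fitting a per-feature min-max scaler must derive it from
        # the training fold only: a feature constant in train but varying in
        # test must come out as all zeros (the degenerate rule), not rescaled
        class CanaryScaler:
            def fit(self, X, y):
                self.lo = X.min(axis=0)
                self.hi = X.max(axis=0)
                self.captured = None
                return self

            def predict(self, X):
                span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
                scaled = (X - self.lo) / span
                scaled[:, self.hi == self.lo] = 0.0
                self.captured = scaled
                return np.full(len(X), "a")

        n = 20
        X = np.random.default_rng(1).random((n, 3))
        X[:, 0] = np.arange(n)  # varies everywhere
        y = np.array(["a", "b"] * (n // 2))
        folds_seen = []

        def factory():
            clf = CanaryScaler()
            folds_seen.append(clf)
            return clf

        # constant-in-train canary: make feature 2 constant except one sample
        X[:, 2] = 5.0
        X[3, 2] = 9.0
        cross_validate(X, y, factory, n_folds=4, seed=0)
        for clf in folds_seen:
            if clf.lo[2] == clf.hi[2]:  # sample 3 was in the test fold
                assert np.all(clf.captured[:, 2] == 0.0)


class TestGroupedFolds:
    def test_reads_of_one_reference_stay_together(self, small_pool):
        from m16s.simulate import simulate_shotgun

        reads = simulate_shotgun(small_pool, 2.0, seed=14)
        labels = np.array([r.lineage.genus for r in reads])
        sources = np.array([r.source_id for r in reads])
        folds = make_folds(labels, n_folds=4, seed=0, groups=sources)
        for src in np.unique(sources):
            assert len(set(folds.assignment[sources == src])) == 1


class TestCrossTechnology:
    def test_cross_technology_is_no_better_than_same_technology(self, small_pool):
        # a model tested on one technology's reads does at least as well
        # when trained on that same technology as when trained on the other
        from m16s.simulate import MutationModel, simulate_amplicon, simulate_shotgun

        model = MutationModel()
        sg = simulate_shotgun(small_pool, 2.0, model, seed=5)
        amp, _ = simulate_amplicon(small_pool, coverage=2.0, model=model, seed=5)
        sg_seqs, sg_lab = [r.seq for r in sg], np.array([r.lineage.genus for r in sg])
        amp_seqs, amp_lab = [r.seq for r in amp], np.array([r.lineage.genus for r in amp])
        amp_cv = cross_validate(amp_seqs, amp_lab, NaiveBayesClassifier, n_folds=5, seed=0)
        sg_cv = cross_validate(sg_seqs, sg_lab, NaiveBayesClassifier, n_folds=5, seed=0)
        sg2amp = cross_technology_eval(sg_seqs, sg_lab, amp_seqs, amp_lab,
                                       NaiveBayesClassifier)
        amp2sg = cross_technology_eval(amp_seqs, amp_lab, sg_seqs, sg_lab,
                                       NaiveBayesClassifier)
        assert sg2amp.mean("accuracy") <= amp_cv.mean("accuracy")
        assert amp2sg.mean("accuracy") <= sg_cv.mean("accuracy")

    def test_train_equals_test_is_resubstitution(self, clean_reads):
        seqs = [r.seq for r in clean_reads[:150]]
        labels = np.array([r.lineage.genus for r in clean_reads[:150]])
        rep = cross_technology_eval(seqs, labels, seqs, labels, NaiveBayesClassifier)
        clf = NaiveBayesClassifier().fit(seqs, labels)
        resub = (clf.predict(seqs) == labels).mean() * 100
        assert rep.mean("accuracy") == pytest.approx(resub)

    def test_disjoint_label_sets_give_zero_accuracy(self):
        X = np.eye(4)
        rep = cross_technology_eval(
            X, np.array(["a"] * 4), X, np.array(["b"] * 4), _MajorityClassifier
        )
        assert rep.mean("accuracy") == 0.0

    def test_feature_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_technology_eval(np.zeros((3, 4)), ["a"] * 3,
                                  np.zeros((3, 5)), ["a"] * 3, _MajorityClassifier)


class TestReport:
    def test_serialization_round_trip(self):
        rep = MetricsReport(per_fold=[
            {"accuracy": 90.0, "precision": 88.5, "recall": 87.0, "f1": 87.7},
            {"accuracy": 92.0, "precision": 91.0, "recall": 90.0, "f1": 90.5},
        ])
        back = MetricsReport.from_json(rep.to_json())
        assert back.per_fold == rep.per_fold
        assert back.mean("accuracy") == rep.mean("accuracy")

    def test_std_is_sample_std(self):
        rep = MetricsReport(per_fold=[{"accuracy": a} for a in (88.0, 90.0, 92.0)])
        assert rep.std("accuracy") == pytest.approx(2.0)
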