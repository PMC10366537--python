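"""Classification bench: metrics, subspace ensemble, CV contracts."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from mieeg import (
    ClassifierSpec,
    ConfusionMatrix,
    FeatureMatrix,
    KernelNaiveBayes,
    RandomSubspaceEnsemble,
    RUSBoostClassifier,
    confusion_metrics,
    cross_validate,
    make_classifier,
    subspace_discriminant_fit,
    subspace_discriminant_predict,
)
from mieeg.core import ValidationError
from mieeg.evaluation import CLASSIFIER_PRESETS


def _gaussian_clouds(rng, n_per_class=50, dim=10, sep=4.0, classes=("A", "B")):
    X, y = [], []
    for i, c in enumerate(classes):
        X.append(rng.standard_normal((n_per_class, dim)) + i * sep)
        y += [c] * n_per_class
    return np.vstack(X), np.array(y)


class TestConfusionMetrics:
    def test_binary_worked_example(self):
        # TP=50 TN=40 FP=5 FN=5, positive class second
        cm = ConfusionMatrix(np.array([[40, 5], [5, 50]]), ("neg", "pos"))
        acc, sen, spe = confusion_metrics(cm)
        assert acc == pytest.approx(90.0)
        assert sen == pytest.approx(100 * 50 / 55)
        assert spe == pytest.approx(100 * 40 / 45)

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 8, 3]), ("a", "b", "c"))
        assert confusion_metrics(cm) == (100.0, 100.0, 100.0)

    def test_four_class_macro_one_vs_rest(self):
        counts = np.array(
            [[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 5, 5], [0, 0, 0, 10]]
        )
        cm = ConfusionMatrix(counts, ("a", "b", "c", "d"))
        acc, sen, spe = confusion_metrics(cm)
        assert acc == pytest.approx(87.5)
        assert sen == pytest.approx((100 + 100 + 50 + 100) / 4)
        # brute-force macro specificity over the 4 one-vs-rest tables
        spes = []
        total = counts.sum()
        for c in range(4):
            tp = counts[c, c]
            fn = counts[c].sum() - tp
            fp = counts[:, c].sum() - tp
            tn = total - tp - fn - fp
            spes.append(tn / (tn + fp))
        assert spe == pytest.approx(100 * np.mean(spes))

    def test_absent_class_excluded_with_warning(self):
        counts = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        with pytest.warns(UserWarning, match="absent"):
            acc, sen, _ = confusion_metrics(cm)
        assert acc == pytest.approx(100.0)
        assert sen == pytest.approx(100.0)


class TestSubspaceDiscriminant:
    def test_separable_clouds_high_training_accuracy(self, rng):
        X, y = _gaussian_clouds(rng, n_per_class=100, dim=10)
        model = subspace_discriminant_fit(X, y, n_learners=30, subspace_dim=5, seed=0)
        pred = subspace_discriminant_predict(model, X)
        assert np.mean(pred == y) >= 0.99

    def test_single_learner_full_dim_equals_plain_lda(self, rng):
        X, y = _gaussian_clouds(rng, n_per_class=30, dim=8, sep=1.0)
        model = subspace_discriminant_fit(X, y, n_learners=1, subspace_dim=8, seed=1)
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-3).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), lda.predict(X))

    def test_seed_determinism(self, rng):
        X, y = _gaussian_clouds(rng, n_per_class=20, dim=12, sep=0.5)
        a = subspace_discriminant_fit(X, y, seed=7).predict(X)
        b = subspace_discriminant_fit(X, y, seed=7).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_tiny_class_rejected(self, rng):
        X = rng.standard_normal((3, 4))
        with pytest.raises(ValidationError):
            subspace_discriminant_fit(X, np.array(["A", "A", "B"]))

    def test_singular_covariance_is_regularised_not_fatal(self, rng):
        # p >> n makes every within-class covariance singular
        X, y = _gaussian_clouds(rng, n_per_class=5, dim=50, sep=3.0)
        model = subspace_discriminant_fit(X, y, n_learners=5, seed=0)
        assert np.mean(model.predict(X) == y) > 0.9

    def test_shuffled_labels_near_chance(self, rng):
        X, y = _gaussian_clouds(rng, n_per_class=50, dim=10, sep=4.0)
        y_perm = rng.permutation(y)
        fm = FeatureMatrix(X, tuple(f"f{i}" for i in range(10)), tuple(y_perm))
        rep = cross_validate(
            fm, ClassifierSpec("ensemble_subspace_discriminant"),
            k=5, repeats=1, seed=4,
        )
        # binomial 3 SD around 50% with n=100 test samples
        assert abs(rep.accuracy - 50.0) <= 3 * 100 * np.sqrt(0.25 / 100)


class TestCustomEstimators:
    def test_kernel_nb_separable(self, rng):
        X, y = _gaussian_clouds(rng, n_per_class=40, dim=4)
        model = KernelNaiveBayes().fit(X, y)
        assert np.mean(model.predict(X) == y) >= 0.95
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_rusboost_handles_imbalance(self, rng):
        X_a = rng.standard_normal((80, 5))
        X_b = rng.standard_normal((12, 5)) + 3.0
        X = np.vstack([X_a, X_b])
        y = np.array(["maj"] * 80 + ["min"] * 12)
        model = RUSBoostClassifier(n_estimators=10, random_state=0).fit(X, y)
        pred = model.predict(X)
        assert np.mean(pred[y == "min"] == "min") >= 0.8


class TestClassifierBench:
    @pytest.mark.parametrize(
        "family,preset",
        [(f, p) for f, presets in CLASSIFIER_PRESETS.items() for p in presets],
    )
    def test_every_preset_fits_and_predicts(self, rng, family, preset):
        X, y = _gaussian_clouds(rng, n_per_class=110, dim=6)
        n_classes = 2
        est = make_classifier(ClassifierSpec(family, preset), 6, n_classes, seed=0)
        est.fit(X, y)
        pred = est.predict(X)
        assert pred.shape == y.shape
        assert np.mean(pred == y) > 0.5

    def test_logistic_restricted_to_binary(self):
        with pytest.raises(ValidationError):
            make_classifier(ClassifierSpec("logistic"), 5, 3)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError):
            make_classifier(ClassifierSpec("perceptron"), 5, 2)


class TestCrossValidate:
    @staticmethod
    def _fm(rng, n=50, classes=("A", "B")):
        X, y = _gaussian_clouds(
            rng, n_per_class=n // len(classes), dim=6, sep=1.0, classes=classes
        )
        return FeatureMatrix(X, tuple(f"f{i}" for i in range(6)), tuple(y))

    def test_partition_contract(self, rng):
        fm = self._fm(rng, n=50)
        rep = cross_validate(fm, ClassifierSpec("tree", "coarse"), k=5, repeats=1, seed=0)
        assert len(rep.confusions) == 1 and len(rep.confusions[0]) == 5
        assert sum(cm.total for cm in rep.confusions[0]) == 50

    def test_stratification_balance(self, rng):
        fm = self._fm(rng, n=50)
        rep = cross_validate(fm, ClassifierSpec("tree", "coarse"), k=5, repeats=1, seed=0)
        for cm in rep.confusions[0]:
            per_class = cm.counts.sum(axis=1)
            assert np.ptp(per_class) <= 1

    def test_seed_determinism(self, rng):
        fm = self._fm(rng)
        a = cross_validate(fm, ClassifierSpec("knn", "fine"), k=5, repeats=2, seed=9)
        b = cross_validate(fm, ClassifierSpec("knn", "fine"), k=5, repeats=2, seed=9)
        assert a.fold_accuracies == b.fold_accuracies

    def test_class_smaller_than_k_rejected(self, rng):
        X = np.vstack([rng.standard_normal((10, 3)), rng.standard_normal((3, 3))])
        fm = FeatureMatrix(X, ("a", "b", "c"), ("A",) * 10 + ("B",) * 3)
        with pytest.raises(ValidationError, match="B"):
            cross_validate(fm, ClassifierSpec("tree", "fine"), k=5, repeats=1, seed=0)

    def test_in_fold_selection_reduces_columns(self, rng):
        fm = self._fm(rng, n=60)
        rep = cross_validate(
            fm, ClassifierSpec("lda"), k=5, repeats=1, seed=2, select_alpha=0.05
        )
        assert all(n <= fm.n_features for n in rep.n_features_used[0])

    def test_report_serialisable(self, rng):
        import json

        fm = self._fm(rng)
        rep = cross_validate(fm, ClassifierSpec("gaussian_nb"), k=5, repeats=1, seed=0)
        d = json.loads(json.dumps(rep.to_dict()))
        assert d["k"] == 5 and len(d["confusions"][0]) == 5
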