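"""Cross-validated classification and confusion-matrix metrics.

Implements the classifier bench used to compare feature sets: decision
trees, discriminant analysis, Naive Bayes (Gaussian and kernel-density),
SVMs, k-NN variants, logistic regression (two classes only) and the
ensemble methods — including a from-scratch random-subspace discriminant
ensemble, the reference analysis's best performer.  Evaluation is
repeated stratified k-fold cross-validation (default 5 folds, 10
repeats) reporting accuracy, macro sensitivity and macro specificity
from per-fold confusion matrices.

Preset hyperparameters follow the conventional fine/medium/coarse
graduations: tree leaf budgets 100/20/4, k-NN neighbourhoods 1/10/100,
RBF kernel scales sqrt(p)/4, sqrt(p), 4*sqrt(p).  Distance- and
margin-based classifiers (k-NN, SVM, logistic) are standardised with
train-fold statistics; tree and discriminant families run on raw
features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .core import FeatureMatrix, ValidationError
from .selection import select_features

__all__ = [
    "ConfusionMatrix", "confusion_metrics", "CVReport", "ClassifierSpec",
    "RandomSubspaceEnsemble", "subspace_discriminant_fit",
    "subspace_discriminant_predict", "KernelNaiveBayes", "RUSBoostClassifier",
    "make_classifier", "cross_validate", "CLASSIFIER_PRESETS",
]


# ---------------------------------------------------------------------------
# Confusion matrices and derived metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Class x class counts; rows are truth, columns are predictions."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_names = tuple(self.class_names)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValidationError("confusion counts must be class x class")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class index c against the rest."""
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum()) - tp
        fp = int(self.counts[:, c].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str],
        class_names: Sequence[str],
    ) -> "ConfusionMatrix":
        counts = _sk_confusion(y_true, y_pred, labels=list(class_names))
        return cls(counts, tuple(class_names))


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %) from a confusion matrix.

    Two classes: the second class is the positive one; ACC, SEN = TP/(TP+FN)
    and SPE = TN/(TN+FP) follow the standard binary definitions.  More
    classes: ACC is trace/total, SEN and SPE are macro averages of the
    one-vs-rest rates; a class absent from the test set is excluded from
    the macro average with a warning.
    """
    if cm.total == 0:
        raise ValidationError("confusion matrix is empty")
    k = len(cm.class_names)
    acc = 100.0 * float(np.trace(cm.counts)) / cm.total
    if k == 2:
        tp, tn, fp, fn = cm.one_vs_rest(1)
        sen = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
        spe = 100.0 * tn / (tn + fp) if tn + fp > 0 else math.nan
        return acc, sen, spe
    sens, spes = [], []
    for c in range(k):
        tp, tn, fp, fn = cm.one_vs_rest(c)
        if tp + fn == 0:
            warnings.warn(
                f"class {cm.class_names[c]!r} absent from the test set; "
                "excluded from macro sensitivity/specificity"
            )
            continue
        sens.append(tp / (tp + fn))
        spes.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
    return acc, 100.0 * float(np.mean(sens)), 100.0 * float(np.mean(spes))


# ---------------------------------------------------------------------------
# Custom estimators
# ---------------------------------------------------------------------------

class RandomSubspaceEnsemble(BaseEstimator, ClassifierMixin):
    """Random-subspace ensemble: each learner sees a random feature subset.

    Every learner is trained on all rows but only `subspace_dim` randomly
    drawn feature columns (without replacement within a subset); prediction
    averages the learners' class posteriors and takes the argmax, breaking
    ties toward the lowest class index.  The default base learner is a
    linear discriminant with diagonal-loading shrinkage, which keeps fits
    well-defined when a subset's pooled covariance is singular.
    """

    def __init__(self, base_estimator=None, n_estimators: int = 30,
                 subspace_dim: int | None = None, random_state: int | None = None):
        self.base_estimator = base_estimator
        self.n_estimators = n_estimators
        self.subspace_dim = subspace_dim
        self.random_state = random_state

    def _make_base(self):
        if self.base_estimator is None:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-3)
        return clone(self.base_estimator)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_estimators < 1:
            raise ValidationError("n_estimators must be >= 1")
        self.classes_, counts = np.unique(y, return_counts=True)
        if np.any(counts < 2):
            small = self.classes_[counts < 2]
            raise ValidationError(f"training classes with < 2 samples: {list(small)}")
        p = X.shape[1]
        dim = self.subspace_dim if self.subspace_dim is not None else math.ceil(p / 2)
        if dim > p:
            raise ValidationError(f"subspace_dim {dim} exceeds feature count {p}")
        rng = np.random.default_rng(self.random_state)
        self.subspaces_ = [
            np.sort(rng.choice(p, size=dim, replace=False))
            for _ in range(self.n_estimators)
        ]
        self.estimators_ = []
        for idx in self.subspaces_:
            est = self._make_base()
            est.fit(X[:, idx], y)
            self.estimators_.append(est)
        self.n_features_in_ = p
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for est, idx in zip(self.estimators_, self.subspaces_):
            cols = np.searchsorted(self.classes_, est.classes_)
            proba[:, cols] += est.predict_proba(X[:, idx])
        return proba / len(self.estimators_)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # first max: lowest index


def subspace_discriminant_fit(
    X: np.ndarray, y: Sequence, n_learners: int = 30,
    subspace_dim: int | None = None, seed: int | None = None,
) -> RandomSubspaceEnsemble:
    """Fit the random-subspace linear-discriminant ensemble."""
    model = RandomSubspaceEnsemble(
        n_estimators=n_learners, subspace_dim=subspace_dim, random_state=seed
    )
    return model.fit(np.asarray(X, dtype=float), np.asarray(y))


def subspace_discriminant_predict(model: RandomSubspaceEnsemble, X: np.ndarray):
    return model.predict(np.asarray(X, dtype=float))


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Class-conditional densities are products of univariate KDEs with
    Silverman's rule-of-thumb bandwidth per class and feature.
    """

    def __init__(self, min_bandwidth: float = 1e-9):
        self.min_bandwidth = min_bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.train_ = []
        self.bandwidths_ = []
        self.log_priors_ = []
        n = len(y)
        for c in self.classes_:
            T = X[y == c]
            m = T.shape[0]
            sd = np.std(T, axis=0, ddof=1) if m > 1 else np.zeros(T.shape[1])
            iqr = np.subtract(*np.percentile(T, [75, 25], axis=0))
            spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
            h = 0.9 * spread * m ** (-0.2)
            h = np.maximum(h, self.min_bandwidth)
            self.train_.append(T)
            self.bandwidths_.append(h)
            self.log_priors_.append(math.log(m / n))
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for ci, (T, h, lp) in enumerate(
            zip(self.train_, self.bandwidths_, self.log_priors_)
        ):
            ll = np.zeros(X.shape[0])
            for j in range(X.shape[1]):
                z = (X[:, j, None] - T[None, :, j]) / h[j]
                logk = -0.5 * z * z - math.log(h[j] * math.sqrt(2 * math.pi))
                mx = logk.max(axis=1)
                ll += mx + np.log(np.mean(np.exp(logk - mx[:, None]), axis=1))
            out[:, ci] = lp + ll
        return out

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """SAMME boosting with per-iteration random undersampling.

    Each boosting round trains its tree on a class-balanced subsample
    (every class undersampled to the smallest class's count, drawn with
    probability proportional to the current boosting weights) and updates
    the weights with the multi-class SAMME rule on the full training set.
    """

    def __init__(self, n_estimators: int = 30, max_leaf_nodes: int = 21,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_leaf_nodes = max_leaf_nodes
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        n = len(y)
        n_min = int(np.bincount(y_idx).min())
        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        for t in range(self.n_estimators):
            sample: list[int] = []
            for ci in range(k):
                idx = np.flatnonzero(y_idx == ci)
                probs = w[idx] / w[idx].sum()
                take = min(n_min, idx.size)
                sample.extend(rng.choice(idx, size=take, replace=False, p=probs))
            sample_arr = np.asarray(sample)
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[sample_arr], y[sample_arr])
            pred = tree.predict(X)
            miss = pred != y
            err = float(np.sum(w[miss]))
            if err >= 1.0 - 1.0 / k:   # no better than chance: discard and stop
                break
            err = max(err, 1e-12)
            alpha = math.log((1.0 - err) / err) + math.log(k - 1)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * miss)
            w /= w.sum()
            if err <= 1e-12:
                break
        if not self.estimators_:  # degenerate: keep one balanced tree
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes, random_state=0
            )
            tree.fit(X, y)
            self.estimators_, self.alphas_ = [tree], [1.0]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = np.searchsorted(self.classes_, tree.predict(X))
            votes[np.arange(X.shape[0]), pred] += alpha
        return self.classes_[np.argmax(votes, axis=1)]


# ---------------------------------------------------------------------------
# Classifier bench
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """A classifier family plus a named preset and optional overrides."""

    family: str
    preset: str = ""
    hyperparameters: dict = field(default_factory=dict)

    @property
    def identifier(self) -> str:
        return f"{self.family}:{self.preset}" if self.preset else self.family


#: family -> allowed presets ("" = no preset axis).
CLASSIFIER_PRESETS: dict[str, tuple[str, ...]] = {
    "tree": ("fine", "medium", "coarse"),
    "lda": ("",),
    "qda": ("",),
    "gaussian_nb": ("",),
    "kernel_nb": ("",),
    "svm": ("linear", "quadratic", "cubic", "fine_gaussian",
            "medium_gaussian", "coarse_gaussian"),
    "knn": ("fine", "medium", "coarse", "cosine", "cubic", "weighted"),
    "logistic": ("",),
    "ensemble_subspace_discriminant": ("",),
    "ensemble_subspace_knn": ("",),
    "ensemble_bagged_trees": ("",),
    "ensemble_boosted_trees": ("",),
    "ensemble_rusboost": ("",),
}

_TREE_LEAVES = {"fine": 100, "medium": 20, "coarse": 4}
_KNN_K = {"fine": 1, "medium": 10, "coarse": 100}


def _inverse_square(d: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(d, 1e-12) ** 2


def make_classifier(
    spec: ClassifierSpec, n_features: int, n_classes: int, seed: int | None = None,
):
    """Instantiate the estimator for a spec; standardisation is attached where
    the family is distance- or margin-based."""
    fam, preset, hp = spec.family, spec.preset, dict(spec.hyperparameters)
    if fam not in CLASSIFIER_PRESETS:
        raise ValidationError(f"unknown classifier family {fam!r}")
    if CLASSIFIER_PRESETS[fam] != ("",) and preset not in CLASSIFIER_PRESETS[fam]:
        raise ValidationError(f"unknown preset {preset!r} for family {fam!r}")

    if fam == "tree":
        return DecisionTreeClassifier(
            max_leaf_nodes=_TREE_LEAVES[preset], random_state=seed, **hp
        )
    if fam == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-3, **hp)
    if fam == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=hp.pop("reg_param", 1e-3), **hp)
    if fam == "gaussian_nb":
        return GaussianNB(**hp)
    if fam == "kernel_nb":
        return KernelNaiveBayes(**hp)
    if fam == "svm":
        scale = math.sqrt(n_features)
        if preset == "linear":
            svc = SVC(kernel="linear", C=1.0, **hp)
        elif preset in ("quadratic", "cubic"):
            svc = SVC(kernel="poly", degree=2 if preset == "quadratic" else 3,
                      C=1.0, gamma="scale", coef0=1.0, **hp)
        else:
            ks = {"fine_gaussian": scale / 4, "medium_gaussian": scale,
                  "coarse_gaussian": 4 * scale}[preset]
            svc = SVC(kernel="rbf", C=1.0, gamma=1.0 / (ks * ks), **hp)
        return make_pipeline(StandardScaler(), svc)
    if fam == "knn":
        if preset in _KNN_K:
            knn = KNeighborsClassifier(n_neighbors=_KNN_K[preset], **hp)
        elif preset == "cosine":
            knn = KNeighborsClassifier(n_neighbors=10, metric="cosine", **hp)
        elif preset == "cubic":
            knn = KNeighborsClassifier(n_neighbors=10, metric="minkowski", p=3, **hp)
        else:  # weighted
            knn = KNeighborsClassifier(n_neighbors=10, weights=_inverse_square, **hp)
        return make_pipeline(StandardScaler(), knn)
    if fam == "logistic":
        if n_classes != 2:
            raise ValidationError("logistic regression is restricted to 2 classes")
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, **hp)
        )
    if fam == "ensemble_subspace_discriminant":
        return RandomSubspaceEnsemble(
            n_estimators=hp.pop("n_learners", 30),
            subspace_dim=hp.pop("subspace_dim", math.ceil(n_features / 2)),
            random_state=seed,
        )
    if fam == "ensemble_subspace_knn":
        return RandomSubspaceEnsemble(
            base_estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=hp.pop("n_learners", 30),
            subspace_dim=hp.pop("subspace_dim", math.ceil(n_features / 2)),
            random_state=seed,
        )
    if fam == "ensemble_bagged_trees":
        return BaggingClassifier(
            DecisionTreeClassifier(random_state=0),
            n_estimators=hp.pop("n_learners", 30), random_state=seed, **hp,
        )
    if fam == "ensemble_boosted_trees":
        return AdaBoostClassifier(
            DecisionTreeClassifier(max_leaf_nodes=21, random_state=0),
            n_estimators=hp.pop("n_learners", 30), random_state=seed, **hp,
        )
    if fam == "ensemble_rusboost":
        return RUSBoostClassifier(
            n_estimators=hp.pop("n_learners", 30), random_state=seed, **hp
        )
    raise ValidationError(f"unhandled classifier family {fam!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-repeat, per-fold confusion matrices and aggregate metrics (%)."""

    classifier: str
    seed: int
    k: int
    repeats: int
    class_names: tuple[str, ...]
    confusions: list[list[ConfusionMatrix]]
    accuracy: float
    sensitivity: float
    specificity: float
    fold_accuracies: list[float]
    n_features_used: list[list[int]] | None = None

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "seed": self.seed,
            "k": self.k,
            "repeats": self.repeats,
            "class_names": list(self.class_names),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fold_accuracies": self.fold_accuracies,
            "confusions": [
                [cm.counts.tolist() for cm in rep] for rep in self.confusions
            ],
            "n_features_used": self.n_features_used,
        }


def _fold_seed(seed: int, repeat: int, fold: int = 0) -> int:
    ss = np.random.SeedSequence([seed, repeat, fold])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def cross_validate(
    fm: FeatureMatrix,
    spec: ClassifierSpec,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    select_alpha: float | None = None,
    ttest_variant: str = "pooled",
) -> CVReport:
    """Repeated stratified k-fold cross-validation of one classifier.

    Folds are re-randomised each repeat from (seed, repeat index).  With
    `select_alpha` set, the significance screen is refit on each training
    fold and applied to its test fold — the leakage-free alternative to
    screening the full dataset up front.
    """
    classes = fm.class_names
    if len(classes) < 2:
        raise ValidationError("cross-validation needs >= 2 classes")
    labels = np.asarray(fm.labels)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    too_small = [c for c, n in counts.items() if n < k]
    if too_small:
        raise ValidationError(
            f"classes smaller than k={k}: {too_small}; stratification impossible"
        )
    X, y = fm.values, labels
    confusions: list[list[ConfusionMatrix]] = []
    fold_accs: list[float] = []
    sens_list: list[float] = []
    spec_list: list[float] = []
    n_used: list[list[int]] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_fold_seed(seed, r))
        rep_cms: list[ConfusionMatrix] = []
        rep_used: list[int] = []
        for f, (tr, te) in enumerate(skf.split(X, y)):
            X_tr, X_te = X[tr], X[te]
            if select_alpha is not None:
                sub = FeatureMatrix(X_tr, fm.names, tuple(y[tr]))
                sel = select_features(sub, select_alpha, variant=ttest_variant)
                mask = sel.mask if sel.mask.any() else np.ones(len(fm.names), bool)
                X_tr, X_te = X_tr[:, mask], X_te[:, mask]
            rep_used.append(X_tr.shape[1])
            est = make_classifier(
                spec, X_tr.shape[1], len(classes), seed=_fold_seed(seed, r, f + 1)
            )
            est.fit(X_tr, y[tr])
            pred = est.predict(X_te)
            cm = ConfusionMatrix.from_predictions(y[te], pred, classes)
            rep_cms.append(cm)
            acc, sen, spe = confusion_metrics(cm)
            fold_accs.append(acc)
            sens_list.append(sen)
            spec_list.append(spe)
        confusions.append(rep_cms)
        n_used.append(rep_used)
    return CVReport(
        classifier=spec.identifier,
        seed=seed,
        k=k,
        repeats=repeats,
        class_names=classes,
        confusions=confusions,
        accuracy=float(np.mean(fold_accs)),
        sensitivity=float(np.nanmean(sens_list)),
        specificity=float(np.nanmean(spec_list)),
        fold_accuracies=fold_accs,
        n_features_used=n_used,
    )
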