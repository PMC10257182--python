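"""Training and comparison of binary classifiers under severe class imbalance.

With ~2% positives, accuracy is meaningless — a classifier that never
predicts "senolytic" scores 98%.  Model selection therefore uses precision
(fraction of predicted positives that are real), recall, and F1 computed
from confusion matrices, with stratified 5-fold cross-validation,
optional minority oversampling (SMOTE) confined to training folds, balanced
class weights, and a precision-maximising grid search.  Five algorithm
families are supported: RBF-kernel support vector machine, random forest,
gradient-boosted tree ensemble, logistic regression, and Gaussian naive
Bayes.

Undefined metrics (zero denominators, e.g. a fold with no predicted
positives) propagate as flagged NaNs and are excluded from fold means with
the exclusion count reported, rather than being silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "ConfusionMatrix",
    "CVReport",
    "classification_metrics",
    "smote_oversample",
    "stratified_kfold_cv",
    "grid_search",
    "stratified_split",
    "train",
    "predict_scores",
    "confusion_on_holdout",
    "save_model",
    "load_model",
]

ALGORITHMS = ("svm", "random_forest", "xgboost", "logistic_regression", "naive_bayes")

METRICS = ("precision", "recall", "f1")


class PlattSVC:
    """RBF-kernel SVM with probabilities from a Platt (sigmoid) calibration.

    The sigmoid is fitted on cross-validated decision values of the training
    data only, with the same class weighting as the SVM itself — so a
    class-weight-balanced SVM yields probabilities of the balanced problem
    (a weighted decision value of 0 maps near P = 0.5), exactly as the other
    weighted estimators behave.
    """

    def __init__(self, C=1.0, gamma="scale", kernel="rbf", class_weight=None,
                 random_state=0):
        self.C, self.gamma, self.kernel = C, gamma, kernel
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        from sklearn.model_selection import cross_val_predict

        self.svc_ = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                        class_weight=self.class_weight,
                        random_state=self.random_state)
        dec = cross_val_predict(self.svc_, X, y, cv=3, method="decision_function")
        self.svc_.fit(X, y)
        self.platt_ = LogisticRegression(class_weight=self.class_weight)
        self.platt_.fit(dec.reshape(-1, 1), y)
        return self

    def predict_proba(self, X):
        dec = self.svc_.decision_function(np.asarray(X, dtype=float))
        return self.platt_.predict_proba(dec.reshape(-1, 1))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus the imbalance-handling knobs that matter here.

    ``class_weight='balanced'`` reweights classes inversely to frequency
    (for the gradient-boosted model this maps to ``scale_pos_weight``; for
    naive Bayes, to uniform class priors).  ``smote_k`` switches on SMOTE
    oversampling with that neighbour count, applied to training folds only.
    """

    algorithm: str
    hyperparams: tuple = ()  # sorted (name, value) pairs
    class_weight: str = "none"  # {"none", "balanced"}
    smote_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {ALGORITHMS}")
        if self.class_weight not in ("none", "balanced"):
            raise ValueError("class_weight must be 'none' or 'balanced'")
        object.__setattr__(self, "hyperparams",
                           tuple(sorted(dict(self.hyperparams).items())))

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    def with_params(self, **kw) -> "ModelSpec":
        merged = {**self.params, **kw}
        return replace(self, hyperparams=tuple(sorted(merged.items())))

    def build(self, y: np.ndarray | None = None):
        """Instantiate the underlying estimator (probability-capable)."""
        p = self.params
        balanced = self.class_weight == "balanced"
        if self.algorithm == "svm":
            return PlattSVC(kernel=p.get("kernel", "rbf"), C=p.get("C", 1.0),
                            gamma=p.get("gamma", "scale"),
                            class_weight="balanced" if balanced else None,
                            random_state=self.seed)
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=p.get("n_estimators", 500),
                max_depth=p.get("max_depth"),
                class_weight="balanced" if balanced else None,
                random_state=self.seed, n_jobs=1)
        if self.algorithm == "xgboost":
            spw = 1.0
            if balanced and y is not None:
                n_pos = int(np.sum(y == 1))
                spw = (len(y) - n_pos) / max(n_pos, 1)
            return XGBClassifier(
                n_estimators=p.get("n_estimators", 100),
                max_depth=p.get("max_depth", 6),
                learning_rate=p.get("learning_rate", 0.3),
                scale_pos_weight=spw,
                random_state=self.seed, n_jobs=1,
                eval_metric="logloss", verbosity=0)
        if self.algorithm == "logistic_regression":
            return LogisticRegression(
                C=p.get("C", 1.0), max_iter=p.get("max_iter", 2000),
                class_weight="balanced" if balanced else None,
                random_state=self.seed)
        if self.algorithm == "naive_bayes":
            return GaussianNB(priors=[0.5, 0.5] if balanced else None)
        raise AssertionError  # unreachable: validated in __post_init__


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Precision, recall and F1 from a confusion matrix.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 = TP/(TP+(FP+FN)/2).
    A zero denominator makes the metric undefined: it is reported as NaN and
    listed in ``undefined`` instead of being coerced to 0.
    """
    out: dict[str, Any] = {}
    undefined = []
    pairs = {
        "precision": (cm.tp, cm.tp + cm.fp),
        "recall": (cm.tp, cm.tp + cm.fn),
        "f1": (cm.tp, cm.tp + 0.5 * (cm.fp + cm.fn)),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = float("nan")
            undefined.append(name)
        else:
            out[name] = num / den
    out["undefined"] = undefined
    return out


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0):
    """Equalise class counts by synthesising minority samples (SMOTE).

    Each synthetic row is a convex combination x + u·(x' − x), u ~ U(0, 1),
    of a minority row x and one of its ``k_neighbors`` nearest minority
    neighbours x'.  Majority rows pass through unchanged; balanced input is
    returned as-is.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X, y
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples <= k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    Xm = X[y == minority]
    # pairwise distances within the minority class
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nbrs = np.argsort(d2, axis=1)[:, :k_neighbors]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    gap = rng.random(size=(n_new, 1))
    x0 = Xm[base]
    x1 = Xm[nbrs[base, pick]]
    synth = x0 + gap * (x1 - x0)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


@dataclass
class CVReport:
    """Fold-wise metrics with means and SDs over the defined folds."""

    spec: ModelSpec
    fold_metrics: list[dict]
    fold_confusions: list[ConfusionMatrix]
    fold_assignment: np.ndarray  # test-fold index per sample
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_undefined: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in METRICS:
            vals = np.array([fm[m] for fm in self.fold_metrics])
            ok = ~np.isnan(vals)
            self.n_undefined[m] = int((~ok).sum())
            self.mean[m] = float(vals[ok].mean()) if ok.any() else float("nan")
            self.sd[m] = float(vals[ok].std(ddof=0)) if ok.any() else float("nan")

    def pooled_confusion(self) -> ConfusionMatrix:
        return ConfusionMatrix(
            tp=sum(c.tp for c in self.fold_confusions),
            fp=sum(c.fp for c in self.fold_confusions),
            fn=sum(c.fn for c in self.fold_confusions),
            tn=sum(c.tn for c in self.fold_confusions),
        )


def _confusion_from_scores(scores, y_true, threshold: float) -> ConfusionMatrix:
    pred = np.asarray(scores) > threshold  # strict: P must exceed the cutoff
    y_true = np.asarray(y_true, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(pred & y_true)),
        fp=int(np.sum(pred & ~y_true)),
        fn=int(np.sum(~pred & y_true)),
        tn=int(np.sum(~pred & ~y_true)),
    )


def stratified_kfold_cv(X, y, spec: ModelSpec, folds: int = 5, seed: int = 0,
                        threshold: float = 0.5) -> CVReport:
    """Stratified k-fold cross-validation of one model spec.

    Per-fold positive counts differ by at most 1.  If the spec requests
    SMOTE, oversampling is applied to each training fold only — the test
    fold never sees synthetic samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < folds:
            raise ValueError(f"class {cls} has {cnt} samples < {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.full(len(y), -1, dtype=int)
    fold_metrics, fold_cms = [], []
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        assignment[te] = fold_idx
        X_tr, y_tr = X[tr], y[tr]
        if spec.smote_k is not None:
            X_tr, y_tr = smote_oversample(X_tr, y_tr, k_neighbors=spec.smote_k,
                                          seed=seed * 1000 + fold_idx)
        model = spec.build(y_tr)
        model.fit(X_tr, y_tr)
        scores = model.predict_proba(X[te])[:, 1]
        cm = _confusion_from_scores(scores, y[te], threshold)
        fold_cms.append(cm)
        fold_metrics.append(classification_metrics(cm))
    return CVReport(spec=spec, fold_metrics=fold_metrics,
                    fold_confusions=fold_cms, fold_assignment=assignment)


def grid_search(X, y, base_spec: ModelSpec, grid: dict, objective: str = "precision",
                folds: int = 5, seed: int = 0):
    """Exhaustive search over a hyperparameter grid, maximising a CV metric.

    ``grid`` maps one hyperparameter name to an iterable of values (e.g.
    ``{"max_depth": range(1, 11)}``).  A cell whose objective is undefined
    on every fold scores −inf.  Ties break toward the smaller value.
    Returns ``(best_spec, log)`` where the log has one entry per cell.
    """
    if not grid or any(len(list(v)) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    if len(grid) != 1:
        raise ValueError("grid search over one hyperparameter at a time")
    (name, values), = grid.items()
    log = []
    best = None
    for v in sorted(values):
        spec = base_spec.with_params(**{name: v})
        report = stratified_kfold_cv(X, y, spec, folds=folds, seed=seed)
        score = report.mean[objective]
        score_cmp = -np.inf if np.isnan(score) else score
        log.append({name: v, objective: score,
                    "n_undefined": report.n_undefined[objective]})
        if best is None or score_cmp > best[0]:
            best = (score_cmp, spec)
    return best[1], log


def stratified_split(X, y, train_frac: float = 0.7, seed: int = 0):
    """Stratified random train/test split preserving class proportions.

    Returns ``(X_train, X_test, y_train, y_test, idx_train, idx_test)``; the
    two index sets are disjoint and exhaustive.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    idx = np.arange(len(y))
    idx_tr, idx_te = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed, shuffle=True
    )
    return X[idx_tr], X[idx_te], y[idx_tr], y[idx_te], idx_tr, idx_te


@dataclass
class TrainedModel:
    """A fitted estimator with its spec and the feature names it was trained on."""

    spec: ModelSpec
    estimator: Any
    feature_names: list[str]

    def scores(self, X, feature_names=None) -> np.ndarray:
        if feature_names is not None and list(feature_names) != self.feature_names:
            raise ValueError("feature names do not match the trained model")
        return self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]


def train(spec: ModelSpec, X, y, feature_names=None) -> TrainedModel:
    """Fit one model (with fold-free SMOTE on the whole training set if set)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if spec.smote_k is not None:
        X, y = smote_oversample(X, y, k_neighbors=spec.smote_k, seed=spec.seed)
    est = spec.build(y)
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, feature_names=list(feature_names))


def predict_scores(model: TrainedModel, X, feature_names=None) -> np.ndarray:
    return model.scores(X, feature_names)


def confusion_on_holdout(model: TrainedModel, X_test, y_test,
                         threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix of a trained model on held-out data (score > threshold)."""
    scores = model.scores(X_test)
    return _confusion_from_scores(scores, y_test, threshold)


_SERIAL_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"version": _SERIAL_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("version") != _SERIAL_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('version')}")
    return payload["model"]
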