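"""Per-question ordinal classifiers and cross-validation.

Base learners come from the standard supervised-learning roster of the
published configuration (naive Bayes, complement naive Bayes, pruned
decision trees in three pruning flavours, random forest).  They are
library-backed; the ordering-aware part — the ordinal decomposition
wrapper — is implemented here.

The wrapper follows the classic binary-decomposition scheme for ordered
classes: for k ordered classes it trains k-1 binary models estimating
Pr(y > 1), ..., Pr(y > k-1) and composes

    P(1)   = 1 - Pr(y > 1)
    P(i)   = Pr(y > i-1) - Pr(y > i)     (1 < i < k)
    P(k)   = Pr(y > k-1)

Negative intermediate masses (inconsistent thresholds) are clipped to 0
and the vector renormalized; prediction is the argmax with ties broken
toward the lower class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import CategoricalNB, ComplementNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import KBinsDiscretizer
from sklearn.tree import DecisionTreeClassifier

from .evaluate import ConfusionMatrix
from .features import FeatureVector

METHODS = (
    "naive-bayes",
    "complement-naive-bayes",
    "decision-tree-pruned",
    "best-first-tree",
    "reduced-error-pruning-tree",
    "random-forest",
    "sentiment-rule",
)

DEFAULT_SEED = 42
DEFAULT_FOLDS = 10


@dataclass(frozen=True)
class ClassifierSpec:
    method: str
    hyperparameters: dict = field(default_factory=dict)
    ordinal: bool = False
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; roster: {METHODS}")


@dataclass(frozen=True)
class CrossValidationPlan:
    k: int = DEFAULT_FOLDS
    stratified: bool = True
    seed: int = DEFAULT_SEED


def _base_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    m = spec.method
    if m == "naive-bayes":
        # Naive Bayes over binned features: the vectors mix small counts,
        # ordinal grades and a bounded sentiment score, which are
        # multimodal within classes; equal-width binning with add-one
        # smoothing models them far better than a single Gaussian and
        # avoids variance collapse on near-constant counts
        n_bins = hp.pop("n_bins", 5)
        hp.setdefault("alpha", 1.0)
        hp.setdefault("min_categories", n_bins)
        return Pipeline(
            [
                ("bin", KBinsDiscretizer(n_bins=n_bins, encode="ordinal", strategy="uniform")),
                ("nb", CategoricalNB(**hp)),
            ]
        )
    if m == "complement-naive-bayes":
        # complement-frequency estimate with add-one smoothing; the dense
        # grade/count/score features are one-hot binned first so they act
        # as the occurrence counts the complement estimate expects
        n_bins = hp.pop("n_bins", 5)
        hp.setdefault("alpha", 1.0)
        return Pipeline(
            [
                ("bin", KBinsDiscretizer(n_bins=n_bins, encode="onehot-dense", strategy="uniform")),
                ("cnb", ComplementNB(**hp)),
            ]
        )
    if m in {"decision-tree-pruned", "best-first-tree", "reduced-error-pruning-tree"}:
        # one pruned-tree implementation with pruning-strategy flags; the
        # three roster names differ only in how aggressively they prune
        pruning = {
            "decision-tree-pruned": {"ccp_alpha": 0.005},
            "best-first-tree": {"max_leaf_nodes": 16},
            "reduced-error-pruning-tree": {"ccp_alpha": 0.01, "min_samples_leaf": 2},
        }[m]
        for k, v in pruning.items():
            hp.setdefault(k, v)
        hp.setdefault("random_state", spec.seed)
        return DecisionTreeClassifier(**hp)
    if m == "random-forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("random_state", spec.seed)
        return RandomForestClassifier(**hp)
    if m == "sentiment-rule":
        return _SentimentRule()
    raise AssertionError(m)


class _SentimentRule:
    """Training-free predictor for the comments question: argmax over the
    one-hot sentiment-label block of the feature vector (assumed to be the
    trailing three columns, negative/neutral/positive)."""

    classes_ = np.array([1, 2, 3])

    def fit(self, X, y=None):
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        block = X[:, -3:]
        return np.argmax(block, axis=1) + 1

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        block = X[:, -3:]
        s = block.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return block / s

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self


class OrdinalClassifier:
    """Frank-Hall-style binary decomposition over ordered integer classes."""

    def __init__(self, spec: ClassifierSpec, classes: Sequence[int]):
        self.spec = spec
        self.classes_ = sorted(set(int(c) for c in classes))
        if len(self.classes_) < 2:
            raise ValueError("ordinal decomposition needs k >= 2 classes")
        self._binaries: list = []
        self._constants: list[Optional[float]] = []

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self._binaries = []
        self._constants = []
        for thr in self.classes_[:-1]:
            target = (y > thr).astype(int)
            if target.min() == target.max():
                # degenerate threshold within a fold: constant probability
                self._binaries.append(None)
                self._constants.append(float(target[0]))
            else:
                est = _base_estimator(self.spec)
                est.fit(X, target)
                self._binaries.append(est)
                self._constants.append(None)
        return self

    def _exceed_probs(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = []
        for est, const in zip(self._binaries, self._constants):
            if est is None:
                cols.append(np.full(X.shape[0], const))
            else:
                proba = est.predict_proba(X)
                classes = list(est.classes_)  # Pipeline delegates to its final step
                idx = classes.index(1) if 1 in classes else None
                cols.append(proba[:, idx] if idx is not None else np.zeros(X.shape[0]))
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        return compose_ordinal_probabilities(self._exceed_probs(X))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        # argmax with ties toward the lower class
        idx = np.zeros(len(probs), dtype=int)
        for r, row in enumerate(probs):
            best = 0
            for j in range(1, len(row)):
                if row[j] > row[best] + 1e-12:
                    best = j
            idx[r] = best
        return np.asarray(self.classes_)[idx]


def compose_ordinal_probabilities(exceed: np.ndarray) -> np.ndarray:
    """Turn threshold probabilities [Pr(y>1), ..., Pr(y>k-1)] into class
    probabilities, clipping negative intermediate masses to 0 and
    renormalizing.  ``exceed`` is (n, k-1); the result is (n, k) with rows
    summing to 1."""
    exceed = np.atleast_2d(np.asarray(exceed, dtype=float))
    n, km1 = exceed.shape
    k = km1 + 1
    probs = np.empty((n, k))
    probs[:, 0] = 1.0 - exceed[:, 0]
    for i in range(1, k - 1):
        probs[:, i] = exceed[:, i - 1] - exceed[:, i]
    probs[:, k - 1] = exceed[:, -1]
    probs = np.clip(probs, 0.0, None)
    totals = probs.sum(axis=1, keepdims=True)
    uniform = np.full_like(probs, 1.0 / k)
    probs = np.where(totals > 0, probs / np.where(totals == 0, 1, totals), uniform)
    return probs


def ordinal_wrap(base: ClassifierSpec, k_classes: int = 3) -> ClassifierSpec:
    """Spec for the ordering-aware wrapper around ``base``."""
    if k_classes < 2:
        raise ValueError("ordinal wrapping needs k >= 2 classes")
    return ClassifierSpec(
        method=base.method,
        hyperparameters=base.hyperparameters,
        ordinal=True,
        seed=base.seed,
    )


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    schema_fingerprint: str
    classes: list[int]
    question_id: str = ""

    def predict(self, vectors: Sequence[FeatureVector]) -> np.ndarray:
        X = _stack(vectors, self.schema_fingerprint)
        return np.asarray(self.estimator.predict(X), dtype=int)

    def save(self, path: str | Path) -> None:
        import joblib

        path = Path(path)
        joblib.dump(self.estimator, path)
        sidecar = {
            "method": self.spec.method,
            "hyperparameters": self.spec.hyperparameters,
            "ordinal": self.spec.ordinal,
            "seed": self.spec.seed,
            "schema_fingerprint": self.schema_fingerprint,
            "classes": self.classes,
            "question_id": self.question_id,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _stack(vectors: Sequence[FeatureVector], fingerprint: Optional[str] = None) -> np.ndarray:
    if not vectors:
        raise ValueError("no feature vectors supplied")
    fp = vectors[0].schema_fingerprint
    for v in vectors:
        if v.schema_fingerprint != fp:
            raise ValueError("feature vectors come from different schemas")
    if fingerprint is not None and fp != fingerprint:
        raise ValueError("schema fingerprint mismatch between model and vectors")
    return np.asarray([v.values for v in vectors], dtype=float)


def train(vectors: Sequence[FeatureVector], spec: ClassifierSpec) -> TrainedModel:
    """Fit one model on gold-labelled vectors sharing a schema.

    Deterministic given the spec's seed; single-class data is a hard
    error.
    """
    X = _stack(vectors)
    y = np.asarray([v.gold for v in vectors])
    if any(g is None for g in (v.gold for v in vectors)):
        raise ValueError("all vectors must carry gold labels for training")
    y = y.astype(int)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2 and spec.method != "sentiment-rule":
        raise ValueError("training data contains a single class")
    if spec.ordinal:
        est: object = OrdinalClassifier(spec, classes=classes or [1, 2, 3])
        est.fit(X, y)
    else:
        est = _base_estimator(spec)
        est.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        schema_fingerprint=vectors[0].schema_fingerprint,
        classes=classes or [1, 2, 3],
        question_id=vectors[0].question_id,
    )


def cross_validate(
    vectors: Sequence[FeatureVector],
    spec: ClassifierSpec,
    plan: Optional[CrossValidationPlan] = None,
) -> ConfusionMatrix:
    """k-fold cross-validation pooling test-fold predictions into one
    confusion matrix.

    Folds are stratified when every class has at least k members,
    otherwise plain shuffled folds with a warning.  Deterministic for a
    fixed plan seed.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    plan = plan or CrossValidationPlan()
    n = len(vectors)
    if n < plan.k:
        raise ValueError(f"{n} instances cannot fill {plan.k} folds; use a smaller k")
    X = _stack(vectors)
    y = np.asarray([v.gold for v in vectors], dtype=int)
    classes = sorted(set(y.tolist()))
    counts = {c: int((y == c).sum()) for c in classes}
    if plan.stratified and min(counts.values()) >= plan.k:
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        splits = splitter.split(X, y)
    else:
        if plan.stratified:
            warnings.warn(
                "a class has fewer members than folds; falling back to plain random folds",
                stacklevel=2,
            )
        splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        splits = splitter.split(X)

    all_classes = classes if len(classes) >= 2 else [1, 2, 3]
    cm = ConfusionMatrix(labels=all_classes)
    for train_idx, test_idx in splits:
        fold_train = [vectors[i] for i in train_idx]
        fold_y = y[train_idx]
        if len(set(fold_y.tolist())) < 2 and spec.method != "sentiment-rule":
            # degenerate fold: predict the majority training class
            maj = int(np.bincount(fold_y).argmax())
            preds = np.full(len(test_idx), maj)
        else:
            model = train(fold_train, spec)
            preds = model.predict([vectors[i] for i in test_idx])
        for i, p in zip(test_idx, preds):
            cm.add(int(y[i]), int(p))
    return cm


#: per-question default methods of the published configuration
DEFAULT_QUESTION_SPECS: dict[str, ClassifierSpec] = {
    "Q3": ClassifierSpec("naive-bayes"),
    "Q4": ClassifierSpec("best-first-tree"),
    "Q5": ClassifierSpec("reduced-error-pruning-tree"),
    "Q6": ClassifierSpec("complement-naive-bayes"),
    "Q7": ClassifierSpec("naive-bayes"),
    "Q8": ClassifierSpec("decision-tree-pruned"),
    "Q9": ClassifierSpec("random-forest"),
    "Q10": ClassifierSpec("sentiment-rule"),
}
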