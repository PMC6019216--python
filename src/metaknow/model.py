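"""Supervised classifiers for Knowledge Type and the two hyperdimensions.

:class:`MetaKnowledgeClassifier` is a scikit-learn estimator (it
supports ``get_params``/``set_params``, clones cleanly and composes with
sklearn model selection).  Input ``X`` is a sequence of
:class:`~metaknow.features.FeatureVector` or plain feature dicts;
categorical values are one-hot encoded by a DictVectorizer whose
vocabulary is frozen on the training data.  The default learner is a
random forest with standard parameters (100 trees, sqrt-of-features
split candidates); an SVM learner is provided for like-for-like
comparisons and swapping learners changes only the fitted state, never
the evaluation plumbing.

``cross_validate`` implements the evaluation protocol used throughout:
stratified k-fold (k = 10 by default; grouped-by-document folds are
available), per-fold per-class precision/recall/F1, macro-averaged
across folds, plus an ``Average`` row that is the arithmetic mean of
the class rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction import DictVectorizer
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MetaKnowledgeClassifier",
    "CVResult",
    "cross_validate",
    "predict_hyperdimensions",
]

TASKS = ("knowledge_type", "new_knowledge", "research_hypothesis")
LEARNERS = ("random_forest", "svm")


def _as_dicts(X) -> List[Dict[str, object]]:
    dicts = []
    for x in X:
        if hasattr(x, "to_dict"):
            dicts.append(x.to_dict())
        elif isinstance(x, dict):
            dicts.append(x)
        else:
            raise TypeError(f"expected FeatureVector or dict, got {type(x).__name__}")
    names = None
    for d in dicts:
        keys = frozenset(d)
        if names is None:
            names = keys
        elif keys != names:
            raise ValueError(
                "mixed feature configurations: all vectors must share one "
                "feature name set"
            )
    return dicts


def _encode(dicts: List[Dict[str, object]]) -> List[Dict[str, object]]:
    """Booleans to 0/1 floats; strings stay categorical for one-hot."""
    out = []
    for d in dicts:
        enc = {}
        for k, v in d.items():
            if isinstance(v, bool):
                enc[k] = float(v)
            else:
                enc[k] = v
        out.append(enc)
    return out


class MetaKnowledgeClassifier(BaseEstimator, ClassifierMixin):
    """Classifier over named feature vectors.

    Parameters
    ----------
    task : str
        "knowledge_type" (6-way), "new_knowledge" or
        "research_hypothesis" (binary).
    learner : str
        "random_forest" (default) or "svm".
    n_estimators : int
        Forest size; 100 mirrors the library-standard default.
    random_state : int or None
        Seed; identical seeds give identical predictions.
    """

    def __init__(
        self,
        task: str = "knowledge_type",
        learner: str = "random_forest",
        n_estimators: int = 100,
        random_state: Optional[int] = None,
    ):
        self.task = task
        self.learner = learner
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _make_estimator(self):
        if self.learner == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features="sqrt",
                random_state=self.random_state,
            )
        if self.learner == "svm":
            return SVC(kernel="linear", random_state=self.random_state)
        raise ValueError(f"unknown learner {self.learner!r}; expected one of {LEARNERS}")

    def fit(self, X, y):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        y = np.asarray(list(y))
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain at least 2 classes")
        dicts = _encode(_as_dicts(X))
        self.vectorizer_ = DictVectorizer(sparse=False)
        M = self.vectorizer_.fit_transform(dicts)
        self.feature_names_ = frozenset(dicts[0])
        self.estimator_ = self._make_estimator()
        self.estimator_.fit(M, y)
        self.classes_ = self.estimator_.classes_
        return self

    def _transform(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        dicts = _encode(_as_dicts(X))
        if dicts and frozenset(dicts[0]) != self.feature_names_:
            raise ValueError(
                "feature configuration mismatch between fit and predict inputs"
            )
        return self.vectorizer_.transform(dicts)

    def predict(self, X) -> np.ndarray:
        return self.estimator_.predict(self._transform(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator_.predict_proba(self._transform(X))

    def positive_scores(self, X, positive=True) -> np.ndarray:
        """Confidence score for the positive class of a binary task.

        Class probability where the learner provides one (random forest),
        otherwise the signed decision-function margin (SVM).
        """
        M = self._transform(X)
        if hasattr(self.estimator_, "predict_proba"):
            proba = self.estimator_.predict_proba(M)
            idx = list(self.classes_).index(positive)
            return proba[:, idx]
        scores = self.estimator_.decision_function(M)
        # decision_function is oriented toward classes_[1]
        return scores if self.classes_[1] == positive else -scores


def predict_hyperdimensions(nk_model, rh_model, X):
    """Joint New Knowledge / Research Hypothesis prediction.

    The two labels are mutually exclusive; when both binary models fire
    on an instance, the one with the higher positive-class confidence
    wins and the other is forced false.  Returns ``(nk, rh, scores)``
    with boolean arrays and a ``(nk_scores, rh_scores)`` pair.
    """
    check_is_fitted(nk_model, "estimator_")
    check_is_fitted(rh_model, "estimator_")
    if nk_model.feature_names_ != rh_model.feature_names_:
        raise ValueError("models were trained with different feature configurations")
    nk = nk_model.predict(X).astype(bool)
    rh = rh_model.predict(X).astype(bool)
    nk_scores = nk_model.positive_scores(X)
    rh_scores = rh_model.positive_scores(X)
    both = nk & rh
    keep_nk = nk_scores >= rh_scores
    nk = nk & ~(both & ~keep_nk)
    rh = rh & ~(both & keep_nk)
    return nk, rh, (nk_scores, rh_scores)


@dataclass
class CVResult:
    """Cross-validation outcome.

    ``per_fold``: list of per-fold DataFrames (class x P/R/F1);
    ``table()``: per-class macro-average across folds plus the
    ``Average`` row; ``confusion``: aggregate confusion matrix (each
    instance tested exactly once); ``fold_of``: test-fold index per
    instance.
    """

    classes: list
    per_fold: list
    confusion: pd.DataFrame
    fold_of: np.ndarray
    k: int

    def table(self) -> pd.DataFrame:
        stacked = pd.concat(self.per_fold)
        agg = stacked.groupby(level=0, sort=False).mean()
        agg = agg.loc[[str(c) for c in self.classes]]
        avg = agg.mean()
        agg.loc["Average"] = avg
        return agg


def cross_validate(
    X,
    y,
    task: str = "knowledge_type",
    learner: str = "random_forest",
    k: int = 10,
    seed: Optional[int] = None,
    groups: Optional[Sequence] = None,
    n_estimators: int = 100,
) -> CVResult:
    """Stratified k-fold cross-validation with per-class P/R/F1 per fold.

    ``groups`` switches to grouped folds (e.g. by document id) instead
    of stratification.  Fold test sets partition the data.
    """
    X = list(X)
    y = np.asarray(list(y))
    if len(X) != len(y):
        raise ValueError("X and y differ in length")
    if len(X) < k:
        raise ValueError(f"need at least k={k} instances, got {len(X)}")
    classes = list(np.unique(y))
    # positive class first for binary boolean tasks (report layout)
    if set(classes) <= {True, False}:
        classes = [c for c in (True, False) if c in classes]

    proto = MetaKnowledgeClassifier(
        task=task, learner=learner, n_estimators=n_estimators, random_state=seed
    )
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(np.zeros(len(y)), y, groups=np.asarray(list(groups)))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(y)), y)

    per_fold = []
    fold_of = np.full(len(y), -1, dtype=int)
    agg_confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splits):
        fold_of[test_idx] = fold
        model = clone(proto)
        model.fit([X[i] for i in train_idx], y[train_idx])
        pred = model.predict([X[i] for i in test_idx])
        gold = y[test_idx]
        p, r, f, _ = precision_recall_fscore_support(
            gold, pred, labels=classes, zero_division=0
        )
        per_fold.append(
            pd.DataFrame(
                {"precision": p, "recall": r, "f1": f},
                index=[str(c) for c in classes],
            )
        )
        agg_confusion += confusion_matrix(gold, pred, labels=classes)

    confusion = pd.DataFrame(
        agg_confusion,
        index=[str(c) for c in classes],
        columns=[str(c) for c in classes],
    )
    return CVResult(classes, per_fold, confusion, fold_of, k)
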