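"""Metrics and analyses: P/R/F1 tables, majority baseline, Cohen's kappa,
feature–label Pearson correlation and ranking.

Result tables follow the two-class report layout used throughout this
task: one row per class (precision, recall, F1) plus an ``Average`` row
that is the arithmetic mean of the class rows.  F1 is 2PR/(P+R), defined
as 0 when P + R = 0 (so a never-predicted class scores 0 across the
board, as in a majority baseline).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRFRow",
    "KappaResult",
    "CorrelationResult",
    "prf_table",
    "majority_baseline",
    "cohens_kappa",
    "feature_label_correlation",
]


@dataclass(frozen=True)
class PRFRow:
    label: str
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class KappaResult:
    """Two-rater Cohen's kappa: (po - pe) / (1 - pe).

    When both raters assign a single identical class, pe = 1 and kappa
    is undefined: ``kappa`` is None and ``undefined`` is True.
    """

    kappa: Optional[float]
    observed_agreement: float
    expected_agreement: float
    n_items: int

    @property
    def undefined(self) -> bool:
        return self.kappa is None


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def prf_table(
    gold: Sequence, predicted: Sequence, classes: Optional[Sequence] = None
) -> pd.DataFrame:
    """Per-class precision/recall/F1 plus the arithmetic ``Average`` row.

    ``classes`` fixes row order; by default classes are listed in sorted
    order (with True before False for boolean labels, so the positive
    class leads).
    """
    gold = list(gold)
    predicted = list(predicted)
    if len(gold) != len(predicted):
        raise ValueError(
            f"label sequences differ in length: {len(gold)} vs {len(predicted)}"
        )
    if classes is None:
        observed = set(gold) | set(predicted)
        if observed <= {True, False}:
            classes = [c for c in (True, False) if c in observed]
        else:
            classes = sorted(observed, key=str)
    rows = []
    for cls in classes:
        tp = sum(1 for g, p in zip(gold, predicted) if g == cls and p == cls)
        fp = sum(1 for g, p in zip(gold, predicted) if g != cls and p == cls)
        fn = sum(1 for g, p in zip(gold, predicted) if g == cls and p != cls)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        rows.append(PRFRow(str(cls), precision, recall, _f1(precision, recall)))
    table = pd.DataFrame(
        [(r.label, r.precision, r.recall, r.f1) for r in rows],
        columns=["class", "precision", "recall", "f1"],
    )
    avg = table[["precision", "recall", "f1"]].mean()
    table.loc[len(table)] = ["Average", avg["precision"], avg["recall"], avg["f1"]]
    return table.set_index("class")


def majority_baseline(labels: Sequence, negative_class=None) -> pd.DataFrame:
    """P/R/F1 table for predicting the most frequent class everywhere.

    A frequency tie is broken toward ``negative_class`` (for boolean
    labels, ``False``) — the conservative choice for negative-majority
    tasks.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("majority baseline needs a non-empty label sequence")
    if negative_class is None and set(labels) <= {True, False}:
        negative_class = False
    counts = Counter(labels)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if negative_class is not None and negative_class in tied:
        majority = negative_class
    else:
        majority = sorted(tied, key=str)[0]
    return prf_table(labels, [majority] * len(labels))


def cohens_kappa(annotator_a: Sequence, annotator_b: Sequence) -> KappaResult:
    """Two-rater Cohen's kappa over an item-by-item contingency table."""
    a = list(annotator_a)
    b = list(annotator_b)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("kappa needs at least one item")
    n = len(a)
    po = sum(1 for x, y in zip(a, b) if x == y) / n
    counts_a, counts_b = Counter(a), Counter(b)
    categories = set(counts_a) | set(counts_b)
    pe = sum(counts_a[c] * counts_b[c] for c in categories) / (n * n)
    if pe >= 1.0:
        return KappaResult(None, po, pe, n)
    return KappaResult((po - pe) / (1 - pe), po, pe, n)


@dataclass
class CorrelationResult:
    """Pearson correlations between features and class indicators.

    ``r``: DataFrame features x classes; ``degenerate``: zero-variance
    features whose correlation is reported as 0 by convention.
    """

    r: pd.DataFrame
    degenerate: tuple

    def top_k(self, cls, k: int = 10) -> pd.Series:
        """Top-k features for one class, ranked by |r| (descending)."""
        col = self.r[cls]
        return col.reindex(col.abs().sort_values(ascending=False).index).head(k)

    def average_rank(self) -> pd.Series:
        """Mean per-class rank of each feature (rank 1 = most correlated),
        sorted so globally informative features come first."""
        ranks = self.r.abs().rank(ascending=False, axis=0)
        return ranks.mean(axis=1).sort_values()


def feature_label_correlation(
    matrix: pd.DataFrame, indicators
) -> CorrelationResult:
    """Pearson r of every (numeric) feature against each class indicator.

    ``indicators`` may be a DataFrame of binary columns (one per class)
    or a label sequence, which is expanded to one indicator per distinct
    label.  Zero-variance features get r = 0 and a degenerate flag.
    """
    if not isinstance(indicators, pd.DataFrame):
        labels = pd.Series(list(indicators))
        indicators = pd.DataFrame(
            {str(cls): (labels == cls).astype(float) for cls in sorted(labels.unique(), key=str)}
        )
    X = matrix.apply(pd.to_numeric, errors="coerce")
    X = X.loc[:, X.notna().all()]
    degenerate = tuple(col for col in X.columns if X[col].nunique() <= 1)
    out = {}
    for cls in indicators.columns:
        y = indicators[cls].to_numpy(dtype=float)
        col_r = {}
        y_std = y.std()
        for feat in X.columns:
            x = X[feat].to_numpy(dtype=float)
            if feat in degenerate or y_std == 0:
                col_r[feat] = 0.0
            else:
                col_r[feat] = float(np.corrcoef(x, y)[0, 1])
        out[cls] = col_r
    return CorrelationResult(pd.DataFrame(out), degenerate)
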