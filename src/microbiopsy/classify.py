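"""KNN and fuzzy-KNN classifiers with stratified 10-fold cross-validation.

The two headline classifiers are implemented natively:

* KNN — majority vote among the k Euclidean-nearest training points
  (default k = 5).  A vote tie is broken by the single nearest
  neighbor's label ("nearest" rule); a distance tie by the lowest
  training index, so predictions are exactly reproducible.
* Fuzzy KNN (Keller) — class memberships are inverse-distance weighted,
  u_c(q) = sum_{j in kNN} u_c(x_j) d_j^(-2/(m-1)) / sum_j d_j^(-2/(m-1)),
  with crisp training memberships; a query coinciding with a training
  point inherits that point's crisp label.  Memberships sum to 1.

Features are z-scored with training-set statistics before distances are
computed (mixed-unit features — pixel areas next to entropies — make raw
Euclidean distance meaningless); zero-variance features are dropped.
SVM (linear kernel) and random-forest (500 trees, 10 candidate features
per split) baselines are adapters over scikit-learn behind the same
fit/predict contract.  Cross-validation is stratified 10-fold with
standardization re-fit on each training fold (no leakage); both pooled
(summed counts) and fold-averaged metrics are reported, fold-averaged
being the primary summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evalmetrics import ClfScore, ConfusionCounts, clf_metrics, confusion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingSet:
    """Standardized training data: X (N x d), integer labels y, and the
    per-feature mean/sd fitted on X (zero-variance features dropped)."""

    x: np.ndarray           # standardized, kept features only
    y: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray        # boolean column filter over the raw features

    @classmethod
    def fit(cls, x: Sequence, y: Sequence) -> "TrainingSet":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y)
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError("X must be (N, d) with one label per row")
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        kept = sd > 0
        if not kept.all():
            logger.info("dropping %d zero-variance features",
                        int((~kept).sum()))
        return cls(x=(x[:, kept] - mean[kept]) / sd[kept], y=y,
                   mean=mean, sd=sd, kept=kept)

    def transform(self, q: Sequence) -> np.ndarray:
        q = np.atleast_2d(np.asarray(q, dtype=np.float64))
        return (q[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]


def _k_nearest(train_x: np.ndarray, query: np.ndarray, k: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the k nearest training rows per query.

    Stable sort on distance, so equidistant neighbors are taken in
    training-index order.
    """
    d = cdist(query, train_x, metric="euclidean")
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return order, np.take_along_axis(d, order, axis=1)


def knn_predict(train: TrainingSet, query: Sequence, k: int = 5) -> np.ndarray:
    """Majority-vote KNN with the "nearest" tie rule."""
    if k < 1 or k > train.x.shape[0]:
        raise ValueError(f"k={k} must be in [1, n_train]")
    q = train.transform(query)
    idx, _ = _k_nearest(train.x, q, k)
    neigh = train.y[idx]
    out = np.empty(q.shape[0], dtype=train.y.dtype)
    for r in range(q.shape[0]):
        labels, counts = np.unique(neigh[r], return_counts=True)
        top = counts.max()
        winners = labels[counts == top]
        if winners.size == 1:
            out[r] = winners[0]
        else:
            out[r] = neigh[r, 0]        # tie: nearest neighbor decides
    return out


def fuzzy_knn_predict(train: TrainingSet, query: Sequence, k: int = 5,
                      m: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Keller-style fuzzy KNN; returns (labels, memberships).

    Membership columns follow ``sorted(unique(train.y))``; each row sums
    to 1.
    """
    if k < 1 or k > train.x.shape[0]:
        raise ValueError(f"k={k} must be in [1, n_train]")
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")
    q = train.transform(query)
    classes = np.unique(train.y)
    idx, dist = _k_nearest(train.x, q, k)
    neigh = train.y[idx]

    u = np.zeros((q.shape[0], classes.size))
    exponent = -2.0 / (m - 1.0)
    for r in range(q.shape[0]):
        if dist[r, 0] <= 1e-12:
            # Coincident with a training point: inherit its crisp label.
            u[r, np.searchsorted(classes, neigh[r, 0])] = 1.0
            continue
        w = dist[r] ** exponent
        w /= w.sum()
        for c, cls in enumerate(classes):
            u[r, c] = w[neigh[r] == cls].sum()
    u = np.clip(u, 0.0, 1.0)     # shield against float round-off overshoot
    labels = classes[np.argmax(u, axis=1)]
    return labels, u


class KnnClassifier:
    """fit/predict wrapper over :func:`knn_predict`."""

    def __init__(self, k: int = 5):
        self.k = k
        self._train: TrainingSet | None = None

    def fit(self, x, y):
        self._train = TrainingSet.fit(x, y)
        return self

    def predict(self, x):
        return knn_predict(self._train, x, self.k)


class FuzzyKnnClassifier:
    """fit/predict wrapper over :func:`fuzzy_knn_predict`; keeps the last
    membership matrix in ``memberships_``."""

    def __init__(self, k: int = 5, m: float = 2.0):
        self.k = k
        self.m = m
        self._train: TrainingSet | None = None
        self.memberships_: np.ndarray | None = None

    def fit(self, x, y):
        self._train = TrainingSet.fit(x, y)
        return self

    def predict(self, x):
        labels, u = fuzzy_knn_predict(self._train, x, self.k, self.m)
        self.memberships_ = u
        return labels


class _SklearnAdapter:
    """Standardizes with training statistics, then delegates to sklearn."""

    def __init__(self, estimator):
        self._est = estimator
        self._train: TrainingSet | None = None

    def fit(self, x, y):
        self._train = TrainingSet.fit(x, y)
        self._est.fit(self._train.x, self._train.y)
        return self

    def predict(self, x):
        return self._est.predict(self._train.transform(x))


def baseline_adapter(name: str, seed: int = 0, **params):
    """SVM (linear kernel) or random-forest baseline behind the shared
    fit/predict contract.  Raises ValueError for an unknown backend."""
    if name == "svm_linear":
        return _SklearnAdapter(SVC(kernel="linear", random_state=seed, **params))
    if name == "random_forest":
        defaults = dict(n_estimators=500, max_features=10)
        defaults.update(params)
        return _SklearnAdapter(RandomForestClassifier(random_state=seed,
                                                      **defaults))
    raise ValueError(f"unknown baseline {name!r}; "
                     "expected 'svm_linear' or 'random_forest'")


def make_classifier(name: str, k: int = 5, m: float = 2.0, seed: int = 0):
    if name == "knn":
        return KnnClassifier(k=k)
    if name == "fknn":
        return FuzzyKnnClassifier(k=k, m=m)
    if name == "svm":
        return baseline_adapter("svm_linear", seed=seed)
    if name == "rf":
        return baseline_adapter("random_forest", seed=seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment per sample."""

    assignment: np.ndarray
    k_folds: int
    seed: int

    @classmethod
    def stratified(cls, y: Sequence, k_folds: int = 10, seed: int = 0
                   ) -> "FoldPlan":
        y = np.asarray(y)
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed)
        assignment = np.empty(y.shape[0], dtype=np.int32)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(y), y)):
            assignment[test_idx] = fold
        return cls(assignment=assignment, k_folds=k_folds, seed=seed)


@dataclass(frozen=True)
class CvResult:
    fold_counts: tuple[ConfusionCounts, ...]
    fold_scores: tuple[ClfScore, ...]
    pooled: ClfScore
    averaged: dict
    flagged_folds: tuple[int, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "per_fold": [s.as_dict() for s in self.fold_scores],
            "pooled": self.pooled.as_dict(),
            "fold_averaged": self.averaged,
            "flagged_folds": list(self.flagged_folds),
        }


def cross_validate(x: Sequence, y: Sequence, classifier, plan: FoldPlan,
                   positive=1) -> CvResult:
    """Stratified k-fold CV with per-fold standardization.

    Folds whose test split contains a single class are flagged (their
    class-conditional metrics are undefined) but still pooled.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    counts: list[ConfusionCounts] = []
    scores: list[ClfScore] = []
    flagged: list[int] = []
    for fold in range(plan.k_folds):
        test = plan.assignment == fold
        train = ~test
        classifier.fit(x[train], y[train])
        pred = classifier.predict(x[test])
        c = confusion(pred, y[test], positive=positive)
        if len(np.unique(y[test])) < 2:
            flagged.append(fold)
        counts.append(c)
        scores.append(clf_metrics(c))
    pooled_counts = counts[0]
    for c in counts[1:]:
        pooled_counts = pooled_counts + c
    pooled = clf_metrics(pooled_counts)
    keys = ("accuracy_pct", "accuracy_fraction", "sensitivity",
            "specificity", "bcr", "precision", "recall", "f_measure", "mcc")
    averaged = {}
    for key in keys:
        vals = [v for s in scores if not np.isnan(v := getattr(s, key))]
        averaged[key] = float(np.mean(vals)) if vals else float("nan")
    return CvResult(fold_counts=tuple(counts), fold_scores=tuple(scores),
                    pooled=pooled, averaged=averaged,
                    flagged_folds=tuple(flagged))
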