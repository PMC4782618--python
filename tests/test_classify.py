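"""KNN / fuzzy KNN classifiers, baselines and the CV protocol."""

import numpy as np
import pytest

from microbiopsy.classify import (
    FoldPlan,
    FuzzyKnnClassifier,
    KnnClassifier,
    TrainingSet,
    baseline_adapter,
    cross_validate,
    fuzzy_knn_predict,
    knn_predict,
)


def two_blob_data(rng, n=100, gap=6.0):
    x = np.vstack([rng.normal(0, 1, (n // 2, 5)),
                   rng.normal(gap, 1, (n - n // 2, 5))])
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    return x, y


def test_single_training_point_dominates(rng):
    ts = TrainingSet.fit([[1.0, 2.0, 3.0]], [1])
    pred = knn_predict(ts, rng.normal(0, 5, (7, 3)), k=1)
    assert (pred == 1).all()


def test_k1_reproduces_training_labels(rng):
    x, y = two_blob_data(rng, 40)
    ts = TrainingSet.fit(x, y)
    assert (knn_predict(ts, x, k=1) == y).all()


def test_knn_vs_full_sort_oracle(rng):
    x = rng.normal(0, 1, (30, 4))
    y = (rng.random(30) > 0.5).astype(int)
    q = rng.normal(0, 1, (12, 4))
    ts = TrainingSet.fit(x, y)
    pred = knn_predict(ts, q, k=5)
    qs = ts.transform(q)
    for row, p in zip(qs, pred):
        d = np.sqrt(((ts.x - row) ** 2).sum(axis=1))
        nearest = np.argsort(d, kind="stable")[:5]
        lab = y[nearest]
        vals, cnt = np.unique(lab, return_counts=True)
        expect = lab[0] if (len(vals) == 2 and cnt[0] == cnt[1]) \
            else vals[np.argmax(cnt)]
        assert p == expect


def test_knn_invariant_to_consistent_scaling(rng):
    """Pre-scaling all features leaves predictions unchanged because
    standardization is re-fit."""
    x, y = two_blob_data(rng, 60)
    q = rng.normal(3, 2, (20, 5))
    scale = np.array([1.0, 100.0, 0.01, 5.0, 42.0])
    a = knn_predict(TrainingSet.fit(x, y), q, k=5)
    b = knn_predict(TrainingSet.fit(x * scale, y), q * scale, k=5)
    assert (a == b).all()


def test_zero_variance_feature_dropped(rng):
    x, y = two_blob_data(rng, 40)
    x = np.hstack([x, np.full((40, 1), 3.0)])
    ts = TrainingSet.fit(x, y)
    assert ts.x.shape[1] == 5
    assert (knn_predict(ts, x, k=1) == y).all()


def test_fuzzy_memberships_sum_to_one(rng):
    x, y = two_blob_data(rng, 50)
    ts = TrainingSet.fit(x, y)
    _, u = fuzzy_knn_predict(ts, rng.normal(2, 3, (30, 5)), k=5)
    assert np.allclose(u.sum(axis=1), 1.0)
    assert (u >= 0).all() and (u <= 1).all()


def test_fuzzy_coincident_query_inherits_label(rng):
    x, y = two_blob_data(rng, 30)
    ts = TrainingSet.fit(x, y)
    labels, u = fuzzy_knn_predict(ts, x[:5], k=5)
    assert (labels == y[:5]).all()
    assert np.allclose(u.max(axis=1), 1.0)


def test_fuzzy_equal_distances_give_class_priors():
    """k = N with all-equal distances: memberships equal class
    proportions (closed form of the inverse-distance weighting)."""
    x = np.array([[1.0, 0], [0, 1], [-1, 0], [0, -1]])
    y = np.array([0, 0, 0, 1])
    ts = TrainingSet.fit(x, y)
    _, u = fuzzy_knn_predict(ts, np.array([[0.0, 0.0]]), k=4)
    assert np.allclose(u, [[0.75, 0.25]])


def test_fuzzy_large_m_approaches_uniform_vote(rng):
    x, y = two_blob_data(rng, 40, gap=3.0)
    ts = TrainingSet.fit(x, y)
    q = rng.normal(1.5, 1, (10, 5))
    _, u = fuzzy_knn_predict(ts, q, k=7, m=50.0)
    qs = ts.transform(q)
    for row, memb in zip(qs, u):
        d = np.sqrt(((ts.x - row) ** 2).sum(axis=1))
        lab = y[np.argsort(d, kind="stable")[:7]]
        uniform = np.array([(lab == c).mean() for c in np.unique(y)])
        assert np.allclose(memb, uniform, atol=0.02)


def test_baselines_on_separable_data(rng):
    x, y = two_blob_data(rng, 80)
    for name in ("svm_linear", "random_forest"):
        clf = baseline_adapter(name, seed=0)
        clf.fit(x, y)
        assert (clf.predict(x) == y).mean() == 1.0
    # two separated noisy arcs
    theta = rng.uniform(0, np.pi, 100)
    moon1 = np.c_[np.cos(theta), np.sin(theta)] + rng.normal(0, 0.1, (100, 2))
    moon2 = np.c_[1 - np.cos(theta), -1.5 - np.sin(theta)] + rng.normal(0, 0.1, (100, 2))
    xm = np.vstack([moon1, moon2])
    ym = np.r_[np.zeros(100, int), np.ones(100, int)]
    for name in ("svm_linear", "random_forest"):
        clf = baseline_adapter(name, seed=0)
        clf.fit(xm, ym)
        assert (clf.predict(xm) == ym).mean() >= 0.9


def test_random_forest_seeded_determinism(rng):
    x, y = two_blob_data(rng, 60, gap=2.0)
    p1 = baseline_adapter("random_forest", seed=3).fit(x, y).predict(x)
    p2 = baseline_adapter("random_forest", seed=3).fit(x, y).predict(x)
    assert (p1 == p2).all()


def test_unknown_baseline_rejected():
    with pytest.raises(ValueError):
        baseline_adapter("neural_net")


def test_fold_plan_stratified_1000():
    y = np.r_[np.zeros(500, int), np.ones(500, int)]
    plan = FoldPlan.stratified(y, k_folds=10, seed=1)
    sizes = np.bincount(plan.assignment)
    assert (sizes == 100).all()
    for fold in range(10):
        frac = y[plan.assignment == fold].mean()
        assert abs(frac - 0.5) <= 0.01


def test_cv_oracle_classifier_perfect(rng):
    x, y = two_blob_data(rng, 100)

    lookup = {row.tobytes(): label for row, label in zip(x, y)}

    class Oracle:
        """Returns the true label of every query (perfect classifier)."""

        def fit(self, xtr, ytr):
            return self

        def predict(self, xq):
            return np.array([lookup[row.tobytes()] for row in xq])

    plan = FoldPlan.stratified(y, k_folds=10, seed=0)
    res = cross_validate(x, y, Oracle(), plan)
    assert res.pooled.accuracy_fraction == 1.0
    for s in res.fold_scores:
        assert s.accuracy_fraction == 1.0


def test_cv_partition_invariance(rng):
    """Shuffling sample order (with the plan permuted identically) leaves
    the pooled counts unchanged."""
    x, y = two_blob_data(rng, 60)
    plan = FoldPlan.stratified(y, k_folds=5, seed=2)
    res1 = cross_validate(x, y, KnnClassifier(k=3), plan)
    perm = rng.permutation(60)
    plan2 = FoldPlan(assignment=plan.assignment[perm], k_folds=5, seed=2)
    res2 = cross_validate(x[perm], y[perm], KnnClassifier(k=3), plan2)
    assert res1.pooled.counts == res2.pooled.counts


def test_cv_single_class_fold_flagged(rng):
    x = rng.normal(0, 1, (20, 3))
    y = np.r_[np.zeros(18, int), np.ones(2, int)]
    plan = FoldPlan.stratified(y, k_folds=4, seed=0)
    res = cross_validate(x, y, KnnClassifier(k=1), plan)
    assert len(res.flagged_folds) == 2      # only 2 positives over 4 folds


def test_fuzzy_classifier_wrapper_exposes_memberships(rng):
    x, y = two_blob_data(rng, 40)
    clf = FuzzyKnnClassifier(k=5)
    clf.fit(x, y).predict(x[:9])
    assert clf.memberships_.shape == (9, 2)
    assert np.allclose(clf.memberships_.sum(axis=1), 1.0)
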