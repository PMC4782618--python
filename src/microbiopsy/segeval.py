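"""Quantitative segmentation evaluation against ground truth.

Binary ROI masks are scored with pixel confusion rates (accuracy,
sensitivity, specificity, FPR) and general label rasters with three
label-permutation-invariant partition measures:

* PRI — probabilistic Rand index: the fraction of unordered pixel pairs
  on which the two partitions agree about same-label vs different-label.
  With a single ground truth the pairwise probabilities are 0/1 and PRI
  reduces to the plain Rand index.
* VOI — variation of information, H(X) + H(Y) - 2 I(X; Y), computed from
  the joint label contingency table in nats (natural log).  VOI >= 0 with
  equality iff the partitions coincide up to relabeling.
* GCE — global consistency error: the symmetrized mean of the local
  refinement errors E(S, G, p) = |R(S,p) \\ R(G,p)| / |R(S,p)|, taking the
  minimum of the two directional sums.  GCE is 0 when either partition
  refines the other.

All three are computed from the contingency table in O(pixels + labels^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "SegScore", "pixel_confusion", "pri", "voi",
           "gce", "score_segmentation"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class SegScore:
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    pri: float
    gce: float
    voi: float
    undefined: tuple[str, ...] = field(default=())


def _as_binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def pixel_confusion(test: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """TP/TN/FP/FN over aligned binary masks (1 = nucleus)."""
    test, gt = _as_binary(test), _as_binary(gt)
    if test.shape != gt.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {gt.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(test & gt)),
        tn=int(np.count_nonzero(~test & ~gt)),
        fp=int(np.count_nonzero(test & ~gt)),
        fn=int(np.count_nonzero(~test & gt)),
    )


def _contingency(s: np.ndarray, g: np.ndarray) -> np.ndarray:
    s = np.asarray(s).ravel()
    g = np.asarray(g).ravel()
    if s.shape != g.shape:
        raise ValueError("label rasters must share a shape")
    _, si = np.unique(s, return_inverse=True)
    _, gi = np.unique(g, return_inverse=True)
    ns, ng = si.max() + 1, gi.max() + 1
    table = np.zeros((ns, ng), dtype=np.int64)
    np.add.at(table, (si, gi), 1)
    return table


def pri(test: np.ndarray, gt: np.ndarray) -> float:
    """Probabilistic Rand index between two label rasters.

    Pair-counting identity: with contingency counts n_ij, row sums a_i and
    column sums b_j over N pixels,
    agreements = C(N,2) + 2*sum C(n_ij,2) - sum C(a_i,2) - sum C(b_j,2).
    """
    table = _contingency(test, gt)
    n = int(table.sum())
    if n < 2:
        raise ValueError("PRI needs at least 2 pixels")
    def comb2(x):
        return (x * (x - 1)) // 2
    total = comb2(n)
    s11 = int(comb2(table).sum())
    sa = int(comb2(table.sum(axis=1)).sum())
    sb = int(comb2(table.sum(axis=0)).sum())
    agreements = total + 2 * s11 - sa - sb
    return agreements / total


def voi(test: np.ndarray, gt: np.ndarray) -> float:
    """Variation of information (nats) between two label rasters."""
    table = _contingency(test, gt).astype(np.float64)
    n = table.sum()
    p = table / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hx, hy = ent(px), ent(py)
    nz = p > 0
    mi = float((p[nz] * (np.log(p[nz])
                         - np.log(np.outer(px, py)[nz]))).sum())
    return max(hx + hy - 2.0 * mi, 0.0)


def gce(test: np.ndarray, gt: np.ndarray) -> float:
    """Global consistency error between two label rasters (in [0, 1])."""
    table = _contingency(test, gt).astype(np.float64)
    n = table.sum()
    a = table.sum(axis=1)   # test-segment sizes
    b = table.sum(axis=0)   # gt-segment sizes
    with np.errstate(invalid="ignore", divide="ignore"):
        e_sg = (table * (a[:, None] - table) / a[:, None])
        e_gs = (table * (b[None, :] - table) / b[None, :])
    e_sg = np.nan_to_num(e_sg).sum()
    e_gs = np.nan_to_num(e_gs).sum()
    return float(min(e_sg, e_gs) / n)


def score_segmentation(test: np.ndarray, gt: np.ndarray) -> SegScore:
    """All seven segmentation measures for a binary test/gt mask pair.

    Metrics with a zero denominator are reported as NaN and listed in
    ``undefined`` rather than silently set to 0.
    """
    counts = pixel_confusion(test, gt)
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = ratio(counts.tp + counts.tn, counts.n, "accuracy")
    sensitivity = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    specificity = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    fpr = ratio(counts.fp, counts.fp + counts.tn, "fpr")
    test_b = _as_binary(test).astype(np.int8)
    gt_b = _as_binary(gt).astype(np.int8)
    return SegScore(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        fpr=fpr,
        pri=pri(test_b, gt_b),
        gce=gce(test_b, gt_b),
        voi=voi(test_b, gt_b),
        undefined=tuple(undefined),
    )
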