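"""Brute-force reference implementations shared by the metric tests.

These deliberately use naive loops and dict/set arithmetic, independent
of the package's contingency-table implementations.
"""

import math

import numpy as np


def pri_oracle(s, g):
    """O(N^2) loop over all unordered pixel pairs."""
    s, g = np.ravel(s), np.ravel(g)
    n = len(s)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            agree += (s[i] == s[j]) == (g[i] == g[j])
    return agree / total


def voi_oracle(s, g):
    s, g = np.ravel(s), np.ravel(g)
    n = len(s)

    def h(labels):
        return -sum((c / n) * math.log(c / n)
                    for c in np.bincount(np.unique(labels, return_inverse=True)[1]))

    joint = {}
    for a, b in zip(s, g):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    ps = {a: np.sum(s == a) / n for a in set(s)}
    pg = {b: np.sum(g == b) / n for b in set(g)}
    mi = sum((c / n) * math.log((c / n) / (ps[a] * pg[b]))
             for (a, b), c in joint.items())
    return h(s) + h(g) - 2 * mi


def gce_oracle(s, g):
    """Literal per-pixel set-difference loops in both directions."""
    s, g = np.ravel(s), np.ravel(g)
    n = len(s)

    def directional(a, b):
        total = 0.0
        for p in range(n):
            ra = {q for q in range(n) if a[q] == a[p]}
            rb = {q for q in range(n) if b[q] == b[p]}
            total += len(ra - rb) / len(ra)
        return total

    return min(directional(s, g), directional(g, s)) / n


def all_partitions(n):
    """Every set partition of range(n), as a label vector."""
    if n == 0:
        yield []
        return
    for part in all_partitions(n - 1):
        k = max(part) + 1 if part else 0
        for c in range(k + 1):
            yield part + [c]
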