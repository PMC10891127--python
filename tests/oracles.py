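"""Independent reference implementations used only by the tests.

These deliberately take the slow, exhaustive route: dynamic programming
for exact one-dimensional k-means, explicit enumeration for hypergeometric
tails and for the region-resampling intertumor score, so the fast package
code is checked against something that shares none of its machinery.
"""

from __future__ import annotations

import itertools

import numpy as np


def exact_kmeans_1d(x: np.ndarray, k: int) -> np.ndarray:
    """Globally optimal 1-D k-means labels via dynamic programming.

    Optimal 1-D clusters are contiguous runs of the sorted values, so the
    problem reduces to an optimal segmentation solvable exactly in
    O(k n^2). Returns labels aligned to the input order.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    k = min(k, n)
    # cost[i][j] = within-SS of xs[i..j] inclusive, from prefix sums
    ps = np.concatenate([[0.0], np.cumsum(xs)])
    ps2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def cost(i, j):
        m = j - i + 1
        s = ps[j + 1] - ps[i]
        return (ps2[j + 1] - ps2[i]) - s * s / m

    INF = float("inf")
    D = np.full((k + 1, n), INF)
    back = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        D[1][j] = cost(0, j)
    for m in range(2, k + 1):
        for j in range(m - 1, n):
            best, arg = INF, m - 1
            for i in range(m - 1, j + 1):
                c = D[m - 1][i - 1] + cost(i, j)
                if c < best - 1e-15:
                    best, arg = c, i
            D[m][j], back[m][j] = best, arg
    labels_sorted = np.zeros(n, dtype=int)
    j = n - 1
    for m in range(k, 0, -1):
        i = back[m][j] if m > 1 else 0
        labels_sorted[i : j + 1] = m - 1
        j = i - 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(|draw of size n intersects first K| >= k) by explicit enumeration."""
    universe = range(N)
    set_a = set(range(K))
    total = 0
    hits = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(set_a.intersection(combo)) >= k:
            hits += 1
    return hits / total


def intertumor_sd_enumeration(X: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """All cross-patient SDs over every one-region-per-patient combination.

    Returns (mean over combinations, per-combination SD matrix of shape
    (n_combos, n_genes)) so callers can form exact Monte-Carlo standard
    errors.
    """
    all_sds = []
    for combo in itertools.product(*groups):
        all_sds.append(X[:, list(combo)].std(axis=1, ddof=1))
    all_sds = np.array(all_sds)
    return all_sds.mean(axis=0), all_sds
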