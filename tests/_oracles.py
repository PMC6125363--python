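"""Independent brute-force reference implementations used only by tests.

Deliberately naive (O(n^2)/O(n^3) loops, textbook formulas) so they share
no code path with the package.
"""

import itertools

import numpy as np


def brute_force_u(x, y) -> float:
    """Mann-Whitney U for x: count of pairwise wins plus half-ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def bh_stepup(p):
    """Benjamini-Hochberg step-up reference: m*p/rank with cumulative min."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


def pearson_textbook(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def auc_pairwise(labels, scores) -> float:
    """O(n^2) AUC: fraction of (positive, negative) pairs won, ties half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def chi2_textbook(table) -> float:
    """Pearson chi-square statistic: sum (O-E)^2 / E from the marginals."""
    t = np.asarray(table, dtype=float)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


def agglomerate_naive(points, method: str):
    """O(n^3) agglomerative clustering; returns sorted merge heights.

    ``complete`` = max pairwise Euclidean distance between clusters,
    ``average`` = mean pairwise. Ties merge the lowest-index pair first
    (heights are compared as sorted multisets, so tie policy is moot).
    """
    pts = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(pts))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = [
                np.linalg.norm(pts[i] - pts[j])
                for i in clusters[a]
                for j in clusters[b]
            ]
            dist = max(d) if method == "complete" else float(np.mean(d))
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def fleiss_kappa_hand(grid) -> float:
    """Fleiss' kappa from first principles on a cases x raters grid."""
    grid = np.asarray(grid)
    cats = sorted({v for row in grid for v in row})
    counts = np.array([[np.sum(row == c) for c in cats] for row in grid], dtype=float)
    n = counts.sum(axis=1)[0]
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = (p_j**2).sum()
    return float((p_bar - p_e) / (1 - p_e))
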