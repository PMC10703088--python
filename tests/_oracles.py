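"""Independent brute-force re-implementations used as test oracles.

Everything here is deliberately naive (explicit loops, dense eigensolvers)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def _beats(si: float, sj: float, regulation: str) -> bool:
    """Pairwise win predicate; exact ties count as a win for both sides."""
    if regulation == "up":
        return si >= sj
    if regulation == "down":
        return si <= sj
    return abs(si) >= abs(sj)


def naive_intersection(tables, regulation):
    """Literal per-pair, per-dataset transcription of the intersection scheme.

    ``tables`` is a list of gene->logFC dicts.  Returns (genes, W, L, n).
    """
    common = set(tables[0])
    for t in tables[1:]:
        common &= set(t)
    genes = sorted(common)
    N, k = len(genes), len(tables)
    W = np.zeros((N, N), dtype=int)
    L = np.zeros((N, N), dtype=int)
    n = np.zeros((N, N), dtype=int)
    for scores in tables:
        for i, gi in enumerate(genes):
            for j, gj in enumerate(genes):
                if i == j:
                    continue
                if _beats(scores[gi], scores[gj], regulation):
                    W[i, j] += 1
                else:
                    L[i, j] += 1
                n[i, j] += 1
    return genes, W, L, n


def naive_union(tables, regulation, thres):
    """Literal transcription of the union scheme with zero padding.

    Candidates pass the filter in >= 1 dataset; a candidate present in a
    dataset competes there with its original score; pairs not co-present
    contribute zeros.
    """

    def passes(v):
        if regulation == "up":
            return v > thres
        if regulation == "down":
            return v < -thres
        return abs(v) > thres

    candidates = set()
    for scores in tables:
        candidates |= {g for g, v in scores.items() if passes(v)}
    genes = sorted(candidates)
    N = len(genes)
    W = np.zeros((N, N), dtype=int)
    L = np.zeros((N, N), dtype=int)
    n = np.zeros((N, N), dtype=int)
    for scores in tables:
        for i, gi in enumerate(genes):
            for j, gj in enumerate(genes):
                if i == j or gi not in scores or gj not in scores:
                    continue
                if _beats(scores[gi], scores[gj], regulation):
                    W[i, j] += 1
                else:
                    L[i, j] += 1
                n[i, j] += 1
    return genes, W, L, n


def dense_stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix via dense eig."""
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def dense_pagerank(A: np.ndarray, alpha: float = 0.85) -> np.ndarray:
    """Damped PageRank by dense eigendecomposition of the Google matrix."""
    N = A.shape[0]
    Z = A.astype(float)
    rowsum = Z.sum(axis=1)
    dangling = rowsum == 0
    Z[dangling] = 1.0 / N
    Z[~dangling] /= rowsum[~dangling, None]
    G = alpha * Z + (1.0 - alpha) / N
    return dense_stationary(G)


def dense_markov(L: np.ndarray) -> np.ndarray:
    """Stationary distribution of the binary losers-vote chain via dense eig."""
    N = L.shape[0]
    V = (L > 0).astype(float)
    rowsum = V.sum(axis=1)
    dangling = rowsum == 0
    V[dangling] = 1.0 / N
    V[~dangling] /= rowsum[~dangling, None]
    return dense_stationary(V)


def trapezoid_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    thresholds = np.unique(scores)[::-1]
    P = labels.sum()
    Nn = len(labels) - P
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        called = scores >= t
        tpr.append(np.sum(called & labels) / P)
        fpr.append(np.sum(called & ~labels) / Nn)
    return float(np.trapezoid(tpr, fpr))
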