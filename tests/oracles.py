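"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (explicit loops, dense algebra)
and independent of the package's computation paths.
"""

from __future__ import annotations

import numpy as np


def silhouette_brute(coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette via explicit pairwise distances."""
    n = coords.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(np.sum((coords[i] - coords[j]) ** 2))
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own) & (np.arange(n) != i)
        if not same.any():
            s[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == l].mean() for l in uniq if l != own)
        s[i] = (b - a) / max(a, b)
    return s


def dbi_brute(coords: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index via explicit per-cluster scatter and
    centroid distances."""
    uniq = np.unique(labels)
    centroids = {}
    scatter = {}
    for l in uniq:
        pts = coords[labels == l]
        c = pts.mean(axis=0)
        centroids[l] = c
        scatter[l] = np.mean([np.sqrt(np.sum((p - c) ** 2)) for p in pts])
    ratios = []
    for l in uniq:
        worst = 0.0
        for l2 in uniq:
            if l2 == l:
                continue
            dist = np.sqrt(np.sum((centroids[l] - centroids[l2]) ** 2))
            worst = max(worst, (scatter[l] + scatter[l2]) / dist)
        ratios.append(worst)
    return float(np.mean(ratios))


def ols_brute(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Hand-solved normal equations beta = (X^T X)^{-1} X^T y."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


def tsca_dense_top_component(Zc: np.ndarray, Q: np.ndarray):
    """Top eigenpair of the dense P x P matrix M = Z Q Z^T."""
    M = Zc @ Q @ Zc.T
    lam, vec = np.linalg.eigh(M)
    return float(lam[-1]), vec[:, -1]


def mode_filter_brute(assignment: np.ndarray, kernel: int, background_votes: bool):
    """Neighborhood-mode label filter by explicit looping."""
    H, W = assignment.shape
    r = kernel // 2
    out = np.zeros_like(assignment)
    for i in range(H):
        for j in range(W):
            if assignment[i, j] == 0:
                continue
            window = assignment[
                max(i - r, 0) : i + r + 1, max(j - r, 0) : j + r + 1
            ].ravel()
            # out-of-image area counts as background
            n_outside = kernel * kernel - window.size
            labels, counts = np.unique(window[window > 0], return_counts=True)
            bg = (window == 0).sum() + n_outside
            if labels.size == 0:
                continue
            best = labels[np.argmax(counts)]
            if background_votes and bg > counts.max():
                continue
            if not background_votes and counts.sum() <= 1:
                continue
            out[i, j] = best
    return out
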