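"""Evaluation of retinotopic maps.

Two families of metrics are provided: image-comparison statistics
against a known ground-truth response (simulation only) and cluster-
separation indices of the assembled map (simulation and experiment),
including penalized "adjusted" variants that charge a map for wrong
cluster counts and deviant cluster sizes.

Cluster indices treat every selected (nonzero-label) pixel as a data
point with its (row, col) coordinates as features: they measure the
spatial separation of the activity centers, not score contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity
from sklearn.metrics import davies_bouldin_score, silhouette_samples

from .core import RetinotopicMap

__all__ = [
    "ClusterEval",
    "image_stats",
    "silhouette_map",
    "dbi_map",
    "adjusted_indices",
]

#: PSNR reported for a perfect (zero-MSE) reconstruction, in dB
PSNR_CAP = 100.0


@dataclass
class ClusterEval:
    """Cluster-separation summary of one retinotopic map."""

    si_median: float = np.nan
    dbi: float = np.nan
    adjusted_si: float = np.nan
    adjusted_dbi: float = np.nan
    n_clusters_found: int = 0
    cluster_sizes: list = field(default_factory=list)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant image: correlation undefined, reported as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def image_stats(result: np.ndarray, truth: np.ndarray) -> dict:
    """Six image-comparison statistics between a score map and truth.

    Both images are expected in [0, 1].  Returns mse, psnr (capped at
    100 dB for a perfect match), cnr (foreground/background contrast of
    the result using truth's partition at 0.5), mssim (local SSIM with
    an 11 x 11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03, unit
    dynamic range), cc (Pearson over all pixels) and cp (Pearson of the
    3 x 3 Laplacian-filtered images, an edge-preservation measure).
    """
    result = np.asarray(result, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if result.shape != truth.shape:
        raise ValueError("result and truth must share a shape")
    diff = result - truth
    mse = float(np.mean(diff**2))
    psnr = PSNR_CAP if mse == 0 else min(10 * np.log10(1.0 / mse), PSNR_CAP)
    fg = truth >= 0.5
    bg = ~fg
    if not fg.any() or not bg.any():
        raise ValueError("truth must contain both foreground (>= 0.5) and background")
    sd_bg = result[bg].std()
    cnr = float((result[fg].mean() - result[bg].mean()) / sd_bg) if sd_bg > 0 else 0.0
    win = min(11, min(result.shape))
    if win % 2 == 0:
        win -= 1
    mssim = float(
        structural_similarity(
            result,
            truth,
            win_size=win,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
    )
    cc = _pearson(result, truth)
    lap_kernel = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
    cp = _pearson(
        ndimage.convolve(result, lap_kernel, mode="nearest"),
        ndimage.convolve(truth, lap_kernel, mode="nearest"),
    )
    return {"mse": mse, "psnr": psnr, "cnr": cnr, "mssim": mssim, "cc": cc, "cp": cp}


def _check_clusters(m: RetinotopicMap) -> tuple[np.ndarray, np.ndarray]:
    coords, labels = m.selected_points()
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError(
            f"cluster indices need at least 2 labels, found {uniq.size}; "
            "the map is degenerate"
        )
    if np.any(counts < 2):
        warnings.warn("cluster(s) with a single pixel present; indices may degenerate")
    return coords, labels


def silhouette_map(m: RetinotopicMap) -> ClusterEval:
    """Median per-pixel silhouette of the selected pixels.

    s(i) = (b_i - a_i) / max(a_i, b_i) with a_i the mean intra-cluster
    distance and b_i the smallest mean distance to another cluster,
    on Euclidean pixel coordinates.
    """
    coords, labels = _check_clusters(m)
    s = silhouette_samples(coords, labels)
    uniq, counts = np.unique(labels, return_counts=True)
    return ClusterEval(
        si_median=float(np.median(s)),
        n_clusters_found=int(uniq.size),
        cluster_sizes=counts.tolist(),
    )


def dbi_map(m: RetinotopicMap) -> ClusterEval:
    """Davies-Bouldin index of the selected pixels.

    Mean over clusters of the worst (S_c + S_c') / d(centroid_c,
    centroid_c') ratio, with S_c the mean distance of members to their
    centroid.  Lower is better; coincident centroids yield infinity.
    """
    coords, labels = _check_clusters(m)
    uniq, counts = np.unique(labels, return_counts=True)
    centroids = np.stack([coords[labels == l].mean(axis=0) for l in uniq])
    dists = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    if np.any(dists[~np.eye(uniq.size, dtype=bool)] == 0):
        warnings.warn("coincident cluster centroids: DBI reported as inf")
        dbi = np.inf
    elif len(labels) > uniq.size:
        dbi = float(davies_bouldin_score(coords, labels))
    else:
        # every cluster a single pixel: zero scatter everywhere
        dbi = 0.0
    return ClusterEval(
        dbi=dbi, n_clusters_found=int(uniq.size), cluster_sizes=counts.tolist()
    )


def _activity_centers(m: RetinotopicMap) -> int:
    """Number of 8-connected components, counted per label."""
    struct = np.ones((3, 3), dtype=bool)
    total = 0
    for l in m.labels:
        _, n = ndimage.label(m.assignment == l, structure=struct)
        total += n
    return total


def adjusted_indices(
    m: RetinotopicMap,
    expected_n: int,
    expected_sizes: list | None = None,
    lambda_size: float = 1.0,
    lambda_count: float = 1.0,
) -> ClusterEval:
    """Penalized silhouette / Davies-Bouldin indices.

    The silhouette is reduced (and the DBI increased) by two additive
    penalty terms: the mean relative deviation of the expected
    clusters' sizes from their expected size, and the relative
    deviation of the number of extracted activity centers (8-connected
    components) from the expected stimulus count.  Penalties only ever
    worsen the indices; the additive form keeps the DBI penalty
    effective even when heavy selection leaves few, tight clusters
    with a small base index.
    """
    if expected_n < 1:
        raise ValueError("expected_n must be >= 1")
    si = silhouette_map(m)
    db = dbi_map(m)
    sizes = np.array(
        [int((m.assignment == l).sum()) for l in range(1, expected_n + 1)], dtype=float
    )
    if expected_sizes is None:
        e_bar = float(m.value.size * 0.1 / expected_n)  # uniform expectation
        expected = np.full(expected_n, e_bar)
    else:
        expected = np.asarray(expected_sizes, dtype=float)
        if expected.size != expected_n:
            raise ValueError("expected_sizes must have expected_n entries")
        e_bar = float(expected.mean())
    size_pen = float(np.mean(np.abs(sizes - e_bar) / e_bar))
    n_centers = _activity_centers(m)
    count_pen = abs(n_centers - expected_n) / expected_n
    adj_si = si.si_median - lambda_size * size_pen - lambda_count * count_pen
    adj_dbi = db.dbi + lambda_size * size_pen + lambda_count * count_pen
    return ClusterEval(
        si_median=si.si_median,
        dbi=db.dbi,
        adjusted_si=float(adj_si),
        adjusted_dbi=float(adj_dbi),
        n_clusters_found=si.n_clusters_found,
        cluster_sizes=si.cluster_sizes,
    )
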