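"""Retinotopic map assembly and post-processing.

Per-stimulus score maps are combined by per-pixel argmax (hue = winning
stimulus, value = its score), thresholded at a percentile of the
maximum-score distribution, cleaned of salt noise with a label-mode
filter, and rendered as an HSV image.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from matplotlib.image import imsave

from .core import RetinotopicMap, ScoreMapSet

__all__ = ["assemble_map", "despeckle", "render_map"]


def assemble_map(
    scores: ScoreMapSet,
    percentile: float = 90.0,
    include_zeros: bool = True,
) -> RetinotopicMap:
    """Combine per-stimulus score maps into a single labeled map.

    Each pixel is assigned the stimulus with the highest score (ties go
    to the lowest stimulus index) with that score as its value; pixels
    whose value does not exceed the ``percentile`` of the max-score
    distribution are dropped to background.  The percentile is taken
    over all pixels' maximum scores by default, or over nonzero ones
    only with ``include_zeros=False``.
    """
    if scores.n == 0 or scores.maps.size == 0:
        raise ValueError("empty score map set")
    value = scores.maps.max(axis=0)
    assignment = scores.maps.argmax(axis=0) + 1
    pool = value.ravel() if include_zeros else value[value > 0].ravel()
    if pool.size == 0:
        cut = np.inf
    else:
        cut = np.percentile(pool, percentile)
    keep = value > cut
    assignment = np.where(keep, assignment, 0)
    value = np.where(keep, value, 0.0)
    return RetinotopicMap(assignment=assignment, value=value, percentile_cut=percentile)


def despeckle(
    m: RetinotopicMap, kernel: int = 3, background_votes: bool = True
) -> RetinotopicMap:
    """Remove salt noise with a neighborhood-mode (median-type) filter.

    Each selected pixel takes the majority label of its ``kernel x
    kernel`` neighborhood.  With ``background_votes=True`` (default,
    the classic median filter on the label image) background competes
    in the vote, so thin or isolated speckles surrounded by background
    are deleted; with ``background_votes=False`` only nonzero labels
    vote and solely isolated single pixels are removed.  The value
    image is rescaled over retained pixels (divided by its maximum so
    scores stay in (0, 1]).
    """
    if kernel % 2 == 0:
        raise ValueError("kernel size must be odd")
    from scipy.ndimage import uniform_filter

    labels = np.unique(m.assignment)
    labels = labels[labels > 0]
    if labels.size == 0:
        return RetinotopicMap(m.assignment.copy(), m.value.copy(), m.percentile_cut)
    # neighborhood counts of every label via a box filter on its mask
    counts = np.stack(
        [
            uniform_filter((m.assignment == l).astype(float), size=kernel, mode="constant")
            for l in labels
        ]
    ) * (kernel * kernel)
    counts = np.rint(counts).astype(int)
    mode_idx = counts.argmax(axis=0)
    mode_count = counts.max(axis=0)
    selected = m.assignment > 0
    if background_votes:
        bg_count = kernel * kernel - counts.sum(axis=0)
        drop = selected & (bg_count > mode_count)
    else:
        # isolated pixels: their own label is the only selected pixel nearby
        drop = selected & (counts.sum(axis=0) <= 1)
    new_assignment = np.where(selected & ~drop, labels[mode_idx], 0)
    new_value = np.where(new_assignment > 0, m.value, 0.0)
    vmax = new_value.max()
    if vmax > 0:
        new_value = new_value / vmax
    return RetinotopicMap(new_assignment, new_value, m.percentile_cut)


def render_map(m: RetinotopicMap, path, n_stimuli: int | None = None) -> None:
    """Write the map as an HSV-encoded PNG plus a JSON legend sidecar.

    Hue encodes the stimulus label (fixed, evenly spaced categorical
    palette in stimulus order), value encodes the score; background is
    black.
    """
    n = int(n_stimuli if n_stimuli is not None else max(m.labels.max(initial=1), 1))
    hsv = np.zeros((*m.assignment.shape, 3))
    sel = m.assignment > 0
    hsv[..., 0] = np.where(sel, (m.assignment - 1) / n, 0.0)
    hsv[..., 1] = np.where(sel, 1.0, 0.0)
    hsv[..., 2] = np.where(sel, m.value, 0.0)
    rgb = hsv_to_rgb(hsv)
    path = Path(path)
    try:
        imsave(path, rgb)
    except OSError as exc:
        raise IOError(f"cannot write map image {path}: {exc}") from exc
    legend = {
        str(k): {"hue": (k - 1) / n, "rgb": [float(c) for c in hsv_to_rgb([(k - 1) / n, 1.0, 1.0])]}
        for k in range(1, n + 1)
    }
    path.with_suffix(".legend.json").write_text(json.dumps(legend, indent=1))
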