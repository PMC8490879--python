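"""Domain types, movie I/O and the shared pre/post-processing transforms.

The universal carrier between pipeline stages is the :class:`FrameStack`,
a T x H x W fluorescence movie with its frame rate.  Stimulus timing is
carried by :class:`StimulusSchedule`; every localization method emits a
:class:`ScoreMapSet` (one score image per stimulus) which is assembled
into a :class:`RetinotopicMap`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FrameStack",
    "StimulusSchedule",
    "ScoreMapSet",
    "RetinotopicMap",
    "load_stack",
    "save_stack",
    "zscore_stack",
    "dff_stack",
    "rescale01",
]


@dataclass
class FrameStack:
    """A T x H x W real-valued movie with its acquisition rate.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Fluorescence values (arbitrary units).  Stored as float64.
    frame_rate : float
        Frames per second; must be positive.
    t0 : float, optional
        Time of the first frame in seconds.  Frame ``i`` occurs at
        ``t0 + i / frame_rate``.
    """

    data: np.ndarray
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a T x H x W array, got shape {self.data.shape}"
            )
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"stack contains {n_bad} non-finite (NaN/Inf) values")
        if self.data.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames (T >= 2)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Time of every frame in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def frame_index(self, t: float) -> int:
        """Index of the frame nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) * self.frame_rate))
        return min(max(i, 0), self.n_frames - 1)

    def as_matrix(self) -> np.ndarray:
        """Return the pixels-by-time matrix Z of shape (H*W, T)."""
        T = self.n_frames
        return self.data.reshape(T, -1).T


@dataclass
class StimulusSchedule:
    """Ordered stimulus onset times plus the expected response latency.

    ``latency`` is the delay (in seconds) between a stimulus onset and
    the peak (or template origin) of the evoked cortical response.
    """

    onsets: np.ndarray
    latency: float = 0.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64).ravel()
        if self.onsets.size < 1:
            raise ValueError("at least one stimulus onset is required")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")
        if self.latency < 0:
            raise ValueError("latency must be non-negative")

    @property
    def n(self) -> int:
        return self.onsets.size

    def inter_stimulus_interval(self) -> float:
        """Median spacing between consecutive onsets (the whole duration
        if only one stimulus was given)."""
        if self.n < 2:
            return np.inf
        return float(np.median(np.diff(self.onsets)))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"onsets": self.onsets.tolist(), "latency": self.latency})
        )

    @classmethod
    def from_json(cls, path) -> "StimulusSchedule":
        d = json.loads(Path(path).read_text())
        return cls(onsets=np.asarray(d["onsets"]), latency=float(d.get("latency", 0.0)))


@dataclass
class ScoreMapSet:
    """Per-stimulus H x W score images produced by a localization method."""

    maps: np.ndarray  # (n, H, W)
    method_name: str = ""

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("maps must be an n x H x W array")

    @property
    def n(self) -> int:
        return self.maps.shape[0]

    def rescaled(self) -> "ScoreMapSet":
        """Rescale every map to [0, 1] (constant maps become zeros)."""
        out = np.stack([rescale01(m) for m in self.maps])
        return ScoreMapSet(out, self.method_name)


@dataclass
class RetinotopicMap:
    """Per-pixel stimulus assignment (hue) and confidence score (value).

    Label 0 marks background / unselected pixels; labels 1..n identify
    the stimulus whose response dominates the pixel.
    """

    assignment: np.ndarray  # (H, W) int
    value: np.ndarray  # (H, W) float in [0, 1]
    percentile_cut: float = 90.0

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.intp)
        self.value = np.asarray(self.value, dtype=np.float64)
        if self.assignment.shape != self.value.shape:
            raise ValueError("assignment and value must share a shape")
        if np.any((self.assignment > 0) != (self.value > 0)):
            raise ValueError("assignment > 0 must coincide with value > 0")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the map."""
        lab = np.unique(self.assignment)
        return lab[lab > 0]

    def selected_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(coords, labels) of selected pixels; coords are (row, col)."""
        rr, cc = np.nonzero(self.assignment)
        coords = np.column_stack([rr, cc]).astype(float)
        return coords, self.assignment[rr, cc]


# ---------------------------------------------------------------------------
# I/O


def load_stack(path, frame_rate: float | None = None) -> FrameStack:
    """Load a movie from a multi-page TIFF or an ``.npz`` archive.

    TIFF files need an explicit ``frame_rate``; ``.npz`` archives carry
    their own (keys ``data`` and ``frame_rate``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read movie: no such file {path}")
    if path.suffix.lower() == ".npz":
        with np.load(path) as z:
            data = z["data"]
            rate = float(z["frame_rate"]) if "frame_rate" in z else frame_rate
        if rate is None:
            raise ValueError("archive carries no frame_rate and none was given")
        return FrameStack(np.asarray(data, dtype=np.float64), rate)
    if frame_rate is None:
        raise ValueError("frame_rate is required when loading a TIFF movie")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read movie {path}: {exc}") from exc
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected T x H x W pages, got shape {data.shape}")
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: movie contains {n_bad} NaN/Inf pixels")
    return FrameStack(data, frame_rate)


def save_stack(stack: FrameStack, path) -> None:
    """Write a movie as a float32 multi-page TIFF or an ``.npz`` archive."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        np.savez_compressed(
            path, data=stack.data.astype(np.float32), frame_rate=stack.frame_rate
        )
        return
    try:
        tifffile.imwrite(
            path, stack.data.astype(np.float32), photometric="minisblack"
        )
    except OSError as exc:
        raise IOError(f"cannot write movie {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Pre/post-processing transforms


def zscore_stack(stack: FrameStack, baseline: tuple[int, int] | None = None) -> FrameStack:
    """Z-score every pixel's time series.

    The mean and (population) standard deviation are taken over the full
    series by default, or over the frame range ``baseline`` when given
    (e.g. a pre-stimulus window).  Constant pixels map to all-zeros with
    a warning rather than raising.
    """
    data = stack.data
    ref = data if baseline is None else data[baseline[0] : baseline[1]]
    if ref.shape[0] == 0:
        raise ValueError("empty baseline window")
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant pixel(s) z-scored to 0")
    sd_safe = np.where(flat, 1.0, sd)
    out = (data - mu) / sd_safe
    out[:, flat] = 0.0
    return FrameStack(out, stack.frame_rate, stack.t0)


def dff_stack(stack: FrameStack, baseline_window: tuple[int, int]) -> FrameStack:
    """Fractional fluorescence change (F - F0)/F0 per pixel.

    ``F0`` is the mean over the frame range ``baseline_window``; pixels
    with ``F0 == 0`` are set to zero with a warning.
    """
    lo, hi = baseline_window
    if not (0 <= lo < hi <= stack.n_frames):
        raise ValueError(f"baseline window {baseline_window} outside [0, {stack.n_frames}]")
    f0 = stack.data[lo:hi].mean(axis=0)
    zero = f0 == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} pixel(s) with zero baseline set to 0")
    if np.any(f0 < 0):
        warnings.warn("negative baseline fluorescence encountered")
    f0_safe = np.where(zero, 1.0, f0)
    out = (stack.data - f0) / f0_safe
    out[:, zero] = 0.0
    return FrameStack(out, stack.frame_rate, stack.t0)


def rescale01(image: np.ndarray) -> np.ndarray:
    """Affinely map an image's [min, max] onto [0, 1].

    A constant image maps to all-zeros.  The transform preserves the
    ordering (and hence the argmax) of pixel values.
    """
    image = np.asarray(image, dtype=np.float64)
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)
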