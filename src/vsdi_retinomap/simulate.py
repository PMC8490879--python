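"""Synthetic VSDI experiments with known ground truth.

The generator emulates an ideal retinotopic-mapping session: five
disc-shaped cortical responses laid out in a quincunx, evoked at 0.5 Hz
over a 10-s movie, corrupted by three additive noise sources (a white
spatio-temporal component, an almost-periodic 3 Hz "heartbeat" riding a
2-D cosine spatial profile, and an almost-periodic 0.67 Hz "breathing"
component) mixed to a requested SNR, on top of a constant DC offset.

Each noise source is a separable (spatial pattern x temporal series)
component; signal and noise powers are measured over the whole movie
with the DC offset excluded from both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import FrameStack, StimulusSchedule

__all__ = [
    "SimConfig",
    "GroundTruth",
    "NoiseComponent",
    "make_patterns",
    "temporal_profile",
    "almost_periodic",
    "mix_to_snr",
    "simulate_experiment",
]

#: fraction of a pattern's peak below which a pixel is background
PATTERN_SUPPORT_THRESHOLD = 0.01


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the standard protocol: a 100 x 100 px field
    imaged at 100 Hz for 10 s, responses peaking at 1, 3, 5, 7 and 9 s,
    discs of radius 4 px blurred with a 2 px Gaussian, temporal Gaussian
    envelopes of sigma 1 s with amplitudes drawn uniformly from
    [0.5, 1.5], the three-source noise model band-limited to 0.4 Hz
    around 3 Hz and 0.67 Hz, and a DC offset of 1.
    """

    grid: tuple[int, int] = (100, 100)
    frame_rate: float = 100.0
    duration: float = 10.0
    onsets: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0)
    disc_radius: float = 4.0
    blur_sigma: float = 2.0
    temporal_sigma: float = 1.0
    amp_range: tuple[float, float] = (0.5, 1.5)
    dc_offset: float = 1.0
    snr_db: float = np.inf
    noise_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    band_hz: float = 0.4
    n_sinusoids: int = 9
    cosine_periods: float = 1.0
    centers: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disc_radius < 1:
            raise ValueError("disc_radius must be >= 1 px")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if self.amp_range[0] >= self.amp_range[1]:
            raise ValueError("amp_range must satisfy low < high")
        if self.snr_db < -30:
            raise ValueError("snr_db below -30 dB is outside the studied range")
        if max(self.onsets) >= self.duration or min(self.onsets) < 0:
            raise ValueError("onsets must fit within the movie duration")
        if any(w < 0 for w in self.noise_weights):
            raise ValueError("noise weights must be non-negative")

    @property
    def n(self) -> int:
        return len(self.onsets)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Noiseless truth of a simulated experiment."""

    assignment: np.ndarray  # (H, W) labels in {0..n}
    patterns: np.ndarray  # (n, H, W), each max-normalized
    amplitudes: np.ndarray  # (n,)
    clean_stack: FrameStack


@dataclass
class NoiseComponent:
    """One noise source, either separable (``spatial x temporal``) or a
    full spatio-temporal field (``field``), scaled to unit RMS before
    its weight is applied."""

    kind: str
    spatial: np.ndarray | None = None
    temporal: np.ndarray | None = None
    field: np.ndarray | None = None
    weight: float = 1.0

    def render(self) -> np.ndarray:
        """The T x H x W movie of this component, unit RMS before weight."""
        if self.field is not None:
            movie = self.field
        else:
            movie = self.temporal[:, None, None] * self.spatial[None, :, :]
        rms = np.sqrt(np.mean(movie**2))
        if rms == 0:
            return movie
        return self.weight * movie / rms


def _default_centers(config: SimConfig) -> np.ndarray:
    """Quincunx layout: four corners of a centered square plus the center.

    The corner discs are inset from the border by the pattern's support
    radius (disc radius + 3 blur sigmas) so that the full blurred disc
    fits in the field; this maximizes the spacing between discs.
    """
    H, W = config.grid
    inset = int(round(config.disc_radius + 3 * config.blur_sigma))
    corners = [
        (inset, inset),
        (inset, W - 1 - inset),
        (H - 1 - inset, inset),
        (H - 1 - inset, W - 1 - inset),
    ]
    # integer centers keep every binary disc pixel-identical in shape
    center = (H // 2, W // 2)
    layout = corners + [center]
    n = config.n
    if n <= 5:
        order = [layout[i] for i in (0, 1, 4, 2, 3)]  # interleave center
        return np.asarray(order[:n], dtype=float)
    # beyond five stimuli: a ring of maximal radius
    radius = min(H, W) / 2.0 - inset
    ang = 2 * np.pi * np.arange(n) / n
    cy = (H - 1) / 2.0 + radius * np.sin(ang)
    cx = (W - 1) / 2.0 + radius * np.cos(ang)
    return np.column_stack([cy, cx])


def make_patterns(config: SimConfig) -> GroundTruth:
    """Build the n spatial response patterns and the truth assignment.

    Each pattern is a binary disc convolved with a Gaussian kernel and
    max-normalized to 1.  The assignment labels each pixel with the
    argmax pattern wherever any pattern exceeds 1% of its peak.

    The returned :class:`GroundTruth` has unit amplitudes and no clean
    stack (those are filled in by :func:`simulate_experiment`).
    """
    H, W = config.grid
    centers = (
        np.asarray(config.centers, dtype=float)
        if config.centers is not None
        else _default_centers(config)
    )
    if centers.shape != (config.n, 2):
        raise ValueError(f"expected {config.n} (row, col) centers, got {centers.shape}")
    yy, xx = np.mgrid[0:H, 0:W]
    patterns = np.empty((config.n, H, W))
    for k, (cy, cx) in enumerate(centers):
        disc = ((yy - cy) ** 2 + (xx - cx) ** 2) <= config.disc_radius**2
        if not disc.any():
            raise ValueError(f"disc {k} at ({cy}, {cx}) lies outside the grid")
        blurred = ndimage.gaussian_filter(disc.astype(float), config.blur_sigma)
        patterns[k] = blurred / blurred.max()
    if config.n > 1:
        overlap = np.sort(patterns, axis=0)[-2]  # second-highest per pixel
        if overlap.max() > 0.5:
            raise ValueError(
                "disc layout invalid: blurred responses overlap beyond 50% of peak"
            )
    support = patterns.max(axis=0) >= PATTERN_SUPPORT_THRESHOLD
    assignment = np.where(support, patterns.argmax(axis=0) + 1, 0)
    return GroundTruth(
        assignment=assignment,
        patterns=patterns,
        amplitudes=np.ones(config.n),
        clean_stack=None,
    )


def temporal_profile(onset: float, amplitude: float, config: SimConfig) -> np.ndarray:
    """Gaussian temporal envelope peaking at ``onset`` (length-T series)."""
    t = np.arange(config.n_frames) / config.frame_rate
    return amplitude * np.exp(-((t - onset) ** 2) / (2 * config.temporal_sigma**2))


def almost_periodic(f0: float, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Narrow-band stochastic oscillation around ``f0`` Hz, unit RMS.

    A sum of ``n_sinusoids`` equally spaced sinusoids across the
    ``band_hz`` band around ``f0``, with folded-normal amplitudes and
    uniform phases.
    """
    if f0 >= config.frame_rate / 2:
        raise ValueError(f"center frequency {f0} Hz is at or above Nyquist")
    if f0 <= config.band_hz / 2:
        raise ValueError("center frequency must exceed half the bandwidth")
    t = np.arange(config.n_frames) / config.frame_rate
    freqs = np.linspace(f0 - config.band_hz / 2, f0 + config.band_hz / 2, config.n_sinusoids)
    amps = np.abs(rng.normal(size=config.n_sinusoids))
    phases = rng.uniform(0, 2 * np.pi, size=config.n_sinusoids)
    series = (amps[:, None] * np.cos(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(
        axis=0
    )
    rms = np.sqrt(np.mean(series**2))
    return series / rms


def mix_to_snr(
    clean: FrameStack,
    noise: FrameStack,
    snr_db: float,
    dc_offset: float = 0.0,
    reference: str = "peak",
) -> FrameStack:
    """Scale ``noise`` to a requested signal-to-noise ratio.

    With the default ``reference="peak"`` the ratio is the clean
    signal's peak power against the per-sample noise variance,
    ``10 log10(max(clean)^2 / mean(noise^2))`` — at 0 dB the noise
    standard deviation equals the response amplitude, so a single frame
    at a response peak is visibly corrupted.  ``reference="energy"``
    uses total energies over the whole movie instead (a much milder
    condition for localized transient signals, whose energy occupies a
    small fraction of the movie).  The DC offset is added afterwards
    and enters neither power.  ``snr_db = +inf`` adds no noise at all.
    """
    if reference == "peak":
        p_clean = float(np.max(np.abs(clean.data)) ** 2)
        p_noise = float(np.mean(noise.data**2))
    elif reference == "energy":
        p_clean = float(np.sum(clean.data**2))
        p_noise = float(np.sum(noise.data**2))
    else:
        raise ValueError(f"unknown SNR reference {reference!r}")
    if p_clean == 0:
        raise ValueError("clean signal has zero power; SNR undefined")
    if np.isinf(snr_db) and snr_db > 0:
        return FrameStack(clean.data + dc_offset, clean.frame_rate, clean.t0)
    if p_noise == 0:
        raise ValueError("noise is identically zero but a finite SNR was requested")
    alpha = np.sqrt(p_clean / (p_noise * 10 ** (snr_db / 10)))
    return FrameStack(
        clean.data + alpha * noise.data + dc_offset, clean.frame_rate, clean.t0
    )


def make_noise(config: SimConfig, rng: np.random.Generator) -> list[NoiseComponent]:
    """The three noise sources, each normalized to unit RMS pre-weight."""
    H, W = config.grid
    T = config.n_frames
    w = config.noise_weights
    yy = np.arange(H)
    cosine = np.cos(2 * np.pi * config.cosine_periods * yy / H)[:, None] * np.ones((1, W))
    comps = [
        # random cortical activity: white in space AND time (full field)
        NoiseComponent(
            kind="white",
            field=rng.normal(size=(T, H, W)),
            weight=w[0],
        ),
        # heartbeat: almost-periodic 3 Hz modulating a 2-D cosine profile
        NoiseComponent(
            kind="periodic3hz",
            spatial=cosine,
            temporal=almost_periodic(3.0, config, rng),
            weight=w[1],
        ),
        # breathing: almost-periodic 0.67 Hz modulating a random profile
        NoiseComponent(
            kind="periodic067hz",
            spatial=rng.normal(size=(H, W)),
            temporal=almost_periodic(0.67, config, rng),
            weight=w[2],
        ),
    ]
    return comps


def simulate_experiment(
    config: SimConfig,
) -> tuple[FrameStack, GroundTruth, StimulusSchedule]:
    """Generate one complete synthetic experiment.

    Returns the noisy movie, the ground truth (patterns, assignment,
    amplitudes, clean stack) and the stimulus schedule.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = make_patterns(config)
    amplitudes = rng.uniform(*config.amp_range, size=config.n)
    clean = np.zeros((config.n_frames, *config.grid))
    for k, onset in enumerate(config.onsets):
        clean += (
            temporal_profile(onset, amplitudes[k], config)[:, None, None]
            * truth.patterns[k][None]
        )
    clean_stack = FrameStack(clean, config.frame_rate)
    noise = sum(c.render() for c in make_noise(config, rng))
    noisy = mix_to_snr(
        clean_stack,
        FrameStack(noise, config.frame_rate),
        config.snr_db,
        dc_offset=config.dc_offset,
    )
    truth.amplitudes = amplitudes
    truth.clean_stack = clean_stack
    schedule = StimulusSchedule(onsets=np.asarray(config.onsets), latency=0.0)
    return noisy, truth, schedule
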