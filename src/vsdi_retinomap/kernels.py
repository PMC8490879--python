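"""Temporal response kernels, TSCA prior matrices, and the GLM design.

The theoretical response curve g(t) is the temporal prior shared by the
template-based localization methods.  Three functional forms are
supported: the canonical alpha function ``t * exp(-b t)`` (causal, peak
at 1/b), a decaying exponential ``exp(-b t) + c``, and a Gaussian
envelope (matched to the simulator's temporal profile, peak at the
onset itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .core import StimulusSchedule

__all__ = [
    "ResponseKernel",
    "TemporalPriors",
    "DesignMatrix",
    "make_kernel",
    "delayed_kernels",
    "make_Cx",
    "make_periodic_prior",
    "make_design",
    "default_priors",
]


@dataclass
class ResponseKernel:
    """A peak-normalized temporal response curve sampled at a frame rate.

    ``samples`` holds g(t) on the onset-relative grid ``t = i / frame_rate``
    for causal forms, so the peak of the sampled curve appears at the
    peak latency of the form.  The Gaussian form is centered on the
    onset (symmetric support), matching the simulated response.
    """

    form: str
    a: float = 1.0
    b: float = 10.0
    c: float = 0.0
    sigma: float = 1.0
    frame_rate: float = 100.0
    duration: float = 2.0
    samples: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.form not in ("alpha_t", "exp_decay", "gaussian"):
            raise ValueError(f"unknown kernel form {self.form!r}")
        if self.form in ("alpha_t", "exp_decay") and self.b <= 0:
            raise ValueError("decay rate b must be positive")
        t = np.arange(int(round(self.duration * self.frame_rate))) / self.frame_rate
        y = self.evaluate(t)
        peak = np.abs(y).max()
        if peak == 0:
            raise ValueError("kernel is identically zero over its support")
        if self.form in ("alpha_t", "exp_decay"):
            tail = abs(self.evaluate(np.array([self.duration]))[0])
            if tail > 0.01 * peak and self.c == 0:
                warnings.warn(
                    "kernel has not decayed below 1% of peak within its duration"
                )
        self.samples = y / peak

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Un-normalized g(t) at onset-relative times ``t`` (casual forms
        vanish for t < 0; the Gaussian is symmetric around t = 0)."""
        t = np.asarray(t, dtype=np.float64)
        if self.form == "alpha_t":
            y = np.where(t >= 0, self.a * t * np.exp(-self.b * t) + self.c, 0.0)
        elif self.form == "exp_decay":
            y = np.where(t >= 0, self.a * np.exp(-self.b * t) + self.c, 0.0)
        else:  # gaussian
            y = self.a * np.exp(-(t**2) / (2 * self.sigma**2))
        return y

    def normalized(self, t: np.ndarray) -> np.ndarray:
        """Peak-normalized g(t) at arbitrary onset-relative times."""
        grid = np.arange(int(round(self.duration * self.frame_rate))) / self.frame_rate
        peak = np.abs(self.evaluate(grid)).max()
        return self.evaluate(t) / peak

    @property
    def peak_latency(self) -> float:
        """Onset-relative time of the kernel's peak."""
        if self.form == "alpha_t":
            return 1.0 / self.b
        return 0.0


def make_kernel(
    form: str = "alpha_t",
    a: float = 1.0,
    b: float = 10.0,
    c: float = 0.0,
    sigma: float = 1.0,
    frame_rate: float = 100.0,
    duration: float = 2.0,
) -> ResponseKernel:
    """Build a sampled, peak-normalized, causal response kernel.

    The default alpha function peaks 0.1 s after onset (``1/b``) and has
    decayed to about 1% of peak by ~0.7 s, consistent with a sub-second
    cortical response.
    """
    return ResponseKernel(
        form=form, a=a, b=b, c=c, sigma=sigma, frame_rate=frame_rate, duration=duration
    )


def delayed_kernels(
    g: ResponseKernel,
    schedule: StimulusSchedule,
    n_frames: int,
    t0: float = 0.0,
) -> np.ndarray:
    """The n x T matrix of delayed copies g_k(t) = g(t - t_k - latency).

    Rows are sampled on the movie's time grid; kernels whose support
    extends past the last frame are truncated (with a warning).
    """
    t = t0 + np.arange(n_frames) / g.frame_rate
    rows = np.empty((schedule.n, n_frames))
    for k, onset in enumerate(schedule.onsets):
        rows[k] = g.normalized(t - onset - schedule.latency)
    end_support = schedule.onsets[-1] + schedule.latency + g.duration
    if end_support > t[-1] + 1.0 / g.frame_rate and g.form != "gaussian":
        warnings.warn("last kernel truncated at the end of the movie")
    return rows


def make_Cx(g_k: np.ndarray) -> np.ndarray:
    """Rank-1 signal autocorrelation prior: the outer product g_k g_k^T."""
    g_k = np.asarray(g_k, dtype=np.float64).ravel()
    if not np.any(g_k):
        raise ValueError("zero kernel: Cx would be the zero matrix")
    return np.outer(g_k, g_k)


def make_periodic_prior(
    f0: float,
    band: float,
    n_frames: int,
    frame_rate: float,
    envelope: str = "gaussian",
) -> np.ndarray:
    """Symmetric Toeplitz prior for band-limited almost-periodic noise.

    First row: ``rho(d) = cos(2 pi f0 d / fs) * env(d)`` with a Gaussian
    (default) or sinc band-limiting envelope; the diagonal is 1.  The
    Gaussian envelope is ``exp(-(pi * band * d / fs)^2 / 2)``.
    """
    if f0 >= frame_rate / 2:
        raise ValueError(f"center frequency {f0} Hz at or above Nyquist")
    lags = np.arange(n_frames) / frame_rate
    carrier = np.cos(2 * np.pi * f0 * lags)
    if envelope == "gaussian":
        env = np.exp(-((np.pi * band * lags) ** 2) / 2)
    elif envelope == "sinc":
        env = np.sinc(band * lags)
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    return toeplitz(carrier * env)


@dataclass
class TemporalPriors:
    """Signal and noise temporal-correlation priors for TSCA.

    ``Cx_list`` holds one rank-1 prior per stimulus; ``Cy_list`` the
    noise priors (identity for white noise plus almost-periodic Toeplitz
    matrices).  ``gamma_x`` weights the signal power, ``gamma_y``
    (negative) penalizes power matching each noise prior.
    """

    Cx_list: list[np.ndarray]
    Cy_list: list[np.ndarray]
    gamma_x: float = 1.0
    gamma_y: float = -0.33

    def __post_init__(self) -> None:
        for C in [*self.Cx_list, *self.Cy_list]:
            if C.ndim != 2 or C.shape[0] != C.shape[1]:
                raise ValueError("priors must be square matrices")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("priors must be symmetric")


def default_priors(
    schedule: StimulusSchedule,
    g: ResponseKernel,
    n_frames: int,
    noise_freqs: tuple[float, ...] = (3.0, 0.67),
    band: float = 0.4,
    gamma_x: float = 1.0,
    gamma_y: float = -0.33,
    identity_only: bool = False,
) -> TemporalPriors:
    """Standard priors: per-stimulus rank-1 signal priors plus identity
    (white) and Toeplitz (almost-periodic) noise priors."""
    gks = delayed_kernels(g, schedule, n_frames)
    Cx_list = [make_Cx(gk) for gk in gks]
    Cy_list: list[np.ndarray] = [np.eye(n_frames)]
    if not identity_only:
        for f0 in noise_freqs:
            Cy_list.append(make_periodic_prior(f0, band, n_frames, g.frame_rate))
    return TemporalPriors(Cx_list, Cy_list, gamma_x=gamma_x, gamma_y=gamma_y)


@dataclass
class DesignMatrix:
    """T x p regressor matrix with per-column roles.

    Roles are ``signal_k`` (delayed response kernels), ``cos_f``/``sin_f``
    (Fourier noise regressors), ``drift`` and ``intercept``.
    """

    X: np.ndarray
    roles: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.roles):
            raise ValueError("one role per column is required")
        cond = np.linalg.cond(self.X)
        if cond > 1e8:
            raise ValueError(
                f"design matrix is rank deficient (condition number {cond:.3g}); "
                "check for collinear regressors"
            )

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def columns(self, prefix: str) -> np.ndarray:
        """Indices of columns whose role starts with ``prefix``."""
        return np.array([i for i, r in enumerate(self.roles) if r.startswith(prefix)])


def make_design(
    schedule: StimulusSchedule,
    g: ResponseKernel,
    noise_freqs: tuple[float, ...] = (3.0, 0.67),
    harmonics: int = 2,
    n_frames: int | None = None,
    frame_rate: float | None = None,
    drift: bool = True,
) -> DesignMatrix:
    """GLM design: delayed kernels + Fourier noise regressors + trend.

    Columns are the n delayed response curves, cosine/sine pairs at
    ``m * f`` for each noise frequency ``f`` and harmonic ``m``, an
    intercept, and (optionally) a linear drift.  All non-intercept
    columns are mean-centered so they are orthogonal to the intercept.
    """
    frame_rate = frame_rate if frame_rate is not None else g.frame_rate
    if n_frames is None:
        raise ValueError("n_frames is required")
    t = np.arange(n_frames) / frame_rate
    cols = []
    roles = []
    for k, gk in enumerate(delayed_kernels(g, schedule, n_frames)):
        cols.append(gk)
        roles.append(f"signal_{k + 1}")
    for f in noise_freqs:
        for m in range(1, harmonics + 1):
            cols.append(np.cos(2 * np.pi * m * f * t))
            roles.append(f"cos_{m * f:g}")
            cols.append(np.sin(2 * np.pi * m * f * t))
            roles.append(f"sin_{m * f:g}")
    if drift:
        cols.append(np.linspace(-0.5, 0.5, n_frames))
        roles.append("drift")
    X = np.column_stack(cols)
    X = X - X.mean(axis=0)
    X = np.column_stack([X, np.ones(n_frames)])
    roles.append("intercept")
    if n_frames <= X.shape[1]:
        raise ValueError("more regressors than frames")
    return DesignMatrix(X=X, roles=roles)
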