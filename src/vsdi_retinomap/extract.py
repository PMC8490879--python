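"""The seven response-localization methods.

Each method is a model object built from a movie and a stimulus
schedule (plus, where relevant, a response kernel and temporal priors);
``fit()`` returns a :class:`LocalizationResult` carrying one score map
per stimulus, from which the retinotopic map and evaluation metrics are
derived.  Thin functional wrappers (:func:`aof`, :func:`mpt`, ...)
mirror the model classes.

Methods
-------
- AverageOfFrames (AOF): mean of the N frames after the expected
  response onset.
- MultiParametricThresholding (MPT): a cascade of amplitude, latency
  and return-to-baseline criteria on z-scored pixel series.
- MaxCorrelationDelay (T_max): per-pixel cross-correlogram with the
  theoretical response curve; the delay of the correlation peak
  determines the driving stimulus.
- DelayedCorrelation (Corr): inner product of each pixel with delayed
  copies of the response curve.
- TSCA: temporally structured component analysis — eigen-decomposition
  of Z Q Z^T where Q encodes signal/noise temporal priors.
- LinearModel (GLM): per-pixel ordinary least squares on response-curve
  and Fourier noise regressors; the signal coefficients localize the
  response, the fitted noise part can be subtracted to denoise.
- TSCAWithGLM: GLM denoising followed by TSCA with an identity-only
  noise prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal
from scipy.sparse.linalg import eigsh

from .core import FrameStack, ScoreMapSet, StimulusSchedule, rescale01, zscore_stack
from .kernels import (
    DesignMatrix,
    ResponseKernel,
    TemporalPriors,
    default_priors,
    delayed_kernels,
    make_design,
    make_kernel,
)

__all__ = [
    "MPTParams",
    "TscaResult",
    "LocalizationResult",
    "ResponseLocalizer",
    "AverageOfFrames",
    "MultiParametricThresholding",
    "MaxCorrelationDelay",
    "DelayedCorrelation",
    "TSCA",
    "LinearModel",
    "TSCAWithGLM",
    "aof",
    "mpt",
    "tmax",
    "corr_delayed",
    "tsca_solve_Q",
    "tsca_extract",
    "glm_fit",
    "glm_denoise",
    "tsca_glm",
    "METHODS",
]


# ---------------------------------------------------------------------------
# Results


@dataclass
class LocalizationResult:
    """Fitted output of a localization method.

    ``score_maps`` holds the post-processed ([0, 1]-rescaled) per-
    stimulus score images; ``raw_maps`` the method's native scores.
    """

    score_maps: ScoreMapSet
    raw_maps: np.ndarray
    method_name: str
    extras: dict = field(default_factory=dict)

    def retinotopic_map(self, percentile: float = 90.0, despeckle: bool = True):
        """Assemble the per-stimulus maps into a retinotopic map."""
        from . import mapgen

        m = mapgen.assemble_map(self.score_maps, percentile=percentile)
        if despeckle:
            m = mapgen.despeckle(m)
        return m

    def evaluate(self, truth, percentile: float = 90.0) -> dict:
        """Image statistics against ground truth plus cluster indices of
        the assembled map.  ``truth`` is a simulator GroundTruth."""
        from . import metrics as _metrics

        per_stim = [
            _metrics.image_stats(self.score_maps.maps[k], truth.patterns[k])
            for k in range(self.score_maps.n)
        ]
        out = {k: float(np.mean([d[k] for d in per_stim])) for k in per_stim[0]}
        rmap = self.retinotopic_map(percentile=percentile)
        expected_sizes = [
            int((truth.assignment == l).sum())
            for l in range(1, truth.patterns.shape[0] + 1)
        ]
        ce = _metrics.adjusted_indices(
            rmap, expected_n=truth.patterns.shape[0], expected_sizes=expected_sizes
        )
        out.update(
            si_median=ce.si_median,
            dbi=ce.dbi,
            adjusted_si=ce.adjusted_si,
            adjusted_dbi=ce.adjusted_dbi,
        )
        return out

    def summary(self) -> str:
        n, H, W = self.score_maps.maps.shape
        lines = [
            f"{self.method_name} localization result",
            "=" * 40,
            f"stimuli: {n}    map size: {H} x {W}",
        ]
        for k in range(n):
            m = self.score_maps.maps[k]
            r, c = np.unravel_index(np.argmax(m), m.shape)
            lines.append(
                f"  stimulus {k + 1}: peak score at (row {r}, col {c}), "
                f"mean score {m.mean():.3f}"
            )
        return "\n".join(lines)


@dataclass
class TscaResult:
    """A single extracted TSCA component."""

    spatial: np.ndarray  # (H, W), rescaled to [0, 1]
    eigenvalue: float
    temporal: np.ndarray  # (T,) projection psi^T Z
    stimulus_index: int


# ---------------------------------------------------------------------------
# Model base class


class ResponseLocalizer:
    """Base class: a localization model over (stack, schedule)."""

    method_name = "base"

    def __init__(self, stack: FrameStack, schedule: StimulusSchedule):
        self.stack = stack
        self.schedule = schedule

    def _raw_maps(self) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def fit(self) -> LocalizationResult:
        raw, extras = self._raw_maps()
        score = ScoreMapSet(raw, self.method_name).rescaled()
        return LocalizationResult(
            score_maps=score, raw_maps=raw, method_name=self.method_name, extras=extras
        )


# ---------------------------------------------------------------------------
# AOF


class AverageOfFrames(ResponseLocalizer):
    """Mean of the N frames starting at each expected response time."""

    method_name = "aof"

    def __init__(self, stack, schedule, n_frames: int = 10):
        super().__init__(stack, schedule)
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.n_avg = n_frames

    def _raw_maps(self):
        T = self.stack.n_frames
        maps = np.empty((self.schedule.n, *self.stack.shape[1:]))
        for k, onset in enumerate(self.schedule.onsets):
            i0 = self.stack.frame_index(onset + self.schedule.latency)
            i1 = i0 + self.n_avg
            if i1 > T:
                warnings.warn(f"averaging window for stimulus {k + 1} truncated at T")
                i1 = T
            maps[k] = self.stack.data[i0:i1].mean(axis=0)
        return maps, {}


# ---------------------------------------------------------------------------
# MPT


@dataclass
class MPTParams:
    """Thresholds of the multi-parametric cascade (z-score units).

    Windows are in seconds relative to each stimulus onset (after the
    schedule's latency).
    """

    abs_threshold: float = 2.0
    top_percent: float = 10.0
    peak_window: tuple[float, float] = (0.0, 0.5)
    baseline_value: float = 0.5
    return_window: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if not (0 < self.top_percent <= 100):
            raise ValueError("top_percent must be in (0, 100]")
        if self.peak_window[0] > self.peak_window[1]:
            raise ValueError("peak_window must be ordered")
        if self.return_window[0] > self.return_window[1]:
            raise ValueError("return_window must be ordered")


class MultiParametricThresholding(ResponseLocalizer):
    """Amplitude / latency / return-to-baseline cascade per pixel.

    For each stimulus, a pixel scores its peak z-amplitude within the
    response epoch iff it (i) exceeds the absolute threshold, (ii) lies
    in the top x% of peak amplitudes, (iii) peaks inside the peak
    window, and (iv) returns below the baseline value inside the return
    window; otherwise it scores 0.
    """

    method_name = "mpt"

    def __init__(self, stack, schedule, params: MPTParams | None = None):
        super().__init__(stack, schedule)
        self.params = params if params is not None else MPTParams()

    def _raw_maps(self):
        p = self.params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore_stack(self.stack).data
        T = self.stack.n_frames
        fs = self.stack.frame_rate
        half_isi = self.schedule.inter_stimulus_interval() / 2
        if not np.isfinite(half_isi):
            half_isi = self.stack.duration / 2
        maps = np.zeros((self.schedule.n, *self.stack.shape[1:]))
        for k, onset in enumerate(self.schedule.onsets):
            t_res = onset + self.schedule.latency
            e0 = max(self.stack.frame_index(t_res - half_isi), 0)
            e1 = min(self.stack.frame_index(t_res + half_isi) + 1, T)
            seg = z[e0:e1]
            peak_amp = seg.max(axis=0)
            peak_t = (e0 + seg.argmax(axis=0)) / fs
            ok = peak_amp > p.abs_threshold
            cut = np.percentile(peak_amp, 100 - p.top_percent)
            ok &= peak_amp >= cut
            ok &= (peak_t >= t_res + p.peak_window[0]) & (
                peak_t <= t_res + p.peak_window[1]
            )
            r0 = self.stack.frame_index(t_res + p.return_window[0])
            r1 = min(self.stack.frame_index(t_res + p.return_window[1]) + 1, T)
            returned = (z[r0:r1] < p.baseline_value).any(axis=0)
            ok &= returned
            if not ok.any():
                warnings.warn(f"MPT: no pixel passed the cascade for stimulus {k + 1}")
            maps[k] = np.where(ok, peak_amp, 0.0)
        return maps, {}


# ---------------------------------------------------------------------------
# T_max


class MaxCorrelationDelay(ResponseLocalizer):
    """Cross-correlogram delay method.

    Each pixel's series is cross-correlated with the response template;
    the delay of the correlation peak assigns the pixel to the stimulus
    whose expected response time is nearest (within half the inter-
    stimulus interval), with the peak correlation as score.  By default
    the correlation is normalized (unit-norm template and pixel series)
    so the threshold is scale-free; the raw correlogram is available
    with ``normalized=False``.
    """

    method_name = "tmax"

    def __init__(
        self,
        stack,
        schedule,
        kernel: ResponseKernel | None = None,
        corr_threshold: float = 0.5,
        normalized: bool = True,
    ):
        super().__init__(stack, schedule)
        if kernel is None:
            kernel = make_kernel(
                "gaussian", sigma=1.0, frame_rate=stack.frame_rate, duration=2.0
            )
        self.kernel = kernel
        self.corr_threshold = corr_threshold
        self.normalized = normalized

    def _template(self) -> tuple[np.ndarray, float]:
        """Sampled template plus the offset (s) of its peak from its start."""
        g = self.kernel
        if g.form == "gaussian":
            half = 2.5 * g.sigma
            t = np.arange(-half, half + 1e-9, 1.0 / g.frame_rate)
            return g.normalized(t), half
        t = np.arange(0, g.duration, 1.0 / g.frame_rate)
        return g.normalized(t), g.peak_latency

    def _raw_maps(self):
        Z = self.stack.as_matrix()
        tmpl, peak_off = self._template()
        L = tmpl.size
        T = Z.shape[1]
        # full mode so templates overhanging either end of the record
        # (edge stimuli) still score; column j is the window starting at
        # frame j - (L - 1)
        if self.normalized:
            # zero-normalized cross-correlation: demeaned unit template
            # against per-window centered, per-window normalized data.
            # Global centering first keeps the windowed variance
            # (s2 - s1^2/n) clear of catastrophic cancellation on the
            # DC-dominated fluorescence scale.
            Zc = Z - Z.mean(axis=1, keepdims=True)
            tmpl_n = tmpl - tmpl.mean()
            tmpl_n = tmpl_n / np.linalg.norm(tmpl_n)
            num = signal.fftconvolve(Zc, tmpl_n[::-1][None, :], mode="full", axes=1)
            ones = np.ones(L)
            ones_T = np.ones(T)
            cnt = np.convolve(ones_T, ones, mode="full")
            s1 = signal.fftconvolve(Zc, ones[None, :], mode="full", axes=1)
            s2 = signal.fftconvolve(Zc**2, ones[None, :], mode="full", axes=1)
            var_w = np.maximum(s2 - s1**2 / cnt[None, :], 0.0)
            # partial-template statistics: exact ZNCC also for windows
            # truncated by the record boundaries
            tpart = np.convolve(ones_T, tmpl_n[::-1], mode="full")
            t2part = np.convolve(ones_T, (tmpl_n**2)[::-1], mode="full")
            tvar = np.maximum(t2part - tpart**2 / cnt, 0.0)
            num_c = num - s1 * (tpart / cnt)[None, :]
            denom = np.sqrt(var_w * tvar[None, :])
            # pixel-relative floor: flat(ish) windows carry no evidence
            tol = 1e-6 * np.sqrt(L) * np.maximum(Zc.std(axis=1), 1e-300)
            corr = np.where(
                denom > tol[:, None], num_c / np.maximum(denom, 1e-300), 0.0
            )
            # nearly-empty truncated windows correlate spuriously (+-1)
            corr[:, cnt < L / 2] = -np.inf
        else:
            Zc = Z - Z.mean(axis=1, keepdims=True)
            corr = signal.fftconvolve(Zc, tmpl[::-1][None, :], mode="full", axes=1)
        j_max = corr.argmax(axis=1)
        r_max = corr[np.arange(corr.shape[0]), j_max]
        peak_time = (
            self.stack.t0 + (j_max - (L - 1)) / self.stack.frame_rate + peak_off
        )
        expected = self.schedule.onsets + self.schedule.latency
        dev = np.abs(peak_time[:, None] - expected[None, :])
        k_star = dev.argmin(axis=1)
        half_isi = self.schedule.inter_stimulus_interval() / 2
        ok = r_max >= self.corr_threshold
        if np.isfinite(half_isi):
            ok &= dev[np.arange(dev.shape[0]), k_star] <= half_isi
        if not ok.any():
            warnings.warn("T_max: no responsive pixels above the correlation threshold")
        maps = np.zeros((self.schedule.n, Z.shape[0]))
        sel = np.nonzero(ok)[0]
        maps[k_star[sel], sel] = r_max[sel]
        H, W = self.stack.shape[1:]
        return maps.reshape(self.schedule.n, H, W), {
            "tau_max": peak_time.reshape(H, W)
        }


# ---------------------------------------------------------------------------
# Corr


class DelayedCorrelation(ResponseLocalizer):
    """Inner product of each pixel with delayed response curves.

    Scores ``v_i(k) = (1/T) sum_t z_i(t) g_k(t)`` with per-pixel mean
    removal (the DC offset would otherwise dominate); a Pearson variant
    normalizes each pixel and kernel to unit variance.
    """

    method_name = "corr"

    def __init__(
        self,
        stack,
        schedule,
        kernel: ResponseKernel | None = None,
        pearson: bool = False,
    ):
        super().__init__(stack, schedule)
        if kernel is None:
            kernel = make_kernel(
                "gaussian", sigma=1.0, frame_rate=stack.frame_rate, duration=2.0
            )
        self.kernel = kernel
        self.pearson = pearson

    def _raw_maps(self):
        T = self.stack.n_frames
        Z = self.stack.as_matrix()
        Zc = Z - Z.mean(axis=1, keepdims=True)
        G = delayed_kernels(self.kernel, self.schedule, T, self.stack.t0)
        Gc = G - G.mean(axis=1, keepdims=True)
        if self.pearson:
            zn = np.linalg.norm(Zc, axis=1, keepdims=True)
            zn[zn == 0] = 1.0
            gn = np.linalg.norm(Gc, axis=1, keepdims=True)
            v = (Zc / zn) @ (Gc / gn).T
        else:
            v = Zc @ Gc.T / T
        H, W = self.stack.shape[1:]
        return v.T.reshape(self.schedule.n, H, W), {}


# ---------------------------------------------------------------------------
# TSCA


def _prior_inner_products(Cy_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Frobenius inner products and traces of the noise priors."""
    m = len(Cy_list)
    gram = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            gram[i, j] = gram[j, i] = float(np.sum(Cy_list[i] * Cy_list[j]))
    tr = np.array([float(np.trace(C)) for C in Cy_list])
    return gram, tr


def _tsca_alphas(
    gk: np.ndarray,
    Cy_list: list[np.ndarray],
    gamma_x: float,
    gamma_y: float,
    cy_gram: np.ndarray | None = None,
    cy_tr: np.ndarray | None = None,
) -> np.ndarray:
    """Coefficients of Q = a_0 Cx + sum_j a_j Cy_j.

    Q is the minimum-Frobenius-norm matrix satisfying the power
    constraints <Q, Cx> = gamma_x tr(Cx) and <Q, Cy_j> = gamma_y
    tr(Cy_j); as a linear combination of the priors, its coefficients
    solve the Gram system G a = b with Frobenius inner products.
    """
    if cy_gram is None or cy_tr is None:
        cy_gram, cy_tr = _prior_inner_products(Cy_list)
    m = len(Cy_list)
    gg = float(gk @ gk)
    if gg == 0:
        raise ValueError("zero signal prior")
    G = np.empty((m + 1, m + 1))
    G[0, 0] = gg**2  # <g g^T, g g^T>
    for j, Cy in enumerate(Cy_list):
        G[0, j + 1] = G[j + 1, 0] = float(gk @ (Cy @ gk))  # <g g^T, Cy>
    G[1:, 1:] = cy_gram
    b = np.concatenate([[gamma_x * gg], gamma_y * cy_tr])
    return np.linalg.pinv(G) @ b


def tsca_solve_Q(
    priors: TemporalPriors, stimulus_index: int = 0
) -> np.ndarray:
    """The TSCA weighting matrix Q for one stimulus.

    Q is the minimum-norm linear combination of the signal prior
    Cx_k and the noise priors satisfying ``<Q, Cx> = gamma_x tr(Cx)``
    and ``<Q, Cy_j> = gamma_y tr(Cy_j)`` (Frobenius inner products);
    a singular Gram system is resolved by pseudo-inverse.
    """
    Cx = priors.Cx_list[stimulus_index]
    if not np.any(Cx) and not any(np.any(C) for C in priors.Cy_list):
        raise ValueError("all-zero priors")
    # Cx is rank one: recover g up to sign from its leading eigenvector
    w, v = np.linalg.eigh(Cx)
    gk = v[:, -1] * np.sqrt(max(w[-1], 0.0))
    alphas = _tsca_alphas(gk, priors.Cy_list, priors.gamma_x, priors.gamma_y)
    Q = alphas[0] * Cx
    for a, Cy in zip(alphas[1:], priors.Cy_list):
        Q = Q + a * Cy
    return Q


def _top_eigpair(B: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest-algebraic eigenpair of a symmetric matrix."""
    n = B.shape[0]
    if n <= 300:
        lam, vec = np.linalg.eigh(B)
        return float(lam[-1]), vec[:, -1]
    try:
        lam, vec = eigsh(B, k=1, which="LA")
        return float(lam[0]), vec[:, 0]
    except Exception:  # pragma: no cover - rare ARPACK failure
        lam, vec = np.linalg.eigh(B)
        return float(lam[-1]), vec[:, -1]


class TSCA(ResponseLocalizer):
    """Temporally structured component analysis.

    Finds, per stimulus, the spatial component psi maximizing the
    quadratic objective psi^T Z Q Z^T psi, where Q is built from the
    rank-1 signal prior g_k g_k^T and the noise priors (identity plus
    almost-periodic Toeplitz matrices), weighted by gamma_x (signal)
    and gamma_y (noise, negative to penalize noise-like power).

    The eigenproblem is solved in the reduced T-dimensional space: with
    the thin factorization Z = U S V^T (from the eigen-decomposition of
    the Gram matrix Z^T Z), the nonzero spectrum of Z Q Z^T equals that
    of B = S V^T Q V S, whose top eigenvector w maps back to
    psi = U w.  The identity and Toeplitz projections of Q are shared
    across stimuli; only the rank-1 signal part is stimulus-specific.
    """

    method_name = "tsca"

    def __init__(
        self,
        stack,
        schedule,
        kernel: ResponseKernel | None = None,
        priors: TemporalPriors | None = None,
        gamma_x: float = 1.0,
        gamma_y: float = -0.33,
        identity_only: bool = False,
        n_components: int = 1,
    ):
        super().__init__(stack, schedule)
        T = stack.n_frames
        if kernel is None:
            kernel = make_kernel(
                "gaussian", sigma=1.0, frame_rate=stack.frame_rate, duration=2.0
            )
        self.kernel = kernel
        if priors is None:
            priors = default_priors(
                schedule,
                kernel,
                T,
                gamma_x=gamma_x,
                gamma_y=gamma_y,
                identity_only=identity_only,
            )
        self.priors = priors
        self.n_components = n_components

    def fit(self) -> LocalizationResult:
        stack, schedule, priors = self.stack, self.schedule, self.priors
        T = stack.n_frames
        H, W = stack.shape[1:]
        Z = stack.as_matrix()
        Zc = Z - Z.mean(axis=1, keepdims=True)
        gks = delayed_kernels(self.kernel, schedule, T, stack.t0)

        # reduced-space factorization via the Gram matrix Z^T Z
        G = Zc.T @ Zc
        lam, V = np.linalg.eigh(G)
        keep = lam > lam[-1] * 1e-12
        lam, V = lam[keep], V[:, keep]
        S = np.sqrt(lam)

        cy_gram, cy_tr = _prior_inner_products(priors.Cy_list)
        # project each noise prior once: B_j = S V^T Cy_j V S
        B_noise = []
        for Cy in priors.Cy_list:
            if Cy.shape[0] == T and np.array_equal(Cy, np.eye(T)):
                B_noise.append(np.diag(lam))
            else:
                P = V.T @ (Cy @ V)
                B_noise.append(S[:, None] * P * S[None, :])

        components: list[TscaResult] = []
        maps = np.empty((schedule.n, H, W))
        for k in range(schedule.n):
            gk = gks[k]
            alphas = _tsca_alphas(
                gk, priors.Cy_list, priors.gamma_x, priors.gamma_y, cy_gram, cy_tr
            )
            u = S * (V.T @ gk)
            B = alphas[0] * np.outer(u, u)
            for a, Bj in zip(alphas[1:], B_noise):
                B = B + a * Bj
            eigval, w = _top_eigpair(B)
            c = V @ (w / S)
            psi = Zc @ c
            nrm = np.linalg.norm(psi)
            if nrm == 0:
                raise np.linalg.LinAlgError(
                    f"TSCA produced a zero component for stimulus {k + 1}"
                )
            psi /= nrm
            temporal = psi @ Zc
            if np.dot(temporal - temporal.mean(), gk - gk.mean()) < 0:
                psi, temporal = -psi, -temporal
            spatial = psi.reshape(H, W)
            maps[k] = spatial
            components.append(
                TscaResult(
                    spatial=rescale01(spatial),
                    eigenvalue=eigval,
                    temporal=temporal,
                    stimulus_index=k,
                )
            )
        score = ScoreMapSet(maps, self.method_name).rescaled()
        return LocalizationResult(
            score_maps=score,
            raw_maps=maps,
            method_name=self.method_name,
            extras={"components": components},
        )


# ---------------------------------------------------------------------------
# GLM


class LinearModel(ResponseLocalizer):
    """Per-pixel OLS on response-curve and Fourier noise regressors."""

    method_name = "glm"

    def __init__(
        self,
        stack,
        schedule,
        kernel: ResponseKernel | None = None,
        design: DesignMatrix | None = None,
        noise_freqs: tuple[float, ...] = (3.0, 0.67),
        harmonics: int = 2,
    ):
        super().__init__(stack, schedule)
        if design is None:
            if kernel is None:
                kernel = make_kernel(
                    "gaussian", sigma=1.0, frame_rate=stack.frame_rate, duration=2.0
                )
            design = make_design(
                schedule,
                kernel,
                noise_freqs=noise_freqs,
                harmonics=harmonics,
                n_frames=stack.n_frames,
                frame_rate=stack.frame_rate,
            )
        self.design = design

    def _fit_betas(self) -> tuple[np.ndarray, np.ndarray]:
        """(beta, residual) with beta of shape (p, P) and residual (T, P)."""
        Y = self.stack.data.reshape(self.stack.n_frames, -1)
        beta, *_ = np.linalg.lstsq(self.design.X, Y, rcond=None)
        resid = Y - self.design.X @ beta
        return beta, resid

    def _raw_maps(self):
        beta, resid = self._fit_betas()
        H, W = self.stack.shape[1:]
        sig = self.design.columns("signal")
        maps = beta[sig].reshape(len(sig), H, W)
        extras = {
            "beta_maps": beta.reshape(self.design.p, H, W),
            "residual": FrameStack(
                resid.reshape(self.stack.shape), self.stack.frame_rate, self.stack.t0
            ),
        }
        return maps, extras

    def denoise(self) -> FrameStack:
        """Subtract the fitted periodic-noise part (Fourier columns).

        Signal, intercept and drift columns are left in place: the
        drift estimate is collinear with responses near the edges of
        the record, and subtracting its noisy estimate distorts them.
        """
        beta, _ = self._fit_betas()
        noise_cols = [
            i
            for i, r in enumerate(self.design.roles)
            if r.startswith(("cos_", "sin_"))
        ]
        Y = self.stack.data.reshape(self.stack.n_frames, -1)
        Yd = Y - self.design.X[:, noise_cols] @ beta[noise_cols]
        return FrameStack(
            Yd.reshape(self.stack.shape), self.stack.frame_rate, self.stack.t0
        )


class TSCAWithGLM(ResponseLocalizer):
    """GLM denoising followed by TSCA with identity-only noise prior.

    After the Fourier noise regressors are fitted and subtracted, only
    (approximately) white noise remains, so the TSCA noise prior
    reduces to the identity matrix.
    """

    method_name = "tsca_glm"

    def __init__(
        self,
        stack,
        schedule,
        kernel: ResponseKernel | None = None,
        noise_freqs: tuple[float, ...] = (3.0, 0.67),
        harmonics: int = 2,
        gamma_x: float = 1.0,
        gamma_y: float = -0.33,
    ):
        super().__init__(stack, schedule)
        if kernel is None:
            kernel = make_kernel(
                "gaussian", sigma=1.0, frame_rate=stack.frame_rate, duration=2.0
            )
        self.kernel = kernel
        self.noise_freqs = noise_freqs
        self.harmonics = harmonics
        self.gamma_x = gamma_x
        self.gamma_y = gamma_y

    def fit(self) -> LocalizationResult:
        glm = LinearModel(
            self.stack,
            self.schedule,
            kernel=self.kernel,
            noise_freqs=self.noise_freqs,
            harmonics=self.harmonics,
        )
        denoised = glm.denoise()
        res = TSCA(
            denoised,
            self.schedule,
            kernel=self.kernel,
            gamma_x=self.gamma_x,
            gamma_y=self.gamma_y,
            identity_only=True,
        ).fit()
        res.method_name = self.method_name
        res.score_maps.method_name = self.method_name
        return res


# ---------------------------------------------------------------------------
# Functional wrappers (spec surface)


def aof(stack, schedule, N: int = 10) -> ScoreMapSet:
    return AverageOfFrames(stack, schedule, n_frames=N).fit().score_maps


def mpt(stack, schedule, params: MPTParams | None = None) -> ScoreMapSet:
    return MultiParametricThresholding(stack, schedule, params).fit().score_maps


def tmax(stack, schedule, g: ResponseKernel, corr_threshold: float = 0.5) -> ScoreMapSet:
    return MaxCorrelationDelay(stack, schedule, g, corr_threshold).fit().score_maps


def corr_delayed(stack, schedule, g: ResponseKernel, pearson: bool = False) -> ScoreMapSet:
    return DelayedCorrelation(stack, schedule, g, pearson=pearson).fit().score_maps


def tsca_extract(
    stack,
    schedule,
    g: ResponseKernel | None = None,
    priors: TemporalPriors | None = None,
    n_components: int = 1,
) -> ScoreMapSet:
    return TSCA(stack, schedule, kernel=g, priors=priors, n_components=n_components).fit().score_maps


def glm_fit(stack, design: DesignMatrix) -> tuple[np.ndarray, FrameStack]:
    """OLS beta maps (p x H x W) and the residual stack."""
    dummy_schedule = StimulusSchedule(onsets=np.array([0.0]))
    model = LinearModel.__new__(LinearModel)
    ResponseLocalizer.__init__(model, stack, dummy_schedule)
    model.design = design
    beta, resid = model._fit_betas()
    H, W = stack.shape[1:]
    return (
        beta.reshape(design.p, H, W),
        FrameStack(resid.reshape(stack.shape), stack.frame_rate, stack.t0),
    )


def glm_denoise(stack, design: DesignMatrix) -> FrameStack:
    dummy_schedule = StimulusSchedule(onsets=np.array([0.0]))
    model = LinearModel.__new__(LinearModel)
    ResponseLocalizer.__init__(model, stack, dummy_schedule)
    model.design = design
    return model.denoise()


def tsca_glm(stack, schedule, g: ResponseKernel | None = None, harmonics: int = 2) -> ScoreMapSet:
    return TSCAWithGLM(stack, schedule, kernel=g, harmonics=harmonics).fit().score_maps


#: registry used by the benchmark sweep and the CLI
METHODS = {
    "aof": AverageOfFrames,
    "mpt": MultiParametricThresholding,
    "tmax": MaxCorrelationDelay,
    "corr": DelayedCorrelation,
    "tsca": TSCA,
    "glm": LinearModel,
    "tsca_glm": TSCAWithGLM,
}
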