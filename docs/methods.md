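# Methods

## The analysis problem

A widefield VSDI movie is a T × H × W array Z(t) sampled at frame rate
f_s, containing localized stimulus-evoked responses superimposed on a
large DC fluorescence level and structured physiological noise.  Given
the stimulus schedule (onsets t_k, expected latency Δt) and a temporal
model of the response, each localization method produces one score
image per stimulus; the retinotopic map is then the per-pixel argmax of
those scores with the maximum score as confidence.

## Synthetic data generator

The simulator emulates an idealized retinotopic-mapping session and is
the source of every benchmark input.

* **Signal.**  n = 5 spatial response patterns: binary discs of radius
  4 px convolved with a Gaussian (σ = 2 px), max-normalized.  Layout is
  a quincunx — four corner discs inset from the border by the pattern
  support radius (disc radius + 3σ = 10 px) plus a central disc — which
  maximizes inter-disc spacing on the default 100 × 100 grid; integer
  centers keep all discs pixel-identical.  Each pattern is modulated by
  a Gaussian temporal envelope (σ = 1 s) peaking at its onset
  (1, 3, 5, 7, 9 s at 0.5 Hz in a 10-s record sampled at 100 Hz, the
  experimental camera rate) with amplitude drawn from U(0.5, 1.5).
  Envelopes of neighboring stimuli overlap (exp(−2) ≈ 0.14 at the 2-s
  spacing); this overlap is intentional and bounds how exactly any
  method can isolate single responses.
* **Noise.**  Three sources, each normalized to unit RMS before equal
  weighting: (i) random cortical activity as an i.i.d. Gaussian field,
  white in space and time; (ii) a heartbeat-like almost-periodic 3 Hz
  oscillation modulating a one-period 2-D cosine profile along the
  image rows; (iii) a breathing-like almost-periodic 0.67 Hz
  oscillation modulating a fixed random spatial profile.  An
  almost-periodic series is a sum of 9 sinusoids equally spaced across
  a 0.4 Hz band with folded-normal amplitudes and uniform phases,
  normalized to unit RMS.  The white source is a full spatio-temporal
  field (not a separable pattern) because a single flickering spatial
  pattern is not a meaningful model of spontaneous activity; the two
  physiological sources are separable, as a global pulse/respiration
  modulation is.
* **Mixing.**  The noise sum is scaled so that
  10·log10(max(clean)² / mean(noise²)) equals the requested SNR: the
  reference is the response's peak amplitude against the per-sample
  noise variance, so at 0 dB the noise standard deviation equals the
  strongest response amplitude and a single frame at a response peak is
  visibly corrupted, and at −10 dB the noise SD is ~3.2× the peak.
  This is the natural convention for localized transient signals; a
  whole-movie total-energy reference (far milder, since the signal
  occupies a small fraction of the movie) is selectable via
  ``mix_to_snr(..., reference="energy")``.  A DC offset (default
  1 a.u.) is added afterwards and enters neither power.
* **Reproducibility.**  One `numpy` Generator seeded from the config;
  repetition sweeps derive per-repetition seeds as base + index.

What the generator does **not** emulate: response propagation /
traveling waves (discs are static), hemodynamic or photobleaching
trends, motion, shot noise scaling with intensity, and spatial
correlation of the spontaneous activity.  Passing benchmarks here
therefore show correctness of the estimators under the stated
generative model, not robustness to every property of real recordings.

## Temporal model g(t)

Three kernel forms are provided: the alpha function t·e^{−bt}
(default b = 10 s⁻¹: peak 0.1 s after onset, decayed below 1 % of peak
within ~0.7 s — a canonical sub-second cortical response), a decaying
exponential e^{−bt} + c, and a Gaussian (σ = 1 s) matched to the
simulator's envelope.  Simulation studies use the matched Gaussian;
experimental analyses would choose the alpha form.  The constant c in
the exponential form is additive with default 0.

## The methods and their numerical choices

* **AOF** averages N = 10 frames (100 ms at 100 Hz) from each expected
  response time.
* **MPT** z-scores each pixel (population SD over the full series) and
  applies four criteria per stimulus epoch (± half the inter-stimulus
  interval): peak above 2 z-units, peak in the top 10 % of peak
  amplitudes, peak time within (0, 0.5) s of the expected response,
  and return below 0.5 z-units within (0.5, 1.5) s.  Note that
  z-scoring equalizes amplitudes, so weakly responding tail pixels can
  score on noiseless data, and the return criterion cannot be verified
  for a stimulus whose window is cut off by the end of the record.
* **T_max** computes a zero-normalized cross-correlogram (ZNCC) of
  every pixel against the sampled response template, exactly also for
  windows truncated by the record boundaries (partial-template
  statistics); windows overlapping the record by less than half the
  template length are excluded as degenerate.  The correlogram peak is
  binned to the nearest expected response time, rejecting deviations
  beyond half the inter-stimulus interval; the default score threshold
  is 0.5.  A raw (unnormalized) correlogram is available by flag.
* **Corr** scores (1/T)·Σ_t z_i(t) g_k(t) after per-pixel mean removal
  (without it the DC offset dominates every score); a Pearson variant
  is available by flag.
* **GLM** regresses every pixel on the n delayed kernels, cosine/sine
  pairs at 1× and 2× each noise frequency (3 and 0.67 Hz), a linear
  drift and an intercept, all noise columns mean-centered; the signal
  coefficients are the score maps.  Denoising subtracts only the
  fitted Fourier columns: the drift estimate is collinear with
  responses near the record edges, and subtracting its noisy estimate
  measurably distorts the first and last stimuli.  Because the
  simulated oscillations occupy a 0.4 Hz band while the regressors sit
  at discrete harmonics, denoising removes only part of the band power
  (factor ≈ 1.2–1.7 on a 10-s record) — a structural property of
  Fourier regression on almost-periodic noise, not a defect.
* **TSCA** solves, per stimulus, the eigenproblem of M = Z Q Zᵀ with
  Q = Σ_j α_j C_j, the minimum-Frobenius-norm combination of the priors
  satisfying ⟨Q, C_x⟩ = γ_x tr C_x and ⟨Q, C_y⟩ = γ_y tr C_y (the
  constraints are read as equalities).  Defaults γ_x = 1,
  γ_y = −0.33 per noise prior: the negative weight penalizes components
  whose temporal power matches a noise prior.  The Toeplitz noise
  priors use a band-limited damped cosine,
  ρ(Δ) = cos(2π f₀ Δ/f_s)·exp(−(π·band·Δ/f_s)²/2) (Gaussian envelope;
  sinc selectable).  Numerically, Z is row-centered and factorized via
  the eigen-decomposition of its T × T Gram matrix; the noise priors
  are projected into that basis once per movie, only the rank-1 signal
  part varies per stimulus, and the top eigenpair of the reduced
  matrix is mapped back to pixel space.  The component sign is fixed
  by a positive correlation of its temporal course with g_k.  The
  reduced solver is verified against dense eigen-decomposition of
  Z Q Zᵀ on small instances to 1e-8.
* **TSCA&GLM** chains GLM denoising with TSCA under an identity-only
  noise prior (after Fourier subtraction the residual is treated as
  white).

## Map assembly and post-processing

Scores are affinely rescaled to [0, 1] per map (constant maps become
zeros; the transform preserves ordering).  Assembly takes the per-pixel
argmax (ties to the lowest stimulus index) and keeps pixels whose
maximum score strictly exceeds the 90th percentile of all pixels'
maximum scores (zeros included; a nonzero-only variant is flagged).
Salt-noise removal is a 3 × 3 neighborhood-majority (median-type)
filter on the label image in which background competes in the vote, so
isolated speckles and thin one-pixel strays are deleted and interior
misassignments are relabeled to the local majority; a gentler
nonzero-only vote (removing only isolated single pixels) is available
by flag.  Despeckling runs after percentile selection (flag to
reverse).  The value image is divided by its maximum over retained
pixels, keeping scores in (0, 1] so selection and positivity remain
consistent.

## Evaluation

* **Image statistics** against the known pattern (simulation only):
  MSE; PSNR = 10·log10(1/MSE) capped at 100 dB; CNR using the truth's
  foreground (≥ 0.5)/background partition; MSSIM (11 × 11 Gaussian
  window, σ = 1.5, K1 = 0.01, K2 = 0.03, unit range; the window shrinks
  to fit tiny test images); Pearson CC; and CP, the Pearson correlation
  of 3 × 3-Laplacian-filtered images (edge preservation).  Per-method
  reports average over stimuli.
* **Cluster indices** on the assembled map: data points are the
  selected pixels with (row, col) features — the indices measure
  spatial separation of activity centers (a score-weighted variant is
  flagged off by default).  Median silhouette and Davies-Bouldin are
  delegated to scikit-learn and verified against quadratic-time
  brute-force oracles; single-pixel clusters get zero scatter,
  coincident centroids report DBI = ∞.
* **Adjusted indices** penalize structural errors the plain indices
  ignore: with m the number of 8-connected activity centers, n the
  expected stimulus count and ē the expected cluster size,
  adjusted SI = SI − λ·mean_c|size_c − ē|/ē − λ·|m − n|/n and
  adjusted DBI = DBI + the same two terms, λ = 1 by default.  These
  penalized forms are this package's own surrogate definition
  (documented here precisely because the reference formulas are not
  published in accessible form); penalties can only worsen an index.
  The DBI penalty is additive rather than multiplicative: under heavy
  noise the selection pipeline leaves few, tight clusters with a small
  base DBI, and a multiplicative penalty would then vanish exactly
  where the structural errors are worst.

## Benchmark conditions and problem sizes

The repetition sweep simulates one movie per repetition and feeds it to
every method, so methods are compared on common data.  Default grid
{∞, 10, 5, 0, −5, −10, −20, −30} dB.  The acceptance computation uses
100 repetitions at full resolution (100 × 100 × 1000); the test suite
uses 30 repetitions at full resolution for the −10 dB comparisons and
30 repetitions per SNR level at half resolution (50 × 50 × 500) for the
degradation trend, sizes chosen to keep a complete run on a single CPU
in minutes while leaving Monte-Carlo error well inside the asserted
tolerances.  Significance marking uses Tukey-HSD at α = 0.05 via
statsmodels.

## Known limitations

* The median pixel silhouette of a *surviving* map saturates: whenever
  extraction works at all, percentile selection plus salt removal
  leaves compact cluster cores, so the median silhouette sits at or
  above the noiseless geometry's 0.86 and barely discriminates among
  the working methods.  The Davies-Bouldin index, the adjusted
  indices, and outright failure rates carry the discrimination
  instead.
* Cluster indices require at least two labeled clusters; a method whose
  maps are empty (e.g., T_max under heavy noise, where no correlation
  clears the threshold) yields NA rows in sweeps.
* TSCA assumes additivity of signal and noise and linear independence
  of the prior set; with a grossly wrong kernel its components mix
  neighboring responses (the temporal-envelope overlap sets the floor).
* No motion correction, registration, ROI tooling, or real-time
  (streaming) operation.
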