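# vsdi-retinomap

Localization of stimulus-evoked cortical responses in voltage-sensitive
dye imaging (VSDI) movies, and generation of high-resolution retinotopic
maps.

In a retinotopic-mapping experiment, small visual stimuli are presented
at different retinal locations at known times while a fluorescent dye
reports membrane potential across the visual cortex at video rate.  The
analysis problem is to decide, for every cortical pixel, *which*
stimulus drove it and *how strongly* — in the presence of heavy
physiological noise (random cortical activity, ~3 Hz heartbeat and
~0.67 Hz breathing artifacts).  This package implements and compares
seven localization methods and the evaluation machinery around them:

| method      | idea |
|-------------|------|
| `aof`       | average the N frames after the expected response time |
| `mpt`       | multi-parametric thresholding: amplitude / latency / return-to-baseline cascade |
| `tmax`      | per-pixel normalized cross-correlogram with the response curve g(t); the delay of the peak assigns the stimulus |
| `corr`      | inner product with delayed copies g_k(t) = g(t − t_k) |
| `tsca`      | temporally structured component analysis (see below) |
| `glm`       | per-pixel OLS on response-curve + Fourier noise regressors |
| `tsca_glm`  | GLM denoising, then TSCA with an identity noise prior |

**TSCA** seeks a spatial component ψ maximizing a weighted
signal-minus-noise power objective
m(ψ) = γ_x s_x²(ψ) + γ_y s_y²(ψ).  With temporal priors — a rank-1
signal autocorrelation C_x = g_k g_kᵀ and noise priors C_y (identity for
white noise, almost-periodic Toeplitz matrices for the oscillatory
artifacts) — the maximizer is the top eigenvector of M = Z Q Zᵀ, where
Z is the pixels × time matrix and Q is the minimum-Frobenius-norm
linear combination of the priors satisfying ⟨Q, C_x⟩ = γ_x tr C_x and
⟨Q, C_y⟩ = γ_y tr C_y.  The implementation solves the equivalent
reduced T-dimensional eigenproblem obtained from the thin factorization
of Z, which makes a 10⁴-pixel, 10³-frame movie tractable in seconds.

Per-stimulus score maps are rescaled to [0, 1], combined by per-pixel
argmax (hue = stimulus, value = score), thresholded at the 90th
percentile of the maximum scores, and cleaned of salt noise.  Maps are
evaluated with image statistics against ground truth (MSE, PSNR, CNR,
MSSIM, CC, CP) and with cluster-separation indices on pixel coordinates
(median silhouette, Davies-Bouldin, and penalized "adjusted" variants).

A built-in simulator generates the full benchmark: five Gaussian-blurred
disc responses (radius 4 px, blur σ = 2 px) on a 100 × 100 grid at
100 Hz, peaking at 1, 3, 5, 7, 9 s with amplitudes U(0.5, 1.5), plus
the three-source noise model mixed to any SNR.

## Worked example

```python
import numpy as np
from vsdi_retinomap import SimConfig, simulate_experiment, TSCA
from vsdi_retinomap.metrics import silhouette_map, dbi_map

stack, truth, schedule = simulate_experiment(SimConfig(snr_db=-10, seed=1))
result = TSCA(stack, schedule).fit()
print(result.summary())
rmap = result.retinotopic_map()          # assemble + despeckle
print("median SI :", round(silhouette_map(rmap).si_median, 3))
print("DBI       :", round(dbi_map(rmap).dbi, 3))
```

prints

```
tsca localization result
========================================
stimuli: 5    map size: 100 x 100
  stimulus 1: peak score at (row 9, col 12), mean score 0.437
  stimulus 2: peak score at (row 11, col 87), mean score 0.431
  stimulus 3: peak score at (row 50, col 50), mean score 0.509
  stimulus 4: peak score at (row 88, col 9), mean score 0.410
  stimulus 5: peak score at (row 90, col 88), mean score 0.470
median SI : 0.941
DBI       : 0.176
```

The five score peaks land on (or within ~2 px of) the five planted disc
centers at (10, 10), (10, 89), (50, 50), (89, 10), (89, 89).  At
−10 dB the per-sample noise standard deviation is more than three times
the strongest response amplitude, yet the assembled map separates the
five response clusters cleanly — the median silhouette (0.94) is at the
level of the noiseless geometry itself (0.86) and the Davies-Bouldin
index (0.18) close to its ideal (0.2).  Threshold-based methods
(`mpt`, `tmax`) produce no usable map under the same noise.

A thin CLI mirrors the library:

```bash
vsdi-retinomap simulate --snr-db -10 --seed 1 --out sim/
vsdi-retinomap extract --method tsca --stack sim/rep000_stack.tif \
    --schedule sim/rep000_schedule.json --frame-rate 100 --out scores.npz
vsdi-retinomap map --scores scores.npz --out map.npz
vsdi-retinomap evaluate --map map.npz --truth sim/rep000_truth.npz \
    --expected-n 5 --out metrics.json
vsdi-retinomap bench --snr -10 --methods all --reps 100 --seed 0 --out bench
```

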