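# tomowave

Wavelet denoising for cryo-electron tomography (cryo-ET), built around a
translation-invariant spline wavelet transform, plus the desk-scale
simulation harness needed to evaluate it: geometric phantoms, SNR-calibrated
Gaussian noise, parallel-beam tilt-series projection, and WBP/SIRT
reconstruction.

Cryo-ET volumes are acquired at extremely low electron dose, so the signal
of interest sits far below the noise floor (variance-ratio SNR on the order
of 0.1). `tomowave` is for people who need to suppress that noise before
visualization, segmentation or reconstruction without smearing away the fine
structure the experiment was done for — and who want to quantify the
trade-off instead of eyeballing it.

## The method

A noisy image is modelled as `f = I + ε` with `ε ~ N(0, σ²)` white Gaussian
noise. Denoising works in three steps:

1. **Forward transform.** A D-dimensional (D = 2 or 3), three-level,
   undecimated spline wavelet transform (dyadic à trous filter bank,
   quadratic-spline low-pass `[1,3,3,1]/8`, first-difference high-pass).
   Every band keeps the full image shape, so the decomposition is
   shift-invariant — no blocking artifacts from decimation.
2. **Coefficient modification.** One of four strategies:
   - `w1` — direct soft thresholding with the universal threshold
     λ = σ√(2 ln N);
   - `w2` — *modified shrinkage*: zero the chosen finest level(s) outright,
     then soft-threshold every remaining band `(j, d)` with the
     subband-dependent threshold λ = σ̂_j² / sd(W_j^d), where
     σ̂_j = Median(|W_j|)/0.6745 is the robust per-level noise estimate;
   - `w3` — spatially adaptive thresholding: replace bands by their
     5×5 (or 5×5×5) moving-window mean;
   - `w4` — cross-scale regularization: attenuate fine-level coefficients by
     the [0, 1]-normalized wavelet modulus `M_{j+1} = √(Σ_d (W_{j+1}^d)²)`
     of the next-coarser level, so only features persistent across scales
     survive.
3. **Inverse transform** of the modified coefficients.

The default configuration — three levels, strategy `w2`, level 1 zeroed,
subband-dependent soft thresholding — is the **modified wavelet shrinkage
filter**, the configuration that gives the best trade-off between noise
suppression and detail preservation on simulated cryo-ET data.

Output quality is measured against the noise-free reference `I` by

- SNR = Σ(I − Ī)² / Σ(f_denoised − I)²  (higher is better),
- MSE = (1/N) Σ(f_denoised − I)²  (lower is better),
- CCC, the centered cross-correlation coefficient in [−1, 1],

all computed within a mask (by default the phantom support dilated by two
voxels).

## Worked example

Run the whole simulation study — 64³ phantom, Gaussian noise at SNR 0.1,
every filter, then tilt-series (±69° at 3°) reconstruction by WBP and SIRT —
with one command:

```sh
tomowave demo --out-dir demo --seed 0
```

which writes `demo/metrics.csv`:

```
strategy,recon,snr,mse,ccc
noisy,none,0.099303,4.532026,0.299089
w1,none,1.129533,0.398432,0.524240
w2_1,none,2.686384,0.167527,0.821617
w2_12,none,1.819245,0.247378,0.728106
w2_123,none,1.129475,0.398452,0.524678
w3_1,none,2.538793,0.177266,0.785495
w4_12,none,2.286780,0.196802,0.754976
noisy,wbp,0.034657,12.985612,0.159918
noisy,sirt,0.511813,0.879310,0.386883
w2_1,wbp,1.596259,0.281935,0.704658
w2_1,sirt,1.495528,0.300925,0.684676
```

Reading the table: the noisy volume sits at its calibrated SNR of ~0.1;
the modified wavelet shrinkage filter (`w2_1`) lifts it to 2.69 while
keeping the highest CCC (0.82) — zeroing more levels (`w2_12`, `w2_123`)
smooths away detail and every metric degrades. On the reconstruction side,
SIRT tolerates the noisy tilt series far better than WBP (CCC 0.39 vs
0.16), and denoising the tilt series before reconstruction improves both
(0.70 and 0.68).

The same pieces are available individually (`simulate`, `denoise`,
`project`, `recon`, `metrics` subcommands; MRC and TIFF in, MRC out), or
from Python:

```python
import tomowave as tw

phantom = tw.make_phantom()
mask = tw.support_mask(phantom)
noisy = tw.add_noise_to_snr(phantom, target_snr=0.1, seed=0, mask=mask)
denoised = tw.denoise_image(noisy, tw.DenoiseConfig())  # w2_1 by default
print(tw.evaluate(denoised, phantom, mask).as_dict())
```

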