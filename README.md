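# gofshrink

Multiscale image denoising by locally-windowed goodness-of-fit tests.

Classic wavelet shrinkage compares each coefficient's *amplitude* to a
threshold. `gofshrink` instead makes a *distributional* decision: for every
detail coefficient of a noisy image's wavelet decomposition, the 5 x 5
window of normalized coefficients around it is tested against the
hypothesis that it is pure Gaussian noise. The test statistic is the
Anderson–Darling distance between the window's empirical distribution
function and the standard normal CDF,

    tau_i = -L - (1/L) * sum_{t=1..L} (2t-1) [ ln F(z_(t)) + ln(1 - F(z_(L+1-t))) ],

and the coefficient is kept verbatim when `tau_i > T_j` (signal) or zeroed
when `tau_i <= T_j` (noise). The scale thresholds `T_j` are calibrated by
Monte Carlo so that a chosen probability of false alarm `Pfa`
(`P(tau > T | noise)`, default 0.005) is met exactly on pure noise.

Two pipelines are provided:

- **GoFShrink-TI** — decimated DWT (db8, 5 levels) with cycle spinning
  (average over 16 circular shifts) for approximate translation
  invariance;
- **GoFShrink-DT** — dual-tree complex wavelet transform (six oriented
  complex subbands per scale, implemented in-package), with the test
  applied independently to real and imaginary parts.

Intended users: anyone denoising single-channel images under additive
Gaussian noise — MRI slices, fluorescence micrographs, standard test
imagery — who wants an interpretable, false-alarm-controlled alternative
to amplitude shrinkage. See `docs/methods.md` for the full model,
numerical choices and limitations.

## Worked example

No external data is needed; the package generates its own phantoms:

```sh
gofshrink phantom clean.png --kind mri_like_ellipses --size 256 --seed 7
gofshrink phantom noisy.png --kind mri_like_ellipses --size 256 --seed 7 --sigma 20
gofshrink evaluate clean.png noisy.png
gofshrink denoise noisy.png denoised.png --method dt --sidecar side.json
gofshrink evaluate clean.png denoised.png
```

which prints (noise realization fixed by the seed):

```
{ "mse": 315.650390625,  "psnr": 23.1387402975427 }   # noisy vs clean
INFO gofshrink: sigma_hat = 17.6263
INFO gofshrink: threshold scale1_real = 4.9910 (retained 0.0241)
INFO gofshrink: threshold scale2_real = 4.5346 (retained 0.1148)
...
{ "mse": 51.599700927734375, "psnr": 31.0043317640758 }  # denoised vs clean
```

Reading the numbers: the noisy file sits at 23.1 dB PSNR (a bit above the
nominal 22.1 dB for sigma = 20 because writing an 8-bit PNG clips the
noise at 0 and 255, which also explains `sigma_hat` = 17.6 < 20). The
denoiser retains only 2.4% of finest-scale coefficients — close to the
false-alarm rate, since that scale is almost pure noise — and
progressively more at coarser, signal-dominated scales, for an output at
31.0 dB: an 7.9 dB improvement. The first `denoise` call of a given
configuration spends ~25 s calibrating the threshold curve on synthetic
noise; curves are cached (and can be precomputed with
`gofshrink calibrate`).

The same pipeline from Python, without 8-bit clipping:

```python
import gofshrink as gs

clean = gs.make_phantom("piecewise_constant_shapes", 256, seed=1)
noisy = gs.add_gaussian_noise(clean, 20.0, seed=2)
result = gs.gofshrink_dt(noisy)                     # or gs.gofshrink_ti(noisy)
print(gs.psnr(clean, noisy), gs.psnr(clean, result.image))
# 22.14 -> 31.7 dB
```

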