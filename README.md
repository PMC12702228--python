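# raman3d

Joint spatial-spectral denoising of hyperspectral Raman image cubes with a
depthwise separable 3D MultiResU-Net — plus everything needed to study the
method end to end: a cellular phantom generator with exact ground truth, a
mixed Poisson-Gaussian detector-noise model, classical baselines
(Savitzky-Golay, PCA truncation), the standard image/spectrum quality
metrics, and a seeded one-command experiment pipeline.

## Who this is for

Hyperspectral Raman imaging (HRI) records a full Raman spectrum at every
pixel, giving an `H×W×B` cube whose third axis is the wavenumber (cm⁻¹).
Short per-pixel integration times make imaging fast but leave the cube
dominated by shot and read-out noise. This package is for spectroscopists
and methods developers who want to reconstruct high-SNR cubes from fast
acquisitions — or to benchmark cube-denoising ideas under controlled,
fully reproducible synthetic conditions.

## The model in brief

Noise is mixed Poisson-Gaussian,

    Y = α·Poisson(X/α) + N(0, σ²),      E[Y|X] = X,  Var[Y|X] = αX + σ²,

with gain α and additive read-noise σ. The denoiser is an encoder-decoder
(U-Net) over the whole cube that replaces standard 3D convolutions with
depthwise separable ones (`C·k³ + C·C_out` weights instead of
`C·C_out·k³`), adds residual blocks (DS conv + batch norm + PReLU), and
fuses multi-scale pseudo-3D features at each downsampling stage: spatial
`3×3×1`/`5×5×1` branches and spectral `1×1×3`/`1×1×5`/dilated `1×1×5` (rate
5)/dilated `1×1×7` (rate 7) branches, gated by squeeze-and-excitation
channel attention. Training uses Adam, batch 2, LR 1e-3 stepped to 1e-4,
and the composite loss `0.1·L1 + 0.9·MSE` on min-max-normalized cubes.
Quality is reported as band-averaged SSIM and PSNR (spatial) and per-pixel
spectral MSE and SNR. See `docs/methods.md` for the full account.

The network runs on numpy (with optional numba-accelerated kernels) through
a small built-in reverse-mode autodiff — no GPU or deep-learning framework
required.

## Worked example

```python
from raman3d.pipeline import run_experiment

manifest = run_experiment({
    "out_dir": "runs/demo",
    "seed": 1,
    "n_cubes": 12,                          # phantom cubes, 32×32×64
    "train": {"epochs": 30, "lr_drop_epoch": 18, "crops_per_cube": 1},
})
for method, report in manifest["metrics"].items():
    m = report["mean"]
    print(f"{method:8s} SSIM {m['ssim']:.3f} PSNR {m['psnr_db']:6.2f} "
          f"SNR {m['snr_db']:6.2f}")
```

This generates 12 seeded cellular phantoms, corrupts them with the
calibrated noise defaults (α=1, σ=2.5 → noisy input around 15–20 dB PSNR),
splits 0.8/0.1/0.1, trains a tiny 2-level width-8 network for 30 epochs on
one CPU core (a few minutes), denoises the test cubes with the network and
with Savitzky-Golay and PCA baselines tuned on the validation split, and
prints:

```
input    SSIM 0.094 PSNR  18.35 SNR   2.85
sg       SSIM 0.098 PSNR  18.21 SNR   1.81
pca      SSIM 0.136 PSNR  18.69 SNR   3.27
network  SSIM 0.378 PSNR  29.18 SNR  11.41
```

Read: the tuned classical baselines barely improve on the noisy input
(per-spectrum smoothing cannot exploit spatial context and inherits the
noisy cube's normalization), while the joint spatial-spectral network gains
~11 dB PSNR and quadruples SSIM. All artifacts (HDF5 cubes, checkpoint,
per-epoch history CSV, JSON/CSV reports, run manifest) land under
`runs/demo/`; re-running with the same config reproduces them bit for bit.

The same stages are available individually from the shell:

```bash
raman3d phantom --out-dir cubes --n 4 --seed 0
raman3d corrupt cubes/phantom_000.h5 --alpha 1.0 --sigma 2.5 --seed 1 --out noisy.h5
raman3d info noisy.h5
raman3d run --config experiment.yaml
raman3d denoise runs/demo/checkpoint.npz noisy.h5 --out denoised.h5
```

## Layout

| module | role |
| --- | --- |
| `raman3d.cube` | `HyperspectralCube`, HDF5 container round-trip, min-max normalization |
| `raman3d.phantom` | synthetic cellular cubes with exact abundance ground truth |
| `raman3d.noise` | Poisson-Gaussian corruption + parameter estimation |
| `raman3d.nn` | autodiff, DS-3D conv blocks, fusion, attention, the U-Net, Adam |
| `raman3d.training` | splits, paired augmentation, composite loss, training loop |
| `raman3d.metrics` / `raman3d.baselines` | SSIM/PSNR/MSE/SNR; S-G and PCA denoisers |
| `raman3d.pipeline` / `raman3d.cli` | end-to-end orchestration and the `raman3d` CLI |
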