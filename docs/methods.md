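# Methods

## Problem setting

Hyperspectral Raman imaging (HRI) acquires a full Raman spectrum at every
pixel of a scanned field, producing an `H×W×B` data cube (spatial height and
width in pixels, `B` spectral bands on a strictly increasing wavenumber axis
in cm⁻¹). Because spontaneous Raman scattering is weak, short per-pixel
integration times give cubes dominated by detector noise; long integration
times give clean cubes but take hours per cell. The package reconstructs
high-SNR cubes from low-SNR acquisitions with a convolutional network that
denoises the full cube jointly across the two spatial axes and the spectral
axis, and ships the surrounding experiment machinery: a synthetic phantom
generator with exact ground truth, a detector-noise model, classical
baselines, quality metrics and a one-command pipeline.

## Noise model

Raman spectral noise is modelled as mixed Poisson-Gaussian:

    Y = α · Poisson(X / α) + N(0, σ²)

- `X` — noise-free intensity (arbitrary detector units), `X ≥ 0`.
- `α > 0` — sensor/analog gain scaling the shot-noise (photon counting)
  term. The `Poisson(X/α)` parameterization is the standard CCD
  calibration form: it preserves the signal scale, `E[Y|X] = X`, and gives
  the affine conditional variance `Var[Y|X] = α·X + σ²`.
- `σ ≥ 0` — standard deviation of the additive read-out/dark noise,
  independent of the signal.

Negative outputs from the Gaussian term are kept by default (real detector
reads dip below baseline); a clip flag exists for display. `α → 0` is
disallowed; a purely additive regime is requested explicitly with
`gaussian_only=True`.

`estimate_noise_params` inverts the variance relation empirically: voxels
are binned by clean intensity (20 bins by default), the residual variance
is computed per bin, and a line `variance = α·intensity + σ²` is fitted.
Because a sample variance from `n` points has sampling variance
`≈ 2·var²/n`, the fit is generalized least squares with weights `n/var²`
after an unweighted pilot pass — without this the high-intensity bins,
whose variance estimates are noisiest in absolute terms, dominate and the
intercept (σ²) estimate becomes several times less efficient.

Default corruption parameters for the phantom experiments are `α = 1.0`,
`σ = 2.5` on phantom intensity units (background 5, peaks up to ~70). They
were calibrated once so that the noisy input of the desk-scale experiment
sits in the 15–20 dB PSNR band after per-cube normalization, the low-SNR
regime the denoiser targets.

## Phantom generator

Clean cubes are exact linear mixtures

    cube = background + Σ_c abundance_c ⊗ spectrum_c

with per-component `H×W` abundance maps and length-`B` component spectra.
Cells are random ellipses with a nucleus sub-ellipse; the default component
recipe is protein (1003, 1450, 1660 cm⁻¹), lipid (1085, 1302, 1440 cm⁻¹,
cytoplasm only) and DNA (795, 1095, 1578 cm⁻¹, nucleus only, elevated
abundance). Lines are Lorentzian by default (Raman lines are
near-Lorentzian); Gaussian is available for tests. Per-cell abundances are
drawn uniformly, textured per pixel, smoothed by a 1 px Gaussian blur and
re-masked to the cell support, so line profiles across a cell are
non-trivial while abundances stay exactly zero outside cells.

What the phantom does and does not emulate: it reproduces the
spatial-spectral low-rank structure, marker-band geometry and the noise
statistics of cellular HRI, which is what a spatial-spectral denoiser
exploits. It does not model autofluorescence baselines, cosmic-ray spikes,
instrument point-spread functions, or calibrated Raman cross-sections.
Passing tests on phantoms therefore demonstrate method behaviour
(denoising gain, method ordering, determinism), not clinical-grade
performance on real tissue data.

## Network

The denoiser is a 3D MultiResU-Net over `(N, 1, H, W, B)` normalized cubes:

- **Depthwise separable 3D convolution** — per-channel `k×k×k` filtering
  followed by `1×1×1` channel mixing; weights `C_in·k³ + C_in·C_out` versus
  `C_in·C_out·k³` for the standard convolution it replaces (344 vs 3456 at
  `C_in=8, C_out=16, k=3`).
- **Residual blocks** — one DS-conv layer with batch normalization and
  PReLU; identity shortcut when widths match, `1×1×1` projection otherwise.
- **Multi-scale feature fusion** at each encoder level before
  downsampling: four pseudo-3D spatial branches (two `3×3×1`, two `5×5×1`
  standard convolutions) and four spectral branches (`1×1×3`, `1×1×5`,
  `1×1×5` dilation 5, `1×1×7` dilation 7 — effective spectral spans 3, 5,
  21 and 43 samples). Each branch emits `C/8` channels; the concatenation
  restores `C` and is gated by squeeze-and-excitation channel attention
  (global average pool → `C→C/r→C` bottleneck, `r = 8` → sigmoid). The
  whole module is a config switch (`use_fusion`) for ablation.
- **Encoder/decoder** — 2×2×2 max pooling down, trilinear upsampling +
  DS conv up, skip concatenation, symmetric depth (default 3 levels, base
  width 16, growth ×2; the desk-scale experiments use 2 levels, width 8).
  Extents not divisible by `2^levels` are reflect-padded at the trailing
  edge and cropped back, so e.g. 58×58×812 cubes pass through unchanged in
  shape.
- **Global residual head** — a zero-initialized `1×1×1` convolution whose
  output is added to the input. The model therefore starts exactly at the
  identity and learns a correction; in short CPU-scale runs this removes
  the long "recover from random initialization" phase and makes training
  monotone-improving from the first epoch. This residual formulation is
  standard for image denoisers.

Design choices where the architecture family leaves freedom: channel
attention realized as squeeze-and-excitation; conv → batch-norm → PReLU
ordering (switchable via `norm_then_act`); dilations 5 and 7 assigned to
the `1×1×5` and `1×1×7` branches in listing order; fusion branch width
`C/8` to keep the module width-neutral. Depth and widths are free
parameters of `NetworkSpec` — no parity with any external implementation is
claimed.

### Numerics

No deep-learning framework is used: the network runs on a small
reverse-mode autodiff tape over numpy arrays (`raman3d.nn.autograd`), with
every operation's backward rule hand-derived and checked against finite
differences in the test suite. Convolution inner loops are JIT-compiled
with numba when available (bitwise-equivalent pure-numpy paths are kept and
tested); activations are float32, the channel-attention gate path runs in
float64 so its sigmoid stays strictly inside (0, 1). All randomness
(initialization, cropping, augmentation, noise) flows from explicit
`numpy.random.Generator` seeds, so identical configs reproduce identical
histories bit for bit on one machine.

## Training recipe

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 2, learning rate 1e-3
stepped to 1e-4 at a configurable drop epoch (default 60 of 100; the
desk-scale runs use 18 of 30, preserving the 60 % position). The loss is
`0.1·mean|r| + 0.9·mean r²` on min-max-normalized cubes. Splits follow
floor(train)/floor(val)/remainder — the rule that yields 115/14/15 from 144
items at 0.8/0.1/0.1. Augmentation applies one identical spatial transform
to both pair members: axis flips and 90° rotations in the image plane (the
spectral axis is never permuted). "Mixing" (pairwise convex blending with
λ ~ Beta(0.4, 0.4), identical λ on input and target) is implemented but off
by default and flagged experimental. Training crops random patches
(default 32×32×64) with a configurable number of crops per cube per epoch;
the best-on-validation parameter state (composite loss) is retained.

## Normalization and metric conventions

Each cube is normalized with one global (min, max) pair over all `H·W·B`
voxels (not per band), and the scale record is kept so outputs can be
mapped back to detector units. Metrics are computed on normalized data
with dynamic range `R = 1`; the convention is recorded in every report
(`normalized_inputs`), and raw-intensity evaluation is available by passing
`R = reference max`.

- **SSIM** per band, averaged over bands: canonical form with
  `C1 = (0.01R)²`, `C2 = (0.03R)²`; local moments from a sliding Gaussian
  window (σ = 1.5, width 7 — sized for small cellular maps) or whole-image
  moments (`window="global"`) for toy checks.
- **PSNR** `10·log10(R²/MSE)` per band, averaged; `inf` sentinel at zero
  error.
- **Spectral MSE** per pixel spectrum, averaged over pixels.
- **Spectral SNR** `10·log10(Σa²/Σ(b−a)²)` with total (summed) powers per
  pixel spectrum, averaged; a zero-power reference raises.

Baselines are applied the way spectroscopists use them: Savitzky-Golay
smoothing per pixel spectrum (polynomial-fit edges, no wrap) and PCA
truncation of the `(H·W)×B` matrix (rank-k reconstruction after
mean-centering). The pipeline tunes both on the validation split by mean
PSNR (window/order grid for S-G; component grid for PCA).

## Desk-scale experiment sizes

The end-to-end study runs 12 phantom cubes of 32×32×64 (two cells each),
split 0.8/0.1/0.1, noise at the calibrated default, a 2-level width-8
network (~11 k parameters), 30 epochs with 5 optimization steps per epoch,
and three seeds with median aggregation. These sizes were chosen so a full
three-seed study completes in minutes on one CPU core while still
exhibiting the qualitative result of interest: the joint spatial-spectral
network clearly outperforms tuned per-spectrum baselines (which are capped
both by in-subspace noise and by the per-cube normalization mismatch they
cannot correct).

## Known limitations

- The phantom's exact low-rank spectral structure flatters subspace
  methods less than real data might; conversely its spatial smoothness is
  favourable to convolutional denoisers. Conclusions are directional.
- Batch normalization with batch size 2 relies on running statistics for
  inference; very small training sets can leave those statistics noisy.
- Whole-cube inference on large cubes (e.g. 58×58×812) is supported via
  pad-and-crop but runs in seconds-to-minutes on one CPU core; there is no
  GPU path.
- The 1D per-spectrum U-Net family of baselines is out of scope; the
  comparison set is S-G, PCA and the noisy input.
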