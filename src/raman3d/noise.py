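"""Mixed Poisson-Gaussian corruption of clean cubes, and its calibration.

Raman spectral noise is dominated by shot noise (photon counting, variance
proportional to the signal) plus signal-independent read-out/dark noise.
The detector model used here is the standard CCD calibration form

    Y = α · Poisson(X / α) + N(0, σ²)

with gain ``α > 0`` and additive std ``σ ≥ 0``, which preserves the signal
scale — ``E[Y | X] = X`` — and gives the affine conditional variance
``Var[Y | X] = α·X + σ²``.  ``estimate_noise_params`` inverts that relation
empirically: it bins voxels by clean intensity, regresses the per-bin
residual variance on the bin's mean intensity, and reads α off the slope and
σ² off the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from raman3d.cube import HyperspectralCube
from raman3d.errors import EstimationError, ValidationError


@dataclass(frozen=True)
class NoiseModelParams:
    """Parameters of the mixed Poisson-Gaussian corruption.

    alpha: sensor/analog gain scaling the Poisson term (> 0).
    sigma: standard deviation of the additive Gaussian term (>= 0).
    seed: RNG seed; identical (clean, params) gives identical noisy output.
    gaussian_only: skip the Poisson term entirely (Y = X + N(0, σ²)).
    clip_negative: clip the clean input at zero instead of raising.
    """

    alpha: float = 1.0
    sigma: float = 0.0
    seed: int = 0
    gaussian_only: bool = False
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if not self.gaussian_only and self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")


def corrupt(clean: HyperspectralCube, params: NoiseModelParams) -> HyperspectralCube:
    """Apply mixed Poisson-Gaussian noise to a clean cube.

    Noise is independent across voxels.  Negative outputs from the Gaussian
    term are kept — real detector reads dip below baseline — so downstream
    code must tolerate values slightly below zero.
    """
    x = np.asarray(clean.data, dtype=np.float64)
    if np.any(x < 0):
        if not params.clip_negative:
            raise ValidationError(
                "clean cube has negative values; set clip_negative=True to clip at zero"
            )
        x = np.clip(x, 0.0, None)
    rng = np.random.default_rng(params.seed)
    if params.gaussian_only:
        y = x + rng.normal(0.0, params.sigma, size=x.shape)
    else:
        y = params.alpha * rng.poisson(x / params.alpha).astype(np.float64)
        if params.sigma > 0:
            y += rng.normal(0.0, params.sigma, size=x.shape)
    noisy = clean.with_data(y)
    return noisy


def estimate_noise_params(
    clean: HyperspectralCube,
    noisy: HyperspectralCube,
    n_bins: int = 20,
) -> tuple[float, float]:
    """Estimate (alpha, sigma²) from a paired clean/noisy cube.

    Bins voxels by clean intensity, computes the residual variance within
    each bin, and fits a generalized least-squares line
    ``variance = alpha · intensity + sigma²``.  A sample variance from n
    points has sampling variance ≈ 2·var²/n, so bins are weighted by
    ``n / var²`` (one reweighting pass after an unweighted pilot fit), which
    keeps the low-intensity bins — the ones that pin the intercept — from
    being drowned out by the noisy high-intensity bins.
    Returns ``(alpha_hat, sigma2_hat)``.

    Raises :class:`EstimationError` when fewer than two populated intensity
    bins exist (the line is then unidentifiable).
    """
    x = np.asarray(clean.data, dtype=np.float64).ravel()
    r = np.asarray(noisy.data, dtype=np.float64).ravel() - x
    if x.shape != r.shape:
        raise ValidationError("clean and noisy cubes must be congruent")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    means, variances, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n < 2:
            continue
        means.append(x[sel].mean())
        variances.append(r[sel].var(ddof=1))
        counts.append(n)
    if len(means) < 2:
        raise EstimationError(
            f"only {len(means)} populated intensity bins; need >= 2 to fit the "
            "variance-vs-intensity line"
        )
    means_arr = np.asarray(means, dtype=np.float64)
    var_arr = np.asarray(variances, dtype=np.float64)
    counts_arr = np.asarray(counts, dtype=np.float64)
    design = np.column_stack([means_arr, np.ones(len(means_arr))])

    def _wls(weights: np.ndarray) -> np.ndarray:
        w = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(design * w[:, None], var_arr * w, rcond=None)
        return coef

    coef = _wls(counts_arr)  # pilot fit, equal-variance weighting
    floor = max(float(var_arr.max()) * 1e-6, 1e-12)
    fitted = np.maximum(design @ coef, floor)
    weights = counts_arr / fitted**2  # GLS: Var(s²) ≈ 2·var²/n
    coef = _wls(weights / weights.max())
    return float(coef[0]), float(coef[1])
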