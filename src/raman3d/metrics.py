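"""Image- and spectrum-quality metrics for denoising evaluation.

Spatial quality uses SSIM and PSNR computed per spectral band and averaged;
spectral fidelity uses MSE and SNR computed per pixel spectrum and averaged.

SSIM follows the canonical form

    SSIM(x, y) = (2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2))

with C1 = (0.01·R)², C2 = (0.03·R)² for dynamic range R, local statistics
from a sliding Gaussian window (σ = 1.5, width 7 — sized for small cellular
maps) and a ``window="global"`` mode using whole-image moments for toys.

PSNR is 10·log10(R² / MSE); spectral SNR is 10·log10(Σ a² / Σ (b−a)²) with
total (summed) powers.  Both return ``inf`` when the estimate equals the
reference exactly.

By default all metrics are computed on min-max normalized data with R = 1;
``evaluate`` records that convention in its report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from raman3d.errors import ConfigError, ShapeError, ValidationError

WindowMode = Literal["gaussian", "global"]


def _check_congruent(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared difference over all points."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _check_congruent(a, b)
    if a.size == 0:
        raise ValidationError("empty input")
    return float(np.mean((b - a) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when y == x."""
    if dynamic_range <= 0:
        raise ConfigError(f"dynamic range must be > 0, got {dynamic_range}")
    err = mse(x, y)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(dynamic_range**2 / err))


def snr(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral signal-to-noise ratio in dB: total signal power over total
    residual power.  ``inf`` when b == a; errors on an identically-zero
    reference (signal power undefined)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _check_congruent(a, b)
    signal = float(np.sum(a * a))
    if signal == 0.0:
        raise ValidationError("reference is identically zero; SNR undefined")
    noise = float(np.sum((b - a) ** 2))
    if noise == 0.0:
        return float("inf")
    return float(10.0 * np.log10(signal / noise))


def _local_stats(img: np.ndarray, sigma: float, width: int) -> np.ndarray:
    radius = (width - 1) // 2
    # truncate chosen so the kernel half-width is exactly `radius` samples
    return ndimage.gaussian_filter(img, sigma, truncate=radius / sigma, mode="reflect")


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    dynamic_range: float = 1.0,
    window: WindowMode = "gaussian",
    sigma: float = 1.5,
    width: int = 7,
) -> float:
    """Structural similarity between two 2-D band images.

    ``window="gaussian"`` computes local moments under a sliding Gaussian
    window and averages the SSIM map over space; ``window="global"`` uses
    whole-image moments (one SSIM value).  Symmetric in (x, y); exactly 1.0
    when the images are identical.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_congruent(x, y)
    if x.ndim != 2:
        raise ShapeError(f"ssim expects 2-D band images, got {x.ndim}-D")
    if dynamic_range <= 0:
        raise ConfigError(f"dynamic range must be > 0, got {dynamic_range}")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2

    if window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = ((x - mu_x) * (y - mu_y)).mean()
    else:
        mu_x = _local_stats(x, sigma, width)
        mu_y = _local_stats(y, sigma, width)
        var_x = _local_stats(x * x, sigma, width) - mu_x**2
        var_y = _local_stats(y * y, sigma, width) - mu_y**2
        cov = _local_stats(x * y, sigma, width) - mu_x * mu_y

    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def ssim_cube(
    x: np.ndarray,
    y: np.ndarray,
    dynamic_range: float = 1.0,
    window: WindowMode = "gaussian",
) -> float:
    """SSIM of two H×W×B cubes: per-band SSIM averaged over bands."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_congruent(x, y)
    return float(np.mean([ssim(x[:, :, b], y[:, :, b], dynamic_range, window) for b in range(x.shape[2])]))


def psnr_cube(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0) -> float:
    """PSNR of two H×W×B cubes: per-band PSNR averaged over bands."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_congruent(x, y)
    return float(np.mean([psnr(x[:, :, b], y[:, :, b], dynamic_range) for b in range(x.shape[2])]))


def spectral_mse_cube(ref: np.ndarray, est: np.ndarray) -> float:
    """Per-pixel spectral MSE averaged over all pixels."""
    ref = np.asarray(ref, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    _check_congruent(ref, est)
    return float(np.mean((est - ref) ** 2))


def spectral_snr_cube(ref: np.ndarray, est: np.ndarray) -> float:
    """Per-pixel spectral SNR (dB) averaged over pixels.

    Pixels whose reference spectrum has zero power carry no defined SNR and
    are excluded; an identically-zero reference cube raises.
    """
    ref = np.asarray(ref, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    _check_congruent(ref, est)
    signal = np.sum(ref * ref, axis=2)
    if not np.any(signal > 0):
        raise ValidationError("reference cube is identically zero; SNR undefined")
    noise = np.sum((est - ref) ** 2, axis=2)
    valid = signal > 0
    with np.errstate(divide="ignore"):
        ratios = 10.0 * np.log10(signal[valid] / noise[valid])  # inf where noise == 0
    return float(np.mean(ratios))


@dataclass(frozen=True)
class MetricReport:
    """Per-sample and mean SSIM/PSNR/MSE/SNR over a test collection."""

    per_sample: tuple[tuple[float, float, float, float], ...]  # (ssim, psnr, mse, snr)
    mean_ssim: float
    mean_psnr_db: float
    mean_mse: float
    mean_snr_db: float
    n: int
    normalized_inputs: bool = True

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "normalized_inputs": self.normalized_inputs,
            "mean": {
                "ssim": self.mean_ssim,
                "psnr_db": self.mean_psnr_db,
                "mse": self.mean_mse,
                "snr_db": self.mean_snr_db,
            },
            "per_sample": [
                {"ssim": s, "psnr_db": p, "mse": m, "snr_db": r} for s, p, m, r in self.per_sample
            ],
        }


def evaluate(
    pred_cubes: Sequence[np.ndarray],
    ref_cubes: Sequence[np.ndarray],
    dynamic_range: float = 1.0,
    window: WindowMode = "gaussian",
    normalized_inputs: bool = True,
) -> MetricReport:
    """Score a collection of reconstructions against references.

    Spatial metrics (SSIM, PSNR) are computed per band and band-averaged;
    spectral metrics (MSE, SNR) per pixel spectrum and pixel-averaged; the
    report's means are arithmetic means over samples.
    """
    if len(pred_cubes) != len(ref_cubes):
        raise ShapeError(f"{len(pred_cubes)} predictions vs {len(ref_cubes)} references")
    if len(pred_cubes) == 0:
        raise ValidationError("empty collection")
    rows = []
    for pred, ref in zip(pred_cubes, ref_cubes):
        rows.append(
            (
                ssim_cube(ref, pred, dynamic_range, window),
                psnr_cube(ref, pred, dynamic_range),
                spectral_mse_cube(ref, pred),
                spectral_snr_cube(ref, pred),
            )
        )
    arr = np.asarray(rows, dtype=np.float64)
    return MetricReport(
        per_sample=tuple(tuple(float(v) for v in row) for row in rows),
        mean_ssim=float(arr[:, 0].mean()),
        mean_psnr_db=float(arr[:, 1].mean()),
        mean_mse=float(arr[:, 2].mean()),
        mean_snr_db=float(arr[:, 3].mean()),
        n=len(rows),
        normalized_inputs=normalized_inputs,
    )
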