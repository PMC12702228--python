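"""Classical per-spectrum denoising baselines: Savitzky-Golay and PCA.

Both operate the way spectroscopists apply them to hyperspectral cubes:
the S-G filter smooths each pixel's spectrum independently along the
spectral axis; PCA flattens the cube to a (H·W)×B matrix, mean-centers it,
and reconstructs from the top-k principal components (equivalently, the
rank-k truncated-SVD reconstruction of the centered matrix).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from raman3d.errors import ConfigError, ShapeError


def sg_denoise(cube_data: np.ndarray, window: int = 9, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing along the spectral axis of an H×W×B cube.

    ``window`` must be odd and no larger than the band count; ``polyorder``
    strictly smaller than ``window``.  Edges use polynomial-fit
    extrapolation (no wrap-around), the common spectroscopy convention.
    Spatial content is untouched.
    """
    cube_data = np.asarray(cube_data, dtype=np.float64)
    if cube_data.ndim != 3:
        raise ShapeError(f"expected H×W×B cube, got {cube_data.ndim} axes")
    n_bands = cube_data.shape[2]
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if window > n_bands:
        raise ConfigError(f"window {window} exceeds band count {n_bands}")
    if polyorder >= window:
        raise ConfigError(f"polyorder {polyorder} must be < window {window}")
    return savgol_filter(cube_data, window_length=window, polyorder=polyorder, axis=2, mode="interp")


def pca_denoise(cube_data: np.ndarray, k: int) -> np.ndarray:
    """Rank-k PCA reconstruction of the pixels×bands matrix.

    Keeps the top ``k`` principal components of the mean-centered
    (H·W)×B matrix and reconstructs, which suppresses the noise energy that
    lies outside the k-dimensional spectral subspace.
    """
    cube_data = np.asarray(cube_data, dtype=np.float64)
    if cube_data.ndim != 3:
        raise ShapeError(f"expected H×W×B cube, got {cube_data.ndim} axes")
    h, w, b = cube_data.shape
    max_k = min(h * w, b)
    if not 1 <= k <= max_k:
        raise ConfigError(f"k must be in [1, {max_k}], got {k}")
    matrix = cube_data.reshape(h * w, b)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix)
    reconstructed = pca.inverse_transform(scores)
    return reconstructed.reshape(h, w, b)


def tune_sg(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    windows: tuple[int, ...] = (5, 7, 9, 11, 15, 21),
    polyorders: tuple[int, ...] = (2, 3),
    score=None,
) -> tuple[int, int]:
    """Pick the (window, polyorder) maximizing mean PSNR on (noisy, clean) pairs."""
    from raman3d.metrics import psnr_cube

    score = score or psnr_cube
    best, best_score = (windows[0], polyorders[0]), -np.inf
    for window in windows:
        if window > pairs[0][0].shape[2]:
            continue
        for polyorder in polyorders:
            if polyorder >= window:
                continue
            value = float(np.mean([score(clean, sg_denoise(noisy, window, polyorder)) for noisy, clean in pairs]))
            if value > best_score:
                best, best_score = (window, polyorder), value
    return best


def tune_pca(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 15, 20),
    score=None,
) -> int:
    """Pick the component count k maximizing mean PSNR on (noisy, clean) pairs."""
    from raman3d.metrics import psnr_cube

    score = score or psnr_cube
    max_k = min(pairs[0][0].shape[0] * pairs[0][0].shape[1], pairs[0][0].shape[2])
    best_k, best_score = 1, -np.inf
    for k in k_grid:
        if k > max_k:
            continue
        value = float(np.mean([score(clean, pca_denoise(noisy, k)) for noisy, clean in pairs]))
        if value > best_score:
            best_k, best_score = k, value
    return best_k
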