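"""Gabor-energy and Gist-PC baseline feature spaces for images.

A multi-scale, multi-orientation Gabor filter bank with quadrature pairs
(energy model), responses pooled over a coarse spatial grid -- the classic
"gist"-style descriptor of low-level image structure. At the published
configuration (16 x 16 grid; 12, 8, 6 and 4 orientations over four scales)
the flattened feature length is 16^2 * (12 + 8 + 6 + 4) = 7680. The GistPC
variant keeps the first principal components of the Gabor feature matrix.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import gabor_kernel
from sklearn.decomposition import PCA

DEFAULT_ORIENTATIONS = (12, 8, 6, 4)
#: one frequency per scale, octave-spaced (cycles per pixel)
DEFAULT_FREQUENCIES = (0.25, 0.125, 0.0625, 0.03125)


def _cyclic_filter(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cyclic (FFT) convolution, same output size as the image.

    The kernel is embedded centered at the origin with wrap-around, so
    kernels larger than the image alias cyclically (the correct periodic
    convolution for any kernel size).
    """
    h, w = image.shape
    kh, kw = kernel.shape
    pad = np.zeros((h, w), dtype=complex)
    ky = (np.arange(kh) - kh // 2) % h
    kx = (np.arange(kw) - kw // 2) % w
    np.add.at(pad, (ky[:, None], kx[None, :]), kernel)
    return np.fft.ifft2(np.fft.fft2(image) * np.fft.fft2(pad))


def _pool_grid(resp: np.ndarray, grid: int) -> np.ndarray:
    """Mean-pool a response map over a grid x grid partition."""
    h, w = resp.shape
    rows = np.array_split(np.arange(h), grid)
    cols = np.array_split(np.arange(w), grid)
    out = np.empty((grid, grid))
    for i, r in enumerate(rows):
        block = resp[r]
        for j, c in enumerate(cols):
            out[i, j] = block[:, c].mean()
    return out


def gabor_features(
    images: np.ndarray,
    grid: int = 16,
    orientations: tuple[int, ...] = DEFAULT_ORIENTATIONS,
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES,
    bandwidth: float = 1.0,
) -> np.ndarray:
    """Pooled Gabor-energy features for a stack of grayscale images.

    ``images`` has shape (n, H, W) with H, W >= grid. Returns an
    (n, grid^2 * sum(orientations)) matrix ordered scale-major, then
    orientation, then grid cell (row-major).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValueError("images must be a (n, H, W) stack of grayscale images")
    n, h, w = images.shape
    if h < grid or w < grid:
        raise ValueError(f"image size {h}x{w} smaller than the {grid}x{grid} grid")
    if len(orientations) != len(frequencies):
        raise ValueError("orientations and frequencies must align per scale")

    kernels = []
    for n_ori, freq in zip(orientations, frequencies):
        for oi in range(n_ori):
            theta = np.pi * oi / n_ori
            k = gabor_kernel(frequency=freq, theta=theta, bandwidth=bandwidth)
            k = k - k.mean()  # DC-free: constant images evoke no energy
            kernels.append(k)

    n_feat = grid * grid * sum(orientations)
    out = np.empty((n, n_feat))
    for ii in range(n):
        img = images[ii]
        col = 0
        for k in kernels:
            energy = np.abs(_cyclic_filter(img, k))  # quadrature-pair energy
            out[ii, col : col + grid * grid] = _pool_grid(energy, grid).ravel()
            col += grid * grid
    return out


def gistpc_features(gabor: np.ndarray, n_pc: int = 50) -> np.ndarray:
    """First ``n_pc`` principal-component scores of a Gabor feature matrix.

    Centered PCA with components ordered by explained variance; requires
    more samples than components.
    """
    gabor = np.asarray(gabor, dtype=float)
    if gabor.shape[0] <= n_pc:
        raise ValueError(
            f"need more than n_pc={n_pc} samples (got {gabor.shape[0]})"
        )
    pca = PCA(n_components=n_pc, svd_solver="full")
    return pca.fit_transform(gabor)
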