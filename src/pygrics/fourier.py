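"""Centered unitary 2D Fourier transforms shared by all k-space code.

The DC component sits at ``(Ny // 2, Nx // 2)``; the transforms are unitary
(norm-preserving), so the encoding operator's energy bookkeeping is exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cfft2", "cifft2", "crop_center", "pad_center"]


def cfft2(img: np.ndarray) -> np.ndarray:
    """Image -> centered k-space (unitary)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho", axes=(-2, -1)), axes=(-2, -1))


def cifft2(ksp: np.ndarray) -> np.ndarray:
    """Centered k-space -> image (unitary)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho", axes=(-2, -1)), axes=(-2, -1))


def crop_center(arr: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Central crop of the last two axes (k-space truncation)."""
    Ny, Nx = arr.shape[-2:]
    y0 = Ny // 2 - ny // 2
    x0 = Nx // 2 - nx // 2
    return arr[..., y0 : y0 + ny, x0 : x0 + nx]


def pad_center(arr: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Zero-pad the last two axes back onto a larger centered grid."""
    Ny, Nx = arr.shape[-2:]
    out = np.zeros(arr.shape[:-2] + (ny, nx), dtype=arr.dtype)
    y0 = ny // 2 - Ny // 2
    x0 = nx // 2 - Nx // 2
    out[..., y0 : y0 + Ny, x0 : x0 + Nx] = arr
    return out
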