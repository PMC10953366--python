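"""Linear sensor-driven motion model and non-rigid image warping.

The motion model is ``u(x, y, t) = alpha(x, y) * s(t)``: a per-pixel pair of
coefficients (pixels per unit sensor amplitude) scaled by the scalar belt
signal. Warping is a backward (pull) bilinear interpolation with zero
contribution from outside the field of view; it is realized as an explicit
sparse matrix so the adjoint is the exact transpose — the property conjugate
gradients on the normal equations requires, and distinct from the inverse
warp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import map_coordinates, uniform_filter1d

from .datamodel import Geometry

__all__ = [
    "AlphaMaps",
    "DisplacementField",
    "predict_displacement",
    "warp_matrix",
    "warp_image",
    "warp_adjoint",
    "interpolate_alpha",
    "frame_displacement_delta",
]


@dataclass
class AlphaMaps:
    """Per-pixel motion-model coefficients, ``coeff[(dy, dx), y, x]``.

    Units are pixels of in-plane displacement per unit sensor amplitude.
    """

    coeff: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.coeff = np.asarray(self.coeff, dtype=np.float64)
        if self.coeff.shape != (2, self.geometry.ny, self.geometry.nx):
            raise ValueError("coeff must be (2, Ny, Nx) matching geometry")
        if not np.all(np.isfinite(self.coeff)):
            raise ValueError("coeff must be finite")

    @classmethod
    def zeros(cls, geometry: Geometry) -> "AlphaMaps":
        return cls(np.zeros((2, geometry.ny, geometry.nx)), geometry)


@dataclass
class DisplacementField:
    """In-plane displacement ``u[(dy, dx), y, x]`` in pixel units."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[0] != 2:
            raise ValueError("u must be (2, Ny, Nx)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("u must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[1:]


def predict_displacement(alpha: AlphaMaps, s_value: float) -> DisplacementField:
    """Displacement field at sensor amplitude ``s_value`` (linear in s)."""
    return DisplacementField(alpha.coeff * float(s_value))


def warp_matrix(u: DisplacementField) -> sp.csr_matrix:
    """Sparse matrix of the backward bilinear warp on a ``(Ny, Nx)`` grid.

    Row ``p`` holds the (up to four) bilinear weights that sample the input
    image at ``x_p + u(x_p)``; source positions outside the grid contribute
    zero, so the matrix row may sum to less than one near the boundary.
    """
    ny, nx = u.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    sy = (yy + u.u[0]).ravel()
    sx = (xx + u.u[1]).ravel()
    y0 = np.floor(sy).astype(np.int64)
    x0 = np.floor(sx).astype(np.int64)
    fy = sy - y0
    fx = sx - x0

    rows, cols, vals = [], [], []
    row_idx = np.arange(ny * nx)
    for dy, dx, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yi = y0 + dy
        xi = x0 + dx
        ok = (yi >= 0) & (yi < ny) & (xi >= 0) & (xi < nx) & (w > 0)
        rows.append(row_idx[ok])
        cols.append(yi[ok] * nx + xi[ok])
        vals.append(w[ok])
    n = ny * nx
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def warp_image(img: np.ndarray, u: DisplacementField) -> np.ndarray:
    """Backward-warp a 2D (possibly complex) image by ``u``."""
    if img.shape != u.shape:
        raise ValueError(f"image shape {img.shape} != field shape {u.shape}")
    W = warp_matrix(u)
    return (W @ img.ravel()).reshape(img.shape)


def warp_adjoint(img: np.ndarray, u: DisplacementField) -> np.ndarray:
    """Exact transpose of :func:`warp_image` for the same ``u``.

    This is the scatter (push) operation, not the inverse warp.
    """
    if img.shape != u.shape:
        raise ValueError(f"image shape {img.shape} != field shape {u.shape}")
    W = warp_matrix(u)
    return (W.T @ img.ravel()).reshape(img.shape)


def _physical_coords_1d(n: int, spacing: float) -> np.ndarray:
    # pixel centres, origin at the grid centre
    return (np.arange(n) - (n - 1) / 2.0) * spacing


def interpolate_alpha(alpha: AlphaMaps, dst_geometry: Geometry, order: int = 1) -> AlphaMaps:
    """Resample motion-model coefficients onto a new image geometry.

    Interpolation happens in physical (mm) coordinates with grids aligned at
    their centres; the pixel-unit coefficients are rescaled by the pixel-size
    ratio so that the *physical* displacement ``coeff * spacing`` is
    preserved. Used to carry a model estimated on one sequence's geometry
    over to another sequence reconstructed without a motion-update step.
    """
    src = alpha.geometry
    half_src = (src.ny * src.pixel_spacing[0] / 2, src.nx * src.pixel_spacing[1] / 2)
    half_dst = (
        dst_geometry.ny * dst_geometry.pixel_spacing[0] / 2,
        dst_geometry.nx * dst_geometry.pixel_spacing[1] / 2,
    )
    if min(half_src[0], half_dst[0]) <= 0 or min(half_src[1], half_dst[1]) <= 0:
        raise ValueError("empty geometry")
    if half_dst[0] > 50 * half_src[0] or half_dst[1] > 50 * half_src[1]:
        raise ValueError("source and destination fields of view do not overlap")

    y_dst = _physical_coords_1d(dst_geometry.ny, dst_geometry.pixel_spacing[0])
    x_dst = _physical_coords_1d(dst_geometry.nx, dst_geometry.pixel_spacing[1])
    # physical mm -> fractional source pixel index
    iy = y_dst / src.pixel_spacing[0] + (src.ny - 1) / 2.0
    ix = x_dst / src.pixel_spacing[1] + (src.nx - 1) / 2.0
    grid = np.meshgrid(iy, ix, indexing="ij")
    out = np.empty((2, dst_geometry.ny, dst_geometry.nx))
    scale = (
        src.pixel_spacing[0] / dst_geometry.pixel_spacing[0],
        src.pixel_spacing[1] / dst_geometry.pixel_spacing[1],
    )
    for c in range(2):
        out[c] = map_coordinates(alpha.coeff[c], grid, order=order, mode="nearest") * scale[c]
    return AlphaMaps(out, dst_geometry)


def frame_displacement_delta(
    u_curr: np.ndarray, u_prev: np.ndarray, smooth_window: int = 3
) -> np.ndarray:
    """Frame-to-frame displacement increment, optionally slice-smoothed.

    ``du = u_curr - u_prev`` gives the per-frame motion direction and
    amplitude. For stacked multi-slice fields (leading axis = slice) a
    moving-average of ``smooth_window`` slices is applied along that axis;
    ``smooth_window=1`` disables smoothing.
    """
    u_curr = np.asarray(u_curr, dtype=np.float64)
    u_prev = np.asarray(u_prev, dtype=np.float64)
    if u_curr.shape != u_prev.shape:
        raise ValueError("displacement shapes differ")
    du = u_curr - u_prev
    if smooth_window > 1 and du.ndim == 4:  # (slice, 2, Ny, Nx)
        du = uniform_filter1d(du, size=smooth_window, axis=0, mode="nearest")
    return du
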