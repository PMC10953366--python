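"""Coil-sensitivity estimation from central k-space and SoS normalization.

Sensitivities are estimated from the fully sampled central band (32 lines
for the fully sampled protocol, 24 calibration lines for the accelerated
one), apodized, inverse-transformed, divided by the root-sum-of-squares
image and smoothed with a penalized (smoothing-spline) filter with roughness
weight ``lambda_smooth = 1000`` applied to magnitude and phase separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn

from .datamodel import ImageVolume, KSpaceData
from .fourier import cfft2, cifft2

__all__ = [
    "CoilMaps",
    "estimate_coil_maps",
    "refine_coil_maps",
    "sos_normalize",
    "spline_smooth2d",
]


@dataclass
class CoilMaps:
    """Complex per-coil sensitivity images, ``maps[(coil), y, x]``."""

    maps: np.ndarray
    n_center_lines_used: int = 0
    smoothing_coeff: float = 0.0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (coil, Ny, Nx)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps must be finite")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


def spline_smooth2d(
    field: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
    n_iter: int = 30,
) -> np.ndarray:
    """Penalized 2D smoother: minimize ``sum w |x - y|^2 + lam |D2 x|^2``.

    The unweighted problem is solved exactly in the DCT domain (reflective
    boundaries) — the discrete analogue of a thin smoothing spline. The
    Laplacian eigenvalues are normalized to [0, 1], so ``lam`` controls the
    grid-size-independent cutoff wavelength (``lam = 1000`` keeps structure
    smoother than roughly a tenth of the field of view). With ``weights``
    (in [0, 1]; low-confidence samples near 0) the weighted normal
    equations are solved by a preconditioned fixed-point iteration, so
    unreliable samples are interpolated from reliable neighbours instead of
    dragging them.
    """
    if lam <= 0:
        return field
    ny, nx = field.shape
    wy = 2.0 - 2.0 * np.cos(np.pi * np.arange(ny) / ny)
    wx = 2.0 - 2.0 * np.cos(np.pi * np.arange(nx) / nx)
    gain = 1.0 / (1.0 + lam * ((wy[:, None] + wx[None, :]) / 8.0) ** 2)

    def smooth(f: np.ndarray) -> np.ndarray:
        return idctn(dctn(f, norm="ortho") * gain, norm="ortho")

    if weights is None:
        return smooth(field)
    w = np.clip(weights, 0.0, 1.0)
    x = smooth(field)
    for _ in range(n_iter):
        x = smooth(w * field + (1.0 - w) * x)
    return x


def _central_band_images(ks: KSpaceData, n_center_lines: int) -> np.ndarray:
    """Low-resolution coil images from the apodized central k-space band."""
    ny, nx = ks.geometry.ny, ks.geometry.nx
    lo = ny // 2 - n_center_lines // 2
    hi = lo + n_center_lines
    grid = np.zeros((ks.n_coils, ny, nx), dtype=np.complex128)
    present = np.zeros(ny, dtype=bool)
    pe = ks.line_meta.phase_encode_index
    for i, row in enumerate(pe):
        if lo <= row < hi:
            grid[:, row, :] = ks.samples[:, i, :]
            present[row] = True
    if present[lo:hi].sum() < n_center_lines:
        raise ValueError(
            f"requested {n_center_lines} central lines but only "
            f"{int(present[lo:hi].sum())} are sampled"
        )
    # Hann apodization across the band suppresses truncation ringing
    window = np.hanning(n_center_lines + 2)[1:-1]
    grid[:, lo:hi, :] *= window[None, :, None]
    return cifft2(grid)


def estimate_coil_maps(
    ks: KSpaceData, n_center_lines: int, smoothing_coeff: float = 1000.0
) -> CoilMaps:
    """Estimate smooth, RSS-normalized coil sensitivities.

    Per coil: zero-fill all but the central phase-encode band, Hann-apodize,
    inverse Fourier transform, divide by the root-sum-of-squares across
    coils, then smooth magnitude and phase with roughness weight
    ``smoothing_coeff``. Phase smoothing operates on the real/imaginary
    parts of the unit-phase field (no unwrapping), which is well behaved at
    low SNR. The returned maps have RSS approximately 1 inside the object.
    """
    low = _central_band_images(ks, n_center_lines)
    # the ratio is only trustworthy where the object gave signal; the shared
    # smoothing helper weights the fit by signal confidence (saturating at
    # 15% of peak RSS so moderate-intensity tissue counts as fully reliable)
    out = _ratio_smooth(low, smoothing_coeff)
    return CoilMaps(out, n_center_lines_used=n_center_lines, smoothing_coeff=smoothing_coeff)


def _ratio_smooth(imgs: np.ndarray, smoothing_coeff: float) -> np.ndarray:
    """Object-cancelling ratio + weighted smoothing + RSS renormalization."""
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    raw = imgs / np.maximum(rss, 1e-6 * max(float(rss.max()), 1e-30))[None]
    conf = np.clip(rss / (0.15 * max(float(rss.max()), 1e-30)), 0.0, 1.0) ** 2
    out = np.empty_like(raw)
    for c in range(raw.shape[0]):
        mag = spline_smooth2d(np.abs(raw[c]), smoothing_coeff, weights=conf, n_iter=60)
        phase = raw[c] / np.maximum(np.abs(raw[c]), 1e-12)
        pr = spline_smooth2d(phase.real, smoothing_coeff, weights=conf, n_iter=60)
        pi = spline_smooth2d(phase.imag, smoothing_coeff, weights=conf, n_iter=60)
        out[c] = mag * (pr + 1j * pi) / np.maximum(np.hypot(pr, pi), 1e-12)
    rss_s = np.sqrt(np.sum(np.abs(out) ** 2, axis=0))
    out /= np.maximum(rss_s, 1e-6 * max(float(rss_s.max()), 1e-30))[None]
    return out


def refine_coil_maps(
    ks: KSpaceData,
    state_of_line: np.ndarray,
    displacements: list,
    smoothing_coeff: float = 1000.0,
    maxit: int = 15,
) -> CoilMaps:
    """Re-estimate sensitivities using the current motion model.

    The initial central-band estimate is taken from motion-mixed k-space, so
    motion ghosting leaks into the maps and masquerades as coil structure.
    Once a displacement model exists, each coil's image can instead be
    reconstructed motion-compensated (a small conjugate-gradient solve of
    ``min_x sum_k |S_k F W_k x - m_ck|^2`` per coil); the coil ratio of
    those images cancels the shared anatomy exactly and yields much cleaner
    maps. Called between fixed-point levels of the joint solver.
    """
    # local import: motion imports nothing from coils, so no cycle
    from .motion import warp_matrix

    geo = ks.geometry
    ny, nx = geo.ny, geo.nx
    pe = ks.line_meta.phase_encode_index
    state_of_line = np.asarray(state_of_line)
    warps = {int(k): warp_matrix(displacements[int(k)]) for k in np.unique(state_of_line)}
    masks = {}
    for k in warps:
        rows = pe[state_of_line == k]
        msk = np.zeros((ny, nx))
        msk[rows, :] = 1.0
        masks[k] = msk

    imgs = np.empty((ks.n_coils, ny, nx), dtype=np.complex128)
    for c in range(ks.n_coils):
        b = np.zeros((ny, nx), dtype=np.complex128)
        for k, W in warps.items():
            lines = np.flatnonzero(state_of_line == k)
            grid = np.zeros((ny, nx), dtype=np.complex128)
            grid[pe[lines], :] = ks.samples[c, lines, :]
            b += (W.T @ cifft2(grid).ravel()).reshape(ny, nx)

        def normal(x: np.ndarray) -> np.ndarray:
            xi = x.reshape(ny, nx)
            out = np.zeros((ny, nx), dtype=np.complex128)
            for k, W in warps.items():
                f = cfft2((W @ xi.ravel()).reshape(ny, nx))
                out += (W.T @ cifft2(f * masks[k]).ravel()).reshape(ny, nx)
            return (out + 1e-4 * xi).ravel()

        # plain CG on the per-coil normal equations
        x = np.zeros(ny * nx, dtype=np.complex128)
        r = b.ravel().copy()
        p = r.copy()
        rs = np.vdot(r, r).real
        b0 = np.sqrt(rs)
        for _ in range(maxit):
            if b0 == 0 or np.sqrt(rs) / b0 < 1e-4:
                break
            Ap = normal(p)
            a = rs / np.vdot(p, Ap).real
            x += a * p
            r -= a * Ap
            rs_new = np.vdot(r, r).real
            p = r + (rs_new / rs) * p
            rs = rs_new
        imgs[c] = x.reshape(ny, nx)

    return CoilMaps(
        _ratio_smooth(imgs, smoothing_coeff),
        n_center_lines_used=0,
        smoothing_coeff=smoothing_coeff,
    )


def sos_normalize(img: ImageVolume, maps: CoilMaps, floor_rel: float = 1e-6) -> ImageVolume:
    """Divide pixelwise by the sum of squared coil-sensitivity magnitudes.

    The denominator is floored at ``floor_rel`` times its maximum so
    background zeros cannot blow up.
    """
    ss = np.sum(np.abs(maps.maps) ** 2, axis=0)
    if img.data.shape[1:] != ss.shape:
        raise ValueError("image and coil-map shapes differ")
    denom = np.maximum(ss, floor_rel * float(ss.max()))
    return ImageVolume(img.data / denom[None], img.geometry)
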