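"""Synthetic test bed: phantom, breathing drive, motion fields, coils, k-space.

Emulates a supine breast-like 2D object deforming in-plane under a
quasi-periodic respiratory drive, acquired shot-by-shot by a multi-coil
Cartesian sequence (fully sampled, or uniformly undersampled with a fully
sampled central calibration band). Every generator is deterministic per
seed, and ground truth (object, coefficients, per-shot sensor value) is
returned alongside the data so reconstruction accuracy is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .coils import CoilMaps
from .datamodel import Geometry, ImageVolume, KSpaceData, LineMeta, RespSignal
from .fourier import cfft2
from .motion import AlphaMaps, predict_displacement, warp_image

__all__ = [
    "make_phantom",
    "make_resp",
    "make_alpha",
    "make_coils",
    "simulate_acquisition",
    "Protocol",
    "SimulationTruth",
]


def make_phantom(size: int, seed: int = 0) -> tuple[ImageVolume, np.ndarray]:
    """Breast-like 2D phantom: two half-elliptical lobes on a chest wall.

    Returns the normalized image (range [0, 1]) and its boolean support
    mask. Internal texture is smooth ellipsoidal "glandular" structure so
    that sharpness metrics have edges to measure.
    """
    if size < 32:
        raise ValueError("phantom size must be >= 32")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    yn = y / (size - 1)
    xn = x / (size - 1)

    img = np.zeros((size, size))
    # chest-wall band along the top
    wall = 0.35 * np.exp(-(((yn - 0.07) / 0.06) ** 2))
    img += wall
    support = yn < 0.16

    # two half-elliptical lobes hanging from the wall
    lobes = []
    for cx in (0.30, 0.70):
        e = ((yn - 0.12) / 0.62) ** 2 + ((xn - cx) / 0.24) ** 2
        lobe = (e < 1.0) & (yn >= 0.10)
        lobes.append(lobe)
        img[lobe] = np.maximum(img[lobe], 0.55 * (1.0 - 0.5 * e[lobe]))
        support |= lobe

    # glandular texture: random bright ellipsoids inside the lobes
    for lobe, cx in zip(lobes, (0.30, 0.70)):
        for _ in range(6):
            gy = rng.uniform(0.2, 0.65)
            gx = cx + rng.uniform(-0.12, 0.12)
            ry = rng.uniform(0.03, 0.08)
            rx = rng.uniform(0.03, 0.08)
            amp = rng.uniform(0.25, 0.45)
            blob = np.exp(-(((yn - gy) / ry) ** 2 + ((xn - gx) / rx) ** 2))
            img += amp * blob * lobe

    img = gaussian_filter(img, 0.8)
    img *= support | (yn < 0.16)
    img -= img.min()
    img /= img.max()
    geometry = Geometry(size, size, (1.0, 1.0), 3.0)
    return ImageVolume(img[None], geometry), support


def make_resp(
    duration_s: float,
    rate_hz: float = 50.0,
    period_s: float = 4.0,
    drift_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    asymmetry: float = 0.3,
) -> RespSignal:
    """Quasi-periodic belt signal: asymmetric raised cosine + drift + noise.

    The inhale/exhale asymmetry is produced by warping the phase of a
    raised cosine (inspiration faster than expiration, as a corrugated-tube
    belt records it); quadratic drift emulates slow air leaks.
    """
    if rate_hz < 10:
        raise ValueError("sensor rate must be >= 10 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    phase = 2 * np.pi * t / period_s
    warped = phase + asymmetry * np.sin(phase)
    breathing = amplitude * 0.5 * (1.0 - np.cos(warped))
    a0, a1, a2 = drift_coeffs
    drift = a0 + a1 * t + a2 * t**2
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    return RespSignal(breathing + drift + noise, sample_rate=rate_hz, t0=0.0)


def _support_taper(geometry: Geometry) -> np.ndarray:
    """Smooth weight, 1 in the breast, rolling off to 0 at the image edges.

    The chest wall stays nearly still, so the taper also suppresses motion
    in the top band (chest-attached anatomy).
    """
    ny, nx = geometry.ny, geometry.nx
    y, x = np.mgrid[0:ny, 0:nx].astype(np.float64)
    yn = y / (ny - 1)
    xn = x / (nx - 1)
    lateral = np.clip((0.5 - np.abs(xn - 0.5)) / 0.18, 0.0, 1.0)
    bottom = np.clip((0.92 - yn) / 0.15, 0.0, 1.0)
    top = np.clip((yn - 0.08) / 0.15, 0.0, 1.0)
    w = lateral * bottom * top
    return gaussian_filter(w, min(ny, nx) * 0.03)


def make_alpha(
    geometry: Geometry,
    pattern: str = "vertical",
    amplitude_px: float = 5.0,
    seed: int = 0,
) -> AlphaMaps:
    """Smooth ground-truth motion-model coefficients (pixels per unit s).

    Patterns mirror the deformation regimes seen across subjects:
    ``vertical`` (dominant up-down motion growing away from the chest
    wall), ``expansion`` (radial in/out) and ``shear`` (lateral motion
    growing with depth). Fields taper to zero outside a chest-attached
    support so the object never slides as a rigid block.
    """
    if amplitude_px > 8:
        raise ValueError("amplitude above 8 px is outside the supported regime")
    ny, nx = geometry.ny, geometry.nx
    y, x = np.mgrid[0:ny, 0:nx].astype(np.float64)
    yn = y / (ny - 1)
    xn = x / (nx - 1)
    taper = _support_taper(geometry)
    coeff = np.zeros((2, ny, nx))
    if pattern == "vertical":
        ramp = np.clip((yn - 0.1) / 0.9, 0.0, 1.0)
        coeff[0] = amplitude_px * ramp
        coeff[1] = 0.15 * amplitude_px * ramp * np.sin(2 * np.pi * xn)
    elif pattern == "expansion":
        ry = yn - 0.5
        rx = xn - 0.5
        r = np.hypot(ry, rx) + 1e-9
        mag = amplitude_px * np.clip(r / 0.5, 0.0, 1.0)
        coeff[0] = mag * ry / r
        coeff[1] = mag * rx / r
    elif pattern == "shear":
        coeff[1] = amplitude_px * np.clip((yn - 0.1) / 0.9, 0.0, 1.0)
        coeff[0] = 0.1 * amplitude_px * np.clip((yn - 0.1) / 0.9, 0.0, 1.0)
    else:
        raise ValueError(f"unknown motion pattern '{pattern}'")
    coeff *= taper[None]
    sigma = min(ny, nx) * 0.02
    for c in range(2):
        coeff[c] = gaussian_filter(coeff[c], sigma)
    return AlphaMaps(coeff, geometry)


def make_coils(n_coils: int, geometry: Geometry, seed: int = 0) -> CoilMaps:
    """Smooth Gaussian-lobe receive sensitivities, RSS-normalized to 1.

    Lobe centres ring the field of view (surface-coil array geometry) with
    a seed-dependent jitter; a single coil degenerates to a flat unit map.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    ny, nx = geometry.ny, geometry.nx
    if n_coils == 1:
        return CoilMaps(np.ones((1, ny, nx), dtype=np.complex128))
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:ny, 0:nx].astype(np.float64)
    maps = np.empty((n_coils, ny, nx), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cy = ny / 2 + 0.55 * ny * np.sin(ang)
        cx = nx / 2 + 0.55 * nx * np.cos(ang)
        width = 0.55 * min(ny, nx) * rng.uniform(0.9, 1.1)
        mag = np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2 * width**2)))
        phase = rng.uniform(-np.pi, np.pi) + 0.5 * ((y - cy) / ny + (x - cx) / nx)
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[None]
    return CoilMaps(maps)


@dataclass
class Protocol:
    """Cartesian shot structure of the simulated sequence."""

    lines_per_shot: int = 1
    shot_interval_s: float = 1.0
    acceleration: int = 1
    n_center_lines: int = 0  # calibration band width when accelerated
    noise_sd: float = 0.0  # complex-noise std per k-space sample


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated acquisition."""

    phantom: ImageVolume
    support: np.ndarray
    alpha: AlphaMaps
    shot_times: np.ndarray
    shot_sensor_values: np.ndarray
    state_of_line: Optional[np.ndarray] = None


def sampled_phase_encodes(ny: int, acceleration: int, n_center_lines: int) -> np.ndarray:
    """Phase-encode rows acquired: stride-``acceleration`` grid + center band."""
    rows = np.arange(ny)
    keep = (rows % acceleration) == (ny // 2) % acceleration
    if n_center_lines > 0:
        lo = ny // 2 - n_center_lines // 2
        keep |= (rows >= lo) & (rows < lo + n_center_lines)
    return rows[keep]


def simulate_acquisition(
    phantom: ImageVolume,
    alpha: AlphaMaps,
    resp: RespSignal,
    coils: CoilMaps,
    protocol: Optional[Protocol] = None,
    seed: int = 0,
    binned_states: Optional[int] = None,
    slice_index: int = 0,
    support: Optional[np.ndarray] = None,
) -> tuple[KSpaceData, SimulationTruth]:
    """Shot-by-shot Cartesian acquisition of a moving object.

    Each shot is stamped with its time, the sensor value there drives the
    displacement ``u = alpha * s(t)``, the warped object is weighted by
    every coil and Fourier transformed, and the shot's phase-encode lines
    are stored. In ``binned_states`` mode the sensor value is first
    quantized to that many state values — the motion model the
    reconstruction assumes — whereas continuous mode deliberately injects
    model mismatch. Phase-encode rows are acquired in an interleaved order
    so consecutive shots sample distant k-space regions (as an actual
    multi-shot sequence does).
    """
    protocol = protocol or Protocol()
    geo = phantom.geometry
    ny, nx = geo.ny, geo.nx
    rng = np.random.default_rng(seed)
    img = phantom.data[0]

    pe_rows = sampled_phase_encodes(ny, protocol.acceleration, protocol.n_center_lines)
    # interleaved ordering: stride through the sampled rows
    n_shots = int(np.ceil(pe_rows.size / protocol.lines_per_shot))
    order = np.concatenate([pe_rows[i::n_shots] for i in range(n_shots)])

    total_time = (n_shots - 1) * protocol.shot_interval_s
    if resp.duration < total_time:
        raise ValueError("respiratory signal shorter than the acquisition")

    s_raw = np.interp(
        np.arange(n_shots) * protocol.shot_interval_s, resp.times, resp.values
    )
    shot_states = None
    if binned_states is not None:
        from .resp import bin_motion_states

        binned = bin_motion_states(
            RespSignal(
                np.concatenate([resp.values, s_raw]), resp.sample_rate
            ),
            n_states=binned_states,
        )
        shot_states = binned.state_labels[-n_shots:]
        values = binned.state_values[shot_states]
    else:
        values = s_raw

    samples = np.zeros((coils.n_coils, order.size, nx), dtype=np.complex128)
    pe_idx = np.empty(order.size, dtype=np.int64)
    ts = np.empty(order.size, dtype=np.float64)
    pos = 0
    for shot in range(n_shots):
        rows = order[pos : pos + protocol.lines_per_shot]
        if rows.size == 0:
            break
        u = predict_displacement(alpha, float(values[shot]))
        moved = warp_image(img.astype(np.complex128), u)
        ksp = cfft2(coils.maps * moved[None])
        samples[:, pos : pos + rows.size, :] = ksp[:, rows, :]
        pe_idx[pos : pos + rows.size] = rows
        ts[pos : pos + rows.size] = shot * protocol.shot_interval_s
        pos += rows.size

    if protocol.noise_sd > 0:
        samples += protocol.noise_sd * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )

    meta = LineMeta(pe_idx, np.full(order.size, slice_index), ts)
    ks = KSpaceData(
        samples,
        meta,
        geo,
        acceleration=protocol.acceleration,
        n_center_calibration_lines=protocol.n_center_lines,
    )
    shot_times = np.arange(n_shots) * protocol.shot_interval_s
    state_of_line = None
    if shot_states is not None:
        state_of_line = np.repeat(shot_states, protocol.lines_per_shot)[: order.size]
    truth = SimulationTruth(
        phantom=phantom,
        support=support if support is not None else np.zeros((ny, nx), dtype=bool),
        alpha=alpha,
        shot_times=shot_times,
        shot_sensor_values=np.asarray(values, dtype=np.float64),
        state_of_line=state_of_line,
    )
    return ks, truth
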