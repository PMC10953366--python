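"""Respiratory-belt signal conditioning and motion-state binning.

The preprocessing chain used before reconstruction is: zero-phase low-pass
filtering (3 Hz cutoff), quadratic drift removal (air-leak drift is well
modelled by a second-order polynomial in time), then re-binning of the
amplitude into ``n_states`` motion states. Because the quadratic fit absorbs
the signal mean, a constant sensor trace maps to zero — i.e. displacement is
always expressed relative to the mean respiratory position.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import butter, filtfilt

from .datamodel import RespSignal

__all__ = [
    "lowpass_filter",
    "correct_drift",
    "bin_motion_states",
    "state_for_line",
    "preprocess",
]


def lowpass_filter(sig: RespSignal, cutoff_hz: float = 3.0, order: int = 4) -> RespSignal:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so the filtered curve has no
    group delay relative to the k-space line timestamps.
    """
    nyquist = sig.sample_rate / 2.0
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    b, a = butter(order, cutoff_hz / nyquist)
    padlen = min(3 * max(len(a), len(b)), sig.values.size - 1)
    return sig.with_values(filtfilt(b, a, sig.values, padlen=padlen))


def correct_drift(sig: RespSignal) -> RespSignal:
    """Remove baseline drift by subtracting a least-squares quadratic in time."""
    if sig.values.size < 3:
        raise ValueError("drift correction needs at least 3 samples")
    t = sig.times - sig.times[0]
    coeffs = np.polynomial.polynomial.polyfit(t, sig.values, deg=2)
    fit = np.polynomial.polynomial.polyval(t, coeffs)
    return sig.with_values(sig.values - fit)


def bin_motion_states(
    sig: RespSignal,
    n_states: int = 12,
    robust_percentiles: tuple[float, float] = (1.0, 99.0),
) -> RespSignal:
    """Assign every sample to one of ``n_states`` amplitude bins.

    Equal-width bins span the robust amplitude range (1st-99th percentile by
    default); outliers are clamped into the end bins, so the labels always
    partition the samples. ``state_values`` are the bin midpoints, strictly
    increasing with the label.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    v = sig.values
    if n_states == 1:
        labels = np.zeros(v.size, dtype=np.int64)
        return dataclasses.replace(
            sig, state_labels=labels, state_values=np.array([float(np.mean(v))])
        )
    lo, hi = np.percentile(v, robust_percentiles)
    if not hi > lo:
        raise ValueError("degenerate amplitude range: constant signal cannot be binned")
    edges = np.linspace(lo, hi, n_states + 1)
    labels = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_states - 1)
    midpoints = 0.5 * (edges[:-1] + edges[1:])
    return dataclasses.replace(
        sig, state_labels=labels.astype(np.int64), state_values=midpoints
    )


def state_for_line(sig: RespSignal, timestamp: float) -> int:
    """Motion state of the nearest-in-time signal sample.

    Ties at the exact midpoint between two samples resolve to the earlier
    sample. Timestamps may overhang the signal span by one sample period.
    """
    if sig.state_labels is None:
        raise ValueError("signal has no state labels; call bin_motion_states first")
    dt = 1.0 / sig.sample_rate
    t_end = sig.t0 + (sig.values.size - 1) * dt
    if timestamp < sig.t0 - dt or timestamp > t_end + dt:
        raise ValueError(f"timestamp {timestamp} s outside signal span [{sig.t0}, {t_end}] s")
    # round-half-down implements the earlier-sample tie rule
    idx = int(np.ceil((timestamp - sig.t0) / dt - 0.5))
    idx = min(max(idx, 0), sig.values.size - 1)
    return int(sig.state_labels[idx])


def preprocess(sig: RespSignal, n_states: int, cutoff_hz: float = 3.0) -> RespSignal:
    """Full conditioning chain: low-pass, drift removal, state binning.

    A signal whose drift-corrected amplitude range is degenerate (e.g. a
    breath-hold or disconnected sensor) falls back to a single state with
    amplitude zero, which makes the reconstruction reduce exactly to the
    motion-free parallel-imaging solve.
    """
    out = correct_drift(lowpass_filter(sig, cutoff_hz=cutoff_hz))
    # degenerate relative to the *raw* signal scale: a constant trace leaves
    # only numerical residue after drift removal, which must not be binned
    raw_scale = max(float(np.ptp(sig.values)), float(np.max(np.abs(sig.values))), 1e-30)
    degenerate = float(np.ptp(out.values)) <= 1e-9 * raw_scale
    try:
        if degenerate:
            raise ValueError("degenerate amplitude range")
        return bin_motion_states(out, n_states=n_states)
    except ValueError:
        labels = np.zeros(out.values.size, dtype=np.int64)
        return dataclasses.replace(
            out, values=np.zeros_like(out.values), state_labels=labels,
            state_values=np.array([0.0]),
        )
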