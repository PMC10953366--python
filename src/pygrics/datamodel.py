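"""Core data containers for k-space, respiratory signals and images.

Conventions (fixed once, used everywhere):

* image arrays are ``(slice, y, x)``, 0-based;
* a k-space *line* is one phase-encode row of the fully sampled Cartesian
  grid, with the DC row at index ``Ny // 2`` (fftshift convention);
* timestamps are stored per line; a *shot* is the group of lines sharing
  one timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "Geometry",
    "LineMeta",
    "KSpaceData",
    "RespSignal",
    "ImageVolume",
    "FormatError",
]


class FormatError(ValueError):
    """A file or container is missing a required key or violates the layout."""


@dataclass(frozen=True)
class Geometry:
    """Image-space geometry of a 2D multi-slice acquisition.

    Parameters
    ----------
    ny, nx : int
        Matrix size (phase-encode rows, readout columns).
    pixel_spacing : tuple of float
        In-plane pixel size ``(dy, dx)`` in millimetres.
    slice_thickness : float
        Slice thickness in millimetres.
    """

    ny: int
    nx: int
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 3.0

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.ny * self.pixel_spacing[0], self.nx * self.pixel_spacing[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


@dataclass
class LineMeta:
    """Per-line acquisition metadata (parallel arrays, one entry per line)."""

    phase_encode_index: np.ndarray  # int, in [0, Ny)
    slice_index: np.ndarray  # int
    timestamp: np.ndarray  # seconds from sequence start

    def __post_init__(self) -> None:
        self.phase_encode_index = np.asarray(self.phase_encode_index, dtype=np.int64)
        self.slice_index = np.asarray(self.slice_index, dtype=np.int64)
        self.timestamp = np.asarray(self.timestamp, dtype=np.float64)
        n = len(self.phase_encode_index)
        if len(self.slice_index) != n or len(self.timestamp) != n:
            raise ValueError("line_meta arrays must have equal length")

    def __len__(self) -> int:
        return len(self.phase_encode_index)


@dataclass
class KSpaceData:
    """Multi-coil Cartesian k-space samples with per-line metadata.

    ``samples`` is complex, indexed ``(coil, line, readout)``; line order is
    acquisition order and every line has exactly one metadata record.
    """

    samples: np.ndarray
    line_meta: LineMeta
    geometry: Geometry
    acceleration: int = 1
    n_center_calibration_lines: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if not np.iscomplexobj(self.samples):
            self.samples = self.samples.astype(np.complex64)
        if self.samples.ndim != 3:
            raise ValueError("samples must be (coil, line, readout)")
        if self.samples.shape[1] != len(self.line_meta):
            raise ValueError("every line must have exactly one meta record")
        if self.acceleration < 1:
            raise ValueError("acceleration must be >= 1")
        self.validate()

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def validate(self) -> None:
        pe = self.line_meta.phase_encode_index
        if pe.size and (pe.min() < 0 or pe.max() >= self.geometry.ny):
            raise ValueError("phase_encode_index out of [0, Ny)")
        for sl in np.unique(self.line_meta.slice_index):
            ts = self.line_meta.timestamp[self.line_meta.slice_index == sl]
            if np.any(np.diff(ts) < 0):
                raise ValueError("timestamps must be non-decreasing within a slice")

    def slices(self) -> np.ndarray:
        return np.unique(self.line_meta.slice_index)

    def for_slice(self, slice_index: int) -> "KSpaceData":
        """Sub-container holding only the lines of one slice."""
        sel = np.flatnonzero(self.line_meta.slice_index == slice_index)
        meta = LineMeta(
            self.line_meta.phase_encode_index[sel],
            self.line_meta.slice_index[sel],
            self.line_meta.timestamp[sel],
        )
        return KSpaceData(
            self.samples[:, sel, :],
            meta,
            self.geometry,
            self.acceleration,
            self.n_center_calibration_lines,
        )


@dataclass
class RespSignal:
    """Uniformly sampled scalar respiratory-sensor series.

    ``state_labels`` / ``state_values`` are filled by motion-state binning:
    each sample gets an integer state in ``[0, n_states)`` and each state a
    representative sensor amplitude.
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0
    state_labels: Optional[np.ndarray] = None
    state_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("signal must be 1D with length >= 2")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.state_labels is not None:
            self.state_labels = np.asarray(self.state_labels, dtype=np.int64)
            if self.state_labels.shape != self.values.shape:
                raise ValueError("state_labels must match values in length")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.sample_rate

    def with_values(self, values: np.ndarray) -> "RespSignal":
        return replace(self, values=np.asarray(values, dtype=np.float64))


@dataclass
class ImageVolume:
    """Image stack ``(slice, y, x)``, complex during reconstruction."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("data must be (slice, y, x)")
        if self.data.shape[1:] != (self.geometry.ny, self.geometry.nx):
            raise ValueError("data shape inconsistent with geometry")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def magnitude(self) -> "ImageVolume":
        return ImageVolume(np.abs(self.data), self.geometry)
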