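"""The motion-aware encoding operator E(u) and its exact adjoint.

``forward`` composes, per motion state: bilinear warp by that state's
displacement, coil-sensitivity weighting, centered unitary 2D FFT, and
extraction of the phase-encode lines acquired while the respiratory signal
was in that state. The measurement vector is ordered deterministically:
states ascending, then coils ascending, then lines in acquisition order,
then readout. ``adjoint`` is the exact transpose-conjugate, so conjugate
gradients on the normal equations is well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .coils import CoilMaps
from .datamodel import Geometry, KSpaceData
from .fourier import cfft2, cifft2
from .motion import DisplacementField, warp_matrix

__all__ = ["EncodingOperator"]


@dataclass
class EncodingOperator:
    """Sampling ∘ Fourier ∘ coil weighting ∘ warp, one warp per motion state.

    Parameters
    ----------
    coil_maps : CoilMaps
        Complex sensitivities, RSS ≈ 1 inside the object.
    state_of_line : array of int
        Motion state of each acquired line (piecewise-constant motion: all
        lines of a state share one displacement field).
    pe_of_line : array of int
        Phase-encode row of each acquired line on the centered grid.
    displacements : list of DisplacementField
        One field per state, indexed by state label.
    geometry : Geometry
    """

    coil_maps: CoilMaps
    state_of_line: np.ndarray
    pe_of_line: np.ndarray
    displacements: list
    geometry: Geometry
    _warps: list = field(init=False, repr=False)
    _lines_by_state: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.state_of_line = np.asarray(self.state_of_line, dtype=np.int64)
        self.pe_of_line = np.asarray(self.pe_of_line, dtype=np.int64)
        if self.state_of_line.shape != self.pe_of_line.shape:
            raise ValueError("state_of_line and pe_of_line must align")
        n_states = len(self.displacements)
        if self.state_of_line.size and (
            self.state_of_line.min() < 0 or self.state_of_line.max() >= n_states
        ):
            raise ValueError("a line is assigned to a state with no displacement field")
        self._warps = [warp_matrix(d) for d in self.displacements]
        self._lines_by_state = {
            int(k): np.flatnonzero(self.state_of_line == k)
            for k in range(n_states)
            if np.any(self.state_of_line == k)
        }

    # ---- bookkeeping -----------------------------------------------------

    @property
    def n_coils(self) -> int:
        return self.coil_maps.n_coils

    @property
    def n_out(self) -> int:
        return self.n_coils * self.state_of_line.size * self.geometry.nx

    @property
    def shape2d(self) -> tuple[int, int]:
        return (self.geometry.ny, self.geometry.nx)

    def pack_measurements(self, samples: np.ndarray) -> np.ndarray:
        """Order acquired samples ``(coil, line, readout)`` as `forward` does."""
        chunks = []
        for k in sorted(self._lines_by_state):
            lines = self._lines_by_state[k]
            for c in range(self.n_coils):
                chunks.append(np.asarray(samples[c, lines, :], dtype=np.complex128).ravel())
        return np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.complex128)

    # ---- operator --------------------------------------------------------

    def forward(self, rho: np.ndarray) -> np.ndarray:
        ny, nx = self.shape2d
        if rho.shape != (ny, nx):
            raise ValueError("image shape inconsistent with operator geometry")
        out = []
        maps = self.coil_maps.maps
        for k in sorted(self._lines_by_state):
            lines = self._lines_by_state[k]
            warped = (self._warps[k] @ rho.ravel()).reshape(ny, nx)
            ksp = cfft2(maps * warped[None])  # (coil, ny, nx)
            pe = self.pe_of_line[lines]
            for c in range(self.n_coils):
                out.append(ksp[c, pe, :].ravel())
        return np.concatenate(out) if out else np.zeros(0, dtype=np.complex128)

    def adjoint(self, m: np.ndarray) -> np.ndarray:
        ny, nx = self.shape2d
        if m.size != self.n_out:
            raise ValueError(f"measurement length {m.size} != {self.n_out}")
        maps = self.coil_maps.maps
        rho = np.zeros((ny, nx), dtype=np.complex128)
        pos = 0
        for k in sorted(self._lines_by_state):
            lines = self._lines_by_state[k]
            pe = self.pe_of_line[lines]
            grid = np.zeros((self.n_coils, ny, nx), dtype=np.complex128)
            for c in range(self.n_coils):
                block = m[pos : pos + lines.size * nx].reshape(lines.size, nx)
                pos += lines.size * nx
                np.add.at(grid[c], (pe, slice(None)), block)
            imgs = cifft2(grid)
            coil_combined = np.sum(np.conj(maps) * imgs, axis=0)
            rho += (self._warps[k].T @ coil_combined.ravel()).reshape(ny, nx)
        return rho

    def normal(self, rho: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(rho))

    def as_dense(self) -> np.ndarray:
        """Explicit matrix of `forward` (small grids only; test oracle)."""
        ny, nx = self.shape2d
        n = ny * nx
        if n > 4096:
            raise ValueError("dense assembly is for small test instances")
        cols = []
        basis = np.zeros((ny, nx), dtype=np.complex128)
        for i in range(n):
            basis.flat[i] = 1.0
            cols.append(self.forward(basis))
            basis.flat[i] = 0.0
        return np.stack(cols, axis=1)

    # ---- constructors ----------------------------------------------------

    @classmethod
    def from_kspace(
        cls,
        ks: KSpaceData,
        coil_maps: CoilMaps,
        state_of_line: np.ndarray,
        state_displacements: list,
    ) -> "EncodingOperator":
        return cls(
            coil_maps=coil_maps,
            state_of_line=state_of_line,
            pe_of_line=ks.line_meta.phase_encode_index,
            displacements=state_displacements,
            geometry=ks.geometry,
        )
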