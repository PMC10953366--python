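"""On-disk formats: HDF5 k-space container, CSV sensor signals, NIfTI images.

HDF5 layout (ISMRMRD-flavoured naming)::

    /kspace/samples                      complex64, (coil, line, readout)
    /kspace/line_meta/phase_encode_index int
    /kspace/line_meta/slice_index        int
    /kspace/line_meta/timestamp          float seconds
    /kspace/geometry                     attrs: ny, nx, pixel_spacing,
                                         slice_thickness, acceleration,
                                         n_center_calibration_lines
    /resp/values, /resp/sample_rate      optional embedded sensor signal
    /alpha/coeff                         optional motion-model coefficients

CSV sensor files have a header row ``time_s,value``.
"""

from __future__ import annotations

import csv
import os
from typing import Optional

import h5py
import nibabel as nib
import numpy as np

from .datamodel import FormatError, Geometry, ImageVolume, KSpaceData, LineMeta, RespSignal

__all__ = [
    "read_kspace",
    "write_kspace",
    "read_resp_csv",
    "write_resp_csv",
    "read_image_nifti",
    "write_image_nifti",
    "read_alpha",
    "write_alpha",
]


def _require(group, key: str):
    if key not in group:
        raise FormatError(f"missing dataset '{group.name}/{key}'")
    return group[key]


def _require_attr(group, key: str):
    if key not in group.attrs:
        raise FormatError(f"missing attribute '{key}' on '{group.name}'")
    return group.attrs[key]


def write_kspace(data: KSpaceData, path, resp: Optional[RespSignal] = None) -> None:
    if not np.all(np.isfinite(data.samples)):
        raise ValueError("refusing to write non-finite k-space samples")
    with h5py.File(path, "w") as f:
        ks = f.create_group("kspace")
        ks.create_dataset("samples", data=data.samples.astype(np.complex64))
        lm = ks.create_group("line_meta")
        lm.create_dataset("phase_encode_index", data=data.line_meta.phase_encode_index)
        lm.create_dataset("slice_index", data=data.line_meta.slice_index)
        lm.create_dataset("timestamp", data=data.line_meta.timestamp)
        geo = ks.create_group("geometry")
        geo.attrs["ny"] = data.geometry.ny
        geo.attrs["nx"] = data.geometry.nx
        geo.attrs["pixel_spacing"] = np.asarray(data.geometry.pixel_spacing)
        geo.attrs["slice_thickness"] = data.geometry.slice_thickness
        geo.attrs["acceleration"] = data.acceleration
        geo.attrs["n_center_calibration_lines"] = data.n_center_calibration_lines
        if resp is not None:
            rg = f.create_group("resp")
            rg.create_dataset("values", data=resp.values)
            rg.create_dataset("sample_rate", data=float(resp.sample_rate))
            rg.create_dataset("t0", data=float(resp.t0))


def read_kspace(path) -> tuple[KSpaceData, Optional[RespSignal]]:
    """Read the HDF5 container; returns the k-space and any embedded signal."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        ks = _require(f, "kspace")
        samples = np.asarray(_require(ks, "samples"), dtype=np.complex64)
        lm = _require(ks, "line_meta")
        meta = LineMeta(
            np.asarray(_require(lm, "phase_encode_index")),
            np.asarray(_require(lm, "slice_index")),
            np.asarray(_require(lm, "timestamp")),
        )
        geo_g = _require(ks, "geometry")
        spacing = np.asarray(_require_attr(geo_g, "pixel_spacing"), dtype=float)
        geometry = Geometry(
            ny=int(_require_attr(geo_g, "ny")),
            nx=int(_require_attr(geo_g, "nx")),
            pixel_spacing=(float(spacing[0]), float(spacing[1])),
            slice_thickness=float(_require_attr(geo_g, "slice_thickness")),
        )
        data = KSpaceData(
            samples,
            meta,
            geometry,
            acceleration=int(geo_g.attrs.get("acceleration", 1)),
            n_center_calibration_lines=int(geo_g.attrs.get("n_center_calibration_lines", 0)),
        )
        resp = None
        if "resp" in f:
            rg = f["resp"]
            resp = RespSignal(
                np.asarray(_require(rg, "values"), dtype=np.float64),
                float(np.asarray(_require(rg, "sample_rate"))),
                t0=float(np.asarray(rg["t0"])) if "t0" in rg else 0.0,
            )
    return data, resp


def write_resp_csv(sig: RespSignal, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for t, v in zip(sig.times, sig.values):
            w.writerow([f"{t:.9g}", f"{v:.12g}"])


def read_resp_csv(path) -> RespSignal:
    """Read a two-column ``time_s,value`` CSV into a :class:`RespSignal`.

    The sample rate is recovered from the (uniform) time column.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError("no samples: empty CSV")
    header = [c.strip().lower() for c in rows[0]]
    if header[:2] != ["time_s", "value"]:
        raise FormatError("CSV must start with header 'time_s,value'")
    body = [r for r in rows[1:] if r]
    if len(body) < 2:
        raise FormatError("no samples: need at least 2 rows")
    t = np.array([float(r[0]) for r in body])
    v = np.array([float(r[1]) for r in body])
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError("time column must be uniformly increasing")
    return RespSignal(v, sample_rate=1.0 / dt[0], t0=float(t[0]))


def _affine(geometry: Geometry) -> np.ndarray:
    dy, dx = geometry.pixel_spacing
    # axis order on disk is (x, y, slice); voxel sizes carried on the diagonal
    return np.diag([dx, dy, geometry.slice_thickness, 1.0])


def write_image_nifti(img: ImageVolume, path) -> None:
    data = img.data
    if np.iscomplexobj(data):
        data = np.abs(data)
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite image")
    # (slice, y, x) -> (x, y, slice) so viewers see the in-plane grid first
    arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0)).astype(np.float32))
    nib.save(nib.Nifti1Image(arr, _affine(img.geometry)), str(path))


def read_image_nifti(path) -> ImageVolume:
    im = nib.load(str(path))
    arr = np.asarray(im.dataobj, dtype=np.float32)
    data = np.transpose(arr, (2, 1, 0))
    zooms = im.header.get_zooms()
    geometry = Geometry(
        ny=data.shape[1],
        nx=data.shape[2],
        pixel_spacing=(float(zooms[1]), float(zooms[0])),
        slice_thickness=float(zooms[2]),
    )
    return ImageVolume(data, geometry)


def write_alpha(coeff: np.ndarray, geometry: Geometry, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("alpha")
        g.create_dataset("coeff", data=np.asarray(coeff, dtype=np.float64))
        g.attrs["ny"] = geometry.ny
        g.attrs["nx"] = geometry.nx
        g.attrs["pixel_spacing"] = np.asarray(geometry.pixel_spacing)
        g.attrs["slice_thickness"] = geometry.slice_thickness


def read_alpha(path) -> tuple[np.ndarray, Geometry]:
    with h5py.File(path, "r") as f:
        g = _require(f, "alpha")
        coeff = np.asarray(_require(g, "coeff"), dtype=np.float64)
        spacing = np.asarray(_require_attr(g, "pixel_spacing"), dtype=float)
        geometry = Geometry(
            ny=int(_require_attr(g, "ny")),
            nx=int(_require_attr(g, "nx")),
            pixel_spacing=(float(spacing[0]), float(spacing[1])),
            slice_thickness=float(_require_attr(g, "slice_thickness")),
        )
    return coeff, geometry
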