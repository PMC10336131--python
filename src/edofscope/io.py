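"""File formats: multi-page TIFF images, HDF5 PSF grids and basis models.

Images travel as (C, H, W) float arrays in memory and are written as
multi-page TIFF (one page per channel, float32 by default).  HDF5 layout:

* PSF grid — ``/psf[field, z, channel, y, x]``, ``/z_um``, ``/field_uv``,
  JSON-serializable attributes under ``/meta``;
* basis models — one group per depth with ``/H[channel, ab, N]``,
  ``/W[N, M]`` (or ``[C, N, M]``), ``/field_uv``, ``/residual_trace``.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile

from .factorization import BasisModel
from .optics import PSFGrid

__all__ = [
    "write_image",
    "read_image",
    "write_psf_grid",
    "read_psf_grid",
    "write_bases",
    "read_bases",
]

_H5OPTS = {"track_times": False}   # keep files byte-reproducible


def write_image(path, image: np.ndarray, dtype=np.float32):
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[None]
    kwargs = {"photometric": "minisblack"}
    if image.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(path, image.astype(dtype), **kwargs)


def read_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    return np.asarray(img, dtype=float)


def write_psf_grid(path, grid: PSFGrid):
    with h5py.File(path, "w") as f:
        f.create_dataset("psf", data=grid.data, **_H5OPTS)
        f.create_dataset("z_um", data=grid.z_um, **_H5OPTS)
        f.create_dataset("field_uv", data=grid.field_uv, **_H5OPTS)
        f.create_dataset("wavelengths_nm", data=np.asarray(grid.wavelengths_nm),
                         **_H5OPTS)
        meta = f.create_dataset("meta", data=np.empty(0), **_H5OPTS)
        meta.attrs["json"] = json.dumps(
            dict(grid.meta, pixel_pitch_um=grid.pixel_pitch_um), sort_keys=True)


def read_psf_grid(path) -> PSFGrid:
    with h5py.File(path, "r") as f:
        meta = json.loads(f["meta"].attrs["json"])
        return PSFGrid(f["psf"][()], f["z_um"][()], f["field_uv"][()],
                       tuple(f["wavelengths_nm"][()]),
                       meta.pop("pixel_pitch_um"), meta)


def write_bases(path, bases: dict):
    """Persist ``{z_um: BasisModel}`` to HDF5."""
    with h5py.File(path, "w") as f:
        for z, bm in sorted(bases.items()):
            g = f.create_group(f"z_{z:+.3f}")
            g.attrs["z_um"] = float(z)
            g.attrs["channel_uniform"] = bool(bm.channel_uniform)
            g.attrs["interpolation"] = bm.interpolation
            g.attrs["psf_shape"] = list(bm.psf_shape)
            g.create_dataset("H", data=bm.H, **_H5OPTS)
            g.create_dataset("W", data=bm.W, **_H5OPTS)
            g.create_dataset("field_uv", data=bm.field_uv, **_H5OPTS)
            g.create_dataset("residual_trace", data=bm.residual_trace, **_H5OPTS)


def read_bases(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for key in f:
            g = f[key]
            z = float(g.attrs["z_um"])
            out[z] = BasisModel(
                g["H"][()], g["W"][()], g["field_uv"][()],
                tuple(int(v) for v in g.attrs["psf_shape"]),
                g["residual_trace"][()],
                channel_uniform=bool(g.attrs["channel_uniform"]),
                interpolation=str(g.attrs["interpolation"]),
                z_um=z)
    return out
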