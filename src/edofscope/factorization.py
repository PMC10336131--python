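"""Low-rank representation of shift-variant PSFs.

A field-varying PSF sampled at M calibration points is stored column-wise
in a non-negative matrix P (ab x M, ab = vectorized PSF pixels) and
approximated as P ~ H W with non-negative bases H (ab x N) and coefficients
W (N x M), N <= M, fitted by hierarchical alternating least squares (HALS).
Coefficient maps can be constrained to be identical across color channels
(one W fitted jointly against the channel-stacked matrix), which suppresses
color fringing in the forward model.  Coefficients are interpolated
bilinearly between calibration points to full-resolution weight maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "PSFMatrix",
    "BasisModel",
    "assemble_psf_matrix",
    "hals_nmf",
    "interpolate_coefficients",
    "reconstruct_psf",
]


@dataclass
class PSFMatrix:
    """Vectorized PSFs per field point, one channel stack.

    ``data`` has shape (C, ab, M): C color channels, ab pixels per cropped
    PSF, M field points.  ``field_uv`` holds the normalized field
    coordinates of each column.
    """

    data: np.ndarray
    field_uv: np.ndarray
    psf_shape: tuple
    downsample: int = 1

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        self.field_uv = np.asarray(self.field_uv, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("PSF matrix entries must be non-negative")
        if self.data.shape[2] != self.field_uv.shape[0]:
            raise ValueError("one field coordinate per column required")
        if self.data.shape[1] != int(np.prod(self.psf_shape)):
            raise ValueError("psf_shape inconsistent with row count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_fields(self) -> int:
        return self.data.shape[2]


def assemble_psf_matrix(psfs: np.ndarray, field_uv, downsample: int = 1,
                        crop: int | None = None) -> PSFMatrix:
    """Crop, downsample, vectorize and merge calibrated PSFs into a matrix.

    Parameters
    ----------
    psfs : ndarray
        Shape (M, y, x) or (M, C, y, x): one PSF per field point (per
        channel).  All PSFs must share a shape.
    downsample : int
        Stride-sampling factor (>= 1) applied after cropping.
    crop : int, optional
        Side length of the centre crop (pixels, before downsampling).

    Column m of the result is the cropped, downsampled, flattened PSF of
    field point m, in the order of ``field_uv``.
    """
    psfs = np.asarray(psfs, dtype=float)
    if psfs.ndim == 3:
        psfs = psfs[:, None]
    if psfs.ndim != 4:
        raise ValueError("expected (M, y, x) or (M, C, y, x) PSF array")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    m, c, h, w = psfs.shape
    if crop is not None:
        if crop > h or crop > w:
            raise ValueError("crop larger than PSF")
        y0 = (h - crop) // 2
        x0 = (w - crop) // 2
        psfs = psfs[:, :, y0:y0 + crop, x0:x0 + crop]
    psfs = psfs[:, :, ::downsample, ::downsample]
    shape = psfs.shape[2:]
    data = psfs.reshape(m, c, -1).transpose(1, 2, 0)
    return PSFMatrix(data, np.asarray(field_uv, dtype=float), shape, downsample)


@dataclass
class BasisModel:
    """Result of the non-negative factorization P ~ H W.

    ``H`` has shape (C, ab, N); ``W`` (N, M) is shared across channels in
    channel-uniform mode, otherwise (C, N, M).  ``residual_trace`` records
    the objective ||H W - P||_F after every HALS sweep.
    """

    H: np.ndarray
    W: np.ndarray
    field_uv: np.ndarray
    psf_shape: tuple
    residual_trace: np.ndarray
    channel_uniform: bool = True
    interpolation: str = "bilinear"
    z_um: float | None = None

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if np.any(self.H < 0) or np.any(self.W < 0):
            raise ValueError("bases and coefficients must be non-negative")

    @property
    def rank(self) -> int:
        return self.H.shape[-1]

    @property
    def n_channels(self) -> int:
        return self.H.shape[0]


def _hals_iterate(p: np.ndarray, h: np.ndarray, w: np.ndarray, sweeps: int):
    """Cyclic HALS sweeps on a single stacked problem p ~ h w.

    Non-negativity by clipping at zero; a component whose coefficient row
    collapses is re-seeded from the largest-residual column.
    """
    n = h.shape[1]
    trace = []
    eps = 1e-12
    for _ in range(sweeps):
        # update H columns
        a = p @ w.T
        b = w @ w.T
        for i in range(n):
            denom = b[i, i]
            if denom < eps:
                continue
            hi = h[:, i] + (a[:, i] - h @ b[:, i]) / denom
            h[:, i] = np.maximum(hi, 0.0)
        # update W rows
        c = h.T @ p
        d = h.T @ h
        for i in range(n):
            denom = d[i, i]
            if denom < eps:
                # dead component: re-seed basis from the worst-fit column
                resid = p - h @ w
                j = int(np.argmax(np.linalg.norm(resid, axis=0)))
                h[:, i] = np.maximum(resid[:, j], 0.0) + eps
                c = h.T @ p
                d = h.T @ h
                denom = d[i, i]
            wi = w[i, :] + (c[i, :] - d[i, :] @ w) / denom
            w[i, :] = np.maximum(wi, 0.0)
        trace.append(float(np.linalg.norm(h @ w - p)))
    return h, w, trace


def hals_nmf(P: PSFMatrix, N: int, iterations: int = 200, seed: int = 0,
             channel_uniform: bool = True) -> BasisModel:
    """Factorize a PSF matrix with hierarchical alternating least squares.

    With ``channel_uniform`` the coefficient matrix W is fitted once against
    the channel-stacked matrix [P_1; ...; P_C] (bases remain per channel),
    so every channel shares the same field weights.  The recorded objective
    is non-increasing per sweep.
    """
    c, ab, m = P.data.shape
    if N > m:
        raise ValueError(f"rank N={N} exceeds number of field points M={m}")
    if N < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    if channel_uniform:
        stacked = P.data.reshape(c * ab, m)
        h = rng.random((c * ab, N))
        w = rng.random((N, m))
        h, w, trace = _hals_iterate(stacked, h, w, iterations)
        H = h.reshape(c, ab, N)
        W = w
    else:
        H = np.empty((c, ab, N))
        W = np.empty((c, N, m))
        traces = []
        for ch in range(c):
            h = rng.random((ab, N))
            w = rng.random((N, m))
            h, w, tr = _hals_iterate(P.data[ch], h, w, iterations)
            H[ch], W[ch] = h, w
            traces.append(tr)
        trace = np.sqrt(np.sum(np.square(traces), axis=0))
    return BasisModel(H, W, P.field_uv, P.psf_shape, np.asarray(trace),
                      channel_uniform=channel_uniform)


def _as_field_grid(field_uv: np.ndarray):
    """Recover the (u, v) product grid behind a flat field-coordinate list.

    Returns (u_axis, v_axis, index array) such that
    ``field_uv[idx[i, j]] == (u_axis[i], v_axis[j])``.
    """
    us = np.unique(field_uv[:, 0])
    vs = np.unique(field_uv[:, 1])
    if us.size * vs.size != field_uv.shape[0]:
        raise ValueError("field coordinates do not form a regular grid")
    idx = np.full((us.size, vs.size), -1, dtype=int)
    for k, (u, v) in enumerate(field_uv):
        i = int(np.searchsorted(us, u))
        j = int(np.searchsorted(vs, v))
        idx[i, j] = k
    if np.any(idx < 0):
        raise ValueError("field coordinates do not form a regular grid")
    return us, vs, idx


def interpolate_coefficients(model: BasisModel, out_shape: tuple,
                             field_extent: tuple = ((-1.0, 1.0), (-1.0, 1.0)),
                             channel: int = 0) -> np.ndarray:
    """Interpolate the fitted coefficients to N full-resolution weight maps.

    The output grid spans ``field_extent`` (normalized field coordinates,
    (u range, v range)) with ``out_shape`` = (height, width); rows map to v,
    columns to u.  Interpolation is bilinear on the calibration grid with
    constant (clamped) extrapolation outside it; maps are clipped at zero.
    At each calibration point the map reproduces the fitted W entry.
    """
    w = model.W if model.channel_uniform else model.W[channel]
    us, vs, idx = _as_field_grid(model.field_uv)
    h, wid = out_shape
    (u0, u1), (v0, v1) = field_extent
    uq = np.linspace(u0, u1, wid)
    vq = np.linspace(v0, v1, h)
    # clamp for constant extrapolation outside the calibrated hull
    uq = np.clip(uq, us[0], us[-1])
    vq = np.clip(vq, vs[0], vs[-1])
    vv, uu = np.meshgrid(vq, uq, indexing="ij")
    pts = np.stack([uu.ravel(), vv.ravel()], axis=-1)
    maps = np.empty((model.rank, h, wid))
    for i in range(model.rank):
        grid_vals = w[i, idx.ravel()].reshape(idx.shape)
        interp = RegularGridInterpolator((us, vs), grid_vals, method="linear")
        maps[i] = np.maximum(interp(pts).reshape(h, wid), 0.0)
    return maps


def reconstruct_psf(model: BasisModel, m: int, channel: int = 0) -> np.ndarray:
    """Reassemble the PSF at calibration field point ``m``:
    ``sum_i W[i, m] H[:, i]`` reshaped to the stored PSF shape."""
    if not 0 <= m < model.field_uv.shape[0]:
        raise IndexError("field index out of range")
    w = model.W if model.channel_uniform else model.W[channel]
    vec = model.H[channel] @ w[:, m]
    return np.maximum(vec, 0.0).reshape(model.psf_shape)
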