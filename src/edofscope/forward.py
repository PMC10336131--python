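"""Shift-variant, depth-resolved image formation.

Two routes compute the coded capture of a scene:

* ``forward_superposition`` — the literal superposition sum
  ``i(x, y) = sum_{u,v} s(u, v) p(u, v, x - u, y - v, z)``, quadratic cost,
  intended as the brute-force oracle on small scenes;
* ``forward_lowrank`` — the FFT-accelerated low-rank model
  ``i = sum_i (s * w_i) (conv) h_i`` built on a fitted basis model, which
  equals the superposition exactly when the factorization and weight
  interpolation are exact.

Conventions (used everywhere in the package): 0-based pixel indices,
row-major images, origin top-left; a PSF kernel of side n has its centre
at pixel ``n // 2`` (the floor midpoint, matching ``fftshift``); boundary
handling is zero-padding to the full linear convolution followed by a
centre crop back to the scene frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.fft import next_fast_len, rfft2, irfft2

from .factorization import BasisModel, interpolate_coefficients

__all__ = [
    "Scene",
    "CodedCapture",
    "conv_same",
    "corr_same",
    "forward_superposition",
    "forward_lowrank",
    "propagate_focal_stack",
    "add_sensor_noise",
]


@dataclass
class Scene:
    """Sample intensity with an optional per-pixel depth map.

    ``image`` is (C, H, W) (a 2-D array is promoted to one channel),
    non-negative, arbitrary units.  ``depth_um`` is (H, W) in micrometres;
    depth values are snapped to the model's depth grid by the stack
    decomposition, not here.
    """

    image: np.ndarray
    depth_um: np.ndarray | None = None
    pixel_pitch_um: float = 3.0

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim == 2:
            self.image = self.image[None]
        if np.any(self.image < 0):
            raise ValueError("scene intensity must be non-negative")
        if self.depth_um is not None:
            self.depth_um = np.asarray(self.depth_um, dtype=float)
            if self.depth_um.shape != self.image.shape[1:]:
                raise ValueError("depth map shape must match the image")

    @property
    def shape(self) -> tuple:
        return self.image.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.image.shape[0]


@dataclass
class CodedCapture:
    """Simulated sensor image (C, H, W) plus provenance."""

    image: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim == 2:
            self.image = self.image[None]


def _pad_fft_conv(img: np.ndarray, ker: np.ndarray, flip: bool) -> np.ndarray:
    """Full linear convolution (or correlation when ``flip``) via rFFT,
    cropped to 'same' with the kernel centre at ``n // 2``."""
    ih, iw = img.shape
    kh, kw = ker.shape
    if flip:
        ker = ker[::-1, ::-1]
        cy, cx = kh - 1 - kh // 2, kw - 1 - kw // 2
    else:
        cy, cx = kh // 2, kw // 2
    fh = next_fast_len(ih + kh - 1, real=True)
    fw = next_fast_len(iw + kw - 1, real=True)
    out = irfft2(rfft2(img, (fh, fw)) * rfft2(ker, (fh, fw)), (fh, fw))
    return out[cy:cy + ih, cx:cx + iw]


def conv_same(img: np.ndarray, ker: np.ndarray) -> np.ndarray:
    """Linear convolution with zero boundary, cropped to the image frame."""
    return _pad_fft_conv(img, ker, flip=False)


def corr_same(img: np.ndarray, ker: np.ndarray) -> np.ndarray:
    """Cross-correlation (adjoint of ``conv_same``) with zero boundary."""
    return _pad_fft_conv(img, ker, flip=True)


def forward_superposition(scene: Scene, psf_lookup) -> CodedCapture:
    """Brute-force shift-variant imaging: every source pixel deposits its
    own PSF.  ``psf_lookup(u, v, z)`` returns the (odd- or even-sided) PSF
    kernel for image row u, column v, and the pixel's depth z (``None``
    when the scene carries no depth map).  O(pixels x PSF size); oracle use.
    """
    c = scene.n_channels
    h, w = scene.shape
    out = np.zeros((c, h, w))
    depth = scene.depth_um
    for u in range(h):
        for v in range(w):
            vals = scene.image[:, u, v]
            if not np.any(vals):
                continue
            z = None if depth is None else float(depth[u, v])
            psf = np.asarray(psf_lookup(u, v, z), dtype=float)
            if psf.ndim == 2:
                psf = np.broadcast_to(psf, (c,) + psf.shape)
            kh, kw = psf.shape[1:]
            cy, cx = kh // 2, kw // 2
            y0, y1 = u - cy, u - cy + kh
            x0, x1 = v - cx, v - cx + kw
            ky0, kx0 = max(0, -y0), max(0, -x0)
            ky1 = kh - max(0, y1 - h)
            kx1 = kw - max(0, x1 - w)
            if ky0 >= ky1 or kx0 >= kx1:
                continue
            out[:, max(0, y0):min(h, y1), max(0, x0):min(w, x1)] += (
                vals[:, None, None] * psf[:, ky0:ky1, kx0:kx1])
    return CodedCapture(out, {"method": "superposition"})


def forward_lowrank(scene: Scene, basis: BasisModel,
                    weight_maps: np.ndarray | None = None) -> CodedCapture:
    """FFT low-rank forward model: ``i = sum_i (s . w_i) conv h_i``.

    ``weight_maps`` (N, H, W) defaults to the bilinear interpolation of the
    fitted coefficients over the scene frame.  Convolutions are zero-padded
    to the linear result and centre-cropped back to the scene shape.
    """
    h, w = scene.shape
    if weight_maps is None:
        weight_maps = interpolate_coefficients(basis, (h, w))
    weight_maps = np.asarray(weight_maps, dtype=float)
    if weight_maps.shape != (basis.rank, h, w):
        raise ValueError("weight maps must be (N, H, W) matching the scene")
    c = scene.n_channels
    if basis.n_channels not in (1, c):
        raise ValueError("basis channel count incompatible with scene")
    out = np.zeros((c, h, w))
    for ch in range(c):
        bch = min(ch, basis.n_channels - 1)
        for i in range(basis.rank):
            ker = basis.H[bch, :, i].reshape(basis.psf_shape)
            out[ch] += conv_same(scene.image[ch] * weight_maps[i], ker)
    return CodedCapture(out, {"method": "lowrank", "rank": basis.rank})


def propagate_focal_stack(slices: dict, bases: dict,
                          weight_maps=None) -> CodedCapture:
    """Multi-depth image formation: each depth-decomposed slice is blurred
    with that depth's basis model and the results are summed.

    Parameters
    ----------
    slices : dict
        ``{z_um: Scene}`` — the depth-decomposed scene (each pixel assigned
        to exactly one depth).
    bases : dict
        ``{z_um: BasisModel}``; every slice depth must be present.
    weight_maps : optional
        ``{z_um: (N, H, W) array}`` to bypass re-interpolation.
    """
    missing = [z for z in slices if z not in bases]
    if missing:
        raise KeyError(f"no basis model for depths {missing}")
    out = None
    for z, sc in slices.items():
        wm = None if weight_maps is None else weight_maps[z]
        cap = forward_lowrank(sc, bases[z], wm)
        out = cap.image if out is None else out + cap.image
    if out is None:
        raise ValueError("empty focal stack")
    return CodedCapture(out, {"method": "stack", "depths": sorted(slices)})


def add_sensor_noise(capture: CodedCapture, gain: float = 100.0,
                     read_sigma: float = 0.0, seed: int = 0) -> CodedCapture:
    """Shot + read noise: the image (arbitrary units) is scaled by ``gain``
    to expected photo-electrons, Poisson-sampled, scaled back, then Gaussian
    read noise of ``read_sigma`` (image units) is added and the result is
    clipped at zero.  Reproducible per seed."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    if read_sigma < 0:
        raise ValueError("read_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    img = np.maximum(capture.image, 0.0)
    noisy = rng.poisson(img * gain).astype(float) / gain
    if read_sigma > 0:
        noisy = noisy + rng.normal(0.0, read_sigma, size=noisy.shape)
    prov = dict(capture.provenance)
    prov.update({"noise": {"gain": gain, "read_sigma": read_sigma, "seed": seed}})
    return CodedCapture(np.maximum(noisy, 0.0), prov)
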