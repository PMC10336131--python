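"""Simulation-supervision training-pair generation.

The pipeline emulates how restoration training data is produced for a
coded microscope without ground-truth captures: a (here synthetic) 3-D
sample is scanned through focus on a conventional microscope to form a
focal stack; the sharp parts of the stack are fused into an all-in-focus
label; and the same stack, decomposed by depth and pushed through the
coded shift-variant forward model, yields the degraded network input.
Stacks cover -150 um ... +150 um in 10 um steps by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .forward import (CodedCapture, Scene, add_sensor_noise, conv_same,
                      propagate_focal_stack)
from .optics import OpticalModel, sensor_psf

__all__ = [
    "FocalStack",
    "TrainingPair",
    "synth_scene",
    "decompose_by_depth",
    "render_focal_stack",
    "depth_fusion",
    "make_training_pair",
    "patchify",
]


@dataclass
class FocalStack:
    """Through-focus image stack: ``slices`` is (n_z, C, H, W) at the
    strictly increasing, uniformly spaced planes ``z_um``."""

    slices: np.ndarray
    z_um: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.slices.ndim != 4:
            raise ValueError("slices must be (n_z, C, H, W)")
        if self.slices.shape[0] != self.z_um.size:
            raise ValueError("one slice per plane expected")
        if self.z_um.size > 1:
            steps = np.diff(self.z_um)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("z grid must be strictly increasing and uniform")

    @property
    def n_planes(self) -> int:
        return self.z_um.size


@dataclass
class TrainingPair:
    """Coded capture (network input) and all-in-focus label, plus the
    per-pixel fusion index map and any extracted patch records."""

    input: np.ndarray          # (C, H, W)
    label: np.ndarray          # (C, H, W)
    fusion_index: np.ndarray   # (H, W) winning z-grid indices
    patches: list = dc_field(default_factory=list)
    meta: dict = dc_field(default_factory=dict)


def _tilted_depth(shape, depth_range_um):
    h, w = shape
    col = np.linspace(-depth_range_um, depth_range_um, w)
    return np.broadcast_to(col, (h, w)).copy()


def synth_scene(kind: str = "mixed", size: int = 256, density: float = 0.05,
                seed: int = 0, depth_range_um: float = 150.0,
                n_channels: int = 3, pixel_pitch_um: float = 3.0) -> Scene:
    """Generate a reproducible synthetic sample with a depth map.

    Kinds: ``beads`` (sparse Gaussian emitters), ``bars`` (resolution-target
    stripes), ``texture`` (band-limited random texture), ``mixed`` (all of
    the above).  The depth map is a plane tilted along the image columns
    spanning the full +-``depth_range_um`` (the classic tilted-sample
    geometry); ``bars`` uses a piecewise-planar three-step map instead.
    ``density`` in (0, 1] scales the bead count / texture contrast.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    img = np.zeros((n_channels, size, size))

    def add_beads(target, frac):
        n = int(round(frac * size * size / 100.0))
        ys = rng.integers(0, size, n)
        xs = rng.integers(0, size, n)
        amp = rng.uniform(0.5, 1.0, n)
        tint = rng.uniform(0.7, 1.0, (n, n_channels))
        for y, x, a, t in zip(ys, xs, amp, tint):
            target[:, y, x] += a * t
        for c in range(n_channels):
            target[c] = ndimage.gaussian_filter(target[c], 1.0)

    def add_bars(target):
        periods = (6, 10, 16, 26)
        band = size // len(periods)
        xs = np.arange(size)
        for bi, p in enumerate(periods):
            stripe = ((xs // (p // 2)) % 2).astype(float)
            target[:, bi * band:(bi + 1) * band, :] += 0.8 * stripe[None, None, :]

    def add_texture(target, contrast):
        for c in range(n_channels):
            noise = rng.standard_normal((size, size))
            tex = ndimage.gaussian_filter(noise, 2.0)
            tex = (tex - tex.min()) / (np.ptp(tex) + 1e-12)
            target[c] += contrast * tex

    if kind == "beads":
        add_beads(img, density)
    elif kind == "bars":
        add_bars(img)
    elif kind == "texture":
        add_texture(img, max(density * 10.0, 0.5))
    elif kind == "mixed":
        add_texture(img, 0.4)
        add_beads(img, density)
        add_bars(img)
    else:
        raise ValueError(f"unknown scene kind {kind!r}")

    img = np.clip(img, 0.0, None)
    if kind == "bars":
        h = size
        depth = np.empty((h, size))
        thirds = np.array_split(np.arange(size), 3)
        for level, cols in zip((-depth_range_um, 0.0, depth_range_um), thirds):
            depth[:, cols] = level
    else:
        depth = _tilted_depth((size, size), depth_range_um)
    return Scene(img, depth, pixel_pitch_um)


def decompose_by_depth(scene: Scene, z_grid) -> dict:
    """One-hot depth decomposition: every pixel is snapped to the nearest
    grid depth; returns ``{z: Scene}`` for the occupied depths only."""
    if scene.depth_um is None:
        raise ValueError("scene has no depth map")
    z_grid = np.asarray(z_grid, dtype=float)
    idx = np.argmin(np.abs(scene.depth_um[..., None] - z_grid), axis=-1)
    out = {}
    for k in np.unique(idx):
        m = idx == k
        if not np.any(scene.image[:, m]):
            continue
        sl = scene.image * m[None]
        out[float(z_grid[k])] = Scene(sl, None, scene.pixel_pitch_um)
    return out


def render_focal_stack(scene: Scene, model: OpticalModel,
                       planes_um=None, psf_size: int | None = None) -> FocalStack:
    """Emulate a conventional (uncoded) through-focus acquisition.

    The slice captured at plane ``z_p`` blurs each scene pixel at depth d
    with the uncoded PSF at defocus ``d - z_p``; pixels are sharpest in the
    slice at their own depth.  PSFs are cached per defocus value.
    """
    if scene.depth_um is None:
        raise ValueError("scene needs a depth map to render a focal stack")
    if planes_um is None:
        planes_um = model.depths_um
    planes_um = np.asarray(planes_um, dtype=float)
    slices_by_depth = decompose_by_depth(scene, planes_um)
    if psf_size is None:
        span = float(np.abs(planes_um).max()) * 2.0
        radius_px = span * model.na / model.pixel_pitch_um
        psf_size = int(2 * np.ceil(radius_px * 1.3) + 1)
        psf_size = max(psf_size, 17)

    cache = {}

    def uncoded_psf(defocus):
        key = round(float(defocus), 6)
        if key not in cache:
            d = np.clip(key, -model.depth_range_um, model.depth_range_um)
            cache[key] = sensor_psf(model, None, d, size=psf_size)
        return cache[key]

    c = scene.n_channels
    h, w = scene.shape
    out = np.zeros((planes_um.size, c, h, w))
    for zi, zp in enumerate(planes_um):
        for d, sub in slices_by_depth.items():
            psf = uncoded_psf(d - zp)
            for ch in range(c):
                out[zi, ch] += conv_same(sub.image[ch], psf)
    return FocalStack(out, planes_um, {"psf_size": psf_size})


def _focus_measure(stack: FocalStack, window: int) -> np.ndarray:
    """Local Laplacian energy per plane, summed over channels."""
    n_z = stack.n_planes
    energy = np.zeros((n_z,) + stack.slices.shape[2:])
    for zi in range(n_z):
        for ch in range(stack.slices.shape[1]):
            lap = ndimage.laplace(stack.slices[zi, ch])
            energy[zi] += ndimage.uniform_filter(lap * lap, size=window)
    return energy


def depth_fusion(stack: FocalStack, window: int = 11, smooth: int = 11):
    """All-in-focus fusion: per-pixel local Laplacian energy picks the
    sharpest plane, the winner map is median-smoothed, and the fused image
    assembles each pixel from its winning slice.

    Returns ``(fused (C, H, W), index_map (H, W))``.
    """
    if stack.n_planes < 2:
        raise ValueError("need at least two slices to fuse")
    energy = _focus_measure(stack, window)
    idx = np.argmax(energy, axis=0)
    if smooth and smooth > 1:
        idx = ndimage.median_filter(idx, size=smooth, mode="nearest")
    n_c = stack.slices.shape[1]
    fused = np.empty((n_c,) + idx.shape)
    for ch in range(n_c):
        fused[ch] = np.take_along_axis(stack.slices[:, ch], idx[None], axis=0)[0]
    return fused, idx


def make_training_pair(scene: Scene, model: OpticalModel, bases: dict,
                       noise: dict | None = None, seed: int = 0,
                       stack: FocalStack | None = None) -> TrainingPair:
    """Build one simulation-supervision pair from a synthetic scene.

    Input: the scene is depth-decomposed onto the basis depth grid and
    propagated through the coded shift-variant forward model (summed over
    depths), optionally with sensor noise.  Label: the uncoded focal stack
    is fused into the all-in-focus image.  ``bases`` maps depth (um) to a
    fitted :class:`~edofscope.factorization.BasisModel`.
    """
    z_grid = np.asarray(sorted(bases), dtype=float)
    slices = decompose_by_depth(scene, z_grid)
    if slices:
        capture = propagate_focal_stack(slices, bases)
    else:
        capture = CodedCapture(np.zeros_like(scene.image))
    if noise:
        capture = add_sensor_noise(capture, seed=seed, **noise)
    if stack is None:
        stack = render_focal_stack(scene, model, planes_um=z_grid)
    label, idx = depth_fusion(stack)
    if capture.image.shape != label.shape:
        raise ValueError("input and label shapes differ")
    return TrainingPair(capture.image, label, idx,
                        meta={"seed": seed, "noise": noise or {}})


def patchify(pair: TrainingPair, n_patches: int = 20, size: int = 512,
             seed: int = 0) -> list:
    """Randomly crop ``n_patches`` aligned input/label patches of
    ``size x size`` (uniform corners, reproducible per seed).  Corner
    records are appended to ``pair.patches``."""
    h, w = pair.input.shape[1:]
    if h < size or w < size:
        raise ValueError("image smaller than the requested patch size")
    rng = np.random.default_rng(seed)
    ys = rng.integers(0, h - size + 1, n_patches)
    xs = rng.integers(0, w - size + 1, n_patches)
    out = []
    for y, x in zip(ys, xs):
        rec = {"y": int(y), "x": int(x), "size": int(size)}
        pair.patches.append(rec)
        out.append((pair.input[:, y:y + size, x:x + size].copy(),
                    pair.label[:, y:y + size, x:x + size].copy()))
    return out
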