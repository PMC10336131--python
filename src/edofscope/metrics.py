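"""Quantitative evaluation: PSF geometry, image quality, contrast.

PSF size follows the calibration protocol of miniature coded microscopes:
binarize at 10% of the peak, keep the largest (8-connected) component,
report its bounding extents.  PSNR/SSIM use the standard definitions
(SSIM with the 11x11 Gaussian window, sigma 1.5, K1 = 0.01, K2 = 0.03).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = [
    "PSFSizeResult",
    "psf_size",
    "fwhm",
    "psnr",
    "ssim",
    "michelson_contrast",
    "chromatic_similarity",
    "volume_reduction",
]


@dataclass(frozen=True)
class PSFSizeResult:
    extent_x_px: int
    extent_y_px: int
    extent_x_um: float
    extent_y_um: float
    threshold_frac: float
    component_pixels: int


def psf_size(psf: np.ndarray, threshold_frac: float = 0.1,
             pixel_pitch_um: float = 1.0) -> PSFSizeResult:
    """Bounding extents of the largest 8-connected component of the PSF
    binarized at ``threshold_frac`` of its maximum intensity."""
    psf = np.asarray(psf, dtype=float)
    if np.any(psf < 0):
        raise ValueError("PSF must be non-negative")
    peak = psf.max()
    if peak <= 0:
        raise ValueError("all-zero PSF has no size")
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold fraction must be in (0, 1)")
    mask = psf >= threshold_frac * peak
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("threshold removed the whole PSF")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    biggest = labels == (1 + int(np.argmax(sizes)))
    ys, xs = np.nonzero(biggest)
    ex = int(xs.max() - xs.min() + 1)
    ey = int(ys.max() - ys.min() + 1)
    return PSFSizeResult(ex, ey, ex * pixel_pitch_um, ey * pixel_pitch_um,
                         threshold_frac, int(biggest.sum()))


def fwhm(profile: np.ndarray, x: np.ndarray | None = None) -> float:
    """Full width at half maximum of a 1-D intensity profile.

    Half-maximum crossings are located by linear interpolation; for
    multimodal profiles the widest crossing pair is used.  Raises if the
    profile never falls below half maximum on either side of the peak.
    """
    profile = np.asarray(profile, dtype=float)
    if x is None:
        x = np.arange(profile.size, dtype=float)
    x = np.asarray(x, dtype=float)
    half = profile.max() / 2.0
    above = profile >= half
    if above.all() or not above.any():
        raise ValueError("profile does not cross half maximum")
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    if i0 == 0 or i1 == profile.size - 1:
        raise ValueError("profile does not fall below half maximum on both sides")

    def interp(a, b):
        # crossing between samples a (below) and b (above) or vice versa
        ya, yb = profile[a], profile[b]
        t = (half - ya) / (yb - ya)
        return x[a] + t * (x[b] - x[a])

    left = interp(i0 - 1, i0)
    right = interp(i1 + 1, i1)
    return float(abs(right - left))


def psnr(a: np.ndarray, b: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if peak is None:
        peak = float(max(a.max(), b.max()))
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(peak) - 10.0 * np.log10(mse))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity with the standard Gaussian window
    (11x11, sigma 1.5) and constants K1 = 0.01, K2 = 0.03."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def michelson_contrast(image: np.ndarray, region=None) -> float:
    """(Imax - Imin) / (Imax + Imin) over the given region (slice tuple or
    boolean mask; whole image by default)."""
    image = np.asarray(image, dtype=float)
    vals = image if region is None else image[region]
    vals = np.asarray(vals)
    if vals.size == 0:
        raise ValueError("empty region")
    hi, lo = float(vals.max()), float(vals.min())
    if hi + lo <= 0:
        raise ValueError("degenerate region: Imax + Imin must be positive")
    return (hi - lo) / (hi + lo)


def chromatic_similarity(psfs_by_channel: np.ndarray) -> dict:
    """SSIM-versus-field curves between color channels.

    ``psfs_by_channel`` has shape (C, M, y, x): per channel, one PSF per
    field point on a matched field grid.  Returns
    ``{(c1, c2): curve of length M}`` for every channel pair.
    """
    psfs = np.asarray(psfs_by_channel, dtype=float)
    if psfs.ndim != 4:
        raise ValueError("expected (C, M, y, x) PSF array")
    c, m = psfs.shape[:2]
    curves = {}
    for c1 in range(c):
        for c2 in range(c1 + 1, c):
            vals = np.empty(m)
            for k in range(m):
                vals[k] = ssim(psfs[c1, k], psfs[c2, k])
            curves[(c1, c2)] = vals
    return curves


def volume_reduction(dims_mm=(323.0, 475.0, 656.0),
                     miniature_mm3: float = 150.0):
    """Volume of a tabletop microscope (W x D x H in mm) and its ratio to
    the miniaturized device volume.  Returns ``(volume_mm3, ratio)``."""
    volume = float(np.prod(np.asarray(dims_mm, dtype=float)))
    if miniature_mm3 <= 0:
        raise ValueError("miniature volume must be positive")
    return volume, volume / miniature_mm3
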