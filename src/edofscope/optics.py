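"""Fourier-optics simulation of a wavefront-coded miniature microscope.

The module models a compact finite-conjugate microscope (NA 0.16, focal
length 1 mm, conjugate distance 6 mm) whose pupil carries a cubic phase
plate for depth-of-field extension.  Point spread functions are computed
with the standard scalar pupil-function model

    PSF(z, field) = | FT{ A(rho) * exp(i [phi_cubic + phi_defocus(z) + phi_field]) } |^2

with the defocus phase ``phi_defocus = (2*pi/lambda) * z * (NA^2/2) * rho^2``
on the normalized pupil radius ``rho``.  Field dependence (the source of
shift variance in the multi-lens device) is emulated with parametric tilt
and coma terms.

All pupil-plane lengths are millimetres, depths and sensor pitches are
micrometres, wavelengths are nanometres.  PSFs are returned on the "natural"
object-space pitch ``lambda * R / (G * NA)`` where ``G`` is the pupil grid
size and ``R = G // 4`` the pupil radius in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.fft import fft2, fftshift, ifftshift, next_fast_len
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "AsphericSurface",
    "CubicPhaseMask",
    "OpticalModel",
    "MTFStack",
    "AlphaCandidate",
    "SweepResult",
    "GridTooCoarseError",
    "aspheric_sag",
    "cubic_phase",
    "simulate_psf",
    "natural_pitch_um",
    "required_grid",
    "mtf_from_psf",
    "compute_mtf_stack",
    "fisher_information",
    "nyquist_mtf_min",
    "alpha_candidates",
    "sweep_alpha",
    "strehl_ratio",
    "sensor_psf",
    "PSFGrid",
    "field_grid",
    "simulate_psf_grid",
]


class GridTooCoarseError(ValueError):
    """Pupil sampling violates the anti-aliasing bound for the requested phase."""


# ---------------------------------------------------------------------------
# surface / mask geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AsphericSurface:
    """Even-polynomial aspheric surface (conic base plus r^2 ... r^16 terms).

    Parameters
    ----------
    curvature : float
        Vertex curvature ``c`` in 1/mm.
    conic : float
        Conic constant ``k`` (dimensionless).
    coefficients : sequence of 8 floats
        Polynomial coefficients ``alpha_1 ... alpha_8`` multiplying
        ``r^2, r^4, ..., r^16``.
    semi_diameter : float
        Clear semi-diameter in mm.
    """

    curvature: float = 0.0
    conic: float = 0.0
    coefficients: tuple = (0.0,) * 8
    semi_diameter: float = 1.0

    def __post_init__(self):
        if len(self.coefficients) != 8:
            raise ValueError("exactly 8 polynomial coefficients expected")
        if self.semi_diameter <= 0:
            raise ValueError("semi_diameter must be positive")


def aspheric_sag(surface: AsphericSurface, r):
    """Surface sag z(r) of an aspheric lens surface in mm.

    ``z = c r^2 / (1 + sqrt(1 - (1+k) c^2 r^2)) + sum_i alpha_i r^(2i)``.

    Raises
    ------
    ValueError
        If ``r`` exceeds the clear semi-diameter or the square-root
        argument is negative.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > surface.semi_diameter):
        raise ValueError("radial coordinate outside clear semi-diameter")
    c, k = surface.curvature, surface.conic
    arg = 1.0 - (1.0 + k) * c * c * r * r
    if np.any(arg < 0):
        raise ValueError("conic square-root argument negative (surface undefined)")
    sag = c * r * r / (1.0 + np.sqrt(arg))
    r2 = r * r
    term = r2.copy()
    for a in surface.coefficients:
        sag = sag + a * term
        term = term * r2
    return sag if sag.ndim else float(sag)


@dataclass(frozen=True)
class CubicPhaseMask:
    """Cubic phase plate with surface height ``h(x, y) = alpha (x^3 + y^3)``.

    ``alpha`` is in mm^-2 and applies to physical coordinates on the plate.
    The surface is antisymmetric, ``h(-x, -y) = -h(x, y)``, which is what
    makes the coded MTF nearly defocus invariant.
    """

    alpha: float
    refractive_index: float = 1.5
    semi_diameter: float = 1.0

    def surface_height(self, x, y):
        return self.alpha * (np.asarray(x) ** 3 + np.asarray(y) ** 3)


def cubic_phase(mask: CubicPhaseMask, x, y, wavelength_nm: float):
    """Phase delay in radians imparted by the cubic plate at (x, y) mm.

    ``phase = 2 pi (n - 1) alpha (x^3 + y^3) / lambda`` with lambda in mm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(x) > mask.semi_diameter) or np.any(np.abs(y) > mask.semi_diameter):
        raise ValueError("coordinates outside the mask aperture")
    lam_mm = wavelength_nm * 1e-6
    ph = 2.0 * np.pi * (mask.refractive_index - 1.0) * mask.surface_height(x, y) / lam_mm
    return ph if ph.ndim else float(ph)


# ---------------------------------------------------------------------------
# optical model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalModel:
    """System constants of the miniature microscope.

    Defaults follow the integrated design: NA 0.16, focal length 1 mm,
    conjugate distance 6 mm, RGB channels at 470/530/590 nm, a 300 um
    design depth range sampled every 10 um, and a field radius of 1.8 mm
    (3.6 mm field of view).  ``field_tilt_waves`` / ``field_coma_waves``
    are the parametric aberration amplitudes (waves at the pupil edge for
    a unit field vector) that create shift-variant PSFs.
    """

    na: float = 0.16
    focal_length_mm: float = 1.0
    conjugate_mm: float = 6.0
    wavelengths_nm: tuple = (470.0, 530.0, 590.0)
    pixel_pitch_um: float = 3.0
    pupil_grid: int = 256
    field_tilt_waves: float = 1.0
    field_coma_waves: float = 0.5
    depth_range_um: float = 150.0
    depth_step_um: float = 10.0
    field_radius_mm: float = 1.8

    def __post_init__(self):
        if not 0.0 < self.na < 1.0:
            raise ValueError("NA must be in (0, 1)")
        if self.pupil_grid < 64 or self.pupil_grid % 2:
            raise ValueError("pupil grid size must be even and >= 64")
        n_steps = self.depth_range_um / self.depth_step_um
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("depth step must divide the depth range")

    @property
    def pupil_semidiameter_mm(self) -> float:
        """Entrance-pupil semi-diameter seen from the object side."""
        return self.conjugate_mm * np.tan(np.arcsin(self.na))

    @property
    def depths_um(self) -> np.ndarray:
        n = int(round(self.depth_range_um / self.depth_step_um))
        return np.arange(-n, n + 1) * self.depth_step_um

    @property
    def nyquist_cyc_mm(self) -> float:
        """Sensor Nyquist frequency in object space, cycles/mm."""
        return 500.0 / self.pixel_pitch_um

    def reference_wavelength_nm(self) -> float:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        return float(w[len(w) // 2])


# ---------------------------------------------------------------------------
# PSF simulation
# ---------------------------------------------------------------------------


def _max_phase_gradient(model: OpticalModel, mask, z_um, field, lam_mm) -> float:
    """Analytic upper bound on |d phase / d x| in rad/mm over the pupil."""
    a = model.pupil_semidiameter_mm
    g = 2.0 * np.pi * abs(z_um) * 1e-3 * model.na**2 / (lam_mm * a)
    if mask is not None:
        g += 6.0 * np.pi * (mask.refractive_index - 1.0) * abs(mask.alpha) * a**2 / lam_mm
    fr = float(np.hypot(*field))
    if fr > 0:
        g += 2.0 * np.pi * model.field_tilt_waves * fr / a
        g += 2.0 * np.pi * model.field_coma_waves * fr * 7.0 / a
    return g


def required_grid(model: OpticalModel, mask=None, z_um=0.0, field=(0.0, 0.0),
                  wavelength_nm=None) -> int:
    """Smallest FFT-friendly pupil grid satisfying the anti-aliasing bound.

    The pupil sample step must keep the phase increment between adjacent
    samples below pi; a safety factor of 0.8 is applied.  The pupil radius
    occupies a quarter of the grid so the PSF is Nyquist sampled.
    """
    lam_mm = (wavelength_nm or model.reference_wavelength_nm()) * 1e-6
    a = model.pupil_semidiameter_mm
    grad = _max_phase_gradient(model, mask, z_um, field, lam_mm)
    r_req = max(64, int(np.ceil(a * grad / (0.8 * np.pi))))
    return int(next_fast_len(4 * r_req, real=True))


def _static_phase(model, mask, field, lam_mm, grid):
    """Defocus-independent pupil phase (cubic + field terms), the squared
    normalized radius map, and the in-aperture mask."""
    radius = grid // 4
    c = grid // 2
    rho_1d = (np.arange(grid) - c) / radius
    ry, rx = np.meshgrid(rho_1d, rho_1d, indexing="ij")
    rho2 = rx * rx + ry * ry
    inside = rho2 <= 1.0

    phase = np.zeros_like(rho2)
    if mask is not None:
        # cubic phase on physical pupil coordinates
        a = model.pupil_semidiameter_mm
        h = mask.surface_height(rx * a, ry * a)
        phase = phase + 2.0 * np.pi * (mask.refractive_index - 1.0) * h / lam_mm
    u, v = field
    if u or v:
        lin = u * rx + v * ry
        phase = phase + 2.0 * np.pi * model.field_tilt_waves * lin
        phase = phase + 2.0 * np.pi * model.field_coma_waves * (3.0 * rho2 - 2.0) * lin
    return phase, rho2, inside


def _pupil_field(model, mask, z_um, field, lam_mm, grid):
    """Full pupil phase and in-aperture mask on the given grid."""
    static, rho2, inside = _static_phase(model, mask, field, lam_mm, grid)
    defconst = (2.0 * np.pi / lam_mm) * (model.na**2 / 2.0)
    return static + defconst * (z_um * 1e-3) * rho2, inside


def _check_sampling(phase, inside):
    """Numeric anti-aliasing guard: phase step between adjacent in-aperture
    samples must stay below pi."""
    for axis in (0, 1):
        d = np.abs(np.diff(phase, axis=axis))
        both = np.logical_and(np.take(inside, range(inside.shape[axis] - 1), axis=axis),
                              np.take(inside, range(1, inside.shape[axis]), axis=axis))
        if d[both].size and d[both].max() >= np.pi:
            raise GridTooCoarseError(
                "pupil sampling too coarse for the requested phase "
                f"(max step {d[both].max():.2f} rad >= pi); increase the grid"
            )


def simulate_psf(model: OpticalModel, mask: CubicPhaseMask | None = None,
                 z_um: float = 0.0, field=(0.0, 0.0), wavelength_nm: float | None = None,
                 grid: int | None = None, dtype=np.complex128) -> np.ndarray:
    """Incoherent PSF of the (optionally coded) system at defocus ``z_um``.

    Parameters
    ----------
    field : pair of floats
        Normalized field position inside the unit disk.
    grid : int, optional
        Pupil grid size; computed from the anti-aliasing bound when omitted.

    Returns
    -------
    ndarray
        ``grid x grid`` PSF, non-negative, normalized to unit sum, centred
        at pixel ``(grid // 2, grid // 2)``.
    """
    if abs(z_um) > model.depth_range_um + 1e-9:
        raise ValueError("defocus outside the design depth range")
    if np.hypot(*field) > 1.0 + 1e-12:
        raise ValueError("field position outside the unit disk")
    lam_nm = wavelength_nm or model.reference_wavelength_nm()
    lam_mm = lam_nm * 1e-6
    if grid is None:
        grid = max(model.pupil_grid, required_grid(model, mask, z_um, field, lam_nm))
    phase, inside = _pupil_field(model, mask, z_um, field, lam_mm, grid)
    _check_sampling(phase, inside)
    pupil = np.zeros_like(phase, dtype=dtype)
    pupil[inside] = np.exp(1j * phase[inside]).astype(dtype)
    amp = fftshift(fft2(ifftshift(pupil)))
    psf = (amp.real**2 + amp.imag**2).astype(np.float64)
    psf /= psf.sum()
    return psf


def natural_pitch_um(model: OpticalModel, wavelength_nm: float, grid: int) -> float:
    """Object-space pixel pitch of a simulated PSF: ``lambda R / (G NA)``."""
    radius = grid // 4
    return wavelength_nm * 1e-3 * radius / (grid * model.na)


# ---------------------------------------------------------------------------
# MTF and depth-invariance merit
# ---------------------------------------------------------------------------


def mtf_from_psf(psf: np.ndarray) -> np.ndarray:
    """2-D modulation transfer function |FT{PSF}| normalized to MTF(0) = 1.

    Input PSF is centred at ``(n // 2, n // 2)``; the returned MTF is
    centred the same way (zero frequency at the centre pixel).
    """
    otf = fftshift(fft2(ifftshift(psf)))
    mtf = np.abs(otf)
    c = psf.shape[0] // 2
    return mtf / mtf[c, psf.shape[1] // 2]


@dataclass
class MTFStack:
    """MTF sampled on a canonical (fx, fy) grid for a list of defocus planes.

    ``values[k]`` is the MTF of plane ``depths_um[k]`` on the square grid
    ``freqs_cyc_mm x freqs_cyc_mm`` spanning +-Nyquist.
    """

    values: np.ndarray          # (n_z, K, K)
    freqs_cyc_mm: np.ndarray    # (K,)
    depths_um: np.ndarray       # (n_z,)
    nyquist_cyc_mm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freqs_cyc_mm = np.asarray(self.freqs_cyc_mm, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.values.shape[0] != self.depths_um.size:
            raise ValueError("one MTF plane per depth expected")

    def nyquist_values(self) -> np.ndarray:
        """Per depth, the minimum MTF over the four on-axis Nyquist points."""
        k = self.freqs_cyc_mm.size
        c = k // 2
        pts = self.values[:, [c, c, 0, -1], [0, -1, c, c]]
        return pts.min(axis=1)


def compute_mtf_stack(model: OpticalModel, mask: CubicPhaseMask | None,
                      depths_um=None, field=(0.0, 0.0), wavelength_nm=None,
                      grid: int | None = None, n_freq: int = 65,
                      dtype=np.complex128) -> MTFStack:
    """Simulate PSFs over depth and resample their MTFs onto a canonical
    frequency grid spanning +-Nyquist (so stacks computed on different
    pupil grids are comparable)."""
    if depths_um is None:
        depths_um = model.depths_um
    depths_um = np.asarray(depths_um, dtype=float)
    if depths_um.size < 1:
        raise ValueError("at least one depth plane required")
    lam_nm = wavelength_nm or model.reference_wavelength_nm()
    if grid is None:
        zmax = float(np.abs(depths_um).max())
        grid = max(model.pupil_grid, required_grid(model, mask, zmax, field, lam_nm))
    f_nyq = model.nyquist_cyc_mm
    f_axis = np.linspace(-f_nyq, f_nyq, n_freq)
    fy, fx = np.meshgrid(f_axis, f_axis, indexing="ij")
    query = np.stack([fx.ravel(), fy.ravel()], axis=-1)

    pitch_mm = natural_pitch_um(model, lam_nm, grid) * 1e-3
    df = 1.0 / (grid * pitch_mm)
    native = (np.arange(grid) - grid // 2) * df
    if f_nyq > native.max():
        raise ValueError("sensor Nyquist frequency beyond simulated band")

    # At field (0,0) the pupil phase is cubic + defocus only; conjugating the
    # pupil and flipping coordinates maps z -> -z onto the same intensity PSF,
    # so MTF(-z) = MTF(z) and only |z| needs simulating.
    on_axis = not (field[0] or field[1])
    todo = np.unique(np.abs(depths_um)) if on_axis else depths_um

    static, rho2, inside = _static_phase(model, mask, field, lam_mm=lam_nm * 1e-6,
                                         grid=grid)
    defconst = (2.0 * np.pi / (lam_nm * 1e-6)) * 1e-3 * (model.na**2 / 2.0)
    computed = {}
    for z in todo:
        phase = static + (defconst * z) * rho2
        _check_sampling(phase, inside)
        pupil = np.zeros(phase.shape, dtype=dtype)
        pupil[inside] = np.exp(1j * phase[inside]).astype(dtype)
        amp = fftshift(fft2(ifftshift(pupil)))
        psf = (amp.real**2 + amp.imag**2).astype(np.float64)
        psf /= psf.sum()
        mtf = mtf_from_psf(psf)
        interp = RegularGridInterpolator((native, native), mtf, method="linear")
        computed[float(z)] = interp(query[:, ::-1]).reshape(n_freq, n_freq)

    planes = np.empty((depths_um.size, n_freq, n_freq))
    for k, z in enumerate(depths_um):
        planes[k] = computed[float(abs(z) if on_axis else z)]
    return MTFStack(planes, f_axis, depths_um, f_nyq)


def fisher_information(stack: MTFStack) -> float:
    """Depth-invariance merit: sum of squared defocus derivatives of the MTF.

    ``FI = sum_f sum_z [MTF(f, z + dz) - MTF(f, z)]^2 / dz^2`` over all
    frequency bins up to Nyquist.  Zero iff all planes are identical.
    """
    if stack.depths_um.size < 2:
        raise ValueError("need at least two defocus planes")
    dz = np.diff(stack.depths_um)
    diffs = np.diff(stack.values, axis=0)
    return float(np.sum((diffs / dz[:, None, None]) ** 2))


def nyquist_mtf_min(stack: MTFStack) -> float:
    """Minimum Nyquist-frequency MTF over the depth range."""
    return float(stack.nyquist_values().min())


# ---------------------------------------------------------------------------
# modulation-strength selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlphaCandidate:
    alpha: float
    fisher_info: float
    min_nyquist_mtf: float
    feasible: bool


@dataclass
class SweepResult:
    """Outcome of the modulation-strength sweep.

    ``candidates`` is in enumeration order; ``ranked`` puts feasible
    candidates (min Nyquist MTF >= threshold) first, ordered by ascending
    Fisher information.  ``selected`` is the feasible candidate with the
    smallest Fisher information, or None if the feasible set is empty.
    """

    candidates: list
    threshold: float

    @property
    def ranked(self) -> list:
        return sorted(self.candidates,
                      key=lambda c: (not c.feasible, c.fisher_info))

    @property
    def selected(self) -> AlphaCandidate | None:
        feas = [c for c in self.candidates if c.feasible]
        if not feas:
            return None
        return min(feas, key=lambda c: c.fisher_info)

    @property
    def feasible_empty(self) -> bool:
        return self.selected is None


def alpha_candidates(alpha_min: float, alpha_max: float,
                     alpha_step: float) -> np.ndarray:
    """Inclusive enumeration ``alpha_min, alpha_min + step, ... <= alpha_max``
    (the canonical design range 0.005 ... 0.075 in 0.005 steps gives 15
    candidates)."""
    if alpha_step <= 0:
        raise ValueError("alpha_step must be positive")
    if alpha_min > alpha_max:
        raise ValueError("alpha_min must not exceed alpha_max")
    n = int(np.floor((alpha_max - alpha_min) / alpha_step + 1e-9)) + 1
    return alpha_min + alpha_step * np.arange(n)


def sweep_alpha(model: OpticalModel, alpha_min: float = 0.005,
                alpha_max: float = 0.075, alpha_step: float = 0.005,
                threshold: float = 0.1, depths_um=None, wavelength_nm=None,
                n_freq: int = 65, dtype=np.complex64,
                refractive_index: float = 1.5) -> SweepResult:
    """Enumerate cubic modulation strengths and rank them by the
    depth-invariance merit subject to the Nyquist-MTF constraint.

    Candidates are ``alpha_min, alpha_min + step, ... <= alpha_max``
    (inclusive).  A candidate is feasible when its minimum Nyquist MTF over
    the depth range stays at or above ``threshold`` (information above the
    noise floor, recoverable by deconvolution); among feasible candidates
    the one with minimum Fisher information is selected.  An empty feasible
    set is reported via the result, not raised.
    """
    alphas = alpha_candidates(alpha_min, alpha_max, alpha_step)
    cands = []
    for a in alphas:
        mask = CubicPhaseMask(alpha=float(a), refractive_index=refractive_index,
                              semi_diameter=model.pupil_semidiameter_mm)
        stack = compute_mtf_stack(model, mask, depths_um=depths_um,
                                  wavelength_nm=wavelength_nm, n_freq=n_freq,
                                  dtype=dtype)
        fi = fisher_information(stack) if stack.depths_um.size > 1 else 0.0
        mn = nyquist_mtf_min(stack)
        cands.append(AlphaCandidate(float(a), fi, mn, bool(mn >= threshold)))
    return SweepResult(cands, threshold)


def sensor_psf(model: OpticalModel, mask: CubicPhaseMask | None, z_um: float,
               field=(0.0, 0.0), wavelength_nm: float | None = None,
               size: int = 65, normalize: bool = True) -> np.ndarray:
    """PSF resampled onto the sensor pixel grid (``model.pixel_pitch_um``).

    The PSF is simulated at its natural (finer) pitch, pre-filtered with a
    box approximating the pixel aperture, bilinearly resampled to the
    sensor pitch, centre-cropped to ``size x size`` and (by default)
    renormalized to unit sum.  ``size`` should be odd so the kernel centre
    is unambiguous; the centre pixel is ``size // 2``.
    """
    from scipy.ndimage import uniform_filter, map_coordinates

    lam_nm = wavelength_nm or model.reference_wavelength_nm()
    psf = simulate_psf(model, mask, z_um, field, lam_nm)
    grid = psf.shape[0]
    nat = natural_pitch_um(model, lam_nm, grid)
    scale = model.pixel_pitch_um / nat
    if scale > 1.5:
        psf = uniform_filter(psf, size=max(2, int(round(scale))), mode="constant")
    c_t = size // 2
    c_s = grid // 2
    j = (np.arange(size) - c_t) * scale + c_s
    yy, xx = np.meshgrid(j, j, indexing="ij")
    out = map_coordinates(psf, [yy, xx], order=1, mode="constant")
    out = np.maximum(out, 0.0)
    if normalize:
        s = out.sum()
        if s <= 0:
            raise ValueError("PSF crop captured no energy; increase size")
        out /= s
    return out


@dataclass
class PSFGrid:
    """Coded/uncoded PSFs indexed by field point, depth and color channel.

    ``data`` has shape (M, n_z, C, y, x) on the sensor pixel pitch.
    """

    data: np.ndarray
    z_um: np.ndarray
    field_uv: np.ndarray
    wavelengths_nm: tuple
    pixel_pitch_um: float
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.field_uv = np.asarray(self.field_uv, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("PSF grid must be (field, z, channel, y, x)")

    def at_depth(self, z: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.z_um - z)))
        if abs(self.z_um[k] - z) > 1e-6:
            raise KeyError(f"depth {z} not in grid")
        return self.data[:, k]


def field_grid(n_side: int, radius: float = 1.0) -> np.ndarray:
    """(n_side^2, 2) normalized field coordinates on a square grid spanning
    +-radius, row-major (v outer, u inner)."""
    ax = np.linspace(-radius, radius, n_side) if n_side > 1 else np.zeros(1)
    vv, uu = np.meshgrid(ax, ax, indexing="ij")
    return np.stack([uu.ravel(), vv.ravel()], axis=-1)


def simulate_psf_grid(model: OpticalModel, mask: CubicPhaseMask | None,
                      field_uv=None, depths_um=None, size: int = 65,
                      wavelengths_nm=None) -> PSFGrid:
    """Simulate the full field x depth x channel PSF grid on the sensor pitch.

    Defaults: a 3x3 field grid spanning the unit field disk's inscribed
    square, the model's depth grid, and the model's wavelength channels.
    """
    if field_uv is None:
        field_uv = field_grid(3, 0.7)
    field_uv = np.asarray(field_uv, dtype=float)
    if depths_um is None:
        depths_um = model.depths_um
    depths_um = np.asarray(depths_um, dtype=float)
    if wavelengths_nm is None:
        wavelengths_nm = model.wavelengths_nm
    data = np.empty((field_uv.shape[0], depths_um.size, len(wavelengths_nm),
                     size, size))
    for fi, (u, v) in enumerate(field_uv):
        for zi, z in enumerate(depths_um):
            for ci, lam in enumerate(wavelengths_nm):
                data[fi, zi, ci] = sensor_psf(model, mask, z, (u, v), lam, size)
    meta = {
        "na": model.na,
        "alpha": 0.0 if mask is None else mask.alpha,
        "pixel_pitch_um": model.pixel_pitch_um,
    }
    return PSFGrid(data, depths_um, field_uv, tuple(wavelengths_nm),
                   model.pixel_pitch_um, meta)


def strehl_ratio(psf: np.ndarray, model: OpticalModel,
                 wavelength_nm: float | None = None) -> float:
    """Peak of the given PSF relative to the diffraction-limited on-axis PSF
    simulated on the same grid (alpha = 0, z = 0, field = 0)."""
    ref = simulate_psf(model, None, 0.0, (0.0, 0.0), wavelength_nm,
                       grid=psf.shape[0])
    return float(psf.max() / ref.max())
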