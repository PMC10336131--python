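"""Pupil-model PSF/MTF simulation, sag utility, and modulation selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edofscope import (AsphericSurface, CubicPhaseMask, GridTooCoarseError,
                       MTFStack, OpticalModel, alpha_candidates, aspheric_sag,
                       compute_mtf_stack, cubic_phase, fisher_information,
                       mtf_from_psf, nyquist_mtf_min, simulate_psf,
                       strehl_ratio, sweep_alpha)
from edofscope.optics import natural_pitch_um, required_grid
from edofscope.metrics import ssim


# ---------------------------------------------------------------------------
# aspheric sag
# ---------------------------------------------------------------------------


class TestAsphericSag:
    def test_flat_surface_is_zero(self):
        s = AsphericSurface()
        r = np.linspace(0, 1, 7)
        assert np.all(aspheric_sag(s, r) == 0.0)

    def test_sphere_closed_form(self):
        # pure conic with k=0 is a sphere: sag = R - sqrt(R^2 - r^2)
        s = AsphericSurface(curvature=0.5, semi_diameter=2.0)
        got = aspheric_sag(s, 1.0)
        expect = 2.0 - np.sqrt(3.0)
        assert abs(got - expect) / expect < 1e-12

    def test_term_by_term_rational_evaluation(self):
        # independent oracle: exact rational arithmetic of the formula
        from fractions import Fraction

        c = Fraction(1, 2)
        k = Fraction(-1)
        a1 = Fraction(1, 10)
        r = Fraction(1)
        # k = -1 removes the square root: arg = 1 - 0 = 1
        exact = c * r**2 / (1 + 1) + a1 * r**2
        s = AsphericSurface(curvature=0.5, conic=-1.0,
                            coefficients=(0.1,) + (0.0,) * 7,
                            semi_diameter=2.0)
        assert abs(aspheric_sag(s, 1.0) - float(exact)) < 1e-15

    def test_domain_errors(self):
        s = AsphericSurface(curvature=1.0, conic=0.5, semi_diameter=3.0)
        with pytest.raises(ValueError):
            aspheric_sag(s, 2.0)   # sqrt argument negative
        with pytest.raises(ValueError):
            aspheric_sag(AsphericSurface(semi_diameter=1.0), 1.5)


# ---------------------------------------------------------------------------
# cubic phase plate
# ---------------------------------------------------------------------------


class TestCubicPhase:
    def test_zero_alpha(self):
        m = CubicPhaseMask(0.0)
        assert cubic_phase(m, 0.3, -0.2, 530.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-0.9, 0.9), st.floats(-0.9, 0.9),
           st.floats(0.005, 0.075))
    def test_antisymmetry(self, x, y, alpha):
        m = CubicPhaseMask(alpha)
        assert cubic_phase(m, -x, -y, 530.0) == pytest.approx(
            -cubic_phase(m, x, y, 530.0), abs=1e-9)

    def test_hand_arithmetic(self):
        m = CubicPhaseMask(0.03, refractive_index=1.5, semi_diameter=0.5)
        got = cubic_phase(m, 0.3, 0.3, 530.0)
        expect = 2 * np.pi * 0.5 * 0.03 * (2 * 0.027) / 5.3e-4
        assert got == pytest.approx(expect, rel=1e-12)

    def test_aperture_check(self):
        with pytest.raises(ValueError):
            cubic_phase(CubicPhaseMask(0.01, semi_diameter=0.4), 0.5, 0.0, 530.0)


# ---------------------------------------------------------------------------
# PSF simulation
# ---------------------------------------------------------------------------


class TestSimulatePsf:
    @pytest.mark.parametrize("alpha,z,field", [
        (0.0, 0.0, (0.0, 0.0)),
        (0.0, 150.0, (0.0, 0.0)),
        (0.01, -75.0, (0.5, -0.3)),
        (0.02, 150.0, (0.0, 0.7)),
    ])
    def test_nonneg_unit_sum(self, model_coarse, alpha, z, field):
        mask = CubicPhaseMask(alpha, semi_diameter=model_coarse.pupil_semidiameter_mm) \
            if alpha else None
        psf = simulate_psf(model_coarse, mask, z, field)
        assert np.all(psf >= 0)
        assert abs(psf.sum() - 1.0) < 1e-9

    def test_unaberrated_focus_centered_symmetric(self, model_coarse):
        psf = simulate_psf(model_coarse, None, 0.0)
        n = psf.shape[0]
        assert np.unravel_index(psf.argmax(), psf.shape) == (n // 2, n // 2)
        flipped = psf[::-1, ::-1]
        rolled = np.roll(flipped, (1, 1), axis=(0, 1))  # even-grid centre
        assert np.abs(psf - rolled).max() < 1e-9

    def test_grid_too_coarse_raises(self, model_coarse):
        mask = CubicPhaseMask(0.05,
                              semi_diameter=model_coarse.pupil_semidiameter_mm)
        with pytest.raises(GridTooCoarseError):
            simulate_psf(model_coarse, mask, 0.0, grid=256)

    def test_out_of_range_inputs(self, model_coarse):
        with pytest.raises(ValueError):
            simulate_psf(model_coarse, None, 400.0)
        with pytest.raises(ValueError):
            simulate_psf(model_coarse, None, 0.0, field=(0.9, 0.9))

    def test_coded_psf_more_depth_invariant(self, model_coarse, coded_mask):
        """The coded PSF keeps its shape through defocus; the uncoded PSF
        does not (similar profiles across the 300 um range)."""
        from edofscope import sensor_psf

        coded0 = sensor_psf(model_coarse, coded_mask, 0.0, size=33)
        coded150 = sensor_psf(model_coarse, coded_mask, 150.0, size=33)
        unc0 = sensor_psf(model_coarse, None, 0.0, size=33)
        unc150 = sensor_psf(model_coarse, None, 150.0, size=33)
        s_coded = ssim(coded0, coded150, data_range=coded0.max())
        s_unc = ssim(unc0, unc150, data_range=unc0.max())
        assert s_coded > s_unc

    def test_defocus_symmetry_on_axis(self, model_coarse, coded_mask):
        """With cubic + defocus phase only, the intensity PSF is identical
        at +z and -z (the shortcut the MTF stack exploits)."""
        psf_p = simulate_psf(model_coarse, coded_mask, 75.0)
        psf_m = simulate_psf(model_coarse, coded_mask, -75.0)
        assert np.abs(psf_p - psf_m).max() < 1e-9


# ---------------------------------------------------------------------------
# MTF
# ---------------------------------------------------------------------------


class TestMtf:
    def test_delta_psf_flat_mtf(self):
        psf = np.zeros((64, 64))
        psf[32, 32] = 1.0
        mtf = mtf_from_psf(psf)
        assert np.abs(mtf - 1.0).max() < 1e-12

    def test_normalization_and_bound(self, model_coarse):
        psf = simulate_psf(model_coarse, None, 50.0)
        mtf = mtf_from_psf(psf)
        n = psf.shape[0]
        assert mtf[n // 2, n // 2] == pytest.approx(1.0)
        assert mtf.max() <= 1.0 + 1e-9

    def test_gaussian_closed_form(self):
        n, sigma = 256, 3.0
        ax = np.arange(n) - n // 2
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        psf = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        psf /= psf.sum()
        mtf = mtf_from_psf(psf)
        f = np.fft.fftshift(np.fft.fftfreq(n))
        fy, fx = np.meshgrid(f, f, indexing="ij")
        expect = np.exp(-2 * np.pi**2 * sigma**2 * (fx**2 + fy**2))
        assert np.abs(mtf - expect).max() <= 1e-6


# ---------------------------------------------------------------------------
# Fisher information and the alpha sweep
# ---------------------------------------------------------------------------


def _toy_stack(values, depths):
    values = np.asarray(values, dtype=float)
    k = values.shape[-1]
    f = np.linspace(-100, 100, k)
    return MTFStack(values, f, np.asarray(depths, dtype=float), 100.0)


class TestFisherInformation:
    def test_identical_planes_zero(self):
        plane = np.random.default_rng(0).random((9, 9))
        st_ = _toy_stack(np.stack([plane] * 4), [0, 10, 20, 30])
        assert fisher_information(st_) == 0.0

    def test_single_bin_two_planes(self):
        a = np.ones((9, 9))
        b = a.copy()
        b[3, 4] += 0.25
        st_ = _toy_stack(np.stack([a, b]), [0.0, 1.0])
        assert fisher_information(st_) == pytest.approx(0.25**2)

    def test_coded_less_than_uncoded(self, model_coarse, coded_mask):
        coded = compute_mtf_stack(model_coarse, coded_mask, dtype=np.complex64)
        uncoded = compute_mtf_stack(model_coarse, None, dtype=np.complex64)
        fi_c = fisher_information(coded)
        fi_u = fisher_information(uncoded)
        assert 0.0 <= fi_c < fi_u
        # coded Nyquist MTF at the depth extremes beats uncoded
        assert coded.nyquist_values()[0] > uncoded.nyquist_values()[0]

    def test_needs_two_planes(self):
        with pytest.raises(ValueError):
            fisher_information(_toy_stack(np.ones((1, 3, 3)), [0.0]))


class TestAlphaSweep:
    def test_enumeration_inclusive(self):
        assert len(alpha_candidates(0.005, 0.075, 0.005)) == 15
        assert len(alpha_candidates(0.01, 0.01, 0.005)) == 1
        np.testing.assert_allclose(alpha_candidates(0.1, 0.3, 0.1),
                                   [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            alpha_candidates(0.1, 0.05, 0.01)
        with pytest.raises(ValueError):
            alpha_candidates(0.0, 0.1, 0.0)

    def test_small_sweep_filter_matches_brute_force(self, model_coarse):
        res = sweep_alpha(model_coarse, 0.01, 0.02, 0.005,
                          depths_um=[-150.0, 0.0, 150.0], n_freq=33)
        assert len(res.candidates) == 3
        # feasibility equals an independent re-filter of the candidate list
        for c in res.candidates:
            assert c.feasible == (c.min_nyquist_mtf >= 0.1)
        feas = [c for c in res.candidates if c.feasible]
        if feas:
            best = min(feas, key=lambda c: c.fisher_info)
            assert res.selected.alpha == best.alpha
            assert res.ranked[0].alpha == best.alpha
        else:
            assert res.feasible_empty

    def test_single_alpha_ranked_first(self, model_coarse):
        res = sweep_alpha(model_coarse, 0.01, 0.01, 0.005,
                          depths_um=[0.0, 150.0], n_freq=17)
        assert len(res.candidates) == 1
        assert res.ranked[0] is res.candidates[0]


class TestStrehl:
    def test_reference_is_one(self, model_coarse):
        psf = simulate_psf(model_coarse, None, 0.0, grid=256)
        assert strehl_ratio(psf, model_coarse) == pytest.approx(1.0)

    def test_bounded_and_ordering(self, model_coarse, coded_mask):
        g = required_grid(model_coarse, coded_mask, 150.0)
        unc = simulate_psf(model_coarse, None, 150.0, grid=g, dtype=np.complex64)
        cod = simulate_psf(model_coarse, coded_mask, 150.0, grid=g,
                           dtype=np.complex64)
        s_unc = strehl_ratio(unc, model_coarse)
        s_cod = strehl_ratio(cod, model_coarse)
        assert s_unc <= 1.0 + 1e-6 and s_cod <= 1.0 + 1e-6
        # heavily defocused uncoded system falls below the coded one
        assert s_unc < s_cod


class TestModelValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            OpticalModel(na=1.2)
        with pytest.raises(ValueError):
            OpticalModel(pupil_grid=50)   # below the minimum grid size
        with pytest.raises(ValueError):
            OpticalModel(pupil_grid=129)  # odd grid
        with pytest.raises(ValueError):
            OpticalModel(depth_step_um=40.0)  # does not divide 150

    def test_natural_pitch(self, model_coarse):
        # lambda/(4 NA) when the pupil fills a quarter of the grid
        pitch = natural_pitch_um(model_coarse, 530.0, 256)
        assert pitch == pytest.approx(530e-3 * 64 / (256 * 0.16))
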