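"""Synthetic scenes, focal-stack rendering, depth fusion, pair generation."""

import numpy as np
import pytest

from edofscope import (OpticalModel, Scene, TrainingPair, decompose_by_depth,
                       depth_fusion, forward_lowrank, make_training_pair,
                       patchify, render_focal_stack, ssim, synth_scene)
from edofscope.training_data import FocalStack
from conftest import make_exact_basis


class TestSynthScene:
    def test_seed_reproducibility_bitwise(self):
        a = synth_scene("mixed", 64, 0.1, seed=42)
        b = synth_scene("mixed", 64, 0.1, seed=42)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.depth_um, b.depth_um)
        c = synth_scene("mixed", 64, 0.1, seed=43)
        assert np.any(c.image != a.image)

    def test_bead_density_limit(self):
        sc = synth_scene("beads", 64, density=1e-6, seed=0)
        assert sc.image.sum() == 0.0

    def test_tilted_depth_map(self):
        sc = synth_scene("mixed", 96, 0.1, seed=1, depth_range_um=150.0)
        d = sc.depth_um
        assert d.min() == -150.0 and d.max() == 150.0
        # monotone along the tilt (column) axis, constant along rows
        assert np.all(np.diff(d[0]) >= 0)
        np.testing.assert_array_equal(d[0], d[-1])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            synth_scene("mixed", 32)
        with pytest.raises(ValueError):
            synth_scene("mixed", 64, density=0.0)
        with pytest.raises(ValueError):
            synth_scene("voronoi", 64)


class TestDepthDecomposition:
    def test_one_hot_partition(self):
        sc = synth_scene("texture", 64, 0.1, seed=2)
        grid = np.array([-150.0, -75.0, 0.0, 75.0, 150.0])
        slices = decompose_by_depth(sc, grid)
        total = sum(s.image for s in slices.values())
        np.testing.assert_allclose(total, sc.image)
        assert set(slices) <= set(grid.tolist())


@pytest.fixture(scope="module")
def coarse_model():
    return OpticalModel(depth_step_um=75.0)


class TestRenderFocalStack:

    def test_zero_scene_zero_stack(self, coarse_model):
        model = coarse_model
        sc = Scene(np.zeros((3, 64, 64)), np.zeros((64, 64)))
        st = render_focal_stack(sc, model)
        assert np.all(st.slices == 0)
        assert st.n_planes == 5

    def test_flat_sample_sharpest_in_focus(self, coarse_model):
        model = coarse_model
        from scipy.ndimage import laplace
        sc = synth_scene("texture", 64, 0.3, seed=3, n_channels=1)
        sc = Scene(sc.image, np.zeros((64, 64)))   # flat at z = 0
        st = render_focal_stack(sc, model)
        energies = [float(np.sum(laplace(st.slices[k, 0]) ** 2))
                    for k in range(st.n_planes)]
        focus_idx = int(np.argmin(np.abs(st.z_um)))
        assert np.argmax(energies) == focus_idx
        assert energies[0] < energies[focus_idx]
        assert energies[-1] < energies[focus_idx]

    def test_bead_peaks_at_its_depth(self, coarse_model):
        model = coarse_model
        img = np.zeros((1, 64, 64))
        img[0, 32, 32] = 1.0
        depth = np.full((64, 64), 75.0)
        st = render_focal_stack(Scene(img, depth), model)
        peaks = st.slices[:, 0].max(axis=(1, 2))
        assert st.z_um[int(np.argmax(peaks))] == 75.0


class TestDepthFusion:
    def test_identical_slices_idempotent(self):
        rng = np.random.default_rng(5)
        plane = rng.random((1, 48, 48))
        st = FocalStack(np.stack([plane] * 3), np.array([-10.0, 0.0, 10.0]))
        fused, idx = depth_fusion(st)
        np.testing.assert_array_equal(fused, plane)

    def test_flat_sample_wins_its_plane(self):
        model = OpticalModel(depth_step_um=75.0)
        sc = synth_scene("texture", 64, 0.3, seed=6, n_channels=1)
        sc = Scene(sc.image, np.zeros((64, 64)))
        st = render_focal_stack(sc, model)
        fused, idx = depth_fusion(st)
        focus_idx = int(np.argmin(np.abs(st.z_um)))
        # on textured pixels (strong local contrast) the focus measure
        # picks the in-focus plane
        from scipy.ndimage import laplace, uniform_filter
        energy = uniform_filter(laplace(sc.image[0]) ** 2, 11)
        textured = energy > np.quantile(energy, 0.7)
        assert np.mean(idx[textured] == focus_idx) > 0.95

    def test_tilted_sample_recovers_sharp_scene(self):
        model = OpticalModel()          # the full 10-um scan protocol
        sc = synth_scene("texture", 160, 0.1, seed=7)
        st = render_focal_stack(sc, model)
        fused, idx = depth_fusion(st)
        scores = [ssim(fused[c], sc.image[c]) for c in range(3)]
        assert min(scores) >= 0.90

    def test_needs_two_slices(self):
        st = FocalStack(np.ones((1, 1, 8, 8)), np.array([0.0]))
        with pytest.raises(ValueError):
            depth_fusion(st)


class TestTrainingPairs:
    @pytest.fixture()
    def bases(self, coded_psfs9, field_uv9):
        bm = make_exact_basis(coded_psfs9, field_uv9)
        return {z: bm for z in (-150.0, -75.0, 0.0, 75.0, 150.0)}

    def test_zero_scene_zero_pair(self, model_coarse, bases):
        sc = Scene(np.zeros((1, 64, 64)), np.zeros((64, 64)))
        pair = make_training_pair(sc, model_coarse, bases)
        assert np.all(pair.input == 0) and np.all(pair.label == 0)

    def test_flat_scene_reduces_to_single_depth_forward(self, model_coarse,
                                                        bases):
        sc = synth_scene("beads", 64, 0.3, seed=8, n_channels=1)
        sc = Scene(sc.image, np.zeros((64, 64)))
        pair = make_training_pair(sc, model_coarse, bases)
        direct = forward_lowrank(sc, bases[0.0])
        np.testing.assert_allclose(pair.input, direct.image, atol=1e-12)

    def test_seed_reproducibility(self, model_coarse, bases):
        sc = synth_scene("mixed", 64, 0.1, seed=9, n_channels=1)
        p1 = make_training_pair(sc, model_coarse, bases,
                                noise={"gain": 50.0, "read_sigma": 0.01},
                                seed=3)
        p2 = make_training_pair(sc, model_coarse, bases,
                                noise={"gain": 50.0, "read_sigma": 0.01},
                                seed=3)
        np.testing.assert_array_equal(p1.input, p2.input)
        np.testing.assert_array_equal(p1.label, p2.label)

    def test_capture_less_sharp_than_label(self, model_coarse, bases):
        """Pipeline smoke check: the coded capture has lower Laplacian
        energy than the fused all-in-focus label."""
        from scipy.ndimage import laplace
        sc = synth_scene("mixed", 64, 0.2, seed=10, n_channels=1)
        pair = make_training_pair(sc, model_coarse, bases)
        e_in = np.sum(laplace(pair.input[0]) ** 2)
        e_lb = np.sum(laplace(pair.label[0]) ** 2)
        assert e_in < e_lb


class TestPatchify:
    def _pair(self, h, w):
        return TrainingPair(np.zeros((3, h, w)), np.zeros((3, h, w)),
                            np.zeros((h, w), dtype=int))

    def test_standard_crop_protocol(self):
        pair = self._pair(2160, 2560)
        patches = patchify(pair, n_patches=20, size=512, seed=0)
        assert len(patches) == 20
        for inp, lbl in patches:
            assert inp.shape == (3, 512, 512)
            assert lbl.shape == (3, 512, 512)
        assert len(pair.patches) == 20
        for rec in pair.patches:
            assert 0 <= rec["y"] <= 2160 - 512
            assert 0 <= rec["x"] <= 2560 - 512

    def test_exact_size_corner_zero(self):
        pair = self._pair(512, 512)
        patchify(pair, n_patches=3, size=512, seed=1)
        assert all(r["y"] == 0 and r["x"] == 0 for r in pair.patches)

    def test_seed_reproducible_corners(self):
        p1, p2 = self._pair(600, 600), self._pair(600, 600)
        patchify(p1, 5, 128, seed=4)
        patchify(p2, 5, 128, seed=4)
        assert p1.patches == p2.patches

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            patchify(self._pair(100, 100), 2, 128, seed=0)
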