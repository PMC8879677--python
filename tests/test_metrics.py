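"""Dice/Hausdorff/Chamfer oracles and the Laplace-spectrum distance."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from spineforge import metrics as M
from spineforge.errors import MetricError, ParameterError
from spineforge.phantoms import make_vertebra_phantom


def brute_force_hausdorff(a, b):
    sa = M._surface_voxels(a).astype(float)
    sb = M._surface_voxels(b).astype(float)
    d = cdist(sa, sb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((6, 6, 6)) > 0.5
        assert M.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert M.dice(a, b) == 0.0

    def test_half_overlapping_cubes(self):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[2:4, 2:4, 2:4] = True
        b[3:5, 2:4, 2:4] = True
        assert M.dice(a, b) == 0.5

    def test_both_empty_undefined(self):
        with pytest.raises(MetricError):
            M.dice(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool))


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = rng.random((6, 6, 6)) > 0.4
        assert M.hausdorff(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        assert M.hausdorff(a, b) == pytest.approx(5.0)

    def test_symmetric_and_matches_brute_force(self, rng):
        a = rng.random((10, 10, 10)) > 0.6
        b = rng.random((10, 10, 10)) > 0.6
        h = M.hausdorff(a, b)
        assert h == M.hausdorff(b, a)
        assert h == pytest.approx(brute_force_hausdorff(a, b))

    def test_empty_mask_undefined(self):
        with pytest.raises(MetricError):
            M.hausdorff(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestPointCloudChamfer:
    def test_default_count_and_determinism(self, rng):
        m = rng.random((8, 8, 8)) > 0.5
        c1 = M.sample_point_cloud(m, seed=3)
        c2 = M.sample_point_cloud(m, seed=3)
        assert c1.shape == (2048, 3)
        np.testing.assert_array_equal(c1, c2)

    def test_points_lie_on_surface(self, rng):
        m = rng.random((8, 8, 8)) > 0.5
        surf = {tuple(v) for v in M._surface_voxels(m)}
        cloud = M.sample_point_cloud(m, n_points=100, seed=0)
        assert all(tuple(p.astype(int)) in surf for p in cloud)

    def test_chamfer_identical_and_offset(self):
        c = np.array([[0.0, 0, 0], [1, 1, 1]])
        np.testing.assert_array_equal(M.chamfer_map(c, c), [0, 0])
        assert M.chamfer_map(np.array([[0.0, 0, 0]]),
                             np.array([[3.0, 0, 0]]))[0] == pytest.approx(9.0)

    def test_kdtree_matches_brute_force(self, rng):
        a = rng.random((50, 3)) * 10
        b = rng.random((40, 3)) * 10
        ref = (cdist(a, b).min(axis=1)) ** 2
        np.testing.assert_allclose(M.chamfer_map(a, b), ref, rtol=1e-12)

    def test_empty_inputs(self):
        with pytest.raises(MetricError):
            M.chamfer_map(np.empty((0, 3)), np.ones((2, 3)))
        with pytest.raises(MetricError):
            M.sample_point_cloud(np.zeros((3, 3, 3), bool))


class TestLaplaceSpectrum:
    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_box_matches_closed_form(self, n):
        box = np.zeros((n + 2,) * 3, bool)
        box[1:n + 1, 1:n + 1, 1:n + 1] = True
        got = M.laplace_spectrum(box, 12).eigenvalues
        ref = M.box_spectrum_closed_form((n, n, n), 12)
        np.testing.assert_allclose(got, ref, atol=1e-8)

    def test_spacing_scales_inverse_square(self):
        box = np.zeros((8, 8, 8), bool)
        box[1:7, 1:7, 1:7] = True
        a = M.laplace_spectrum(box, 5, spacing=1.0).eigenvalues
        b = M.laplace_spectrum(box, 5, spacing=2.0).eigenvalues
        np.testing.assert_allclose(a, 4 * b, rtol=1e-10)

    def test_rigid_rotation_preserves_spectrum(self, small_spec):
        m = make_vertebra_phantom(12, small_spec, 5).mask
        a = M.laplace_spectrum(m, 20).eigenvalues
        b = M.laplace_spectrum(np.rot90(m, axes=(1, 2)), 20).eigenvalues
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_continuum_scaling_law(self):
        # scaling a shape by s scales eigenvalues by 1/s^2; the effective
        # Dirichlet side of an n-voxel box is (n+1)h, so s = 33/17 here
        small = np.zeros((18,) * 3, bool)
        small[1:17, 1:17, 1:17] = True
        big = np.zeros((34,) * 3, bool)
        big[1:33, 1:33, 1:33] = True
        l_small = M.laplace_spectrum(small, 1).eigenvalues[0]
        l_big = M.laplace_spectrum(big, 1).eigenvalues[0]
        s2 = (33.0 / 17.0) ** 2
        assert abs(l_small / l_big - s2) / s2 < 0.05

    def test_too_many_eigenvalues_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        with pytest.raises(ParameterError):
            M.laplace_spectrum(m, 100)
        with pytest.raises(MetricError):
            M.laplace_spectrum(np.zeros((3, 3, 3), bool), 1)


class TestWESD:
    def test_identical_spectra_zero(self):
        s = M.SpectrumResult(np.array([1.0, 2.0, 3.0]), 1.0)
        assert M.wesd(s, s) == 0.0

    def test_single_term_hand_value(self):
        a = M.SpectrumResult(np.array([1.0]), 1.0)
        b = M.SpectrumResult(np.array([2.0]), 1.0)
        assert M.wesd(a, b, p=2.0) == pytest.approx(0.5)  # |1-2|/(1*2)

    def test_symmetry(self, rng):
        a = M.SpectrumResult(np.sort(rng.random(10)) + 0.5, 1.0)
        b = M.SpectrumResult(np.sort(rng.random(10)) + 0.5, 1.0)
        assert M.wesd(a, b) == M.wesd(b, a)

    def test_parameter_validation(self):
        a = M.SpectrumResult(np.array([1.0]), 1.0)
        b = M.SpectrumResult(np.array([1.0, 2.0]), 1.0)
        with pytest.raises(ParameterError):
            M.wesd(a, a, p=1.0)  # p must exceed d/2 = 1.5
        with pytest.raises(ParameterError):
            M.wesd(a, b)


class TestNWESD:
    def test_identical_masks_zero(self, small_spec):
        m = make_vertebra_phantom(10, small_spec, 1).mask
        assert M.nwesd(m, m, 20) == 0.0

    def test_bounded_in_unit_interval(self, small_spec):
        a = make_vertebra_phantom(8, small_spec, 1).mask
        b = make_vertebra_phantom(24, small_spec, 1).mask
        v = M.nwesd(a, b, 30)
        assert 0 <= v < 1

    def test_rigid_rotation_invariance(self, small_spec):
        m = make_vertebra_phantom(14, small_spec, 2).mask
        assert M.nwesd(m, np.rot90(m, axes=(0, 1)), 30) < 1e-9

    def test_single_voxel_perturbation_is_small(self):
        cube = np.zeros((14,) * 3, bool)
        cube[1:13, 1:13, 1:13] = True
        bumped = cube.copy()
        bumped[0, 6, 6] = True
        assert M.nwesd(cube, bumped, 30) < 0.05


def test_evaluate_masks_report(small_spec):
    a = make_vertebra_phantom(9, small_spec, 0).mask
    vol_a = np.where(a, 9, 0)
    b = np.roll(vol_a, 1, axis=0)
    df = M.evaluate_masks(b, vol_a, n_eigenvalues=20)
    assert list(df.columns) == ["label", "dice", "hausdorff_mm", "nwesd"]
    row = df.iloc[0]
    assert row.label == 9 and 0 < row.dice < 1 and row.hausdorff_mm >= 1.0
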