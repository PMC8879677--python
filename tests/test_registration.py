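"""Affine matrices, displacement fields, warping, and losses."""

import numpy as np
import pytest

from spineforge.registration import (AffineParams, affine_to_field,
                                     build_affine_matrix, compose_fields,
                                     l1_shape_loss, smoothness_penalty,
                                     total_loss, warp)


def brute_force_warp(template, matrix, center):
    """Independent per-voxel pull-back oracle with its own trilinear sampler."""
    out = np.zeros_like(template, dtype=float)
    m3 = matrix[:3, :3]
    for idx in np.ndindex(template.shape):
        src = m3 @ (np.asarray(idx, float) - center) + center
        i0 = np.floor(src).astype(int)
        f = src - i0
        val = 0.0
        for off in np.ndindex(2, 2, 2):
            j = i0 + off
            if all(0 <= j[d] < template.shape[d] for d in range(3)):
                wgt = np.prod([f[d] if off[d] else 1 - f[d] for d in range(3)])
                val += wgt * template[tuple(j)]
        out[idx] = val
    return out >= 0.5


class TestAffineMatrix:
    def test_identity(self):
        np.testing.assert_array_equal(
            build_affine_matrix(AffineParams(0, 0, 0, 1)), np.eye(4))

    def test_z_rotation_quarter_turn(self):
        m = build_affine_matrix(AffineParams(0, 0, np.pi / 2, 1))
        np.testing.assert_allclose(m @ [1, 0, 0, 1], [0, 1, 0, 1], atol=1e-12)

    def test_pure_scale(self):
        np.testing.assert_allclose(build_affine_matrix(AffineParams(0, 0, 0, 2)),
                                   np.diag([2.0, 2, 2, 1]))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            AffineParams(0, 0, 0, -1.0)

    def test_rotation_block_orthonormal_for_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t = rng.uniform(-np.pi, np.pi, 3)
            m = build_affine_matrix(AffineParams(*t, 1.0))
            r = m[:3, :3]
            assert np.abs(r.T @ r - np.eye(3)).max() < 1e-12
            assert abs(np.linalg.det(r) - 1) < 1e-12


class TestField:
    def test_identity_matrix_gives_zero_field(self):
        f = affine_to_field(np.eye(4), (8, 8, 8))
        assert np.all(f == 0)

    def test_scale_displacement_at_known_point(self):
        f = affine_to_field(np.diag([2.0, 2, 2, 1]), (9, 9, 9))
        # center (4,4,4); at center + (3,0,0): u = 2*3 - 3 = 3
        np.testing.assert_allclose(f[:, 7, 4, 4], [3, 0, 0], atol=1e-12)

    def test_magnitude_linear_in_offset(self):
        m = build_affine_matrix(AffineParams(0.2, -0.1, 0.3, 1.2))
        f = affine_to_field(m, (17, 17, 17))
        c = 8
        r1 = np.linalg.norm(f[:, c + 2, c, c])
        r2 = np.linalg.norm(f[:, c + 4, c, c])
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-9)

    def test_compose_identity_inverse_commutative(self, rng):
        a = rng.standard_normal((3, 4, 4, 4))
        b = rng.standard_normal((3, 4, 4, 4))
        np.testing.assert_array_equal(compose_fields(a, np.zeros_like(a)), a)
        assert np.all(compose_fields(a, -a) == 0)
        np.testing.assert_array_equal(compose_fields(a, b), compose_fields(b, a))

    def test_compose_grid_mismatch(self, rng):
        with pytest.raises(ValueError):
            compose_fields(np.zeros((3, 4, 4, 4)), np.zeros((3, 5, 4, 4)))


class TestWarp:
    def test_zero_field_returns_template(self, rng):
        tpl = rng.random((6, 6, 6)) > 0.5
        out = warp(tpl.astype(float), np.zeros((3, 6, 6, 6)))
        np.testing.assert_array_equal(out.astype(bool), tpl)

    def test_quarter_turn_matches_array_rotation(self, rng):
        # odd grid: rotation about the center voxel permutes voxels exactly
        tpl = np.zeros((17, 17, 17))
        tpl[4:13, 5:12, 6:11] = (rng.random((9, 7, 5)) > 0.3).astype(float)
        m = build_affine_matrix(AffineParams(0, 0, np.pi / 2, 1))
        fld = affine_to_field(np.linalg.inv(m), tpl.shape, center=np.full(3, 8.0))
        out = warp(tpl, fld).astype(bool)
        np.testing.assert_array_equal(out, np.rot90(tpl.astype(bool), k=1,
                                                    axes=(0, 1)))

    def test_constant_field_shifts_opposite_sampling(self, rng):
        tpl = rng.random((8, 8, 8))
        fld = np.zeros((3, 8, 8, 8))
        fld[0] = 1.0
        out = warp(tpl, fld, soft=True)
        np.testing.assert_allclose(out[:7], tpl[1:], atol=1e-12)

    def test_label_multiplication_after_threshold(self):
        tpl = np.ones((4, 4, 4))
        out = warp(tpl, np.zeros((3, 4, 4, 4)), label=20)
        assert set(np.unique(out)) == {20}

    def test_oracle_equivalence_random_params(self, rng):
        tpl = np.zeros((16, 16, 16))
        tpl[4:12, 5:11, 4:11] = 1.0
        center = np.full(3, 8.0)
        for _ in range(5):
            p = AffineParams(*rng.uniform(-np.pi / 6, np.pi / 6, 3),
                             rng.uniform(0.7, 1.4))
            m = build_affine_matrix(p)
            out = warp(tpl, affine_to_field(m, tpl.shape, center=center)).astype(bool)
            ref = brute_force_warp(tpl, m, center)
            assert (out == ref).mean() >= 0.99

    def test_scale_changes_volume_cubically(self):
        tpl = np.zeros((32, 32, 32))
        tpl[10:22, 11:21, 12:20] = 1.0
        m = build_affine_matrix(AffineParams(0, 0, 0, 1.0 / 1.2))  # pull-back: grows
        out = warp(tpl, affine_to_field(m, tpl.shape))
        ratio = out.sum() / tpl.sum()
        assert abs(ratio - 1.2 ** 3) / 1.2 ** 3 < 0.1


class TestLosses:
    def test_l1_zero_for_equal(self, rng):
        x = rng.random((5, 5, 5))
        assert l1_shape_loss(x, x) == 0.0

    def test_l1_label_magnitude(self):
        assert l1_shape_loss(np.zeros((4, 4, 4)), np.full((4, 4, 4), 20)) == 20.0

    def test_l1_symmetric(self, rng):
        a, b = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        assert l1_shape_loss(a, b) == l1_shape_loss(b, a)

    def test_smoothness_examples(self):
        assert smoothness_penalty(np.zeros((3, 4, 4, 4))) == 0.0
        f = np.zeros((3, 4, 4, 4))
        f[0] = 1.0
        assert smoothness_penalty(f) == 1.0
        assert smoothness_penalty(np.ones((3, 4, 4, 4))) == 3.0

    def test_total_loss_weights(self):
        t = np.full((4, 4, 4), 1.0)
        zero_field = np.zeros((3, 4, 4, 4))
        assert total_loss(t, t, zero_field) == 0.0
        # L_l1 = 1, L_smooth = 0 -> 10
        assert total_loss(np.zeros_like(t), t, zero_field) == pytest.approx(10.0)
        # L_l1 = 0, L_smooth = 2 -> 0.2
        f = np.zeros((3, 4, 4, 4))
        f[0] = 2.0
        assert total_loss(t, t, f) == pytest.approx(0.2)

    def test_negative_weights_rejected(self):
        t = np.zeros((2, 2, 2))
        with pytest.raises(ValueError):
            total_loss(t, t, np.zeros((3, 2, 2, 2)), alpha_p=-1)

    def test_total_loss_zero_iff_perfect(self, rng):
        t = (rng.random((4, 4, 4)) > 0.5) * 9.0
        f = np.zeros((3, 4, 4, 4))
        assert total_loss(t, t, f) == 0.0
        f[1, 0, 0, 0] = 0.1
        assert total_loss(t, t, f) > 0.0


def test_field_nifti_roundtrip(tmp_path, rng):
    from spineforge.registration import load_field_nifti, save_field_nifti

    field = rng.standard_normal((3, 6, 6, 6))
    save_field_nifti(field, tmp_path / "field.nii.gz")
    back = load_field_nifti(tmp_path / "field.nii.gz")
    np.testing.assert_allclose(back, field, atol=1e-6)
    with pytest.raises(ValueError):
        save_field_nifti(np.zeros((2, 4, 4, 4)), tmp_path / "bad.nii.gz")
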