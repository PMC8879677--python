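"""Network contracts: encoders, SE fusion, decoders, identity initialization."""

import numpy as np
import pytest

from spineforge.autodiff import Tensor
from spineforge.errors import BatchContractError, ConfigError
from spineforge.model import ModelConfig, SpineRegistrationModel
from spineforge.nn import SEBlock, se_fuse
from spineforge.phantoms import PhantomSpec
from spineforge.projection import ProjectionGeometry
from spineforge.training import make_dataset


@pytest.fixture(scope="module")
def tiny_data():
    spec = PhantomSpec(n_vertebrae=3, grid_size=32, body_radius_range=(5.0, 8.0),
                       process_length_range=(6.0, 9.0), seed=0)
    samples, atlas = make_dataset(1, spec, ProjectionGeometry(), seed=2)
    return samples[0], atlas


@pytest.fixture(scope="module")
def tiny_config():
    return ModelConfig(patch_size=32, out_size=32, n_batch_vertebrae=3, seed=0)


class TestConfig:
    def test_incompatible_sizes_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(patch_size=48)
        with pytest.raises(ConfigError):
            ModelConfig(mlp_widths=(0,))

    def test_roundtrip_dict(self, tiny_config):
        assert ModelConfig.from_dict(tiny_config.to_dict()) == tiny_config


class TestSEFusion:
    def test_saturated_gate_passes_input_through(self, rng):
        se = SEBlock(4, 2, rng)
        se.fc2.bias.data[:] = 30.0  # sigmoid ~ 1: gating identity
        x = Tensor(rng.standard_normal((2, 2, 5, 5)).astype(np.float32))
        a = Tensor(rng.standard_normal((2, 2, 5, 5)).astype(np.float32))
        out = se_fuse(x, a, se)
        np.testing.assert_allclose(out.data[:, :2], x.data, atol=1e-5)
        np.testing.assert_allclose(out.data[:, 2:], a.data, atol=1e-5)

    def test_zero_input_zero_output(self, rng):
        se = SEBlock(2, 2, rng)
        z = Tensor(np.zeros((1, 1, 4, 4), np.float32))
        assert np.all(se_fuse(z, z, se).data == 0)

    def test_shape_preserved(self, rng):
        se = SEBlock(6, 3, rng)
        x = Tensor(rng.standard_normal((2, 3, 4, 4)).astype(np.float32))
        assert se_fuse(x, x, se).shape == (2, 6, 4, 4)

    def test_channel_mismatch_rejected(self, rng):
        se = SEBlock(4, 2, rng)
        x = Tensor(np.zeros((1, 3, 4, 4), np.float32))
        with pytest.raises(ValueError):
            se(x)


class TestEncoders:
    def test_views_produce_identical_latent_shapes(self, tiny_config, tiny_data):
        sample, _ = tiny_data
        model = SpineRegistrationModel(tiny_config)
        xs = np.stack([p.xs for p in sample.pairs]).astype(np.float32)
        ys = np.stack([p.ys for p in sample.pairs]).astype(np.float32)
        xc = np.stack([p.xc for p in sample.pairs]).astype(np.float32)
        yc = np.stack([p.yc for p in sample.pairs]).astype(np.float32)
        lat_s, feat_s = model.sagittal_encoder(xs, ys)
        lat_c, feat_c = model.coronal_encoder(xc, yc)
        assert lat_s.shape == lat_c.shape == (3, 8, 8, 8, 8)
        assert feat_s.shape == feat_c.shape

    def test_channel_count_scales_with_config(self, tiny_config):
        big = ModelConfig(**{**tiny_config.to_dict(), "latent_channels": 16,
                             "mlp_widths": (64,)})
        model = SpineRegistrationModel(ModelConfig.from_dict(big.to_dict()))
        x = np.zeros((1, 32, 32), np.float32)
        assert model.sagittal_encoder(x, x)[0].shape[1] == 16

    def test_zero_input_finite_output(self, tiny_config):
        model = SpineRegistrationModel(tiny_config)
        x = np.zeros((2, 32, 32), np.float32)
        out, feat = model.sagittal_encoder(x, x)
        assert np.isfinite(out.data).all() and np.isfinite(feat.data).all()

    def test_wrong_patch_size_rejected(self, tiny_config):
        model = SpineRegistrationModel(tiny_config)
        with pytest.raises(ValueError):
            model.sagittal_encoder(np.zeros((1, 16, 16), np.float32),
                                   np.zeros((1, 16, 16), np.float32))


class TestForward:
    def test_identity_at_initialization(self, tiny_config, tiny_data):
        sample, atlas = tiny_data
        model = SpineRegistrationModel(tiny_config)
        out = model.forward(sample.pairs, sample.centroids_mm, atlas)
        assert len(out.soft_shapes) == len(sample.pairs)
        for soft, lab in zip(out.soft_shapes, out.labels):
            np.testing.assert_array_equal(
                soft.data, atlas.template_for(lab).astype(np.float32))
        np.testing.assert_allclose(out.params_float(),
                                   np.tile([0, 0, 0, 1], (3, 1)))

    def test_affine_params_bounded(self, tiny_config, tiny_data, rng):
        sample, atlas = tiny_data
        model = SpineRegistrationModel(tiny_config)
        # randomize the affine head: outputs must stay in the declared ranges
        model.affine_decoder.head.weight.data[:] = rng.standard_normal(
            model.affine_decoder.head.weight.shape).astype(np.float32)
        out = model.forward(sample.pairs, sample.centroids_mm, atlas)
        p = out.params_float()
        assert np.all(np.abs(p[:, :3]) <= np.pi / 4 + 1e-6)
        assert np.all((p[:, 3] >= 0.5) & (p[:, 3] <= 2.0))

    def test_unsorted_batch_rejected(self, tiny_config, tiny_data):
        sample, atlas = tiny_data
        model = SpineRegistrationModel(tiny_config)
        with pytest.raises(BatchContractError):
            model.forward(sample.pairs[::-1], sample.centroids_mm[::-1], atlas)

    def test_oversized_batch_rejected(self, tiny_config, tiny_data):
        sample, atlas = tiny_data
        model = SpineRegistrationModel(tiny_config)
        with pytest.raises(BatchContractError):
            model.forward(sample.pairs * 2, np.tile(sample.centroids_mm, (2, 1)),
                          atlas)

    def test_variant_fields(self, tiny_config, tiny_data):
        sample, atlas = tiny_data
        model = SpineRegistrationModel(tiny_config)
        aff = model.forward(sample.pairs, sample.centroids_mm, atlas,
                            variant="affine_only")
        assert aff.deformable_fields is None
        assert all(f is not None for f in aff.affine_fields)
        dfm = model.forward(sample.pairs, sample.centroids_mm, atlas,
                            variant="deformable_only")
        assert all(f is None for f in dfm.affine_fields)
        assert dfm.deformable_fields.shape == (3, 3, 32, 32, 32)
        with pytest.raises(ConfigError):
            model.forward(sample.pairs, sample.centroids_mm, atlas, variant="x")

    def test_deformable_fields_item_independent(self, tiny_config, tiny_data):
        # perturbing vertebra 2's patch must not change vertebra 1's field
        sample, atlas = tiny_data
        model = SpineRegistrationModel(tiny_config)
        base = model.forward(sample.pairs, sample.centroids_mm, atlas,
                             variant="deformable_only")
        import copy
        pairs2 = copy.deepcopy(sample.pairs)
        pairs2[2].xs += 10.0
        pert = model.forward(pairs2, sample.centroids_mm, atlas,
                             variant="deformable_only")
        np.testing.assert_array_equal(base.deformable_fields.data[0],
                                      pert.deformable_fields.data[0])


class TestReproducibility:
    def test_same_seed_bitwise_equal_parameters(self, tiny_config):
        a = SpineRegistrationModel(tiny_config)
        b = SpineRegistrationModel(tiny_config)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seed_differs(self, tiny_config):
        other = ModelConfig.from_dict({**tiny_config.to_dict(), "seed": 5})
        a = SpineRegistrationModel(tiny_config)
        b = SpineRegistrationModel(other)
        assert any(not np.array_equal(pa.data, pb.data)
                   for pa, pb in zip(a.parameters(), b.parameters()))

    def test_save_load_roundtrip(self, tiny_config, tmp_path):
        model = SpineRegistrationModel(tiny_config)
        model.save(tmp_path / "ckpt")
        loaded = SpineRegistrationModel.load(tmp_path / "ckpt")
        assert loaded.config == model.config
        for pa, pb in zip(model.parameters(), loaded.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
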