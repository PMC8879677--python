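"""The 2D-to-3D registration network.

Two view-specific encoders lift sagittal/coronal patches (image + VOI
annotation, combined by squeeze-and-excitation gating) into co-registered 3D
latent grids; the missing dimension of each view is expanded by a learned
per-pixel projection followed by an anisotropic convolution whose long kernel
axis runs along the expanded direction (left-right for sagittal,
anterior-posterior for coronal).  Two decoders turn the fused latent into a
displacement field:

* an affine decoder — an MLP over the whole spine batch (features, downscaled
  templates, normalized centroids and labels of *all* vertebrae concatenated)
  predicting per-vertebra rotations (bounded to +/- pi/4) and an isotropic
  scale in [1/2, 2]; no translation, since the centroid sits at a fixed patch
  pixel;
* a fully-convolutional deformable decoder producing a free-form per-voxel
  field for each vertebra independently (weights shared, no intra-batch
  mixing).

Both output heads are zero-initialized, so an untrained model reproduces the
template atlas exactly (identity transform at step 0).  All vertebrae of one
spine run through the convolutional stages as one batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import DTYPE, Tensor, concat, stack, upsample_nearest3d, warp3d
from .errors import BatchContractError, ConfigError
from .nn import Adam, Conv2d, Conv3d, Linear, Module, SEBlock, se_fuse
from .phantoms import LABEL_MAX, LABEL_MIN, TemplateAtlas

CENTROID_SCALE_MM = 100.0


@dataclass(frozen=True)
class ModelConfig:
    patch_size: int = 64
    out_size: int = 64
    base_channels: int = 16
    latent_channels: int = 8
    latent_grid: int = 8
    se_reduction: int = 4
    mlp_widths: tuple[int, ...] = (256, 128)
    n_batch_vertebrae: int = 17
    affine_channels: int = 4
    field_gain: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("patch_size", "out_size"):
            v = getattr(self, name)
            ratio = v / self.latent_grid
            if v <= 0 or ratio < 1 or 2 ** int(np.log2(ratio)) != int(ratio):
                raise ConfigError(f"{name}={v} must be latent_grid * power of two")
        if any(w <= 0 for w in self.mlp_widths):
            raise ConfigError("mlp widths must be positive")
        if self.n_batch_vertebrae < 1:
            raise ConfigError("n_batch_vertebrae must be >= 1")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["mlp_widths"] = list(self.mlp_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "mlp_widths" in d:
            d["mlp_widths"] = tuple(d["mlp_widths"])
        return cls(**d)


@dataclass
class ModelOutput:
    soft_shapes: list[Tensor]          # per-vertebra real-valued warped templates
    affine_params: list[tuple[Tensor, Tensor, Tensor, Tensor]]
    affine_fields: list[Tensor | None]
    deformable_fields: Tensor | None   # batched (n, 3, X, Y, Z)
    labels: list[int]

    def params_float(self) -> np.ndarray:
        """(n, 4) array of (theta_x, theta_y, theta_z, S)."""
        return np.array([[float(t.data) for t in p] for p in self.affine_params])


class _ViewEncoder(Module):
    def __init__(self, cfg: ModelConfig, view: str, rng: np.random.Generator):
        c = cfg.base_channels
        self.view = view
        self.img_stem = Conv2d(1, c, 3, rng, pad=1)
        self.ann_stem = Conv2d(1, c, 3, rng, pad=1)
        self.se = SEBlock(2 * c, cfg.se_reduction, rng)
        n_down = int(np.log2(cfg.patch_size // cfg.latent_grid))
        self.downs = [Conv2d(2 * c, 2 * c, 3, rng, stride=2, pad=1)
                      for _ in range(n_down)]
        self.expand = Conv2d(2 * c, cfg.latent_channels * cfg.latent_grid, 1, rng)
        # long kernel axis along the expanded dimension (x for sagittal, y coronal)
        kernel = (5, 1, 1) if view == "sagittal" else (1, 5, 1)
        pads = (2, 0, 0) if view == "sagittal" else (0, 2, 0)
        self.aniso = Conv3d(cfg.latent_channels, cfg.latent_channels, kernel, rng,
                            pad=pads)
        self.cfg = cfg

    def __call__(self, patches: np.ndarray,
                 annotations: np.ndarray) -> tuple[Tensor, Tensor]:
        """patches/annotations: (B, patch, patch) arrays.

        Returns the co-registered 3D latent (B, Cl, g, g, g) and the
        pre-expansion 2D feature grid (B, 2C, g, g) — the latter feeds the
        affine decoder, which flattens encoder features directly.
        """
        cfg = self.cfg
        if patches.shape[1:] != (cfg.patch_size,) * 2:
            raise ValueError(
                f"expected {cfg.patch_size}x{cfg.patch_size} inputs, got "
                f"{patches.shape[1:]}")
        fi = self.img_stem(Tensor(patches[:, None])).leaky_relu()
        fa = self.ann_stem(Tensor(annotations[:, None])).leaky_relu()
        f = se_fuse(fi, fa, self.se)
        affine_feat = None
        for down in self.downs:
            f = down(f).leaky_relu()
            if affine_feat is None:
                affine_feat = f  # first downsampled grid: keeps in-plane detail
        if affine_feat is None:
            affine_feat = f
        e = self.expand(f)  # (B, Cl*g, g, g): image rows=z, cols=(y|x)
        g = cfg.latent_grid
        nb = patches.shape[0]
        e = e.reshape(nb, cfg.latent_channels, g, g, g)  # (B, Cl, expand, z', inplane)
        if self.view == "sagittal":
            lat = e.transpose((0, 1, 2, 4, 3))       # (B, Cl, x, y, z)
        else:
            lat = e.transpose((0, 1, 4, 2, 3))       # (B, Cl, x, y, z)
        return self.aniso(lat).leaky_relu(), affine_feat


class _DeformableDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        cl = 2 * cfg.latent_channels + 1  # fused views + template channel
        n_up = int(np.log2(cfg.out_size // cfg.latent_grid))
        # channels shrink toward full resolution: the field is smooth there
        chans = [cfg.base_channels] + [max(cfg.base_channels // 4, 4)] * n_up
        self.head_in = Conv3d(cl, chans[0], 3, rng, pad=1)
        self.ups = [Conv3d(chans[i], chans[i + 1], 3, rng, pad=1)
                    for i in range(n_up)]
        self.head_out = Conv3d(chans[-1], 3, 1, rng, zero_init=True)
        self.gain = cfg.field_gain

    def __call__(self, fused: Tensor, templates_ds: np.ndarray) -> Tensor:
        x = concat([fused, Tensor(templates_ds[:, None])], axis=1)
        x = self.head_in(x).leaky_relu()
        for up in self.ups:
            x = upsample_nearest3d(x, 2)
            x = up(x).leaky_relu()
        return self.head_out(x) * self.gain


class _AffineDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        # one channel-reducing conv per view over the encoders' 2D features;
        # in-plane positions (the signed axial-rotation cue) stay unmixed
        self.reduce_sag = Conv2d(2 * cfg.base_channels, cfg.affine_channels, 3,
                                 rng, pad=1)
        self.reduce_cor = Conv2d(2 * cfg.base_channels, cfg.affine_channels, 3,
                                 rng, pad=1)
        g2 = cfg.latent_grid // 2
        feat_grid = max(cfg.patch_size // 2, cfg.latent_grid)
        self.feat_dim = (2 * cfg.affine_channels * feat_grid ** 2
                         + g2 ** 3 + 3 + 1 + 1)
        dims = [cfg.n_batch_vertebrae * self.feat_dim, *cfg.mlp_widths]
        self.hidden = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.head = Linear(dims[-1], cfg.n_batch_vertebrae * 4, rng, zero_init=True)
        self.cfg = cfg

    def __call__(self, feat_sag: Tensor, feat_cor: Tensor,
                 extras: np.ndarray) -> list[tuple[Tensor, ...]]:
        """feat_*: (B, 2C, g, g) encoder features; extras: per-vertebra
        (template + centroid + label + presence) vector."""
        cfg = self.cfg
        nb = feat_sag.shape[0]
        red_s = self.reduce_sag(feat_sag).leaky_relu().reshape(nb, -1)
        red_c = self.reduce_cor(feat_cor).leaky_relu().reshape(nb, -1)
        per_vert = concat([red_s, red_c, Tensor(extras)], axis=1)  # (B, feat_dim)
        pad = cfg.n_batch_vertebrae - nb
        if pad:
            per_vert = concat(
                [per_vert, Tensor(np.zeros((pad, self.feat_dim), dtype=DTYPE))], axis=0)
        x = per_vert.reshape(1, cfg.n_batch_vertebrae * self.feat_dim)
        for lin in self.hidden:
            x = lin(x).leaky_relu()
        out = self.head(x).reshape(cfg.n_batch_vertebrae * 4)
        params = []
        quarter_pi = np.pi / 4.0
        ln2 = np.log(2.0)
        for i in range(nb):
            o = out[4 * i:4 * i + 4]
            tx = o[0].tanh() * quarter_pi
            ty = o[1].tanh() * quarter_pi
            tz = o[2].tanh() * quarter_pi
            s = (o[3].tanh() * ln2).exp()  # scale in [1/2, 2], always positive
            params.append((tx, ty, tz, s))
        return params


def _affine_field_tensor(tx: Tensor, ty: Tensor, tz: Tensor, s: Tensor,
                         rel: np.ndarray, shape: tuple,
                         inverse: bool = True) -> Tensor:
    """Differentiable tau: displacement field of the pose R(tx)R(ty)R(tz)T(S)
    about the patch center; ``rel`` is the constant (3, N) grid-offset matrix.

    The warp is a pull-back (the output reads the template at x + u), so
    realizing the *pose* M on the shape requires the field of M^-1 =
    Rz(-tz)Ry(-ty)Rx(-tx)T(1/S); that is the default.  With
    ``inverse=False`` the field of M itself is produced.
    """
    one = Tensor(np.ones(()))
    zero = Tensor(np.zeros(()))
    if inverse:
        tx, ty, tz = -tx, -ty, -tz
    cx, sx = tx.cos(), tx.sin()
    cy, sy = ty.cos(), ty.sin()
    cz, sz = tz.cos(), tz.sin()
    rx = stack([stack([one, zero, zero]), stack([zero, cx, -sx]),
                stack([zero, sx, cx])])
    ry = stack([stack([cy, zero, sy]), stack([zero, one, zero]),
                stack([-sy, zero, cy])])
    rz = stack([stack([cz, -sz, zero]), stack([sz, cz, zero]),
                stack([zero, zero, one])])
    if inverse:
        m = rz.matmul(ry).matmul(rx) * s.recip()
    else:
        m = rx.matmul(ry).matmul(rz) * s
    u = (m - Tensor(np.eye(3))).matmul(Tensor(rel))
    return u.reshape((3, *shape))


class SpineRegistrationModel(Module):
    """Full model: per-view encoders, SE fusion, affine + deformable decoders."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.sagittal_encoder = _ViewEncoder(config, "sagittal", rng)
        self.coronal_encoder = _ViewEncoder(config, "coronal", rng)
        self.affine_decoder = _AffineDecoder(config, rng)
        self.deformable_decoder = _DeformableDecoder(config, rng)
        n = config.out_size
        grid = np.stack(np.meshgrid(*[np.arange(n, dtype=DTYPE)] * 3,
                                    indexing="ij"), axis=0)
        self._rel = (grid - float(n // 2)).reshape(3, -1)
        self._shape3 = (n,) * 3
        self._atlas_cache: dict = {}

    def encode(self, patch_pairs: list) -> tuple[Tensor, Tensor, Tensor]:
        """Both views for all vertebrae -> (fused 3D latent, per-view 2D feats)."""
        xs = np.stack([np.asarray(p.xs, dtype=DTYPE) for p in patch_pairs])
        ys = np.stack([np.asarray(p.ys, dtype=DTYPE) for p in patch_pairs])
        xc = np.stack([np.asarray(p.xc, dtype=DTYPE) for p in patch_pairs])
        yc = np.stack([np.asarray(p.yc, dtype=DTYPE) for p in patch_pairs])
        lat_s, feat_s = self.sagittal_encoder(xs, ys)
        lat_c, feat_c = self.coronal_encoder(xc, yc)
        return concat([lat_s, lat_c], axis=1), feat_s, feat_c

    def forward(self, patch_pairs: list, centroids_mm: np.ndarray,
                atlas: TemplateAtlas, variant: str = "combined") -> ModelOutput:
        if variant not in ("combined", "affine_only", "deformable_only"):
            raise ConfigError(f"unknown variant {variant!r}")
        labels = [p.label for p in patch_pairs]
        if len(labels) > self.config.n_batch_vertebrae:
            raise BatchContractError(
                f"batch of {len(labels)} exceeds n_batch_vertebrae")
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise BatchContractError(
                f"batch labels must be strictly increasing (one spine, "
                f"cranio-caudal order); got {labels}")
        templates, ds_list = [], []
        for lab in labels:
            key = (id(atlas), lab)
            if key not in self._atlas_cache:
                self._atlas_cache[key] = (
                    atlas.template_for(lab).astype(DTYPE),
                    atlas.downscaled_for(lab).astype(DTYPE))
            tpl, ds = self._atlas_cache[key]
            templates.append(tpl)
            ds_list.append(ds)
        templates_ds = np.stack(ds_list)
        centroids_mm = np.asarray(centroids_mm, dtype=float)
        rel_centroids = centroids_mm - centroids_mm.mean(axis=0, keepdims=True)

        fused, feat_s, feat_c = self.encode(patch_pairs)
        if variant != "deformable_only":
            g2 = self.config.latent_grid // 2
            extras = np.stack([np.concatenate([
                _block_mean3(templates_ds[i], self.config.latent_grid // g2).ravel(),
                np.asarray(rel_centroids[i], dtype=float) / CENTROID_SCALE_MM,
                [(labels[i] - LABEL_MIN) / (LABEL_MAX - LABEL_MIN)],
                [1.0],  # presence bit for batch padding
            ]) for i in range(len(labels))]).astype(DTYPE)
            params = self.affine_decoder(feat_s, feat_c, extras)
        else:
            zero = Tensor(np.zeros(()))
            one = Tensor(np.ones(()))
            params = [(zero, zero, zero, one) for _ in labels]

        gd_all = None
        if variant != "affine_only":
            gd_all = self.deformable_decoder(fused, templates_ds)

        soft, ga_list = [], []
        for i in range(len(labels)):
            ga = None
            if variant != "deformable_only":
                tx, ty, tz, s = params[i]
                ga = _affine_field_tensor(tx, ty, tz, s, self._rel, self._shape3)
            if gd_all is not None:
                field = ga + gd_all[i] if ga is not None else gd_all[i]
            else:
                field = ga
            soft.append(warp3d(templates[i], field))
            ga_list.append(ga)
        return ModelOutput(soft_shapes=soft, affine_params=params,
                           affine_fields=ga_list, deformable_fields=gd_all,
                           labels=labels)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        import yaml

        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SpineRegistrationModel":
        import yaml

        path = Path(path)
        config = ModelConfig.from_dict(
            yaml.safe_load(path.with_suffix(".yaml").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.parameters()):
                p.data = data[f"param_{i}"].astype(DTYPE)
        return model


def _block_mean3(volume: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(volume, dtype=float)
    m = volume.shape[0] // factor
    return volume.reshape(m, factor, m, factor, m, factor).mean(axis=(1, 3, 5))


def make_optimizer(model: SpineRegistrationModel, lr: float = 1e-4) -> Adam:
    return Adam(model.parameters(), lr=lr)
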