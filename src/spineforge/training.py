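"""Supervised training on DRR patch pairs, ablation variants, and spine-level
inference with stacking.

The supervision target of each vertebra is the {0, label}-valued crop of the
ground-truth label volume around its centroid; the loss is

    L = alpha_p * mean|y - label * (G o template)| + alpha_s * mean(|Gd|_1)

with alpha_p = 10 and alpha_s = 0.1, minimized with Adam at learning rate
1e-4.  One spine forms one optimization step (the affine decoder fuses the
whole batch).  Variants: ``combined`` uses Ga + Gd, ``affine_only`` drops the
deformable field, ``deformable_only`` drops the affine field.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

import logging

from . import autodiff as ad
from .autodiff import DTYPE, Tensor

log = logging.getLogger("spineforge.training")
from .errors import DataError, DivergenceError
from .metrics import dice
from .model import ModelConfig, SpineRegistrationModel, make_optimizer
from .phantoms import (AffineParams, PhantomSpec, SpinePhantom, TemplateAtlas,
                       build_template_atlas, make_spine_phantom,
                       make_vertebra_phantom)
from .projection import (PatchPair, ProjectionGeometry, extract_patch,
                         make_voi_annotation, patch_pairs_for_spine,
                         project_point, znormalize)

ATLAS_POPULATION_PER_LABEL = 5


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    alpha_p: float = 10.0
    alpha_s: float = 0.1
    epochs: int = 50
    variant: str = "combined"
    split: tuple[int, int] = (5, 1)  # train : val
    folds: int = 5
    patience: int = 10
    restore_best: bool = True  # load the best-val-loss parameters at the end
    log_val: bool = True  # evaluate the validation split every epoch
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.variant not in ("affine_only", "deformable_only", "combined"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.alpha_p < 0 or self.alpha_s < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class SpineSample:
    """One spine's network inputs and supervision."""

    sample_id: str
    pairs: list[PatchPair]
    centroids_mm: np.ndarray          # (n, 3), global spine coordinates
    targets: list[np.ndarray]         # per vertebra, {0, label}-valued crops
    poses: list[AffineParams] | None = None  # ground-truth poses if synthetic

    @property
    def labels(self) -> list[int]:
        return [p.label for p in self.pairs]


@dataclass
class SpineModel:
    """Stacked per-vertebra reconstruction."""

    masks: dict[int, np.ndarray]
    centroids: dict[int, np.ndarray]  # voxel-index coords in assembled volume
    volume: np.ndarray
    spacing: float


def assemble_spine_batch(sample: SpineSample) -> SpineSample:
    """Sort a spine sample's vertebrae by ascending label; reject duplicates."""
    labels = sample.labels
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise DataError(f"duplicate vertebral labels in spine batch: {dup}")
    order = np.argsort(labels)
    return SpineSample(
        sample_id=sample.sample_id,
        pairs=[sample.pairs[i] for i in order],
        centroids_mm=np.asarray(sample.centroids_mm)[order],
        targets=[sample.targets[i] for i in order],
        poses=None if sample.poses is None else [sample.poses[i] for i in order],
    )


def extract_target(spine: SpinePhantom, label: int, out_size: int) -> np.ndarray:
    """{0, label}-valued crop of the label volume around the centroid voxel."""
    c = np.round(spine.centroids[label]).astype(int)
    half = out_size // 2
    out = np.zeros((out_size,) * 3, dtype=np.int16)
    lo = c - half
    hi = lo + out_size
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, spine.labels.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    crop = spine.labels[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        np.where(crop == label, label, 0)
    return out


def build_atlas_for_spec(spec: PhantomSpec, downscale_factor: int,
                         seed: int = 12345) -> TemplateAtlas:
    """Shape-prior atlas from a small canonical population per label."""
    population = []
    for lab in spec.labels:
        for k in range(ATLAS_POPULATION_PER_LABEL):
            population.append(make_vertebra_phantom(
                lab, spec, np.random.default_rng([seed, lab, k])))
    return build_template_atlas(population, spec.grid_size, downscale_factor)


def make_dataset(n_spines: int, spec: PhantomSpec, geometry: ProjectionGeometry,
                 seed: int = 0) -> tuple[list[SpineSample], TemplateAtlas]:
    """Synthetic training corpus: spines -> DRR patch pairs + mask targets."""
    samples = []
    for i in range(n_spines):
        sp = replace(spec, seed=int(zlib.crc32(f"spine:{seed}:{i}".encode()) % 2 ** 31))
        spine = make_spine_phantom(sp)
        pairs = patch_pairs_for_spine(spine, geometry, patch_size=spec.grid_size)
        targets = [extract_target(spine, p.label, spec.grid_size) for p in pairs]
        centroids_mm = np.array([spine.centroids[p.label] for p in pairs]) * spine.spacing
        poses = [spine.poses[p.label] for p in pairs]
        samples.append(assemble_spine_batch(SpineSample(
            sample_id=f"spine{i:04d}", pairs=pairs, centroids_mm=centroids_mm,
            targets=targets, poses=poses)))
    atlas = build_atlas_for_spec(spec, spec.grid_size // 8)
    return samples, atlas


def split_dataset(samples: list[SpineSample], config: TrainConfig
                  ) -> tuple[list[SpineSample], list[SpineSample]]:
    """Deterministic, disjoint, exhaustive train/val split (default 5:1).

    Assignment is a pure function of (sample id, seed): samples are ordered by
    a hash and the first ceil(n * val/(train+val)) become validation.
    """
    tr, va = config.split
    keyed = sorted(samples, key=lambda s: zlib.crc32(
        f"{s.sample_id}:{config.seed}".encode()))
    n_val = max(1, int(np.ceil(len(samples) * va / (tr + va)))) if len(samples) > 1 else 0
    val = keyed[:n_val]
    train = keyed[n_val:]
    return train, val


def fold_assignment(sample_id: str, n_folds: int, seed: int) -> int:
    """Stable fold index for cross-validation."""
    return zlib.crc32(f"fold:{sample_id}:{seed}".encode()) % n_folds


def _spine_loss(model: SpineRegistrationModel, sample: SpineSample,
                atlas: TemplateAtlas, config: TrainConfig):
    out = model.forward(sample.pairs, sample.centroids_mm, atlas,
                        variant=config.variant)
    l1_terms = [
        (soft * float(lab) - Tensor(target.astype(DTYPE))).abs().mean()
        for soft, target, lab in zip(out.soft_shapes, sample.targets, out.labels)]
    l1 = ad.stack(l1_terms).mean()
    loss = l1 * config.alpha_p
    if out.deformable_fields is not None:
        # vertebra-mean of the field-magnitude penalty, batched
        smooth = out.deformable_fields.abs().sum(axis=1).mean()
        loss = loss + smooth * config.alpha_s
    return loss, out


def _val_metrics(model, samples, atlas, config) -> tuple[float, float]:
    """(mean loss, vertebra-mean Dice at 0.5 threshold) over samples."""
    losses, dices = [], []
    for s in samples:
        loss, out = _spine_loss(model, s, atlas, config)
        losses.append(float(loss.data))
        for soft, target in zip(out.soft_shapes, s.targets):
            dices.append(dice(soft.data >= 0.5, target > 0))
    return float(np.mean(losses)), float(np.mean(dices))


def identity_baseline(samples: list[SpineSample], atlas: TemplateAtlas
                      ) -> tuple[float, float]:
    """Loss/Dice of the unwarped templates (what zero-init heads produce)."""
    losses, dices = [], []
    for s in samples:
        for pair, target in zip(s.pairs, s.targets):
            tpl = atlas.template_for(pair.label)
            losses.append(np.abs(tpl * float(pair.label) - target).mean())
            dices.append(dice(tpl, target > 0))
    return float(np.mean(losses)), float(np.mean(dices))


def train(model: SpineRegistrationModel, dataset: list[SpineSample],
          atlas: TemplateAtlas, config: TrainConfig
          ) -> tuple[SpineRegistrationModel, pd.DataFrame]:
    """Minimize the registration loss over the training split.

    Early-stops on validation loss (``config.patience`` epochs) and restores
    the best parameters.  Epoch 0 rows record the pre-update state.  Returns
    the model and a history frame (epoch, split, loss, dice).
    """
    if not dataset:
        raise DataError("empty dataset")
    train_set, val_set = split_dataset(dataset, config)
    if not train_set:
        train_set, val_set = dataset, dataset
    if not val_set:
        val_set = train_set
    opt = make_optimizer(model, lr=config.learning_rate)
    history: list[dict] = []

    def log_eval(epoch: int):
        tr_loss, tr_dice = _val_metrics(model, train_set, atlas, config)
        va_loss, va_dice = _val_metrics(model, val_set, atlas, config)
        history.append({"epoch": epoch, "split": "train", "loss": tr_loss,
                        "dice": tr_dice})
        history.append({"epoch": epoch, "split": "val", "loss": va_loss,
                        "dice": va_dice})
        return va_loss

    best_loss = log_eval(0)
    best_params = [p.data.copy() for p in model.parameters()]
    stale = 0
    step = 0
    for epoch in range(1, config.epochs + 1):
        order = np.random.default_rng([config.seed, epoch]).permutation(len(train_set))
        ep_losses = []
        for idx in order:
            loss, _ = _spine_loss(model, train_set[idx], atlas, config)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at step {step}")
            model.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
            log.debug("step %d spine %s loss %.6f", step,
                      train_set[idx].sample_id, float(loss.data))
            step += 1
        history.append({"epoch": epoch, "split": "train",
                        "loss": float(np.mean(ep_losses)), "dice": np.nan})
        need_val = (config.log_val or config.restore_best
                    or config.patience <= config.epochs
                    or epoch == config.epochs)
        if not need_val:
            continue
        va_loss, va_dice = _val_metrics(model, val_set, atlas, config)
        history.append({"epoch": epoch, "split": "val", "loss": va_loss,
                        "dice": va_dice})
        if va_loss < best_loss - 1e-9:
            best_loss = va_loss
            best_params = [p.data.copy() for p in model.parameters()]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if config.restore_best:
        for p, best in zip(model.parameters(), best_params):
            p.data = best
    return model, pd.DataFrame(history, columns=["epoch", "split", "loss", "dice"])


# ---------------------------------------------------------------------------
# inference

def infer_spine(model: SpineRegistrationModel, sagittal_image: np.ndarray,
                coronal_image: np.ndarray, centroid_table: dict[int, np.ndarray],
                atlas: TemplateAtlas, *, spacing: float = 1.0,
                geometry: ProjectionGeometry | None = None,
                volume_shape: tuple | None = None) -> SpineModel:
    """Reconstruct a 3D spine from two orthogonal views + 3D centroids.

    ``centroid_table`` maps label -> 3D centroid in voxel-index coordinates of
    the (possibly virtual) volume grid.  With ``geometry`` given, centroids
    are projected to pixels through it; otherwise the views are assumed
    axis-aligned 1:1 projections (pixel = dropped-axis coordinate).
    """
    if not centroid_table:
        raise DataError("empty centroid table")
    labels = sorted(centroid_table)
    size = model.config.patch_size
    half = size // 2
    pairs = []
    for lab in labels:
        c3 = np.asarray(centroid_table[lab], dtype=float)
        patches = {}
        for view, img in (("sagittal", sagittal_image), ("coronal", coronal_image)):
            if geometry is not None and volume_shape is not None:
                cpx = project_point(c3, volume_shape, spacing, geometry, view)
            else:
                axes = {"sagittal": (2, 1), "coronal": (2, 0)}[view]
                cpx = np.array([c3[axes[0]], c3[axes[1]]])
            cpx = np.round(cpx)
            patch = znormalize(extract_patch(np.asarray(img, dtype=float), cpx, size))
            ann = make_voi_annotation(np.array([half, half], dtype=float), 1.0,
                                      1.0, (size, size)).pixels.astype(float)
            patches[view] = (patch, ann)
        pairs.append(PatchPair(xs=patches["sagittal"][0], xc=patches["coronal"][0],
                               ys=patches["sagittal"][1], yc=patches["coronal"][1],
                               label=lab, centroid_global=c3))
    centroids_mm = np.array([centroid_table[l] for l in labels]) * spacing
    out = model.forward(pairs, centroids_mm, atlas, variant="combined")

    masks = {lab: (soft.data >= 0.5) for lab, soft in zip(labels, out.soft_shapes)}
    return stack_spine(masks, centroid_table, spacing,
                       out_size=model.config.out_size)


def stack_spine(masks: dict[int, np.ndarray], centroid_table: dict[int, np.ndarray],
                spacing: float, out_size: int) -> SpineModel:
    """Place per-vertebra masks at their 3D centroids; higher label wins overlap."""
    labels = sorted(masks)
    half = out_size // 2
    cents = np.array([np.round(centroid_table[l]).astype(int) for l in labels])
    origin = cents.min(axis=0) - half
    extent = cents.max(axis=0) + half + 1 - origin
    volume = np.zeros(tuple(extent), dtype=np.int16)
    centroids_out = {}
    for lab, c in zip(labels, cents):
        lo = c - half - origin
        region = (slice(lo[0], lo[0] + out_size), slice(lo[1], lo[1] + out_size),
                  slice(lo[2], lo[2] + out_size))
        patch = volume[region]
        patch[masks[lab] & (patch < lab)] = lab
        centroids_out[lab] = (c - origin).astype(float)
    return SpineModel(masks=masks, centroids=centroids_out, volume=volume,
                      spacing=spacing)
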