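"""Differentiable-geometry primitives: affine matrices, displacement fields,
template warping, and the training losses.

Conventions
-----------
* Volumes are indexed ``(x, y, z)`` = (left-right, anterior-posterior,
  cranio-caudal), isotropic spacing in mm.
* Displacement fields use the pull-back (sampling-map) convention: the warped
  shape reads the template at ``x + u(x)``, so the identity transform yields
  the zero field and fields compose by voxelwise addition.
* Rotation/scaling center is the fixed centroid voxel of the grid (the patch
  center unless stated otherwise); the affine transform carries no
  translation, since patches are extracted with the centroid at a fixed pixel.
* Angles are radians internally, degrees at CLI/file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: loss weights: prediction (L1) term and field-magnitude regularizer
ALPHA_P = 10.0
ALPHA_S = 0.1


@dataclass(frozen=True)
class AffineParams:
    """Per-vertebra pose: rotations about x/y/z (radians) and isotropic scale."""

    theta_x: float
    theta_y: float
    theta_z: float
    scale: float

    def __post_init__(self):
        if not np.isfinite([self.theta_x, self.theta_y, self.theta_z, self.scale]).all():
            raise ValueError("affine parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.theta_x, self.theta_y, self.theta_z, self.scale)

    def inverse(self) -> "AffineParams":
        """Parameters whose matrix is the exact inverse only for single-axis
        rotations; for general poses invert the matrix instead."""
        return AffineParams(-self.theta_x, -self.theta_y, -self.theta_z, 1.0 / self.scale)


def rot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0, 0], [0, c, -s, 0], [0, s, c, 0], [0, 0, 0, 1]], dtype=float)


def rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s, 0], [0, 1, 0, 0], [-s, 0, c, 0], [0, 0, 0, 1]], dtype=float)


def rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0, 0], [s, c, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float)


def build_affine_matrix(params: AffineParams) -> np.ndarray:
    """Homogeneous 4x4 ``R(θx)·R(θy)·R(θz)·T(S)`` with isotropic scale S."""
    if params.scale <= 0:
        raise ValueError("scale must be positive")
    scale = np.diag([params.scale, params.scale, params.scale, 1.0])
    return rot_x(params.theta_x) @ rot_y(params.theta_y) @ rot_z(params.theta_z) @ scale


def affine_to_field(matrix: np.ndarray, grid_shape: tuple[int, int, int],
                    center: np.ndarray | None = None) -> np.ndarray:
    """Displacement field (3, X, Y, Z) realizing an affine matrix about ``center``.

    ``u(x) = M·(x − c) + c − x``: warping a template through this field with the
    pull-back convention applies the *inverse* spatial transform to the shape;
    pair it with the inverse matrix to pose a shape forward.  The identity
    matrix maps to the zero field.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("expected a 4x4 homogeneous matrix")
    if center is None:
        center = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    center = np.asarray(center, dtype=float)
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape],
                                indexing="ij"), axis=0)
    rel = grid - center.reshape(3, 1, 1, 1)
    m3 = matrix[:3, :3]
    return np.einsum("ij,jxyz->ixyz", m3 - np.eye(3), rel)


def compose_fields(field_a: np.ndarray, field_b: np.ndarray) -> np.ndarray:
    """Voxelwise sum of two displacement fields on the same grid."""
    field_a = np.asarray(field_a)
    field_b = np.asarray(field_b)
    if field_a.shape != field_b.shape:
        raise ValueError(f"field grids differ: {field_a.shape} vs {field_b.shape}")
    return field_a + field_b


def warp(template: np.ndarray, field: np.ndarray, *, soft: bool = False,
         label: int | None = None) -> np.ndarray:
    """Warp a template through a displacement field (trilinear, zero-padded).

    With ``soft=True`` the real-valued resampling is returned (training-time
    output); otherwise the result is thresholded at 0.5 — ties count as
    foreground — and multiplied by ``label`` when given.
    """
    template = np.asarray(template, dtype=float)
    field = np.asarray(field, dtype=float)
    if field.shape != (3, *template.shape):
        raise ValueError(f"field shape {field.shape} does not match template {template.shape}")
    base = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in template.shape],
                                indexing="ij"), axis=0)
    coords = base + field
    out = ndimage.map_coordinates(template, coords.reshape(3, -1), order=1,
                                  mode="constant", cval=0.0).reshape(template.shape)
    if soft:
        return out
    mask = (out >= 0.5).astype(np.int16)
    if label is not None:
        mask = mask * np.int16(label)
    return mask


def save_field_nifti(field: np.ndarray, path, spacing: float = 1.0) -> None:
    """Displacement field as 4D NIfTI, last axis = vector component (mm)."""
    import nibabel as nib

    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError("expected a (3, X, Y, Z) field")
    affine = np.diag([spacing] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.moveaxis(field, 0, -1), affine), str(path))


def load_field_nifti(path) -> np.ndarray:
    import nibabel as nib

    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.moveaxis(data, -1, 0)


def save_mask_nifti(mask: np.ndarray, path, spacing: float = 1.0) -> None:
    """Integer label mask as NIfTI."""
    import nibabel as nib

    affine = np.diag([spacing] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine), str(path))


def l1_shape_loss(prediction: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute voxel difference between label-scaled volumes."""
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ValueError("prediction/target shapes differ")
    return float(np.mean(np.abs(prediction - target)))


def smoothness_penalty(field: np.ndarray) -> float:
    """Mean over voxels of |ux|+|uy|+|uz| — the normalized field-magnitude
    integral that discourages large deformations."""
    field = np.asarray(field, dtype=float)
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError("expected a (3, X, Y, Z) field")
    return float(np.abs(field).sum(axis=0).mean())


def total_loss(prediction: np.ndarray, target: np.ndarray, field: np.ndarray,
               alpha_p: float = ALPHA_P, alpha_s: float = ALPHA_S) -> float:
    if alpha_p < 0 or alpha_s < 0:
        raise ValueError("loss weights must be non-negative")
    return alpha_p * l1_shape_loss(prediction, target) + alpha_s * smoothness_penalty(field)
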