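"""Digitally reconstructed radiographs and network-input construction.

A DRR is the line integral of volume intensity along rays from a virtual
focal point to detector pixels.  The sagittal view projects along the
left-right (x) axis, the coronal view along the anterior-posterior (y) axis;
image rows run cranio-caudally (z), so the spine is vertical in both views.

Two ray models are provided:

* ``parallel`` — exact voxel-column integration (intensity x voxel length),
  the analytic surface used in tests;
* ``perspective`` — stepped trilinear sampling along diverging rays from a
  focal point, with the classic standing-radiograph geometry (1800 mm
  source-to-detector, 1500 mm source-to-object).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import (DegenerateImageError, MissingLabelError, OutOfBoundsError)

PATCH_SIZE = 64
VOI_RADIUS_MM = 1.0

#: image (row, col) axes of each view in volume (x, y, z) terms
_VIEW_AXES = {"sagittal": (2, 1, 0), "coronal": (2, 0, 1)}  # (row, col, ray)


@dataclass(frozen=True)
class ProjectionGeometry:
    source_to_detector: float = 1800.0
    source_to_object: float = 1500.0
    detector_spacing: float = 1.0
    mode: str = "perspective"
    step_mm: float = 0.5

    def __post_init__(self):
        if self.mode not in ("perspective", "parallel"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        if self.mode == "perspective" and not (
                0 < self.source_to_object < self.source_to_detector):
            raise ValueError("need 0 < source_to_object < source_to_detector")
        if self.detector_spacing <= 0 or self.step_mm <= 0:
            raise ValueError("spacings must be positive")

    @property
    def magnification(self) -> float:
        return self.source_to_detector / self.source_to_object


@dataclass
class Radiograph2D:
    pixels: np.ndarray  # (rows, cols)
    spacing: float
    view: str


@dataclass
class VOIAnnotation:
    pixels: np.ndarray  # binary, aligned with a Radiograph2D
    centroid_px: np.ndarray


@dataclass
class PatchPair:
    """The four 2D network inputs of one vertebra plus its identity."""

    xs: np.ndarray
    xc: np.ndarray
    ys: np.ndarray
    yc: np.ndarray
    label: int
    centroid_global: np.ndarray  # voxel-index coordinates in the spine volume


# ---------------------------------------------------------------------------
# ray casting

def _detector_grid(vol_shape, spacing, geometry: ProjectionGeometry, view: str):
    """Pixel-center positions (mm, volume frame) on the detector plane."""
    row_ax, col_ax, ray_ax = _VIEW_AXES[view]
    extent = np.asarray(vol_shape, dtype=float) * spacing
    mag = geometry.magnification if geometry.mode == "perspective" else 1.0
    n_rows = int(np.ceil(extent[row_ax] * mag / geometry.detector_spacing)) + 4
    n_cols = int(np.ceil(extent[col_ax] * mag / geometry.detector_spacing)) + 4
    return n_rows, n_cols


def _volume_center(vol_shape, spacing) -> np.ndarray:
    return (np.asarray(vol_shape, dtype=float) - 1.0) / 2.0 * spacing


def project_point(point_vox: np.ndarray, vol_shape, spacing: float,
                  geometry: ProjectionGeometry, view: str) -> np.ndarray:
    """Map a 3D voxel-index point to (row, col) detector pixel coordinates."""
    row_ax, col_ax, ray_ax = _VIEW_AXES[view]
    point_vox = np.asarray(point_vox, dtype=float)
    if geometry.mode == "parallel":
        # axis-dropped voxel coordinates: pixel grid == voxel grid
        return np.array([point_vox[row_ax], point_vox[col_ax]])
    n_rows, n_cols = _detector_grid(vol_shape, spacing, geometry, view)
    rel = point_vox * spacing - _volume_center(vol_shape, spacing)
    # focal point on the -ray axis at source_to_object from the center
    depth = geometry.source_to_object + rel[ray_ax]
    scale = geometry.source_to_detector / depth
    row = rel[row_ax] * scale / geometry.detector_spacing + (n_rows - 1) / 2.0
    col = rel[col_ax] * scale / geometry.detector_spacing + (n_cols - 1) / 2.0
    return np.array([row, col])


def _cast(volume: np.ndarray, spacing: float, geometry: ProjectionGeometry,
          view: str, reduce: str) -> np.ndarray:
    """Shared ray machinery; ``reduce`` is 'sum' (line integral) or 'max'."""
    row_ax, col_ax, ray_ax = _VIEW_AXES[view]
    if geometry.mode == "parallel":
        vol = np.clip(volume, 0.0, None) if reduce == "sum" else volume
        if reduce == "sum":
            img = vol.sum(axis=ray_ax) * spacing
        else:
            img = vol.max(axis=ray_ax)
        # result axes: remaining volume axes in order; bring (row, col) front.
        # Pixel grid coincides with the dropped-axis voxel grid.
        rem = [a for a in range(3) if a != ray_ax]
        return np.ascontiguousarray(img.transpose(rem.index(row_ax), rem.index(col_ax)))

    n_rows, n_cols = _detector_grid(volume.shape, spacing, geometry, view)
    c_mm = _volume_center(volume.shape, spacing)
    source = c_mm.copy()
    source[ray_ax] -= geometry.source_to_object
    det_r = (np.arange(n_rows) - (n_rows - 1) / 2.0) * geometry.detector_spacing
    det_c = (np.arange(n_cols) - (n_cols - 1) / 2.0) * geometry.detector_spacing
    rr, cc = np.meshgrid(det_r, det_c, indexing="ij")
    pix = np.empty((3, n_rows, n_cols))
    pix[ray_ax] = c_mm[ray_ax] + (geometry.source_to_detector - geometry.source_to_object)
    pix[row_ax] = c_mm[row_ax] + rr
    pix[col_ax] = c_mm[col_ax] + cc

    # clip each ray to the volume's bounding slab (slab intersection)
    dirs = pix - source.reshape(3, 1, 1)
    lo = -0.5 * spacing
    hi = (np.asarray(volume.shape) - 0.5) * spacing
    t0 = np.zeros((n_rows, n_cols))
    t1 = np.ones((n_rows, n_cols))
    for ax in range(3):
        d = dirs[ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo - source[ax]) / d
            tb = (hi[ax] - source[ax]) / d
        tmin = np.where(np.abs(d) > 1e-12, np.minimum(ta, tb), 0.0)
        tmax = np.where(np.abs(d) > 1e-12, np.maximum(ta, tb), 1.0)
        inside = (source[ax] >= lo) & (source[ax] <= hi[ax])
        tmin = np.where(np.abs(d) > 1e-12, tmin, np.where(inside, 0.0, 1.0))
        tmax = np.where(np.abs(d) > 1e-12, tmax, np.where(inside, 1.0, 0.0))
        t0 = np.maximum(t0, tmin)
        t1 = np.minimum(t1, tmax)
    seg = np.maximum(t1 - t0, 0.0)
    ray_len = np.linalg.norm(dirs, axis=0)
    n_steps = max(int(np.ceil((seg * ray_len).max() / geometry.step_mm)), 1)

    img = np.zeros((n_rows, n_cols))
    valid = seg > 0
    if not valid.any():
        import warnings
        warnings.warn("volume entirely outside the ray bundle; all-zero DRR")
        return img
    frac = (np.arange(n_steps) + 0.5) / n_steps
    # chunk over steps to bound memory
    acc = np.zeros((n_rows, n_cols))
    vol = np.clip(volume, 0.0, None) if reduce == "sum" else np.asarray(volume, float)
    for k0 in range(0, n_steps, 64):
        f = frac[k0:k0 + 64]
        t = t0[None] + f.reshape(-1, 1, 1) * seg[None]
        pts = source.reshape(3, 1, 1, 1) + dirs[:, None] * t[None]
        idx = pts / spacing
        samp = ndimage.map_coordinates(vol, idx.reshape(3, -1), order=1,
                                       mode="constant", cval=0.0)
        samp = samp.reshape(len(f), n_rows, n_cols)
        if reduce == "sum":
            acc += samp.sum(axis=0)
        else:
            acc = np.maximum(acc, samp.max(axis=0))
    if reduce == "sum":
        step_len = seg * ray_len / n_steps
        img = acc * step_len
    else:
        img = acc
    return img


def raycast_drr(volume: np.ndarray, geometry: ProjectionGeometry,
                view: str) -> Radiograph2D:
    """Line-integral projection of an intensity volume (see module docs)."""
    spacing = getattr(volume, "spacing", 1.0)
    vol = np.asarray(volume, dtype=float)
    img = _cast(vol, spacing, geometry, view, reduce="sum")
    return Radiograph2D(pixels=img, spacing=geometry.detector_spacing
                        if geometry.mode == "perspective" else spacing, view=view)


def project_labels(label_volume: np.ndarray, geometry: ProjectionGeometry,
                   view: str, label: int) -> tuple[np.ndarray, np.ndarray]:
    """Binary silhouette of one label (any-hit compositing) + projected centroid."""
    label_volume = np.asarray(label_volume)
    sel = label_volume == label
    if not sel.any():
        raise MissingLabelError(f"label {label} absent from volume")
    img = _cast(sel.astype(float), 1.0, geometry, view, reduce="max")
    silhouette = img >= 0.5
    centroid3d = np.array(np.nonzero(sel), dtype=float).mean(axis=1)
    centroid_px = project_point(centroid3d, label_volume.shape, 1.0, geometry, view)
    return silhouette, centroid_px


# ---------------------------------------------------------------------------
# annotations, patches, normalization

def make_voi_annotation(centroid_px: np.ndarray, radius_mm: float, spacing: float,
                        shape: tuple[int, int]) -> VOIAnnotation:
    """Disc of ``radius_mm`` around the centroid (pixel-center distances)."""
    centroid_px = np.asarray(centroid_px, dtype=float)
    if not ((0 <= centroid_px[0] <= shape[0] - 1)
            and (0 <= centroid_px[1] <= shape[1] - 1)):
        raise OutOfBoundsError(f"centroid {centroid_px} outside image {shape}")
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    dist2 = (rr - centroid_px[0]) ** 2 + (cc - centroid_px[1]) ** 2
    disc = dist2 <= (radius_mm / spacing) ** 2
    return VOIAnnotation(pixels=disc, centroid_px=centroid_px)


def extract_patch(image: np.ndarray, centroid_px: np.ndarray,
                  size: int = PATCH_SIZE) -> np.ndarray:
    """``size``-square window with the centroid at pixel (size//2, size//2);
    out-of-image area is zero-filled."""
    image = np.asarray(image)
    r, c = np.round(np.asarray(centroid_px, dtype=float)).astype(int)
    half = size // 2
    out = np.zeros((size, size), dtype=float)
    r0, c0 = r - half, c - half
    src_r0, src_c0 = max(r0, 0), max(c0, 0)
    src_r1 = min(r0 + size, image.shape[0])
    src_c1 = min(c0 + size, image.shape[1])
    if src_r1 > src_r0 and src_c1 > src_c0:
        out[src_r0 - r0:src_r1 - r0, src_c0 - c0:src_c1 - c0] = \
            image[src_r0:src_r1, src_c0:src_c1]
    return out


def znormalize(image: np.ndarray) -> np.ndarray:
    """Z-score normalization: (I - mean) / std."""
    image = np.asarray(image, dtype=float)
    sigma = image.std()
    if sigma == 0:
        raise DegenerateImageError("constant image: z-normalization undefined")
    return (image - image.mean()) / sigma


def patch_pairs_for_spine(spine, geometry: ProjectionGeometry,
                          patch_size: int = PATCH_SIZE,
                          radius_mm: float = VOI_RADIUS_MM) -> list[PatchPair]:
    """Full network-input construction for every vertebra of a spine phantom.

    One DRR per view is cast once; per vertebra, the 3D centroid is projected,
    a z-normalized image patch is extracted around it, and a centered VOI disc
    is drawn.  Patches are ordered by ascending label.
    """
    drr = {v: raycast_drr(_with_spacing(spine.intensity, spine.spacing), geometry, v)
           for v in ("sagittal", "coronal")}
    pairs = []
    for lab in sorted(spine.centroids):
        patches = {}
        for v in ("sagittal", "coronal"):
            cpx = project_point(spine.centroids[lab], spine.intensity.shape,
                                spine.spacing, geometry, v)
            cpx_int = np.round(cpx)
            img = znormalize(extract_patch(drr[v].pixels, cpx_int, patch_size))
            half = patch_size // 2
            ann = make_voi_annotation(np.array([half, half], dtype=float), radius_mm,
                                      drr[v].spacing, (patch_size, patch_size))
            patches[v] = (img.astype(np.float32), ann.pixels.astype(np.float32))
        pairs.append(PatchPair(xs=patches["sagittal"][0], xc=patches["coronal"][0],
                               ys=patches["sagittal"][1], yc=patches["coronal"][1],
                               label=lab, centroid_global=spine.centroids[lab].copy()))
    return pairs


class _with_spacing(np.ndarray):
    """View of an array carrying a ``spacing`` attribute for the caster."""

    def __new__(cls, arr, spacing):
        obj = np.asarray(arr, dtype=float).view(cls)
        obj.spacing = float(spacing)
        return obj


def save_patch_bundle(pairs: list[PatchPair], path) -> None:
    """Write patch pairs as an NPZ archive plus a JSON manifest sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {}
    manifest = []
    for p in pairs:
        for name in ("xs", "xc", "ys", "yc"):
            arrays[f"L{p.label}_{name}"] = getattr(p, name)
        manifest.append({"label": int(p.label),
                         "centroid": [float(v) for v in p.centroid_global],
                         "views": ["sagittal", "coronal"]})
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_patch_bundle(path) -> list[PatchPair]:
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    pairs = []
    with np.load(path.with_suffix(".npz")) as data:
        for entry in manifest:
            lab = entry["label"]
            pairs.append(PatchPair(
                xs=data[f"L{lab}_xs"], xc=data[f"L{lab}_xc"],
                ys=data[f"L{lab}_ys"], yc=data[f"L{lab}_yc"],
                label=lab, centroid_global=np.array(entry["centroid"])))
    return pairs


def save_drr_nifti(radiograph: Radiograph2D, path) -> None:
    import nibabel as nib

    affine = np.diag([radiograph.spacing, radiograph.spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(radiograph.pixels[..., None].astype(np.float32),
                             affine), str(path))


def save_drr_png(radiograph: Radiograph2D, path) -> None:
    """16-bit PNG preview, intensity range scaled to [0, 65535]."""
    import imageio.v3 as iio

    px = radiograph.pixels
    lo, hi = px.min(), px.max()
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    iio.imwrite(str(path), (scaled * 65535).astype(np.uint16))
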