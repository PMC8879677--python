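"""Synthetic spine phantoms: vertebra-like shapes, curved spines, and templates.

The generator emulates the structure the registration method assumes: each
vertebra is an ellipsoidal body with a posterior spinous-process protrusion,
sized monotonically from T1 (label 8) to L5 (label 24), stacked along a smooth
kyphotic/lordotic centroid curve inside a soft-tissue background, with
per-vertebra random pose jitter.  Everything is a pure function of
(parameters, seed) so downstream modules are testable without any download.

Array axes are (x, y, z) = (left-right, anterior-posterior, cranio-caudal);
+y is posterior (the process side).  Internal coordinates are voxel indices
(voxel centers at ``index * spacing`` mm); centroid CSV files use mm from the
corner of voxel 0, i.e. ``(index + 0.5) * spacing``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, InvalidLabelError, MissingTemplateError
from .registration import AffineParams, affine_to_field, build_affine_matrix, warp

LABEL_MIN = 8
LABEL_MAX = 24
#: label -> anatomical name, T1..T12 then L1..L5
LABEL_NAMES = {LABEL_MIN + i: (f"T{i + 1}" if i < 12 else f"L{i - 11}") for i in range(17)}

BONE_INTENSITY = 1000.0
SOFT_TISSUE_INTENSITY = 200.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic spine population.

    Sizes are in mm.  ``grid_size`` is the canonical per-vertebra cubic grid
    (also the output-patch grid of the network); ``body_radius_range`` and
    ``process_length_range`` interpolate linearly from T1 to L5.
    """

    n_vertebrae: int = 17
    voxel_spacing: float = 1.0
    body_radius_range: tuple[float, float] = (6.0, 10.0)
    process_length_range: tuple[float, float] = (8.0, 14.0)
    curve_amplitude: float = 10.0
    noise_sigma: float = 20.0
    seed: int = 0
    grid_size: int = 64
    start_label: int = LABEL_MIN
    rot_jitter_deg: float = 10.0
    scale_jitter: float = 0.08
    centroid_jitter_mm: float = 1.5
    disc_gap_mm: float = 4.0

    def __post_init__(self):
        if not (1 <= self.n_vertebrae <= 17):
            raise ValueError("n_vertebrae must be in [1, 17]")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        for name in ("body_radius_range", "process_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        if not (LABEL_MIN <= self.start_label
                and self.start_label + self.n_vertebrae - 1 <= LABEL_MAX):
            raise ValueError("labels must stay within {8..24}")

    @property
    def labels(self) -> list[int]:
        return list(range(self.start_label, self.start_label + self.n_vertebrae))

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["body_radius_range"] = list(d["body_radius_range"])
        d["process_length_range"] = list(d["process_length_range"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        d["body_radius_range"] = tuple(d["body_radius_range"])
        d["process_length_range"] = tuple(d["process_length_range"])
        return cls(**d)


@dataclass
class VertebraPhantom:
    label: int
    mask: np.ndarray  # 3D bool
    centroid: np.ndarray  # voxel-index coordinates of the body center
    pose_truth: AffineParams = field(
        default_factory=lambda: AffineParams(0.0, 0.0, 0.0, 1.0))


@dataclass
class SpinePhantom:
    intensity: np.ndarray
    labels: np.ndarray  # int16, values in {0} | spec labels
    centroids: dict[int, np.ndarray]  # label -> voxel-index coordinates
    poses: dict[int, AffineParams]
    spacing: float
    spec: PhantomSpec


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _size_fraction(label: int) -> float:
    return (label - LABEL_MIN) / (LABEL_MAX - LABEL_MIN)


def make_vertebra_phantom(label: int, spec: PhantomSpec, rng_state=0) -> VertebraPhantom:
    """Canonical (unposed) vertebra shape on the spec's cubic grid.

    The body is an ellipsoid whose surface is modulated by a smooth random
    quadratic field shared across labels for a given seed, so shape size is
    monotone in label by set inclusion.  The spinous process is an elliptic
    rod along +y, attached inside the body.
    """
    if not (LABEL_MIN <= int(label) <= LABEL_MAX):
        raise InvalidLabelError(f"label {label} outside supported range {{8..24}}")
    rng = _as_rng(rng_state)
    t = _size_fraction(label)
    r = spec.body_radius_range[0] + t * (spec.body_radius_range[1] - spec.body_radius_range[0])
    proc_len = (spec.process_length_range[0]
                + t * (spec.process_length_range[1] - spec.process_length_range[0]))
    semi = np.array([r, 0.85 * r, 0.60 * r])  # width, AP depth, height (mm)

    n = spec.grid_size
    # body center at the fixed patch-center voxel n//2 (integer), so phantom,
    # atlas and network patches all share one centroid convention
    center = float(n // 2)
    coords = (np.stack(np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij"), axis=0)
              - center) * spec.voxel_spacing

    # smooth surface modulation: quadratic form on the direction sphere
    amp = 0.05
    quad = rng.standard_normal((3, 3))
    quad = (quad + quad.T) / 2.0
    q = coords / semi.reshape(3, 1, 1, 1)
    rho = np.sqrt((q ** 2).sum(axis=0)) + 1e-9
    d = q / rho
    mod = 1.0 + amp * np.einsum("ixyz,ij,jxyz->xyz", d, quad, d)
    body = rho <= mod

    wx, wz = 0.22 * r, 0.30 * r
    x, y, z = coords
    # spinous process: posterior rod along +y
    rod = (((x / wx) ** 2 + (z / wz) ** 2) <= 1.0) & \
          (y >= 0.5 * semi[1]) & (y <= 0.5 * semi[1] + proc_len)
    # transverse processes: lateral rods along +/-x (first-order axial-rotation
    # cue in the projections, as in real vertebrae)
    wing_len = 0.6 * proc_len
    wy, wz2 = 0.18 * r, 0.22 * r
    wings = (((y / wy) ** 2 + (z / wz2) ** 2) <= 1.0) & \
            (np.abs(x) <= 0.8 * semi[0] + wing_len)
    mask = body | rod | wings
    return VertebraPhantom(label=int(label), mask=mask,
                           centroid=np.full(3, center, dtype=float))


def pose_vertebra(phantom: VertebraPhantom, params: AffineParams,
                  rng_state=None) -> VertebraPhantom:
    """Resample a vertebra under the exact affine transform of the engine.

    The shape is mapped forward by ``R(θx)R(θy)R(θz)T(S)`` about its centroid
    (a point at offset d from the centroid lands at offset M·d), implemented
    as a pull-back warp through the field of the inverse matrix.
    """
    if params.scale <= 0:
        raise ValueError("scale must be positive")
    matrix = build_affine_matrix(params)
    fld = affine_to_field(np.linalg.inv(matrix), phantom.mask.shape,
                          center=phantom.centroid)
    posed = warp(phantom.mask.astype(float), fld) > 0
    return VertebraPhantom(label=phantom.label, mask=posed,
                           centroid=phantom.centroid.copy(), pose_truth=params)


def make_spine_phantom(spec: PhantomSpec) -> SpinePhantom:
    """A full synthetic spine: posed vertebrae on a smooth curve + intensities."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels
    n = spec.grid_size
    half = n // 2

    # cranio-caudal pitch per vertebra: body height + disc gap
    heights = []
    for lab in labels:
        t = _size_fraction(lab)
        r = spec.body_radius_range[0] + t * (spec.body_radius_range[1]
                                             - spec.body_radius_range[0])
        heights.append(2 * 0.60 * r + spec.disc_gap_mm)
    pitch = np.asarray(heights) / spec.voxel_spacing

    margin = half + 2
    cj = spec.centroid_jitter_mm / spec.voxel_spacing
    nx = int(2 * margin)
    ny = int(2 * margin
             + 2 * np.ceil(spec.curve_amplitude / spec.voxel_spacing + cj))
    nz = int(np.ceil(pitch.sum()) + 2 * margin)
    vol_shape = (nx, ny, nz)

    z_positions = margin + np.cumsum(pitch) - pitch / 2.0
    tpar = (np.arange(len(labels)) + 0.5) / len(labels)
    y_curve = spec.curve_amplitude / spec.voxel_spacing * np.sin(2 * np.pi * tpar)
    # tangent of the centroid curve -> nominal sagittal tilt (rotation about x)
    dz = np.gradient(z_positions)
    dy = np.gradient(y_curve)
    tilt = np.arctan2(dy, dz)

    intensity = np.zeros(vol_shape, dtype=float)
    label_vol = np.zeros(vol_shape, dtype=np.int16)
    centroids: dict[int, np.ndarray] = {}
    poses: dict[int, AffineParams] = {}
    jr = np.deg2rad(spec.rot_jitter_deg)

    for k, lab in enumerate(labels):
        canon = make_vertebra_phantom(lab, spec, np.random.default_rng([spec.seed, lab]))
        pose = AffineParams(
            theta_x=float(tilt[k] + rng.uniform(-jr, jr)),
            theta_y=float(rng.uniform(-jr, jr)),
            theta_z=float(rng.uniform(-jr, jr)),
            scale=float(rng.uniform(1.0 - spec.scale_jitter, 1.0 + spec.scale_jitter)),
        )
        posed = pose_vertebra(canon, pose)
        target = np.array([nx / 2.0 + rng.uniform(-cj, cj),
                           ny / 2.0 + y_curve[k] + rng.uniform(-cj, cj),
                           z_positions[k]])
        offset = np.round(target - posed.centroid).astype(int)
        lo = offset
        hi = offset + n
        if (lo < 0).any() or (hi > np.asarray(vol_shape)).any():
            raise GeometryError(
                f"volume {vol_shape} too small to place vertebra {lab} at {target}")
        region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        patch = label_vol[region]
        # caudal (higher) label wins on overlap
        patch[posed.mask & (patch < lab)] = lab
        centroids[lab] = posed.centroid + offset
        poses[lab] = pose

    intensity[label_vol > 0] = BONE_INTENSITY
    # soft-tissue elliptic cylinder around the spine, full cranio-caudal extent
    xg, yg = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    soft = (((xg - nx / 2.0) / (0.45 * nx)) ** 2
            + ((yg - ny / 2.0) / (0.45 * ny)) ** 2) <= 1.0
    soft3 = np.broadcast_to(soft[:, :, None], vol_shape) & (label_vol == 0)
    intensity[soft3] = SOFT_TISSUE_INTENSITY
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=vol_shape)

    return SpinePhantom(intensity=intensity, labels=label_vol, centroids=centroids,
                        poses=poses, spacing=spec.voxel_spacing, spec=spec)


@dataclass
class TemplateAtlas:
    """Per-label canonical shapes, centroid-aligned on a common cubic grid."""

    templates: dict[int, np.ndarray]  # label -> bool (grid_size^3)
    downscaled: dict[int, np.ndarray]  # label -> float, block-averaged
    grid_size: int
    downscale_factor: int

    def template_for(self, label: int) -> np.ndarray:
        if label not in self.templates:
            raise MissingTemplateError(f"no template for label {label}")
        return self.templates[label]

    def downscaled_for(self, label: int) -> np.ndarray:
        if label not in self.downscaled:
            raise MissingTemplateError(f"no template for label {label}")
        return self.downscaled[label]


def _block_mean(volume: np.ndarray, factor: int) -> np.ndarray:
    n = volume.shape[0]
    if n % factor:
        raise ValueError("grid size not divisible by downscale factor")
    m = n // factor
    return volume.astype(float).reshape(m, factor, m, factor, m, factor).mean(axis=(1, 3, 5))


def build_template_atlas(population, grid_size: int,
                         downscale_factor: int = 8) -> TemplateAtlas:
    """Majority-vote atlas (occupancy >= 50%, ties included) of centroid-aligned masks."""
    votes: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    center = np.full(3, grid_size // 2, dtype=int)
    for ph in population:
        shift = center - np.round(ph.centroid).astype(int)
        aligned = np.zeros((grid_size,) * 3, dtype=np.int32)
        src_lo = np.maximum(0, -shift)
        src_hi = np.minimum(ph.mask.shape, grid_size - shift)
        dst_lo = src_lo + shift
        dst_hi = src_hi + shift
        if (src_hi <= src_lo).any():
            continue
        aligned[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            ph.mask[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
        if ph.label not in votes:
            votes[ph.label] = np.zeros((grid_size,) * 3, dtype=np.int32)
            counts[ph.label] = 0
        votes[ph.label] += aligned
        counts[ph.label] += 1
    templates = {lab: (2 * votes[lab] >= counts[lab]) for lab in sorted(votes)}
    downscaled = {lab: _block_mean(tpl, downscale_factor)
                  for lab, tpl in templates.items()}
    return TemplateAtlas(templates=templates, downscaled=downscaled,
                         grid_size=grid_size, downscale_factor=downscale_factor)


# ---------------------------------------------------------------------------
# file I/O

def save_spine_phantom(spine: SpinePhantom, out_dir: str | Path) -> dict[str, str]:
    """Write intensity/label NIfTIs, centroid CSV and the spec JSON sidecar."""
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spine.spacing] * 3 + [1.0])
    paths = {
        "intensity": str(out / "intensity.nii.gz"),
        "labels": str(out / "labels.nii.gz"),
        "centroids": str(out / "centroids.csv"),
        "spec": str(out / "phantom_spec.json"),
    }
    nib.save(nib.Nifti1Image(spine.intensity.astype(np.float32), affine), paths["intensity"])
    nib.save(nib.Nifti1Image(spine.labels.astype(np.int16), affine), paths["labels"])
    rows = [{"label": lab,
             "x": (c[0] + 0.5) * spine.spacing,
             "y": (c[1] + 0.5) * spine.spacing,
             "z": (c[2] + 0.5) * spine.spacing}
            for lab, c in sorted(spine.centroids.items())]
    pd.DataFrame(rows).to_csv(paths["centroids"], index=False, float_format="%.4f")
    spine.spec.to_json(paths["spec"])
    return paths


def load_centroids(path: str | Path, spacing: float = 1.0) -> dict[int, np.ndarray]:
    """Read a centroid CSV (mm, voxel-corner origin) into voxel-index coords."""
    import pandas as pd

    df = pd.read_csv(path)
    return {int(r["label"]): np.array([r["x"], r["y"], r["z"]]) / spacing - 0.5
            for _, r in df.iterrows()}
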