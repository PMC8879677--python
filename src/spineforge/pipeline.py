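"""End-to-end orchestration: config handling, the phantom -> DRR -> train ->
infer -> evaluate chain, and report/manifest writing.

A single global seed is fanned out to every stochastic stage by stable
hashing of the stage name, so a rerun with the same config and seed is
bit-reproducible down to the metrics CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .metrics import DEFAULT_N_EIGENVALUES, DEFAULT_P, dice, hausdorff, nwesd
from .model import ModelConfig, SpineRegistrationModel
from .phantoms import PhantomSpec, make_spine_phantom, save_spine_phantom
from .projection import (ProjectionGeometry, patch_pairs_for_spine, raycast_drr,
                         save_drr_nifti, save_drr_png, _with_spacing)
from .training import (TrainConfig, extract_target, infer_spine, make_dataset,
                       train)

log = logging.getLogger("spineforge")


@dataclass(frozen=True)
class MetricDefaults:
    n_eigenvalues: int = DEFAULT_N_EIGENVALUES
    p: float = DEFAULT_P

    def __post_init__(self):
        if self.n_eigenvalues < 1:
            raise ConfigError("n_eigenvalues must be >= 1")
        if self.p <= 1.5:
            raise ConfigError("p must exceed d/2 = 1.5")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: ProjectionGeometry = field(default_factory=ProjectionGeometry)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricDefaults = field(default_factory=MetricDefaults)
    n_spines: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_spines < 2:
            raise ConfigError("n_spines must be >= 2 (train + held-out)")


_SECTIONS = {"phantom": PhantomSpec, "geometry": ProjectionGeometry,
             "model": ModelConfig, "train": TrainConfig, "metrics": MetricDefaults}
_TUPLE_FIELDS = {"body_radius_range", "process_length_range", "mlp_widths", "split"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % 2 ** 31


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    coerced = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
               for k, v in data.items()}
    try:
        return cls(**coerced)
    except (ValueError, ConfigError) as exc:
        raise ConfigError(f"invalid value in '{section}': {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Parse, default, and validate a YAML pipeline config; reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            top[key] = _build_section(_SECTIONS[key], val, key)
        elif key in ("n_spines", "seed"):
            top[key] = val
        else:
            raise ConfigError(f"unknown key '{key}'")
    try:
        return PipelineConfig(**top)
    except (ValueError, ConfigError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    d = {}
    for key, cls in _SECTIONS.items():
        section = dataclasses.asdict(getattr(config, key))
        d[key] = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in section.items()}
    d["n_spines"] = config.n_spines
    d["seed"] = config.seed
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({k: str(v) for k, v in dataclasses.asdict(config).items()},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report(metrics_rows: list[dict], path: str | Path) -> None:
    """Per-vertebra CSV plus mean/std footer rows, 4-decimal formatting."""
    if not metrics_rows:
        raise DataError("no metric rows to write")
    df = pd.DataFrame(metrics_rows)
    cols = list(df.columns)
    agg_mean = {c: df[c].mean() for c in cols if c != "label"}
    agg_std = {c: df[c].std(ddof=0) for c in cols if c != "label"}
    out_rows = [dict(r) for r in metrics_rows]
    out_rows.append({"label": "mean", **agg_mean})
    out_rows.append({"label": "std", **agg_std})
    out = pd.DataFrame(out_rows, columns=cols)
    out.to_csv(path, index=False, float_format="%.4f")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict[str, str]]
    timestamps: dict[str, float]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute phantom -> drr -> train -> infer -> evaluate; write a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    stages: dict[str, dict[str, str]] = {}
    timestamps: dict[str, float] = {}
    manifest = RunManifest(config_hash=config_hash(config), version=__version__,
                           stages=stages, timestamps=timestamps)

    def finish(stage: str, files: dict[str, str]):
        stages[stage] = files
        timestamps[stage] = time.time()
        log.info("stage %s done: %d file(s)", stage, len(files))

    try:
        # -- phantom: held-out test spine ------------------------------------
        test_spec = replace(config.phantom,
                            seed=stage_seed(config.seed, "phantom-test"))
        test_spine = make_spine_phantom(test_spec)
        phantom_dir = out / "phantom"
        files = save_spine_phantom(test_spine, phantom_dir)
        files["config"] = str(out / "config.yaml")
        save_config(config, files["config"])
        finish("phantom", files)

        # -- drr --------------------------------------------------------------
        drr_dir = out / "drr"
        drr_dir.mkdir(exist_ok=True)
        drrs = {}
        files = {}
        vol = _with_spacing(test_spine.intensity, test_spine.spacing)
        for view in ("sagittal", "coronal"):
            rg = raycast_drr(vol, config.geometry, view)
            drrs[view] = rg
            files[f"{view}_nifti"] = str(drr_dir / f"{view}.nii.gz")
            files[f"{view}_png"] = str(drr_dir / f"{view}.png")
            save_drr_nifti(rg, files[f"{view}_nifti"])
            save_drr_png(rg, files[f"{view}_png"])
        finish("drr", files)

        # -- train ------------------------------------------------------------
        train_dir = out / "train"
        train_dir.mkdir(exist_ok=True)
        dataset, atlas = make_dataset(config.n_spines - 1, config.phantom,
                                      config.geometry,
                                      seed=stage_seed(config.seed, "dataset"))
        model = SpineRegistrationModel(replace(
            config.model, seed=stage_seed(config.seed, "model-init")))
        tc = replace(config.train, seed=stage_seed(config.seed, "train"))
        model, history = train(model, dataset, atlas, tc)
        ckpt = train_dir / "checkpoint"
        model.save(ckpt)
        hist_path = train_dir / "history.csv"
        history.to_csv(hist_path, index=False, float_format="%.6f")
        finish("train", {"checkpoint_weights": str(ckpt) + ".npz",
                         "checkpoint_config": str(ckpt) + ".yaml",
                         "history": str(hist_path)})

        # -- infer ------------------------------------------------------------
        infer_dir = out / "infer"
        infer_dir.mkdir(exist_ok=True)
        spine_model = infer_spine(
            model, drrs["sagittal"].pixels, drrs["coronal"].pixels,
            test_spine.centroids, atlas, spacing=test_spine.spacing,
            geometry=config.geometry, volume_shape=test_spine.intensity.shape)
        import nibabel as nib
        pred_path = infer_dir / "spine.nii.gz"
        affine = np.diag([test_spine.spacing] * 3 + [1.0])
        nib.save(nib.Nifti1Image(spine_model.volume.astype(np.int16), affine),
                 str(pred_path))
        finish("infer", {"spine": str(pred_path)})

        # -- evaluate ----------------------------------------------------------
        rows = []
        for lab in sorted(test_spine.centroids):
            target = extract_target(test_spine, lab, config.model.out_size) > 0
            pred = spine_model.masks[lab]
            k = min(config.metrics.n_eigenvalues, int(pred.sum()), int(target.sum()))
            rows.append({
                "label": lab,
                "dice": dice(pred, target),
                "hausdorff_mm": hausdorff(pred, target, test_spine.spacing),
                "nwesd": nwesd(pred, target, k, config.metrics.p,
                               test_spine.spacing),
            })
        report_path = out / "metrics.csv"
        write_report(rows, report_path)
        finish("evaluate", {"report": str(report_path)})
    except Exception as exc:
        done = list(stages)
        raise type(exc)(
            f"pipeline aborted after stages {done}: {exc}").with_traceback(
                exc.__traceback__) from None

    manifest_path = out / "manifest.json"
    stages["manifest"] = {"manifest": str(manifest_path)}
    timestamps["manifest"] = time.time()
    manifest.save(manifest_path)
    return manifest
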