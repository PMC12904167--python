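"""Reading and writing the pipeline's on-disk artifacts.

Images are single-file multi-channel TIFFs (channel 0 = Z-line, channel 1 =
NSP, 16-bit).  Ground truth travels as schema-versioned JSON, tabular outputs
as UTF-8 comma-separated CSV with a mandatory header row, units in column
names, and 0-based (row, col) pixel-center coordinates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import PipelineConfig
from .image import FiberImage
from .simulate import GROUND_TRUTH_SCHEMA_VERSION, CohortDataset, GroundTruth

logger = logging.getLogger("myoseries")


def write_fiber_image(path: str | Path, image: FiberImage) -> Path:
    """Write a two-channel 16-bit TIFF with the pixel pitch in its metadata."""
    path = Path(path)
    data = np.clip(image.data, 0, 65535).astype(np.uint16)
    ppu = 1.0 / image.pixel_pitch  # pixels per µm
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(ppu, ppu),
        resolutionunit="NONE",
        metadata={"pixel_pitch_um": image.pixel_pitch, "axes": "CYX"},
    )
    return path


def read_fiber_image(
    path: str | Path, config: PipelineConfig | None = None
) -> FiberImage:
    """Load a >= 2-channel TIFF, resolving channel roles and pixel pitch.

    The pixel pitch comes from the file metadata when present; a configured
    pitch always wins (a conflict is logged as a warning).  Integer data are
    promoted to float64.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_pitch = None
        try:
            meta = tf.shaped_metadata or tf.imagej_metadata
            if meta:
                doc = meta[0] if isinstance(meta, (list, tuple)) else meta
                meta_pitch = float(doc.get("pixel_pitch_um"))
        except (TypeError, ValueError, AttributeError):
            meta_pitch = None
    if data.ndim == 2:
        raise ValueError(
            f"{path} has a single channel; two channels are required "
            "(channel 0 = Z-line/alpha-actinin, channel 1 = NSP)"
        )
    if data.ndim != 3:
        raise ValueError(f"{path}: unsupported TIFF layout {data.shape}")
    if data.shape[0] > data.shape[-1]:  # (H, W, C) -> (C, H, W)
        data = np.moveaxis(data, -1, 0)
    if data.shape[0] < 2:
        raise ValueError(
            f"{path} has {data.shape[0]} channel(s); two are required"
        )
    config_pitch = config.pixel_pitch_um if config is not None else None
    if config_pitch is not None and meta_pitch is not None:
        if not np.isclose(config_pitch, meta_pitch, rtol=1e-6):
            logger.warning(
                "pixel pitch conflict for %s: metadata %.6f vs config %.6f "
                "µm/px; using the configured value",
                path,
                meta_pitch,
                config_pitch,
            )
        pitch = config_pitch
    elif meta_pitch is not None:
        pitch = meta_pitch
    elif config_pitch is not None:
        pitch = config_pitch
    else:
        raise ValueError(f"{path}: pixel pitch not in metadata and no config given")
    if config is not None and (config.channel_zline, config.channel_nsp) != (0, 1):
        order = [config.channel_zline, config.channel_nsp] + [
            c
            for c in range(data.shape[0])
            if c not in (config.channel_zline, config.channel_nsp)
        ]
        data = data[order]
    return FiberImage(data=data.astype(np.float64), pixel_pitch=pitch)


def write_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    path.write_text(truth.model_dump_json(indent=1) + "\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != GROUND_TRUTH_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: ground-truth schema {doc.get('schema_version')} "
            f"!= supported {GROUND_TRUTH_SCHEMA_VERSION}"
        )
    return GroundTruth(**doc)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write a simulated cohort: TIFFs, ground-truth JSONs, manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.records:
        stem = f"{rec.muscle_id}_{rec.fiber_id}"
        img_path = write_fiber_image(out_dir / f"{stem}.tif", rec.image)
        write_ground_truth(out_dir / f"{stem}.truth.json", rec.truth)
        rows.append(
            {
                "muscle_id": rec.muscle_id,
                "fiber_id": rec.fiber_id,
                "group": rec.group,
                "rapamycin": rec.rapamycin,
                "path": img_path.name,
                "sha256": sha256_file(img_path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest(manifest_path: str | Path, verify: bool = True) -> pd.DataFrame:
    """Read a cohort manifest, verifying file checksums before analysis."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"muscle_id", "fiber_id", "group", "rapamycin", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks required columns: {sorted(missing)}")
    if manifest.empty:
        raise ValueError(f"manifest {manifest_path} is empty")
    base = manifest_path.parent
    if verify and "sha256" in manifest.columns:
        for _, row in manifest.iterrows():
            actual = sha256_file(base / row["path"])
            if actual != row["sha256"]:
                raise ValueError(
                    f"checksum mismatch for {row['path']}: manifest "
                    f"{row['sha256'][:12]}..., file {actual[:12]}..."
                )
    return manifest


def write_json(path: str | Path, doc: dict) -> Path:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
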