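"""Cohort-level orchestration of the per-fiber analyses.

Each stage consumes a manifest (muscle_id, fiber_id, group, rapamycin, path)
plus the pipeline configuration and produces tidy CSV/JSON artifacts.  The
stages are deliberately independent so any one can be re-run from its inputs;
all randomness derives from the stage seed.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .hotspots import (
    call_positive_fiber,
    classify_rois,
    detect_hotspots,
    estimate_local_background,
    hotspot_table,
    hotspots_per_roi_paired,
    percent_positive_fibers,
    qualifying,
)
from .image import FiberImage
from .io import read_fiber_image, read_manifest
from .morphology import classify_fiber_hotspots, summarize_mix
from .morphometry import (
    exclude_outliers,
    normalize_to_control,
    single_fiber_records,
)
from .splits import splits_per_fiber
from .stats import compare_groups
from .zline import (
    extract_roi,
    mean_continuous_zline_length,
    roi_mean_zline_length,
    segment_zlines,
    select_roi,
    skeletonize_zlines,
    trace_continuous_zlines,
)

logger = logging.getLogger("myoseries")


def _stable_hash(*parts) -> int:
    """Process-independent small hash for deriving per-fiber seeds."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) % 100003


def _default_fiber_mask(image: FiberImage) -> FiberImage:
    """Fibers rendered by this package fill a horizontal band; when a mask is
    absent (plain TIFF input) treat rows whose mean Z-line intensity clearly
    exceeds the image floor as fiber."""
    if image.fiber_mask is not None:
        return image
    row_mean = image.zline.mean(axis=1)
    thr = row_mean.min() + 0.25 * (row_mean.max() - row_mean.min())
    rows = row_mean > thr
    mask = np.zeros(image.shape, dtype=bool)
    mask[rows, :] = True
    image.fiber_mask = mask
    return image


def _iter_images(manifest: pd.DataFrame, base: Path, config: PipelineConfig):
    for _, row in manifest.iterrows():
        image = read_fiber_image(base / row["path"], config)
        _default_fiber_mask(image)
        yield row, image


def zline_stage(
    manifest_path: str | Path, config: PipelineConfig, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Continuous Z-line length per ROI, per fiber and per sample."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    per_line, per_roi = [], []
    for row, image in _iter_images(manifest, manifest_path.parent, config):
        for k in range(config.n_rois_per_fiber):
            roi_seed = seed * 100003 + _stable_hash(row["muscle_id"], row["fiber_id"], k)
            roi = select_roi(
                image, extent=(config.roi_rows_px, config.roi_cols_px), rng_seed=roi_seed
            )
            raster = extract_roi(image.zline, roi)
            mask, _ = segment_zlines(
                raster, image.pixel_pitch, ridge_sigma_um=config.ridge_sigma_um
            )
            if not mask.any():
                logger.warning(
                    "empty Z-line mask for %s %s roi %d",
                    row["muscle_id"],
                    row["fiber_id"],
                    k,
                )
                continue
            lines = trace_continuous_zlines(
                skeletonize_zlines(mask),
                image.pixel_pitch,
                config.theta_max_deg,
                config.min_line_length_um,
            )
            roi_id = f"{row['muscle_id']}_{row['fiber_id']}_roi{k}"
            for ln in lines:
                per_line.append(
                    {"roi_id": roi_id, "line_id": ln.id, "length_um": ln.length_um}
                )
            per_roi.append(
                {
                    "muscle_id": row["muscle_id"],
                    "fiber_id": row["fiber_id"],
                    "group": row["group"],
                    "rapamycin": row["rapamycin"],
                    "roi_id": roi_id,
                    "n_lines": len(lines),
                    "mean_length_um": mean_continuous_zline_length(
                        lines, config.zline_weighting
                    ),
                }
            )
    roi_df = pd.DataFrame(per_roi)
    sample = (
        roi_df.groupby(["muscle_id", "group", "rapamycin"], as_index=False)[
            "mean_length_um"
        ]
        .mean()
        .rename(columns={"mean_length_um": "mean_continuous_zline_length_um"})
    )
    return {"lines": pd.DataFrame(per_line), "rois": roi_df, "samples": sample}


def splits_stage(
    manifest_path: str | Path, config: PipelineConfig, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Net transverse split counts per A-band, fiber and sample."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    aband_rows, fiber_rows = [], []
    for row, image in _iter_images(manifest, manifest_path.parent, config):
        fiber_seed = seed * 100003 + _stable_hash(row["muscle_id"], row["fiber_id"])
        mean_net, table = splits_per_fiber(
            image, n_abands=config.n_abands, seed=fiber_seed
        )
        table = table.assign(
            muscle_id=row["muscle_id"], fiber_id=row["fiber_id"], group=row["group"],
            rapamycin=row["rapamycin"],
        )
        aband_rows.append(table)
        fiber_rows.append(
            {
                "muscle_id": row["muscle_id"],
                "fiber_id": row["fiber_id"],
                "group": row["group"],
                "rapamycin": row["rapamycin"],
                "mean_net": mean_net,
                "mean_per_10um": float(table["per_10um"].mean()),
            }
        )
    fiber_df = pd.DataFrame(fiber_rows)
    sample = fiber_df.groupby(
        ["muscle_id", "group", "rapamycin"], as_index=False
    )[["mean_net", "mean_per_10um"]].mean()
    return {"abands": pd.concat(aband_rows, ignore_index=True), "fibers": fiber_df, "samples": sample}


def hotspot_stage(
    manifest_path: str | Path, config: PipelineConfig, seed: int = 0
) -> dict:
    """Hotspot detection, positive-fiber calls and paired ROI counts."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    hs_tables, fiber_rows, paired_rows = [], [], []
    for row, image in _iter_images(manifest, manifest_path.parent, config):
        bg = estimate_local_background(
            image.nsp,
            image.fiber_mask,
            image.pixel_pitch,
            window_um=config.background_window_um,
        )
        hotspots = detect_hotspots(
            image.nsp,
            bg,
            image.fiber_mask,
            image.pixel_pitch,
            candidate_fold=config.candidate_fold,
            fold_threshold=config.fold_threshold,
            min_diameter_nm=config.min_diameter_nm,
            max_diameter_nm=config.max_diameter_nm,
            size_measure=config.size_measure,
            smooth_sigma_px=config.detect_smooth_sigma_px,
        )
        tab = hotspot_table(hotspots).assign(
            muscle_id=row["muscle_id"], fiber_id=row["fiber_id"]
        )
        hs_tables.append(tab)
        positive = call_positive_fiber(hotspots, config.positive_min_count)
        fiber_rows.append(
            {
                "muscle_id": row["muscle_id"],
                "fiber_id": row["fiber_id"],
                "group": row["group"],
                "rapamycin": row["rapamycin"],
                "n_hotspots": len(qualifying(hotspots)),
                "positive": positive,
            }
        )
        if positive:
            try:
                rois = classify_rois(
                    image,
                    roi_size_um=config.roi_size_um,
                    disarray_fraction=config.disarray_fraction,
                )
            except ValueError:
                rois = []
            pair_seed = seed * 100003 + _stable_hash(row["muscle_id"], row["fiber_id"])
            pair = hotspots_per_roi_paired(rois, hotspots, seed=pair_seed)
            if pair is not None:
                paired_rows.append(
                    {
                        "muscle_id": row["muscle_id"],
                        "fiber_id": row["fiber_id"],
                        "group": row["group"],
                        "rapamycin": row["rapamycin"],
                        "normal_mean": pair[0],
                        "disarrayed_mean": pair[1],
                    }
                )
    fiber_df = pd.DataFrame(fiber_rows)
    sample_rows = []
    for (muscle, group, rap), sub in fiber_df.groupby(
        ["muscle_id", "group", "rapamycin"]
    ):
        sample_rows.append(
            {
                "muscle_id": muscle,
                "group": group,
                "rapamycin": rap,
                "n_fibers": len(sub),
                "pct_positive": percent_positive_fibers(list(sub["positive"])),
            }
        )
    return {
        "hotspots": pd.concat(hs_tables, ignore_index=True)
        if hs_tables
        else pd.DataFrame(),
        "fibers": fiber_df,
        "paired": pd.DataFrame(paired_rows),
        "samples": pd.DataFrame(sample_rows),
    }


def morphology_stage(
    manifest_path: str | Path, config: PipelineConfig, seed: int = 0
) -> dict:
    """Hotspot morphology classification and per-fiber mixture summary."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    rows, labels_per_fiber = [], []
    for row, image in _iter_images(manifest, manifest_path.parent, config):
        bg = estimate_local_background(
            image.nsp,
            image.fiber_mask,
            image.pixel_pitch,
            window_um=config.background_window_um,
        )
        hotspots = detect_hotspots(
            image.nsp,
            bg,
            image.fiber_mask,
            image.pixel_pitch,
            candidate_fold=config.candidate_fold,
            fold_threshold=config.fold_threshold,
            min_diameter_nm=config.min_diameter_nm,
            max_diameter_nm=config.max_diameter_nm,
            size_measure=config.size_measure,
            smooth_sigma_px=config.detect_smooth_sigma_px,
        )
        morphs, excluded = classify_fiber_hotspots(
            image,
            hotspots,
            tau_span=config.tau_span,
            tau_reg=config.tau_reg,
            expected_sarcomere_um=config.expected_sarcomere_um,
        )
        labels = [m.label for m in morphs]
        if labels:
            labels_per_fiber.append(labels)
        for m in morphs:
            rows.append(
                {
                    "muscle_id": row["muscle_id"],
                    "fiber_id": row["fiber_id"],
                    "group": row["group"],
                    "hotspot_id": m.hotspot_id,
                    "span": m.span,
                    "start_phase": m.start_phase,
                    "end_phase": m.end_phase,
                    "label": m.label,
                    "excluded": False,
                }
            )
        for hid in excluded:
            rows.append(
                {
                    "muscle_id": row["muscle_id"],
                    "fiber_id": row["fiber_id"],
                    "group": row["group"],
                    "hotspot_id": hid,
                    "span": np.nan,
                    "start_phase": np.nan,
                    "end_phase": np.nan,
                    "label": "",
                    "excluded": True,
                }
            )
    mix = (
        summarize_mix(labels_per_fiber, config.min_hotspots_per_fiber)
        if labels_per_fiber
        else pd.DataFrame()
    )
    return {"hotspots": pd.DataFrame(rows), "mix": mix}


def morphometry_stage(
    table: pd.DataFrame, config: PipelineConfig
) -> dict:
    """Single-fiber morphometry: derived counts, curation, and group tests.

    ``table`` is a single-fiber table with columns group, rapamycin,
    fiber_length_um, sarcomere_length_um.  Returns the curated records, the
    exclusion log, relative-to-control summaries and the two-way ANOVA of
    the serial sarcomere number (surgery x rapamycin) when both factors
    vary, else the two-group t test.
    """
    records = single_fiber_records(table)
    kept_parts, logs = [], []
    for keys, sub in records.groupby(["group", "rapamycin"]):
        vals = sub["n_sarcomeres"].to_numpy()
        if len(vals) >= 3:
            kept, log = exclude_outliers(vals, config.outlier_z_threshold)
            log = log.assign(group=keys[0], rapamycin=keys[1])
            logs.append(log)
            keep_mask = np.abs(
                (vals - vals.mean()) / (vals.std(ddof=1) if vals.std(ddof=1) else 1.0)
            ) <= config.outlier_z_threshold
            kept_parts.append(sub[keep_mask])
        else:
            kept_parts.append(sub)
    curated = pd.concat(kept_parts, ignore_index=True)
    control = curated[
        (curated["group"] == "sham") & (curated["rapamycin"] == curated["rapamycin"].iloc[0])
    ]
    rel = curated.copy()
    for col in ("fiber_length_um", "n_sarcomeres"):
        rel[f"{col}_rel"] = normalize_to_control(
            curated[col].to_numpy(), control[col].to_numpy()
        )
    if curated["rapamycin"].nunique() > 1:
        result = compare_groups(
            "anova2",
            curated.rename(columns={"n_sarcomeres": "value"}),
            value="value",
            factor_a="group",
            factor_b="rapamycin",
        )
    else:
        result = compare_groups(
            "t",
            curated.rename(columns={"n_sarcomeres": "value"}),
            value="value",
            group="group",
        )
    exclusions = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["index", "value", "z_score", "group", "rapamycin"])
    )
    return {
        "records": curated,
        "relative": rel,
        "exclusions": exclusions,
        "test": result,
    }
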