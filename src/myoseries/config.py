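"""Pipeline configuration: a flat, versioned key-value document.

Unknown keys are a hard error so that misspelled options never fall back to
silent defaults.  Units are encoded in the key names (``_um``, ``_nm``,
``_deg``).  Every analysis stage writes the fully resolved configuration and
the package version next to its outputs.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

try:
    PACKAGE_VERSION = pkg_version("myoseries")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    PACKAGE_VERSION = "0.0.0+source"

CONFIG_SCHEMA_VERSION = 1


class PipelineConfig(BaseModel):
    """All tunable analysis parameters, flat and fully resolved."""

    model_config = ConfigDict(extra="forbid")

    config_version: int = CONFIG_SCHEMA_VERSION
    # acquisition
    pixel_pitch_um: float = 0.103
    channel_zline: int = 0
    channel_nsp: int = 1
    # continuous Z-line length
    roi_rows_px: int = 200
    roi_cols_px: int = 400
    n_rois_per_fiber: int = 1
    theta_max_deg: float = 20.0
    zline_weighting: str = "unweighted"  # or "length"
    min_line_length_um: float = 0.0
    ridge_sigma_um: float = 0.15
    # split counting
    n_abands: int = 40
    # hotspot detection
    background_window_um: float = 5.0
    candidate_fold: float = 1.5
    fold_threshold: float = 2.0
    min_diameter_nm: float = 400.0
    max_diameter_nm: float = 1900.0
    size_measure: str = "min_feret"  # or "equivalent_diameter" / "max_feret"
    detect_smooth_sigma_px: float = 1.5
    positive_min_count: int = 2
    # ROI classification and pairing
    roi_size_um: float = 10.0
    disarray_fraction: float = 0.6
    # morphology classification
    tau_span: float = 0.25
    tau_reg: float = 0.25
    expected_sarcomere_um: float = 2.4
    min_hotspots_per_fiber: int = 1
    # morphometry
    outlier_z_threshold: float = 3.0
    sarcomere_profile_segments: int = 3


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON config file; unknown keys raise."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    return PipelineConfig(**raw)


def dump_config(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write the resolved config + package version next to stage outputs."""
    out = Path(out_dir) / "config_used.json"
    doc = {"package_version": PACKAGE_VERSION, **config.model_dump()}
    out.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return out
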