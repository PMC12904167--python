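"""Synthetic striated-fiber images and single-fiber cohorts with planted ground truth.

The generator emulates longitudinally sectioned fast-twitch muscle fibers imaged
for alpha-actinin (channel 0, periodic Z-line striations) and newly synthesized
proteins (channel 1, NSP click label).  The fiber axis runs along image columns,
so Z-lines appear as near-vertical bright ridges spaced one sarcomere length
apart.  Every planted feature is recorded in a :class:`GroundTruth` object that
downstream recovery tests use as their oracle.

Planted features
----------------
* **Transverse splits** - a Y-shaped bifurcation of the Z-lines bounding one
  inter-Z-line gap (A-band).  On the lateral side beyond ``lateral_fraction``
  the gap carries one extra in-series sarcomere: the two bounding Z-lines are
  displaced by -SL/4 and +SL/4 and a daughter Z-line appears at the gap
  center, giving a locally uniform 3/4-sarcomere spacing and the misaligned
  appearance that depresses the continuous Z-line length.
* **NSP hotspots** - rectangular blobs in the NSP channel whose axial span and
  Z-line registration follow one of five sarcomerogenesis morphologies
  (``yu``: one sarcomere Z-to-Z; ``rodier``: two sarcomeres Z-to-Z;
  ``hzone``: one sarcomere centered on a Z-line; plus short/long atypical).
  The mean intensity over the blob mask equals ``fold`` x the NSP background,
  matching the operand of the downstream fold-enrichment detection rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.ndimage import gaussian_filter

from .image import CHANNEL_NSP, CHANNEL_ZLINE, FiberImage

GROUND_TRUTH_SCHEMA_VERSION = 1

HOTSPOT_CLASSES = ("yu", "rodier", "hzone", "short_atypical", "long_atypical")
HotspotClass = Literal["yu", "rodier", "hzone", "short_atypical", "long_atypical"]


# --------------------------------------------------------------------------- #
# specifications
# --------------------------------------------------------------------------- #


class ImageSpec(BaseModel):
    """Raster geometry, optics and noise of one synthetic acquisition.

    The default pixel pitch of 0.103 µm/px reproduces the acquisition scale at
    which a 200 x 400 px selection covers 20.6 x 41.2 µm.
    """

    model_config = ConfigDict(extra="forbid")

    pixel_pitch: float = 0.103  # µm per pixel
    shape: tuple[int, int] = (320, 448)  # (rows, cols)
    psf_sigma: float = 0.15  # µm; Gaussian PSF applied by add_noise
    gaussian_sd: float = 10.0  # additive read-noise SD, intensity units
    poisson_gain: float = 1.0  # photons per intensity unit; 0 disables shot noise
    seed: int = 0

    @field_validator("pixel_pitch")
    @classmethod
    def _pitch_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("pixel_pitch must be > 0")
        return v

    @field_validator("psf_sigma", "gaussian_sd", "poisson_gain")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise parameters must be >= 0")
        return v

    @field_validator("shape")
    @classmethod
    def _shape_min(cls, v: tuple[int, int]) -> tuple[int, int]:
        if min(v) < 64:
            raise ValueError("image dimensions must be >= 64 px")
        return v


class FiberModel(BaseModel):
    """Geometry and photometry of one straight, horizontally oriented fiber.

    ``lateral_phase_break`` applies a pure lateral shear: every Z-line in rows
    beyond ``fraction`` of the fiber width is shifted axially by ``shift_um``.
    It exists to build misalignment-only configurations (broken striations
    without Y-branches), e.g. every Z-line bisected at mid-width.
    """

    model_config = ConfigDict(extra="forbid")

    axis_row_um: Optional[float] = None  # fiber center row; image center if None
    width_um: float = 30.0
    sarcomere_length_um: float = 2.4
    zline_intensity: float = 1000.0
    aband_intensity: float = 300.0
    background_intensity: float = 50.0
    nsp_background: float = 100.0  # NSP channel level inside the fiber
    nsp_outside: float = 20.0
    zline_sigma_um: float = 0.08  # rendered ridge Gaussian half-width
    axial_phase_um: float = 0.0  # shifts the whole striation pattern
    lateral_phase_break: Optional[tuple[float, float]] = None  # (fraction, shift_um)

    @field_validator("width_um", "sarcomere_length_um")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("fiber geometry values must be > 0")
        return v

    @model_validator(mode="after")
    def _intensity_order(self) -> "FiberModel":
        if not (
            self.zline_intensity > self.aband_intensity >= self.background_intensity
        ):
            raise ValueError(
                "intensities must satisfy zline > aband >= background"
            )
        return self


class SplitEvent(BaseModel):
    """One planted transverse split.

    ``aband_index`` names the inter-Z-line gap that gains (sense +1) or loses
    (sense -1) one in-series sarcomere on the lateral side beyond
    ``lateral_fraction`` of the fiber width.
    """

    model_config = ConfigDict(extra="forbid")

    aband_index: int
    lateral_fraction: float
    sense: Literal[1, -1] = 1

    @field_validator("lateral_fraction")
    @classmethod
    def _interior(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("lateral_fraction must lie strictly inside (0, 1)")
        return v


class HotspotSpec(BaseModel):
    """One planted NSP hotspot.

    ``diameter_nm`` is the target short-axis (lateral) width of the rendered
    blob, the measure by which detection gates hotspot size; the axial extent
    is fixed by the morphology class.
    ``span_sarcomeres`` applies to the atypical classes only (short < 2,
    long > 2, in units of the local sarcomere length).
    """

    model_config = ConfigDict(extra="forbid")

    model_class: HotspotClass
    anchor_sarcomere: int
    lateral_fraction: float = 0.5
    diameter_nm: float = 1500.0
    fold: float = 3.0
    span_sarcomeres: Optional[float] = None

    @field_validator("diameter_nm", "fold")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("diameter_nm and fold must be > 0")
        return v

    @model_validator(mode="after")
    def _span_rules(self) -> "HotspotSpec":
        if self.model_class == "short_atypical":
            if self.span_sarcomeres is None:
                object.__setattr__(self, "span_sarcomeres", 1.5)
            if not self.span_sarcomeres < 2:
                raise ValueError("short_atypical span must be < 2 sarcomeres")
        elif self.model_class == "long_atypical":
            if self.span_sarcomeres is None:
                object.__setattr__(self, "span_sarcomeres", 3.4)
            if not self.span_sarcomeres > 2:
                raise ValueError("long_atypical span must be > 2 sarcomeres")
        elif self.span_sarcomeres is not None:
            raise ValueError(
                "span_sarcomeres applies only to the atypical classes; "
                f"{self.model_class} has a fixed span"
            )
        return self


# --------------------------------------------------------------------------- #
# realized ground truth
# --------------------------------------------------------------------------- #


class RealizedSplit(BaseModel):
    model_config = ConfigDict(extra="forbid")

    event: SplitEvent
    row_px: float  # lateral coordinate where the extra sarcomere is fully formed
    gap_center_col_px: float  # axial center of the affected gap (base geometry)


class RealizedHotspot(BaseModel):
    model_config = ConfigDict(extra="forbid")

    spec: HotspotSpec
    label: HotspotClass
    bbox: tuple[int, int, int, int]  # (rmin, rmax, cmin, cmax), inclusive
    n_pixels: int
    value: float  # rendered blob intensity (= fold x nsp background)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rmin, rmax, cmin, cmax = self.bbox
        m[rmin : rmax + 1, cmin : cmax + 1] = True
        return m


class GroundTruth(BaseModel):
    """Exact record of every planted feature, in realized pixel coordinates."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = GROUND_TRUTH_SCHEMA_VERSION
    image_spec: ImageSpec
    fiber: FiberModel
    splits: list[RealizedSplit] = Field(default_factory=list)
    hotspots: list[RealizedHotspot] = Field(default_factory=list)
    zline_positions: list[list[float]] = Field(default_factory=list)
    base_zline_cols_px: list[float] = Field(default_factory=list)
    fiber_rows: tuple[int, int] = (0, 0)  # [top, bottom) row range of the fiber

    def n_zlines_at_row(self, row: int) -> int:
        """Planted Z-line count in the lateral column at ``row``.

        Equals the base count plus the signed sum of split events whose fully
        formed side contains ``row`` (the conservation bookkeeping that the
        rendered raster must reproduce outside transition zones).
        """
        n = len(self.base_zline_cols_px)
        for s in self.splits:
            if s.event.sense == 1 and row >= s.row_px:
                n += 1
            elif s.event.sense == -1 and row <= s.row_px:
                n += 1
        return n

    def signed_split_sum(self) -> int:
        return sum(s.event.sense for s in self.splits)


# --------------------------------------------------------------------------- #
# geometry
# --------------------------------------------------------------------------- #


@dataclass
class _FiberFrame:
    """Pixel-space geometry shared by the renderer and the planting logic."""

    row_top: int
    row_bottom: int  # exclusive
    sl_px: float
    base_cols: np.ndarray  # base Z-line axial positions, px

    @property
    def width_px(self) -> int:
        return self.row_bottom - self.row_top

    @property
    def n_gaps(self) -> int:
        return len(self.base_cols) - 1


def _fiber_frame(spec: ImageSpec, fiber: FiberModel) -> _FiberFrame:
    rows, cols = spec.shape
    sl_px = fiber.sarcomere_length_um / spec.pixel_pitch
    width_px = int(round(fiber.width_um / spec.pixel_pitch))
    center = (
        rows / 2.0
        if fiber.axis_row_um is None
        else fiber.axis_row_um / spec.pixel_pitch
    )
    top = int(round(center - width_px / 2.0))
    bottom = top + width_px
    if top < 0 or bottom > rows:
        raise ValueError(
            f"fiber of width {width_px} px does not fit in {rows} image rows"
        )
    x0 = 0.75 * sl_px + fiber.axial_phase_um / spec.pixel_pitch
    n_lines = int(math.floor((cols - 0.75 * sl_px - x0) / sl_px)) + 1
    if n_lines < 3:
        raise ValueError("image too narrow for at least three Z-lines")
    base_cols = x0 + sl_px * np.arange(n_lines)
    return _FiberFrame(top, bottom, sl_px, base_cols)


def _validate_splits(frame: _FiberFrame, splits: list[SplitEvent]) -> None:
    seen: set[int] = set()
    for s in splits:
        if not (0 <= s.aband_index < frame.n_gaps):
            raise ValueError(
                f"split aband_index {s.aband_index} outside 0..{frame.n_gaps - 1}"
            )
        if s.aband_index in seen:
            raise ValueError(
                f"two splits planted in the same gap {s.aband_index}; "
                "one split per inter-Z-line gap is supported"
            )
        seen.add(s.aband_index)


def _split_weight(frame: _FiberFrame, split: SplitEvent, row: float) -> float:
    """Y-branch interpolation weight at a lateral row.

    1 on the fully formed side of the split, 0 outside, linear over a
    one-sarcomere-wide transition band adjacent to the realized row.
    """
    r0 = frame.row_top + split.lateral_fraction * frame.width_px
    t = frame.sl_px
    if split.sense == 1:
        return float(np.clip((row - (r0 - t)) / t, 0.0, 1.0))
    return float(np.clip(((r0 + t) - row) / t, 0.0, 1.0))


def _row_zline_positions(
    frame: _FiberFrame, fiber_shift_px: float, splits: list[SplitEvent], row: int
) -> np.ndarray:
    """Axial Z-line positions (px) in one lateral row, all splits applied."""
    offsets = np.zeros_like(frame.base_cols)
    weights = []
    for s in splits:
        w = _split_weight(frame, s, row)
        weights.append(w)
        if w <= 0.0:
            continue
        k = s.aband_index
        offsets[k] -= 0.25 * frame.sl_px * w
        offsets[k + 1] += 0.25 * frame.sl_px * w
    daughters: list[float] = []
    for s, w in zip(splits, weights):
        if w <= 0.0:
            continue
        k = s.aband_index
        # the daughter emanates from its parent line's current position
        # (parent offset excluding this split's own -SL/4 contribution), so
        # the Y stays attached even when a neighboring split is active
        parent_other = offsets[k] + 0.25 * frame.sl_px * w
        daughters.append(
            frame.base_cols[k]
            + parent_other
            + w * (0.5 * frame.sl_px - parent_other)
        )
    pos = np.concatenate([frame.base_cols + offsets, np.asarray(daughters)])
    pos = np.sort(pos) + fiber_shift_px
    return pos


def _phase_break_shift(
    frame: _FiberFrame, fiber: FiberModel, pitch: float, row: int
) -> float:
    if fiber.lateral_phase_break is None:
        return 0.0
    fraction, shift_um = fiber.lateral_phase_break
    if row >= frame.row_top + fraction * frame.width_px:
        return shift_um / pitch
    return 0.0


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #


def _hotspot_axial_bounds(
    frame: _FiberFrame, spec: HotspotSpec, zcols: np.ndarray
) -> tuple[float, float]:
    a = spec.anchor_sarcomere
    needed = a + (2 if spec.model_class in ("rodier", "hzone") else 1)
    if a < 0 or needed >= len(zcols):
        raise ValueError(
            f"hotspot anchor_sarcomere {a} ({spec.model_class}) needs Z-lines "
            f"up to index {needed}, image has {len(zcols)}"
        )
    if spec.model_class == "yu":
        return zcols[a], zcols[a + 1]
    if spec.model_class == "rodier":
        return zcols[a], zcols[a + 2]
    if spec.model_class == "hzone":
        return (zcols[a] + zcols[a + 1]) / 2.0, (zcols[a + 1] + zcols[a + 2]) / 2.0
    # atypical classes: centered on the Z-line bounding the anchor sarcomere
    half = 0.5 * spec.span_sarcomeres * frame.sl_px
    center = zcols[a + 1] if a + 1 < len(zcols) else zcols[a]
    return center - half, center + half


def _realize_hotspot(
    frame: _FiberFrame,
    image_spec: ImageSpec,
    fiber: FiberModel,
    spec: HotspotSpec,
    splits: list[SplitEvent],
) -> RealizedHotspot:
    pitch_nm = image_spec.pixel_pitch * 1000.0
    center_row = frame.row_top + spec.lateral_fraction * frame.width_px
    shift = _phase_break_shift(frame, fiber, image_spec.pixel_pitch, int(center_row))
    # anchor indexing refers to the base (unsplit) lattice
    base = frame.base_cols + shift
    c0, c1 = _hotspot_axial_bounds(frame, spec, base)
    # the spec diameter is the blob's short axis (lateral width)
    lat_px = max(2.0, spec.diameter_nm / pitch_nm)
    rmin = int(round(center_row - lat_px / 2.0))
    rmax = int(round(center_row + lat_px / 2.0)) - 1
    cmin, cmax = int(round(c0)), int(round(c1))
    if rmin < frame.row_top or rmax >= frame.row_bottom:
        raise ValueError("hotspot extends outside the fiber laterally")
    if cmin < 0 or cmax >= image_spec.shape[1]:
        raise ValueError("hotspot extends outside the image axially")
    n_pixels = (rmax - rmin + 1) * (cmax - cmin + 1)
    return RealizedHotspot(
        spec=spec,
        label=spec.model_class,
        bbox=(rmin, rmax, cmin, cmax),
        n_pixels=n_pixels,
        value=spec.fold * fiber.nsp_background,
    )


def render_fiber(
    spec: ImageSpec,
    fiber: FiberModel,
    splits: list[SplitEvent] | None = None,
    hotspots: list[HotspotSpec] | None = None,
    merge_policy: Literal["reject", "allow"] = "reject",
) -> tuple[FiberImage, GroundTruth]:
    """Render a noise-free two-channel fiber image with planted ground truth.

    The returned raster carries no PSF blur or noise; apply
    :func:`add_noise` for a realistic acquisition.  With
    ``merge_policy="reject"`` (default), planted hotspots whose masks would
    fuse into a single connected component raise a ``ValueError`` so that
    one-to-one recovery against the ground truth stays unambiguous;
    ``"allow"`` renders them anyway (used to study merged morphologies).
    """
    splits = list(splits or [])
    hotspots = list(hotspots or [])
    frame = _fiber_frame(spec, fiber)
    _validate_splits(frame, splits)

    rows, cols = spec.shape
    col_idx = np.arange(cols, dtype=np.float64)
    sigma_px = max(fiber.zline_sigma_um / spec.pixel_pitch, 0.35)

    ch0 = np.full((rows, cols), fiber.background_intensity, dtype=np.float64)
    zline_positions: list[list[float]] = []
    for r in range(rows):
        if not (frame.row_top <= r < frame.row_bottom):
            zline_positions.append([])
            continue
        shift = _phase_break_shift(frame, fiber, spec.pixel_pitch, r)
        pos = _row_zline_positions(frame, shift, splits, r)
        pos = pos[(pos >= 0) & (pos <= cols - 1)]
        zline_positions.append([float(p) for p in pos])
        profile = np.zeros(cols)
        for p in pos:
            lo = max(0, int(p - 5 * sigma_px))
            hi = min(cols, int(p + 5 * sigma_px) + 1)
            profile[lo:hi] += np.exp(
                -0.5 * ((col_idx[lo:hi] - p) / sigma_px) ** 2
            )
        np.clip(profile, 0.0, 1.0, out=profile)
        ch0[r] = fiber.aband_intensity + (
            fiber.zline_intensity - fiber.aband_intensity
        ) * profile

    fiber_mask = np.zeros((rows, cols), dtype=bool)
    fiber_mask[frame.row_top : frame.row_bottom] = True

    ch1 = np.full((rows, cols), fiber.nsp_outside, dtype=np.float64)
    ch1[fiber_mask] = fiber.nsp_background
    realized_hotspots = [
        _realize_hotspot(frame, spec, fiber, h, splits) for h in hotspots
    ]
    if merge_policy == "reject":
        for i in range(len(realized_hotspots)):
            for j in range(i + 1, len(realized_hotspots)):
                ri, rj = realized_hotspots[i].bbox, realized_hotspots[j].bbox
                if (
                    ri[0] <= rj[1] + 1
                    and rj[0] <= ri[1] + 1
                    and ri[2] <= rj[3] + 1
                    and rj[2] <= ri[3] + 1
                ):
                    raise ValueError(
                        f"planted hotspots {i} and {j} would merge into one "
                        "connected component; ground truth would be ambiguous "
                        "(pass merge_policy='allow' to render anyway)"
                    )
    for h in realized_hotspots:
        rmin, rmax, cmin, cmax = h.bbox
        ch1[rmin : rmax + 1, cmin : cmax + 1] = h.value

    realized_splits = []
    for s in splits:
        realized_splits.append(
            RealizedSplit(
                event=s,
                row_px=frame.row_top + s.lateral_fraction * frame.width_px,
                gap_center_col_px=float(
                    (frame.base_cols[s.aband_index] + frame.base_cols[s.aband_index + 1])
                    / 2.0
                ),
            )
        )

    image = FiberImage(
        data=np.stack([ch0, ch1]),
        pixel_pitch=spec.pixel_pitch,
        fiber_mask=fiber_mask,
        meta={"image_spec": spec.model_dump(), "fiber": fiber.model_dump()},
    )
    truth = GroundTruth(
        image_spec=spec,
        fiber=fiber,
        splits=realized_splits,
        hotspots=realized_hotspots,
        zline_positions=zline_positions,
        base_zline_cols_px=[float(c) for c in frame.base_cols],
        fiber_rows=(frame.row_top, frame.row_bottom),
    )
    return image, truth


def add_noise(image: FiberImage, spec: ImageSpec) -> FiberImage:
    """Apply PSF blur followed by Poisson-Gaussian noise; fully seeded.

    With ``psf_sigma = gaussian_sd = poisson_gain = 0`` the output equals the
    input.  Identical (image, spec) pairs produce bit-identical arrays.
    """
    out = image.copy()
    sigma_px = spec.psf_sigma / spec.pixel_pitch
    if sigma_px > 0:
        for c in range(out.data.shape[0]):
            out.data[c] = gaussian_filter(out.data[c], sigma_px, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    if spec.poisson_gain > 0:
        counts = rng.poisson(np.clip(out.data, 0, None) * spec.poisson_gain)
        out.data = counts / spec.poisson_gain
    if spec.gaussian_sd > 0:
        out.data = out.data + rng.normal(0.0, spec.gaussian_sd, out.data.shape)
    out.meta["noise_applied"] = spec.model_dump()
    return out


# --------------------------------------------------------------------------- #
# cohort simulation
# --------------------------------------------------------------------------- #


class CohortConfig(BaseModel):
    """Study-design parameters for a two-group (sham vs MOV) imaging cohort.

    Split densities are expressed as splits per A-band per 10 µm of fiber
    width, i.e. the expected number of split events an A-band traced across
    the full width of a 10-µm-wide fiber would cross.  The defaults encode the
    study contrast used throughout the package: a 4.9-fold higher split
    density and a ~60% vs ~5% hotspot-positive fiber rate under overload.
    With ``planting="exact"`` the per-fiber split count is the rounded
    expectation (quota planting, minimal sampling noise); ``"poisson"`` draws
    it from a Poisson law.
    """

    model_config = ConfigDict(extra="forbid")

    n_muscles_per_group: int = 3
    fibers_per_muscle: int = 10
    split_density_sham: float = 0.05  # splits / A-band / 10 µm width
    split_density_mov: float = 0.245  # 4.9 x sham
    planting: Literal["exact", "poisson"] = "exact"
    hotspot_positive_fraction_sham: float = 0.05
    hotspot_positive_fraction_mov: float = 0.60
    hotspots_per_positive_fiber: int = 4
    hotspot_class_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "yu": 0.695,
            "rodier": 0.17,
            "hzone": 0.003,
            "short_atypical": 0.044,
            "long_atypical": 0.088,
        }
    )
    hotspot_split_affinity: float = 0.75  # fraction anchored at split gaps
    include_rapamycin_arm: bool = False
    image_spec: ImageSpec = Field(default_factory=ImageSpec)
    fiber: FiberModel = Field(default_factory=FiberModel)
    noise: bool = True

    @field_validator("hotspot_class_mix")
    @classmethod
    def _mix_valid(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(HOTSPOT_CLASSES)
        if unknown:
            raise ValueError(f"unknown hotspot classes in mix: {sorted(unknown)}")
        total = sum(v.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"hotspot_class_mix must sum to 1, got {total}")
        return v


@dataclass
class CohortRecord:
    muscle_id: str
    fiber_id: str
    group: str  # "sham" | "mov"
    rapamycin: str  # "veh" | "rap"
    image: FiberImage
    truth: GroundTruth


@dataclass
class CohortDataset:
    records: list[CohortRecord]
    config: CohortConfig

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "muscle_id": r.muscle_id,
                    "fiber_id": r.fiber_id,
                    "group": r.group,
                    "rapamycin": r.rapamycin,
                    "path": f"{r.muscle_id}_{r.fiber_id}.tif",
                }
                for r in self.records
            ]
        )


def _plant_splits(
    frame: _FiberFrame,
    density: float,
    width_um: float,
    planting: str,
    rng: np.random.Generator,
) -> list[SplitEvent]:
    lam = density * width_um / 10.0  # expected events per A-band trace
    expected = lam * frame.n_gaps
    n = int(round(expected)) if planting == "exact" else int(rng.poisson(expected))
    if n > frame.n_gaps:
        raise ValueError(
            f"requested {n} splits but the fiber has only {frame.n_gaps} "
            "inter-Z-line gaps (one split per gap); lower the density"
        )
    gaps = rng.choice(frame.n_gaps, size=n, replace=False)
    return [
        SplitEvent(
            aband_index=int(g),
            lateral_fraction=float(rng.uniform(0.15, 0.85)),
            sense=1,
        )
        for g in sorted(gaps)
    ]


def _plant_hotspots(
    frame: _FiberFrame,
    config: CohortConfig,
    splits: list[SplitEvent],
    positive_fraction: float,
    rng: np.random.Generator,
) -> list[HotspotSpec]:
    if rng.uniform() < positive_fraction:
        n = config.hotspots_per_positive_fiber
    else:
        n = int(rng.uniform() < 0.3)  # occasional isolated (sub-threshold) locus
    classes = list(config.hotspot_class_mix)
    probs = np.array([config.hotspot_class_mix[c] for c in classes])
    split_gaps = [s.aband_index for s in splits]
    out: list[HotspotSpec] = []
    used_anchors: set[int] = set()
    max_anchor = frame.n_gaps - 3  # leave room for two-sarcomere morphologies
    attempts = 0
    while len(out) < n and attempts < 50 * max(n, 1):
        attempts += 1
        if split_gaps and rng.uniform() < config.hotspot_split_affinity:
            anchor = int(rng.choice(split_gaps))
        else:
            anchor = int(rng.integers(1, max(max_anchor, 2)))
        anchor = min(max(anchor, 1), max_anchor)
        # keep anchors 3+ gaps apart so blobs never touch (one-to-one recovery)
        if any(abs(anchor - a) < 4 for a in used_anchors):
            continue
        used_anchors.add(anchor)
        label = classes[int(rng.choice(len(classes), p=probs))]
        out.append(
            HotspotSpec(
                model_class=label,
                anchor_sarcomere=anchor,
                lateral_fraction=float(rng.uniform(0.25, 0.75)),
                diameter_nm=float(rng.uniform(1100.0, 1700.0)),
                fold=float(rng.uniform(2.5, 4.0)),
            )
        )
    return out


def simulate_cohort(config: CohortConfig, seed: int) -> CohortDataset:
    """Generate a reproducible sham/MOV imaging cohort with ground truth.

    Every fiber gets its own child seed derived from ``seed`` via
    ``numpy.random.SeedSequence``, so the dataset is fully determined by
    (config, seed) while individual fibers remain statistically independent.
    """
    root = np.random.SeedSequence(seed)
    arms = ["veh", "rap"] if config.include_rapamycin_arm else ["veh"]
    groups = ["sham", "mov"]
    records: list[CohortRecord] = []
    n_fibers = (
        len(arms) * len(groups) * config.n_muscles_per_group * config.fibers_per_muscle
    )
    children = root.spawn(n_fibers)
    i = 0
    for rap in arms:
        for group in groups:
            density = (
                config.split_density_mov
                if group == "mov"
                else config.split_density_sham
            )
            pos_frac = (
                config.hotspot_positive_fraction_mov
                if group == "mov"
                else config.hotspot_positive_fraction_sham
            )
            for m in range(config.n_muscles_per_group):
                muscle_id = f"{group}_{rap}_m{m + 1}"
                for f in range(config.fibers_per_muscle):
                    child = children[i]
                    i += 1
                    rng = np.random.default_rng(child)
                    frame = _fiber_frame(config.image_spec, config.fiber)
                    splits = _plant_splits(
                        frame, density, config.fiber.width_um, config.planting, rng
                    )
                    hotspots = _plant_hotspots(frame, config, splits, pos_frac, rng)
                    spec = config.image_spec.model_copy(
                        update={"seed": int(child.generate_state(1)[0] % (2**31))}
                    )
                    image, truth = render_fiber(spec, config.fiber, splits, hotspots)
                    if config.noise:
                        image = add_noise(image, spec)
                    records.append(
                        CohortRecord(
                            muscle_id=muscle_id,
                            fiber_id=f"f{f + 1}",
                            group=group,
                            rapamycin=rap,
                            image=image,
                            truth=truth,
                        )
                    )
    return CohortDataset(records=records, config=config)


# --------------------------------------------------------------------------- #
# single-fiber cohort tables
# --------------------------------------------------------------------------- #


class SingleFiberTableParams(BaseModel):
    """Group-level parameters of the single-fiber morphometry generator.

    Fiber lengths are lognormal (positive by construction) with the stated
    mean and coefficient of variation.  Sarcomere length is drawn
    independently of group when ``sarcomere_length_unchanged`` is set,
    emulating a design in which overload lengthens fibers purely by adding
    in-series sarcomeres.  The default overload effect is a 7.5% increase in
    mean fiber length with no rapamycin modulation.
    """

    model_config = ConfigDict(extra="forbid")

    fiber_length_mean_sham_um: float = 2400.0
    mov_length_factor: float = 1.075
    rap_length_factor: float = 1.0  # rapamycin-insensitive by default
    sarcomere_length_mean_um: float = 2.4
    sarcomere_length_unchanged: bool = True
    mov_sarcomere_factor: float = 1.0  # used only if unchanged=False
    fiber_length_cv: float = 0.08
    sarcomere_length_cv: float = 0.02
    n_per_group: int = 30
    groups: list[str] = Field(default_factory=lambda: ["sham", "mov"])
    rapamycin_arms: list[str] = Field(default_factory=lambda: ["veh"])
    timepoint_days: int = 8

    @field_validator("fiber_length_cv", "sarcomere_length_cv")
    @classmethod
    def _cv_nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("coefficients of variation must be >= 0")
        return v


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def simulate_single_fiber_table(
    params: SingleFiberTableParams, seed: int
) -> pd.DataFrame:
    """Draw a single-fiber morphometry table (one row per isolated fiber)."""
    rng = np.random.default_rng(seed)
    rows = []
    for rap in params.rapamycin_arms:
        for group in params.groups:
            mean_len = params.fiber_length_mean_sham_um
            if group == "mov":
                mean_len *= params.mov_length_factor
            if rap == "rap":
                mean_len *= params.rap_length_factor
            mean_sl = params.sarcomere_length_mean_um
            if group == "mov" and not params.sarcomere_length_unchanged:
                mean_sl *= params.mov_sarcomere_factor
            lengths = _lognormal(rng, mean_len, params.fiber_length_cv, params.n_per_group)
            sls = _lognormal(
                rng, mean_sl, params.sarcomere_length_cv, params.n_per_group
            )
            for fl, sl in zip(lengths, sls):
                rows.append(
                    {
                        "group": group,
                        "rapamycin": rap,
                        "timepoint_days": params.timepoint_days,
                        "fiber_length_um": float(fl),
                        "sarcomere_length_um": float(sl),
                    }
                )
    return pd.DataFrame(rows)
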