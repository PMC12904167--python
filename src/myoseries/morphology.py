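"""Classifying NSP hotspot morphology against sarcomerogenesis models.

Each qualifying hotspot is measured for its axial span (in units of the local
sarcomere length) and for the registration of its two axial boundaries to the
nearest Z-lines.  The measured morphology is then matched, in order, against
the three candidate mechanisms of in-series sarcomere addition:

* ``yu``     - Z-line splitting of a single sarcomere: the hotspot spans
               exactly one sarcomere, Z-line to Z-line.
* ``rodier`` - Z-line splitting with titin-thick-filament detachment: the
               hotspot spans exactly two in-series sarcomeres, Z to Z.
* ``hzone``  - H-zone splitting: the hotspot occupies the adjacent inner
               halves of two in-series sarcomeres, i.e. one sarcomere length
               centered on the shared Z-line (boundaries mid-sarcomere).

Hotspots matching none of the models are ``short_atypical`` (span < 2) or
``long_atypical`` (span >= 2).  Because two adjacent yu-type events merge
into a blob with rodier geometry, the rule order resolves that ambiguity the
same way the measurement alone would: a two-sarcomere Z-registered blob is
called rodier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .hotspots import Hotspot
from .image import FiberImage
from .morphometry import mean_sarcomere_length_from_profile

LABELS = ("yu", "rodier", "hzone", "short_atypical", "long_atypical")


@dataclass
class SarcomereRegistration:
    """Z-line positions flanking a hotspot along the fiber axis."""

    zline_cols_px: np.ndarray  # ascending axial positions near the hotspot
    local_sarcomere_length_um: float

    def __post_init__(self) -> None:
        if len(self.zline_cols_px) < 2:
            raise ValueError("registration requires at least two flanking Z-lines")
        if self.local_sarcomere_length_um <= 0:
            raise ValueError("local sarcomere length must be positive")


@dataclass
class HotspotMorphology:
    """Measured axial geometry of one hotspot, in sarcomere units."""

    hotspot_id: int
    span: float  # axial extent / local sarcomere length
    start_phase: float  # in [0, 0.5]: boundary distance to nearest Z-line
    end_phase: float
    local_sarcomere_length_um: float
    label: str | None = None


def register_hotspot(
    image: FiberImage,
    hotspot: Hotspot,
    window_sarcomeres: float = 3.0,
    expected_sarcomere_um: float = 2.4,
) -> SarcomereRegistration:
    """Locate the Z-lines flanking a hotspot and the local sarcomere length.

    The Z-line channel is averaged over the hotspot's lateral rows to a 1-D
    axial profile.  The local sarcomere length comes from the profile's
    autocorrelation, refined by the median of plausible inter-peak spacings;
    the flanking Z-line positions are then a lattice at that period whose
    phase is the circular mean of the detected peak positions, which stays
    correct even when individual peaks are missed in noise.  Raises when
    fewer than two Z-line peaks are resolvable at the locus (the morphology
    is then unmeasurable).
    """
    rmin, rmax, cmin, cmax = hotspot.bbox
    profile = image.zline[rmin : rmax + 1].mean(axis=0)
    sl_guess_px = expected_sarcomere_um / image.pixel_pitch
    try:
        sl_um = mean_sarcomere_length_from_profile(
            profile, image.pixel_pitch, min_periods=4
        )
        sl_px = sl_um / image.pixel_pitch
    except ValueError:
        sl_px = sl_guess_px
    prominence = 0.15 * max(np.ptp(profile), 1e-9)
    peaks, _ = find_peaks(
        profile, distance=max(2, int(0.6 * sl_px)), prominence=prominence
    )
    window = window_sarcomeres * sl_px
    near = peaks[(peaks >= cmin - window) & (peaks <= cmax + window)]
    if len(near) < 2:
        raise ValueError(
            f"only {len(near)} Z-lines resolvable near hotspot {hotspot.id}; "
            "morphology unmeasurable"
        )
    spacings = np.diff(near)
    plausible = spacings[(spacings > 0.7 * sl_px) & (spacings < 1.3 * sl_px)]
    if len(plausible):
        sl_px = float(np.median(plausible))
    # lattice phase: circular mean of peak positions modulo the period
    angles = 2.0 * np.pi * near / sl_px
    phase = float(
        np.angle(np.exp(1j * angles).mean()) / (2.0 * np.pi) * sl_px
    ) % sl_px
    k0 = int(np.floor((cmin - window - phase) / sl_px))
    k1 = int(np.ceil((cmax + window - phase) / sl_px))
    lattice = phase + sl_px * np.arange(k0, k1 + 1)
    return SarcomereRegistration(
        zline_cols_px=lattice,
        local_sarcomere_length_um=sl_px * image.pixel_pitch,
    )


def measure_axial_span(
    hotspot: Hotspot,
    registration: SarcomereRegistration,
    pixel_pitch: float,
) -> HotspotMorphology:
    """Project the hotspot mask onto the fiber axis and phase it to Z-lines.

    The axial extent is taken from the mask's column-occupancy profile: only
    columns holding at least half of the modal lateral thickness count, so a
    stray noise pixel fused to the blob cannot stretch the measured span.
    Boundaries are the outer pixel edges; each boundary's phase is its
    distance to the nearest Z-line in units of the local sarcomere length,
    folded into [0, 0.5].
    """
    cols, counts = np.unique(hotspot.coords[:, 1], return_counts=True)
    solid = cols[counts >= 0.5 * counts.max()]
    cmin, cmax = int(solid.min()), int(solid.max())
    x0, x1 = cmin - 0.5, cmax + 0.5
    sl_px = registration.local_sarcomere_length_um / pixel_pitch
    span = (x1 - x0) / sl_px
    z = registration.zline_cols_px

    def phase(x: float) -> float:
        d = float(np.min(np.abs(z - x))) / sl_px
        return min(d, abs(1.0 - d), 0.5) if d <= 1.0 else 0.5

    return HotspotMorphology(
        hotspot_id=hotspot.id,
        span=float(span),
        start_phase=phase(x0),
        end_phase=phase(x1),
        local_sarcomere_length_um=registration.local_sarcomere_length_um,
    )


def classify(
    morph: HotspotMorphology,
    tau_span: float = 0.25,
    tau_reg: float = 0.25,
) -> str:
    """Assign a morphology label; total on measured morphologies.

    Rules, applied in order:

    1. span within ``tau_span`` of 1 and both boundaries Z-registered
       (phases <= ``tau_reg``)            -> ``yu``
    2. span within ``tau_span`` of 2 and both boundaries Z-registered
                                          -> ``rodier``
    3. span within ``tau_span`` of 1 and both boundaries mid-sarcomere
       (phases >= 0.5 - ``tau_reg``)      -> ``hzone``
    4. otherwise ``short_atypical`` when span < 2, else ``long_atypical``.
    """
    registered = morph.start_phase <= tau_reg and morph.end_phase <= tau_reg
    mid = (
        morph.start_phase >= 0.5 - tau_reg and morph.end_phase >= 0.5 - tau_reg
    )
    if abs(morph.span - 1.0) <= tau_span and registered:
        label = "yu"
    elif abs(morph.span - 2.0) <= tau_span and registered:
        label = "rodier"
    elif abs(morph.span - 1.0) <= tau_span and mid:
        label = "hzone"
    elif morph.span < 2.0:
        label = "short_atypical"
    else:
        label = "long_atypical"
    morph.label = label
    return label


def classify_fiber_hotspots(
    image: FiberImage,
    hotspots: list[Hotspot],
    tau_span: float = 0.25,
    tau_reg: float = 0.25,
    expected_sarcomere_um: float = 2.4,
) -> tuple[list[HotspotMorphology], list[int]]:
    """Measure and classify every qualifying hotspot of a fiber image.

    Returns the classified morphologies and the ids of hotspots excluded
    because their local Z-lines could not be resolved.
    """
    morphs: list[HotspotMorphology] = []
    excluded: list[int] = []
    for h in hotspots:
        if not h.qualifies:
            continue
        try:
            reg = register_hotspot(
                image, h, expected_sarcomere_um=expected_sarcomere_um
            )
        except ValueError:
            excluded.append(h.id)
            continue
        m = measure_axial_span(h, reg, image.pixel_pitch)
        classify(m, tau_span=tau_span, tau_reg=tau_reg)
        morphs.append(m)
    return morphs, excluded


def summarize_mix(
    labels_per_fiber: list[list[str]], min_hotspots_per_fiber: int = 1
) -> pd.DataFrame:
    """Per-fiber class proportions and their sample mean +/- SEM.

    Fibers with fewer than ``min_hotspots_per_fiber`` classified hotspots are
    excluded from the summary.  Per-fiber proportions sum to 1.
    Returns a table indexed by class with columns ``mean_proportion``,
    ``sem`` and ``n_fibers``.
    """
    rows = []
    for labels in labels_per_fiber:
        if len(labels) < min_hotspots_per_fiber:
            continue
        counts = {lab: 0 for lab in LABELS}
        for lab in labels:
            if lab not in counts:
                raise ValueError(f"unknown morphology label {lab!r}")
            counts[lab] += 1
        total = len(labels)
        rows.append({lab: counts[lab] / total for lab in LABELS})
    if not rows:
        raise ValueError("no fibers meet the minimum hotspot count")
    per_fiber = pd.DataFrame(rows)
    n = len(per_fiber)
    sem = per_fiber.std(ddof=1) / np.sqrt(n) if n > 1 else per_fiber.iloc[0] * 0.0
    return pd.DataFrame(
        {
            "mean_proportion": per_fiber.mean(),
            "sem": sem,
            "n_fibers": n,
        }
    )
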