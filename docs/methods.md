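# Methods

This note documents the models behind `myoseries`, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not establish about real micrographs.

## Image model and the synthetic generator

A fiber is modeled as a straight horizontal band of width *w* (default
30 µm) in a two-channel raster at pixel pitch 0.103 µm/px — the scale at
which a 200 × 400 px selection covers 20.6 × 41.2 µm.  Channel 0
(α-actinin) is a periodic set of near-vertical Gaussian ridges at the
sarcomere spacing λ (default 2.4 µm, a mid-range resting value for mouse
fast-twitch muscle; the analysis code never hard-codes it) over an A-band
plateau; channel 1 (NSP) is a uniform cytoplasmic background with planted
rectangular hotspot blobs whose *mean* intensity equals `fold` × background,
matching the operand of the detection rule.  Acquisition is emulated by a
Gaussian PSF (σ = 0.15 µm) followed by Poisson shot noise and additive
Gaussian read noise, all seeded; (spec, seed) determines every output bit.

**Transverse splits.**  A split of inter-Z-line gap *k* is rendered as a
Y-branch: on the lateral side beyond `lateral_fraction` of the fiber width
the two bounding Z-lines displace by ∓λ/4 and a daughter Z-line sits at the
former gap center, giving uniform 3λ/4 spacing across the affected three
gaps — one extra in-series sarcomere on that side, with the local
misalignment that shortens traced Z-line segments.  The branch opens over a
one-sarcomere-wide lateral transition band placed *below* the realized
coordinate, so the planted signed count changes exactly at
`lateral_fraction · w` and the conservation oracle
(count per column = base + signed crossings) is exact outside transition
bands.  Daughters emanate from their parent's *current* position, so the Y
stays attached even when a neighboring gap is split.  One split per gap;
senses −1 render the mirror-image merge.  Overlapping hotspots are rejected
by default so planted-vs-detected matching stays one-to-one; a
`merge_policy="allow"` escape hatch exists to study deliberately fused
blobs.

**Hotspot geometry.**  The five morphology classes fix the axial extent
(one sarcomere Z-to-Z; two sarcomeres Z-to-Z; one sarcomere centered on a
Z-line; or an atypical span below/above two sarcomeres) and
`diameter_nm` sets the blob's lateral (short-axis) width.

**Cohorts.**  `simulate_cohort` encodes the study contrast as defaults:
split densities 0.05 vs 0.245 splits per A-band per 10 µm width (a 4.9-fold
ratio), hotspot-positive fiber fractions 0.05 vs 0.60, a class mixture of
69.5% yu / 17% rodier / 0.3% hzone / 4.4% short- and 8.8% long-atypical,
and an optional rapamycin arm that is by construction without effect
(the biology being emulated is rapamycin-insensitive).  With
`planting="exact"` (default) per-fiber counts are the rounded expectation —
quota planting that keeps benchmark effect sizes essentially deterministic —
while `"poisson"` draws them.  The single-fiber table generator draws
lognormal fiber lengths (positivity at a specified CV, default 8%) with a
+7.5% overload effect and a group-independent sarcomere length (2.4 µm,
CV 2%), so longitudinal growth is purely serial sarcomere addition.

**What the generator does not emulate:** curved or tapered fibers, 3-D
section geometry, fiber-type heterogeneity, labeling chemistry artifacts,
spatially varying background, or photobleaching.  Passing the planted-oracle
tests therefore establishes the *correctness of the statistics under the
stated image model*, not performance on arbitrary real tissue; on real data
the tunable thresholds below are the knobs that absorb the difference.

## Continuous Z-line length

Segmentation is Sato ridge enhancement (σ ≈ 0.15 µm, reflect-padded so
border ridges keep their length) with Otsu thresholding, then
skeletonization.  The skeleton is decomposed into branchless arcs; branch
points (degree ≥ 3) always terminate segments, and arcs are further cut
wherever the orientation turns by more than θ_max (default 20°, chosen to
break at split-induced kinks while tolerating PSF wobble).  Turns are
measured between chords of half-width 4 px; pixels closer than one chord to
a path end are not tested, because shorter chords alias the 45° quantization
of 8-connected walks into spurious turns.  Every skeleton pixel belongs to
exactly one segment (branch pixels attach to one incident arc,
deterministically), segment length is the path arc length × pixel pitch,
and single-pixel segments legitimately contribute zero length (a
configurable minimum-length floor exists, default 0).  The per-ROI statistic
is the unweighted mean over segments; a length-weighted variant (Σl²/Σl) is
available.  With θ_max = 180° and no branch points the segments reduce to
the skeleton's connected components.

## A-band tracing and net split counts

The tracer follows one inter-Z-line gap laterally through per-row ridge
runs, matching each boundary to the nearest run within 3 px (5 missed rows
tolerated before the trace is flagged incomplete and its count reported as a
lower bound).  A persistent new ridge strictly inside the gap is a
**bifurcation** (+1); the trace continues in the sub-gap containing the
previous center, ties breaking to the left.  Boundaries converging within
4 px are a **merge** (−1); the trace continues in the gap holding the
previous center.  At a Y-branch the two ridges first fuse into one
anomalously wide run whose center drifts before separating again; when a
boundary then faces a freshly separated pair it re-binds to the axially
earlier member whenever that member is a plausible continuation.  Because
daughters wedge toward increasing axial coordinate in the rendered geometry,
this attributes every branch event to exactly one A-band; in tissue without
that chirality the worst case is attribution to the adjacent A-band, leaving
fiber totals unchanged.  Net = |bifurcations − merges|, which on planted
data equals the change in in-series sarcomere count across the width.
Per fiber, 40 A-bands (or all available, with a warning) are selected
uniformly without duplicates at the fiber mid-row, seeded; counts are
normalized per 10 µm of width, and the absolute width is also reported.

## Hotspot detection and ROI pairing

The local background is a rank filter at the 45th percentile (the median
after discarding the brightest 10% of the window) over a 5-µm window —
about two sarcomeres, large enough that a hotspot cannot inflate its own
background, small enough to track fiber-scale gradients — restricted to the
fiber mask and computed on a 2× downsampled grid for speed.  Candidates are
8-connected components above 1.5× background: deliberately below the
qualification fold so near-threshold loci are reported with reason codes
rather than silently vanishing.  Each candidate is measured on its level set
at 2.0× background, whose blurred edge sits near the true blob boundary.
Qualification requires fold ≥ 2.0 **and** a short-axis (min-Feret) width of
400–1900 nm, all gates inclusive.  The short axis is the default size
measure because the 400–1900 nm bounds describe how wide a sarcomere-scale
locus is *across*, irrespective of how many sarcomeres it spans axially: an
area-equivalent diameter would geometrically disqualify any blob longer than
about 2.3 sarcomeres, contradicting the existence of qualifying long-streak
morphologies.  Equivalent-area and max-Feret measures remain available by
configuration.  A fiber is hotspot-positive with ≥ 2 qualifying loci
("multiple", configurable).

For the disarray association, the fiber is tiled into 100-µm² square ROIs,
each analyzed locally for its mean continuous Z-line length; an ROI is
*disarrayed* below 0.6× the fiber-level median of ROI means (the factor
motivated by the ~40% disarray-induced reduction the statistic is designed
to capture), unclassifiable tiles are excluded, and equal seeded samples of
each class are compared as paired per-fiber means; fibers lacking one class
are excluded from pairing.

## Morphology classification

The Z-line channel is averaged over the hotspot's rows into an axial
profile.  The local sarcomere length comes from the profile's
autocorrelation (sub-pixel, parabolic interpolation), refined by the median
of inter-peak spacings within ±30% of it; boundary phases are measured
against a Z-line *lattice* at that period whose phase is the circular mean
of the detected peaks — robust to individual peaks lost in noise.  The
axial span uses the mask's column-occupancy profile (columns holding ≥ half
the modal lateral thickness), so a stray noise pixel cannot stretch the
span.  Hotspots with fewer than two resolvable Z-line peaks are excluded
with a reason and never enter the mixture denominator.  Classification
applies the rules in the order one-sarcomere-Z-registered →
two-sarcomere-Z-registered → Z-centered, with τ_span = τ_reg = 0.25
sarcomere (halfway between the ideal classes; exposed in config).  With
τ_span < 0.5 the three model regions are pairwise disjoint up to the shared
phase boundary.  The ordering resolves the known degeneracy that two
adjacent one-sarcomere events merge into a blob with exact two-sarcomere
geometry: such a blob is called rodier, never hzone.  Per-fiber class
proportions sum to 1; the sample summary is mean ± SEM over fibers with at
least the configured minimum of classified hotspots.

## Morphometry and statistics

Serial sarcomere number is the exact quotient fiber length / mean sarcomere
length (never rounded).  Sarcomere length per fiber is the mean of three
seeded axial line profiles, each requiring ≥ 10 periods and an
autocorrelation peak above the noise floor.  Outlier exclusion is a single
pass per group with a strict > 3 sample-SD rule (a value at exactly 3 SD is
retained); re-application could exclude more and is deliberately not
iterated.  Normalization divides by the control-group mean.  The test
battery dispatches to Student's and paired t tests, one-way ANOVA with
Tukey HSD, two-way ANOVA with Type II sums of squares (chosen for the
unbalanced group sizes typical of such designs) and Fisher's LSD within
factor levels using the model MSE, and two-way repeated-measures ANOVA for
paired ROI-class data.  The two-way F statistics are verified in the test
suite against an independently written nested least-squares oracle to 1e-8,
and the full generator → morphometry → t-test pipeline holds its type-I
error within [0.03, 0.07] at α = 0.05 over 2000 null replicates.

## Problem sizes and reproducibility

Default rasters are 320 × 448 px (320 × 1024 px for the 40-A-band split
cohorts); acceptance-style checks use 10–20 ROIs per condition, 8
fibers/group for fold-change recovery, 50 renders per morphology class, 60+
seeded images for detection recall, and 1000–2000 replicates for the
statistical calibrations — sizes at which every planted effect is resolved
with comfortable margin by a desktop CPU.  All randomness flows from
explicit seeds (cohorts spawn per-fiber child seeds via
`numpy.random.SeedSequence`); CLI stages derive per-fiber seeds from a CRC
of the stage seed and the fiber identity, and all JSON/CSV/TIFF outputs are
byte-reproducible under a fixed seed and configuration.

## Known limitations

Straight horizontal fibers only (rotated input is handled through ROI
orientation, not curved-axis tracing); the split geometry is a kinematic
stand-in, not a mechanical model of titin/thick-filament rearrangement;
the A-band tracer's branch attribution assumes the generator's Y chirality;
hotspot blobs are rectangles with uniform intensity rather than textured
protein accumulations; and the detection thresholds (candidate fold,
smoothing, disarray fraction) are calibrated on this image model and should
be revisited for real acquisitions.
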