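"""Render a synthetic striated fiber with planted splits and hotspots.

Builds a two-channel image (Z-lines + NSP label), plants two transverse
splits and two NSP hotspots, adds realistic optics and noise, and prints the
ground truth the generator recorded.
"""

from myoseries import (
    FiberModel,
    HotspotSpec,
    ImageSpec,
    SplitEvent,
    add_noise,
    render_fiber,
)

spec = ImageSpec(seed=42)
fiber = FiberModel()
splits = [
    SplitEvent(aband_index=4, lateral_fraction=0.4),
    SplitEvent(aband_index=9, lateral_fraction=0.6),
]
hotspots = [
    HotspotSpec(model_class="yu", anchor_sarcomere=4, lateral_fraction=0.4),
    HotspotSpec(model_class="rodier", anchor_sarcomere=12, lateral_fraction=0.55),
]

clean, truth = render_fiber(spec, fiber, splits, hotspots)
noisy = add_noise(clean, spec)

print(f"image shape (channels, rows, cols): {noisy.data.shape}")
print(f"pixel pitch: {noisy.pixel_pitch} um/px")
print(f"planted Z-lines: {len(truth.base_zline_cols_px)}")
for s in truth.splits:
    print(
        f"  split in gap {s.event.aband_index}: extra sarcomere fully formed "
        f"below row {s.row_px:.0f}"
    )
for h in truth.hotspots:
    print(f"  {h.label} hotspot at bbox {h.bbox}, {h.n_pixels} px")
# The split count along any lateral column equals the base Z-line count plus
# the number of splits whose realized row lies above it:
print(f"Z-lines at fiber top: {truth.n_zlines_at_row(truth.fiber_rows[0] + 1)}")
print(f"Z-lines at fiber bottom: {truth.n_zlines_at_row(truth.fiber_rows[1] - 1)}")
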