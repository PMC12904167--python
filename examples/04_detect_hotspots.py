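"""Detect NSP hotspots and call hotspot-positive fibers.

Plants three hotspots (one below the fold gate), estimates the local
background, detects candidates, and prints each candidate's qualification
verdict: a locus qualifies when its mean enrichment is >= 2x the local
background and its short-axis width lies in 400-1900 nm.
"""

from myoseries import (
    FiberModel,
    HotspotSpec,
    ImageSpec,
    add_noise,
    call_positive_fiber,
    detect_hotspots,
    estimate_local_background,
    render_fiber,
)

spec = ImageSpec(seed=11)
fiber = FiberModel()
planted = [
    HotspotSpec(model_class="yu", anchor_sarcomere=3, lateral_fraction=0.35, fold=3.0),
    HotspotSpec(model_class="rodier", anchor_sarcomere=8, lateral_fraction=0.6, fold=2.5),
    HotspotSpec(model_class="yu", anchor_sarcomere=13, lateral_fraction=0.4, fold=1.8),
]
image, _ = render_fiber(spec, fiber, hotspots=planted)
image = add_noise(image, spec)

background = estimate_local_background(image.nsp, image.fiber_mask, image.pixel_pitch)
hotspots = detect_hotspots(
    image.nsp, background, image.fiber_mask, image.pixel_pitch, smooth_sigma_px=1.5
)

for h in hotspots:
    verdict = "qualifies" if h.qualifies else f"rejected ({', '.join(h.reasons)})"
    print(
        f"candidate {h.id}: fold {h.fold:.2f}, width {h.min_feret_nm:4.0f} nm, "
        f"axial extent {h.axial_extent_um:.2f} um -> {verdict}"
    )

print(f"\nfiber hotspot-positive (>= 2 qualifying loci): {call_positive_fiber(hotspots)}")
print("The fold-1.8 locus is detected but rejected by the 2x enrichment gate.")
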