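"""Classify hotspot morphology against the sarcomerogenesis models.

Plants one hotspot of each morphology class, measures each blob's axial span
in local-sarcomere units and its boundary registration to the Z-lines, and
prints the assigned class:

  yu      - spans one sarcomere, Z-line to Z-line (single Z-line splitting)
  rodier  - spans two in-series sarcomeres, Z to Z
  hzone   - one sarcomere centered on a Z-line (H-zone splitting)
  short/long atypical - fits no model (span < 2 / > 2 sarcomeres)
"""

from myoseries import (
    FiberModel,
    HotspotSpec,
    ImageSpec,
    add_noise,
    detect_hotspots,
    estimate_local_background,
    render_fiber,
)
from myoseries.morphology import classify_fiber_hotspots, summarize_mix

spec = ImageSpec(seed=23)
fiber = FiberModel()
planted = [
    HotspotSpec(model_class="yu", anchor_sarcomere=1, lateral_fraction=0.2),
    HotspotSpec(model_class="rodier", anchor_sarcomere=5, lateral_fraction=0.4),
    HotspotSpec(model_class="hzone", anchor_sarcomere=9, lateral_fraction=0.6),
    HotspotSpec(model_class="short_atypical", anchor_sarcomere=12, lateral_fraction=0.8),
    HotspotSpec(model_class="long_atypical", anchor_sarcomere=14, lateral_fraction=0.3),
]
image, truth = render_fiber(spec, fiber, hotspots=planted)
image = add_noise(image, spec)

background = estimate_local_background(image.nsp, image.fiber_mask, image.pixel_pitch)
hotspots = detect_hotspots(
    image.nsp, background, image.fiber_mask, image.pixel_pitch, smooth_sigma_px=1.5
)
morphs, excluded = classify_fiber_hotspots(image, hotspots)

for m in sorted(morphs, key=lambda m: m.hotspot_id):
    print(
        f"hotspot {m.hotspot_id}: span {m.span:.2f} sarcomeres, boundary "
        f"phases ({m.start_phase:.2f}, {m.end_phase:.2f}) -> {m.label}"
    )
print(f"\nplanted classes: {sorted(h.label for h in truth.hotspots)}")

mix = summarize_mix([[m.label for m in morphs]])
print("\nper-fiber class proportions:")
print(mix["mean_proportion"].to_string())
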