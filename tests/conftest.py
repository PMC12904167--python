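import numpy as np
import pytest

from myoseries.simulate import FiberModel, HotspotSpec, ImageSpec, SplitEvent, render_fiber


@pytest.fixture(scope="session")
def spec():
    return ImageSpec()


@pytest.fixture(scope="session")
def fiber():
    return FiberModel()


@pytest.fixture(scope="session")
def ideal_image(spec, fiber):
    """Noise-free pristine striations (no splits, no hotspots)."""
    image, truth = render_fiber(spec, fiber)
    return image, truth


@pytest.fixture(scope="session")
def split_image(spec, fiber):
    """Noise-free fiber with four planted transverse splits."""
    splits = [
        SplitEvent(aband_index=k, lateral_fraction=f)
        for k, f in [(2, 0.3), (5, 0.5), (8, 0.7), (11, 0.4)]
    ]
    image, truth = render_fiber(spec, fiber, splits)
    return image, truth


@pytest.fixture(scope="session")
def hotspot_image(spec, fiber):
    """Noise-free fiber with one hotspot of each morphology class."""
    hotspots = [
        HotspotSpec(model_class="yu", anchor_sarcomere=1, lateral_fraction=0.2),
        HotspotSpec(model_class="rodier", anchor_sarcomere=5, lateral_fraction=0.4),
        HotspotSpec(model_class="hzone", anchor_sarcomere=9, lateral_fraction=0.6),
        HotspotSpec(
            model_class="short_atypical", anchor_sarcomere=12, lateral_fraction=0.8
        ),
        HotspotSpec(
            model_class="long_atypical", anchor_sarcomere=14, lateral_fraction=0.3
        ),
    ]
    image, truth = render_fiber(spec, fiber, hotspots=hotspots)
    return image, truth
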