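import numpy as np
import pytest

from perfviz import synthgen


@pytest.fixture
def layout():
    return synthgen.SceneLayout.default()


@pytest.fixture
def small_layout():
    """32x32 scene: one 'vital' zone band plus a reference card."""
    h = w = 32
    zone = np.zeros((h, w), dtype=bool)
    zone[8:, :] = True
    ref = np.zeros((h, w), dtype=bool)
    ref[1:6, 1:10] = True
    fov = zone.copy()
    return synthgen.SceneLayout(h, w, {"vital": zone}, ref, fov)


def single_zone_layout(h=24, w=24, label="vital"):
    zone = np.zeros((h, w), dtype=bool)
    zone[6:, :] = True
    ref = np.zeros((h, w), dtype=bool)
    ref[1:4, 1:8] = True
    return synthgen.SceneLayout(h, w, {label: zone}, ref, zone.copy())
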