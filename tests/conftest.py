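import numpy as np
import pytest

from fundusseg.synthetic import SpecSampler, SyntheticSpec, generate_fundus


def rasterized_circle(radius, size=256, center=None):
    """Brute-force pixel-centre rasterization of a circle (oracle geometry)."""
    if center is None:
        center = (size // 2, size // 2)
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


@pytest.fixture(scope="session")
def default_fundus():
    return generate_fundus(SyntheticSpec())


@pytest.fixture(scope="session")
def easy_sampler_128():
    """Easy desk-scale conditions: big bright circular-ish discs, mild noise."""
    return SpecSampler(image_size=128, disc_semi_axis_range=(22, 38),
                       noise_sigma=5.0, vessel_count=2, center_jitter=10)
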