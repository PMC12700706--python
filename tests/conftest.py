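import numpy as np
import pytest

from puncta.core import Punctum, PunctaSet, RoiSpec


@pytest.fixture
def roi52():
    return RoiSpec(52.0, 52.0)


@pytest.fixture
def roi180():
    return RoiSpec(180.0, 180.0)


def make_set(channel, points, roi, feret=0.4, area=0.1, total=10.0, mean=1.0):
    """Hand-built PunctaSet from a list of (x, y) centroids."""
    puncta = [
        Punctum(
            id=i,
            channel=channel,
            centroid_xy=(float(x), float(y)),
            area=area,
            feret_diameter=feret,
            total_intensity=total,
            mean_intensity=mean,
        )
        for i, (x, y) in enumerate(points)
    ]
    return PunctaSet(channel, roi, puncta)


@pytest.fixture
def make_puncta_set():
    return make_set
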