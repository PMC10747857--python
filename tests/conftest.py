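import numpy as np
import pytest
from shapely.geometry import box

from soilrisk.synthetic import StudyRegion


@pytest.fixture
def small_region() -> StudyRegion:
    """20 x 20 km study rectangle gridded at 1 km."""
    return StudyRegion(
        polygon=box(0.0, 0.0, 20_000.0, 20_000.0),
        cell_size=1000.0,
        nrows=20,
        ncols=20,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
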