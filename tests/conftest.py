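import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from slidescape.core_io import CELL_TYPES, SlideGeometry

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cells(rng, n, width=256.0, height=256.0, types=CELL_TYPES, offset=(0.0, 0.0)):
    """Random typed cell table with morphology in valid ranges."""
    return pd.DataFrame({
        "x": offset[0] + rng.uniform(0, width, n),
        "y": offset[1] + rng.uniform(0, height, n),
        "cell_type": rng.choice(types, n),
        "area": rng.gamma(30.0, 8.0, n),
        "eccentricity": rng.beta(5, 5, n),
        "solidity": rng.beta(20, 3, n),
        "extent": rng.beta(10, 4, n),
    })


@pytest.fixture
def small_geometry():
    return SlideGeometry(slide_id="toy", width_px=512, height_px=512)
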