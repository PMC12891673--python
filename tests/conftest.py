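import numpy as np
import pytest
from shapely.geometry import LineString

from riverkin import (
    DispersalKernelSpec,
    LandscapeSpec,
    RiverSet,
    generate_landscape,
    simulate_world,
)


@pytest.fixture(scope="session")
def default_world():
    """One synthetic study at default noise with a mild female aversion."""
    kernel = DispersalKernelSpec(female_crossing_aversion=0.5)
    records, rivers, truth = simulate_world(seed=1, n_families=60, kernel=kernel)
    return records, rivers, truth


@pytest.fixture(scope="session")
def straight_rivers():
    """Three straight horizontal rivers at y = 50, 100, 150 km."""
    spec = LandscapeSpec(meander_amplitude=0.0)
    return generate_landscape(spec, seed=0)


@pytest.fixture(scope="session")
def meander_rivers():
    return generate_landscape(LandscapeSpec(), seed=3)


@pytest.fixture()
def one_river():
    """A single straight river along y = 0 spanning x in [-10, 10] km."""
    return RiverSet(
        names=["flat"],
        lines=[LineString([(-10_000, 0), (10_000, 0)])],
        reference_azimuth_deg=0.0,
    )
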