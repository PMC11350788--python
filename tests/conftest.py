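import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from rangerisk import ClimateStack, GridSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_grid() -> GridSpec:
    """6x24 grid at 15-degree cells spanning all longitudes (fast checks)."""
    return GridSpec(west=-180, south=-45, resolution_arcmin=15 * 60,
                    n_rows=6, n_cols=24)


@pytest.fixture
def small_grid() -> GridSpec:
    """30x60 global grid at 6-degree cells (fast model fits)."""
    return GridSpec(west=-180, south=-90, resolution_arcmin=360, n_rows=30,
                    n_cols=60)


@pytest.fixture
def gradient_stack(small_grid) -> ClimateStack:
    """Two-variable stack: latitudinal temperature + longitudinal moisture."""
    lat = small_grid.lat_centers()[:, None]
    lon = small_grid.lon_centers()[None, :]
    temp = 28.0 - 0.5 * np.abs(lat) + 0.0 * lon
    wet = 1000.0 + 500.0 * np.sin(np.radians(lon)) + 0.0 * lat
    return ClimateStack(small_grid, {"temp": temp, "precip": wet})
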