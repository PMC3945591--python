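import numpy as np
import pytest

from hazpop.raster import GridSpec, Raster, ZoneMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def spec_3x3():
    return GridSpec(n_rows=3, n_cols=3, cell_size=1.0,
                    origin_lon=10.0, origin_lat=3.0)


@pytest.fixture
def spec_20x20():
    return GridSpec(n_rows=20, n_cols=20, cell_size=0.5,
                    origin_lon=0.0, origin_lat=5.0)


def random_zoned_raster(spec, rng, n_zones=4, nodata_frac=0.1):
    """A random value raster plus a random zone map on the same spec."""
    values = rng.integers(0, 100, spec.shape).astype(float)
    values[rng.random(spec.shape) < nodata_frac] = spec.nodata
    zones = ZoneMap(spec, rng.integers(0, n_zones + 1, spec.shape))
    return Raster(spec, values), zones
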