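"""Shared fixtures: small synthetic landscapes generated once per session."""

import numpy as np
import pytest

from cluesim import synthetic
from cluesim.rasterkit import Grid, LULCMap


@pytest.fixture(scope="session")
def landscape200():
    """Default 200×200 study landscape: map pair, drivers and truth."""
    lulc_t0, lulc_t1, drivers, truth = synthetic.generate_fixture_set(seed=2)
    return {"t0": lulc_t0, "t1": lulc_t1, "drivers": drivers, "truth": truth}


@pytest.fixture(scope="session")
def landscape100():
    """Smaller 100×100 landscape for allocation experiments."""
    dem = synthetic.generate_dem(100, 100, seed=5)
    features = synthetic.generate_features(100, 100, seed=5)
    drivers = synthetic.generate_drivers(dem, features)
    lulc, truth = synthetic.generate_lulc(drivers, seed=5)
    return {"lulc": lulc, "drivers": drivers, "truth": truth}


def make_lulc(codes, cellsize=60.0, nodata=-9999):
    """Build a LULCMap from a 2-D list of class codes (nodata allowed)."""
    return LULCMap(Grid(np.asarray(codes, dtype=np.int32), cellsize=cellsize, nodata_value=nodata))
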