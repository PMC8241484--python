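import numpy as np
import pandas as pd
import pytest

from opscr.spatial import AsciiRaster, build_habitat_grid, build_detector_grid
from opscr.simulate import flagship_config, generate_study


def make_raster(extent, value=0.0, cellsize=10.0, array=None):
    """Constant (or given) raster covering ``extent`` exactly."""
    xmin, ymin, xmax, ymax = extent
    ncols = int(round((xmax - xmin) / cellsize))
    nrows = int(round((ymax - ymin) / cellsize))
    if array is None:
        array = np.full((nrows, ncols), float(value))
    return AsciiRaster(values=array, xllcorner=xmin, yllcorner=ymin,
                       cellsize=cellsize)


@pytest.fixture
def habitat_3x3():
    """60 x 60 km habitat, 3 x 3 cells of 20 km, constant covariate, no buffer."""
    extent = (0.0, 0.0, 60.0, 60.0)
    return build_habitat_grid(extent, 20.0, make_raster(extent), buffer_width=0.0)


@pytest.fixture
def grids_small():
    """Habitat with buffer plus a detector grid fully inside it."""
    extent = (0.0, 0.0, 40.0, 40.0)
    raster = make_raster((-20.0, -20.0, 60.0, 60.0))
    habitat = build_habitat_grid(extent, 20.0, raster, buffer_width=20.0)
    detectors = build_detector_grid(extent, 10.0, 2.0, habitat)
    return habitat, detectors


@pytest.fixture(scope="session")
def small_synthetic_study():
    """A compact but fully featured synthetic study shared across tests."""
    cfg = flagship_config(core_extent=(0.0, 0.0, 60.0, 60.0), buffer_width=20.0,
                          M=60, T=4, p0=0.15)
    return generate_study(cfg, 42)
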