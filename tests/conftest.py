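import numpy as np
import pytest

from landtrax.legend import Legend, default_legend
from landtrax.trajectory import LandcoverSeries, TrajectoryRaster


@pytest.fixture(scope="session")
def legend() -> Legend:
    return default_legend()


def series_from_codes(rasters, years=None, legend=None, pixel_size_m=30.0) -> LandcoverSeries:
    """Build a LandcoverSeries from a (n_years, rows, cols) code array."""
    rasters = np.asarray(rasters)
    years = list(years) if years is not None else list(range(2008, 2008 + rasters.shape[0]))
    return LandcoverSeries(years=years, rasters=rasters,
                           legend=legend or default_legend(), pixel_size_m=pixel_size_m)


def traj_from_grid(codes, code_book) -> TrajectoryRaster:
    """Build a TrajectoryRaster from an explicit code grid and code book."""
    codes = np.asarray(codes, dtype=np.int32)
    n_years = len(next(iter(code_book.values())))
    return TrajectoryRaster(codes=codes, code_book=dict(code_book), n_years=n_years)


def uniform_sequence_traj(seq, shape=(1, 1)) -> TrajectoryRaster:
    """A trajectory raster where every pixel carries the same sequence."""
    return traj_from_grid(np.zeros(shape, dtype=np.int32), {0: tuple(seq)})
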