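import numpy as np
import pytest

from sarwheat import GridMeta, Raster, SceneConfig, generate_scene


@pytest.fixture
def meta():
    return GridMeta(
        n_rows=8, n_cols=8, pixel_size=10.0, origin=(0.0, 80.0), crs_id="local"
    )


def make_raster(values, units="index", pixel_size=10.0, origin=None, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * pixel_size)
    m = GridMeta(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        pixel_size=pixel_size,
        origin=origin,
        nodata_value=nodata,
    )
    return Raster(m, values, units)


@pytest.fixture(scope="session")
def default_scene():
    """One fully rendered synthetic scene shared across tests."""
    return generate_scene(SceneConfig(seed=7))
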