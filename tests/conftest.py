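import numpy as np
import pytest

from lucfrontier import (
    DEFAULT_CLASS_LABELS,
    GeneratorConfig,
    GridGeometry,
    LandCoverMap,
    make_scene,
)


def random_landcover(rng, n_rows=40, n_cols=40, cell_size=30.0, p_nodata=0.0):
    """A random categorical map over the full class roster."""
    codes = list(DEFAULT_CLASS_LABELS)
    geom = GridGeometry(n_rows, n_cols, cell_size, origin_y=n_rows * cell_size)
    cells = rng.choice(codes, size=(n_rows, n_cols))
    if p_nodata > 0:
        cells = np.where(
            rng.random((n_rows, n_cols)) < p_nodata, geom.nodata_code, cells
        )
    return LandCoverMap(geom, cells)


@pytest.fixture(scope="session")
def small_scene():
    """A 120x120 synthetic scene shared by read-only tests."""
    cfg = GeneratorConfig(
        geometry=GridGeometry(120, 120, 30.0, origin_y=120 * 30.0), seed=7
    )
    return make_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
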