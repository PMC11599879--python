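import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from mcpi import CoastScene, RasterGrid, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene() -> CoastScene:
    """A small homogeneous straight-coast scene (900 m band, 8 m canopy)."""
    return generate_scene(SceneConfig(), seed=1)


@pytest.fixture(scope="session")
def varied_scene() -> CoastScene:
    """Straight coast with per-region width/height/NDVI heterogeneity."""
    cfg = SceneConfig(
        n_cols=320,
        n_rows=100,
        width_m=(900.0, 1000.0, 1234.0, 600.0),
        height_m=(8.0, 3.5, 6.25, 11.0),
        ndvi=(0.7, 0.55, 0.62, 0.8),
        n_regions=4,
    )
    return generate_scene(cfg, seed=3)


def craft_scene(
    mask: np.ndarray,
    height: np.ndarray | None = None,
    red: float | np.ndarray = 0.08,
    nir: float | np.ndarray = 0.40,
    ocean_rows: int = 2,
    pixel: float = 30.0,
    epoch: int = 2019,
) -> CoastScene:
    """Build a CoastScene directly from hand-written arrays.

    The ocean occupies the bottom ``ocean_rows`` rows; the nominal coastline
    runs along their upper edge.
    """
    mask = np.asarray(mask, dtype=bool)
    n_rows, n_cols = mask.shape
    if height is None:
        height = np.where(mask, 7.0, 0.0)
    ocean = np.zeros_like(mask)
    ocean[:ocean_rows] = True
    red = np.broadcast_to(np.asarray(red, dtype=float), mask.shape).copy()
    nir = np.broadcast_to(np.asarray(nir, dtype=float), mask.shape).copy()

    def grid(v):
        return RasterGrid(v, 0.0, 0.0, pixel)

    y_coast = ocean_rows * pixel
    return CoastScene(
        epoch=epoch,
        mask=grid(mask),
        height=grid(np.asarray(height, dtype=float)),
        red=grid(red),
        nir=grid(nir),
        ocean=grid(ocean),
        coastline=LineString([(0.0, y_coast), (n_cols * pixel, y_coast)]),
        regions=[box(0.0, 0.0, n_cols * pixel, n_rows * pixel)],
        truth=pd.DataFrame(columns=["region_id", "width_m", "height_m", "ndvi"]),
        config=None,
    )
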