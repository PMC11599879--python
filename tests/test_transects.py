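import math

import numpy as np
import pytest
from shapely.geometry import Point

from mcpi import (
    EmptyDomainError,
    RasterGrid,
    SceneConfig,
    TransectSample,
    aggregate_region,
    build_transects,
    extract_regions,
    generate_scene,
    sample_transect,
    wrap_coastline,
)
from conftest import craft_scene


# -- coastline wrapping -----------------------------------------------------


def test_wrap_of_straight_band_lies_on_seaward_edge(default_scene):
    line = wrap_coastline(default_scene.mask, default_scene.ocean, tolerance=30.0)
    ys = {round(y, 6) for _, y in line.coords}
    assert ys == {600.0}  # coast offset of the default config, grid-aligned


def test_wrap_halfplane_contains_disjoint_patches():
    mask = np.zeros((20, 30), dtype=bool)
    mask[4:8, 2:10] = True  # patch 1
    mask[6:12, 18:28] = True  # patch 2, further landward
    scene = craft_scene(mask)
    line = wrap_coastline(scene.mask, scene.ocean, tolerance=0.0)
    # every mangrove cell centre must lie on or landward (higher y) of the wrap
    x, y = scene.mask.cell_centres(mask)
    for xi, yi in zip(x, y):
        s = line.project(Point(xi, yi))
        assert yi >= line.interpolate(s).y - 1e-9


def test_wrap_simplification_reduces_vertices():
    cfg = SceneConfig(coast_amplitude_m=120.0, coast_wavelength_m=2000.0)
    scene = generate_scene(cfg, seed=0)
    fine = wrap_coastline(scene.mask, scene.ocean, tolerance=0.0)
    coarse = wrap_coastline(scene.mask, scene.ocean, tolerance=200.0)
    assert len(fine.coords) >= len(coarse.coords)


def test_wrap_requires_mangroves():
    empty = craft_scene(np.zeros((10, 10), dtype=bool))
    with pytest.raises(EmptyDomainError):
        wrap_coastline(empty.mask, empty.ocean)


# -- transect construction --------------------------------------------------


def test_transect_count_and_directions_on_straight_coast(default_scene):
    line = wrap_coastline(default_scene.mask, default_scene.ocean, tolerance=30.0)
    # shrink spacing so the short demo coast yields floor(L/s) + 1 anchors
    transects = build_transects(line, default_scene.ocean, spacing=500.0, length=3000.0)
    assert len(transects) == int(line.length // 500.0) + 1
    for t in transects:
        assert t.direction == pytest.approx((0.0, 1.0))  # ocean is south


def test_ten_km_line_thousand_m_spacing_gives_eleven():
    mask = np.zeros((20, 400), dtype=bool)
    mask[4:10, :] = True
    scene = craft_scene(mask)  # 12 km coast; wrap spans the band columns
    line = wrap_coastline(scene.mask, scene.ocean, tolerance=30.0)
    n = int(line.length // 1000.0) + 1
    assert len(build_transects(line, scene.ocean, spacing=1000.0, length=3000.0)) == n


def test_sinusoid_transects_perpendicular_to_analytic_tangent():
    cfg = SceneConfig(
        n_cols=300, n_rows=100, coast_amplitude_m=200.0, coast_wavelength_m=4000.0,
        width_m=600.0, coast_offset_m=900.0,
    )
    scene = generate_scene(cfg, seed=0)
    transects = build_transects(
        scene.coastline, scene.ocean, spacing=500.0, length=2000.0,
        tangent_fn=cfg.coast_tangent,
    )
    for t in transects:
        tx, ty = cfg.coast_tangent(t.anchor[0]).ravel()
        dot = t.direction[0] * tx + t.direction[1] * ty
        assert abs(dot) < 1e-6  # perpendicular to the generating sinusoid


def test_reversed_ocean_flips_directions_exactly(default_scene):
    line = wrap_coastline(default_scene.mask, default_scene.ocean, tolerance=30.0)
    fwd = build_transects(line, default_scene.ocean, spacing=500.0, length=3000.0)
    flipped_ocean = RasterGrid(
        ~default_scene.ocean.values,
        default_scene.ocean.x0,
        default_scene.ocean.y0,
        default_scene.ocean.pixel_size,
    )
    rev = build_transects(line, flipped_ocean, spacing=500.0, length=3000.0)
    for a, b in zip(fwd, rev):
        assert b.direction == pytest.approx((-a.direction[0], -a.direction[1]))


# -- sampling ---------------------------------------------------------------


def test_segmented_band_counts_mangrove_cells_only():
    # 10 mangrove rows, 1 gap, 5 more -> N = 15, width 450 m
    mask = np.zeros((40, 5), dtype=bool)
    mask[2:12, 2] = True
    mask[13:18, 2] = True
    scene = craft_scene(mask)
    line = wrap_coastline(scene.mask, scene.ocean, tolerance=0.0)
    (t,) = build_transects(line, scene.ocean, spacing=1e9, length=40 * 30.0)
    s = sample_transect(scene, t)
    assert s.n_mangrove == 15
    assert s.width_m(30.0) == 450.0
    assert s.mean_height == pytest.approx(7.0)  # constant field


def test_open_water_transect_is_empty(default_scene):
    from mcpi import Transect

    t = Transect(index=0, anchor=(3000.0, 30.0), direction=(0.0, -1.0), length=900.0)
    s = sample_transect(default_scene, t)
    assert s.n_mangrove == 0 and not s.contains_mangrove


# -- aggregation ------------------------------------------------------------


def _sample(n, h=math.nan, v=math.nan):
    return TransectSample(0, n, h, v, n > 0)


def test_region_means():
    rec = aggregate_region([_sample(10, 4.0, 0.5), _sample(30, 8.0, 0.7)], 0, 2019, 30.0)
    assert rec.amw_m == pytest.approx(600.0)  # mean of 300 and 900
    assert rec.ach_m == pytest.approx(6.0)
    assert rec.ndvi == pytest.approx(0.6)
    assert (rec.m, rec.n) == (2, 2)


def test_empty_transects_excluded_by_default_but_switchable():
    samples = [_sample(10, 4.0, 0.5), _sample(0), _sample(30, 8.0, 0.7)]
    strict = aggregate_region(samples, 0, 2019, 30.0)
    assert strict.amw_m == pytest.approx(600.0) and (strict.m, strict.n) == (3, 2)
    lenient = aggregate_region(samples, 0, 2019, 30.0, include_empty_transects=True)
    assert lenient.amw_m == pytest.approx(400.0)  # zero-width transect included
    # the height/NDVI means never include empty transects either way
    assert lenient.ach_m == pytest.approx(6.0)


def test_ach_is_mean_of_transect_means_not_pooled_pixel_mean():
    # transect A: 10 cells at 4 m; transect B: 2 cells at 10 m
    samples = [_sample(10, 4.0, 0.5), _sample(2, 10.0, 0.5)]
    rec = aggregate_region(samples, 0, 2019, 30.0)
    pooled = (10 * 4.0 + 2 * 10.0) / 12  # 5.0
    assert rec.ach_m == pytest.approx(7.0)
    assert rec.ach_m != pytest.approx(pooled)


def test_all_empty_region_flagged():
    rec = aggregate_region([_sample(0), _sample(0)], 0, 2019, 30.0)
    assert rec.n == 0 and math.isnan(rec.amw_m)


# -- end-to-end region extraction ------------------------------------------


def test_only_mangrove_regions_yield_records():
    cfg = SceneConfig(n_cols=320, n_regions=8, width_m=(900, 0, 0, 600, 0, 0, 0, 1200))
    scene = generate_scene(cfg, seed=1)
    recs = extract_regions(scene, spacing=300.0, length=2000.0)
    assert sorted(r.region_id for r in recs) == [0, 3, 7]


def test_region_records_close_to_ground_truth(varied_scene):
    recs = extract_regions(varied_scene, spacing=250.0, length=2500.0)
    truth = varied_scene.truth.set_index("region_id")
    assert len(recs) == len(truth)
    for r in recs:
        assert abs(r.amw_m - truth.loc[r.region_id, "width_m"]) <= 30.0
        assert r.ach_m == pytest.approx(truth.loc[r.region_id, "height_m"], abs=1e-9)
        assert r.ndvi == pytest.approx(truth.loc[r.region_id, "ndvi"], abs=1e-9)


def test_spacing_insensitivity_on_homogeneous_band(default_scene):
    coarse = extract_regions(default_scene, spacing=500.0, length=2000.0)
    fine = extract_regions(default_scene, spacing=250.0, length=2000.0)
    for a, b in zip(coarse, fine):
        assert abs(a.amw_m - b.amw_m) < 30.0


def test_empty_region_set_rejected(default_scene):
    with pytest.raises(EmptyDomainError):
        extract_regions(default_scene, regions=[])
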