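"""Synthetic coastal scene generator with known ground truth.

Emulates, at desk scale, the kind of inputs a global mangrove-protection
analysis consumes: a mangrove presence mask, a canopy-height raster, a
red/NIR surface-reflectance pair, a coastline polyline and tropical-storm
tracks.  Scenes are planar (projected metres) with the ocean on the
decreasing-y side of the coastline by construction, and carry a per-region
ground-truth table (true cross-shore width, true mean canopy height, true
NDVI) so that every downstream stage — transect sampling, index
construction, trends, cluster exchange, storm validation — can be tested
for closure against known values.

"Regions" are rectangular full-height tiles along the coast, a desk-scale
analogue of 1-degree analysis grid cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, box, mapping, shape

from .grid import RasterGrid

__all__ = [
    "SceneConfig",
    "CoastScene",
    "ChangeSpec",
    "StormTrack",
    "generate_scene",
    "generate_scene_pair",
    "generate_storms",
    "with_ndvi_damage",
    "scene_to_dir",
    "scene_from_dir",
    "storms_to_geojson",
    "storms_from_geojson",
    "ConfigurationError",
]

# reflectance of non-mangrove background cells
_OCEAN_RED, _OCEAN_NIR = 0.06, 0.03
_LAND_RED, _LAND_NIR = 0.18, 0.24


class ConfigurationError(ValueError):
    """Invalid scene or change configuration."""


def _per_region(value, n_regions: int, name: str) -> np.ndarray:
    """Broadcast a scalar or per-region sequence to an (n_regions,) array."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_regions, float(arr[0]))
    if arr.size != n_regions:
        raise ConfigurationError(
            f"{name}: expected a scalar or {n_regions} per-region values, got {arr.size}"
        )
    return arr


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic coastal scene.

    The mangrove band runs shore-parallel, starting at the coastline and
    extending landward (increasing y) by the cross-shore width ``width_m``,
    which may vary by region and (optionally) log-normally by column.

    Attributes
    ----------
    n_cols, n_rows : int
        Raster size in pixels.
    pixel_size : float
        Cell side in metres (default 30, a Landsat-class resolution).
    coast_offset_m : float or None
        Distance of the straight-coast baseline from the bottom edge;
        defaults to 25% of the raster height.
    coast_amplitude_m, coast_wavelength_m : float
        Sinusoidal coastline y(x) = offset + A sin(2 pi x / L); amplitude 0
        gives a straight coast.
    width_m : float or sequence
        True cross-shore band width, scalar or one value per region.
    width_lognormal_sigma : float
        If positive, per-column widths are drawn log-normally with the
        configured width as median and this log-scale sigma.
    height_m : float or sequence
        True canopy height (m), scalar or per region.
    height_gradient_per_m : float
        Linear alongshore height gradient (m of height per m of x), a
        latitudinal-gradient stand-in.
    ndvi : float or sequence
        Target NDVI of mangrove cells, scalar or per region; realised by
        fixing red reflectance and solving the NDVI definition for NIR.
    red_reflectance : float
        Red-band reflectance of mangrove cells.
    fragmentation : float
        Probability that a band cell is a gap (non-mangrove), emulating
        fragmented stands.
    n_regions : int
        Number of equal-width full-height region tiles along x.
    nodata : float
        Nodata sentinel for float rasters.
    """

    n_cols: int = 200
    n_rows: int = 80
    pixel_size: float = 30.0
    coast_offset_m: float | None = None
    coast_amplitude_m: float = 0.0
    coast_wavelength_m: float = 5000.0
    width_m: float | Sequence[float] = 900.0
    width_lognormal_sigma: float = 0.0
    height_m: float | Sequence[float] = 8.0
    height_gradient_per_m: float = 0.0
    ndvi: float | Sequence[float] = 0.7
    red_reflectance: float = 0.08
    fragmentation: float = 0.0
    n_regions: int = 4
    nodata: float = -9999.0

    # -- derived geometry --------------------------------------------------

    @property
    def extent_x(self) -> float:
        return self.n_cols * self.pixel_size

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.pixel_size

    @property
    def coast_offset(self) -> float:
        return 0.25 * self.extent_y if self.coast_offset_m is None else self.coast_offset_m

    def coast_y(self, x):
        """Coastline elevation y(x) in planar metres."""
        x = np.asarray(x, dtype=float)
        if self.coast_amplitude_m == 0.0:
            return np.full_like(x, self.coast_offset)
        return self.coast_offset + self.coast_amplitude_m * np.sin(
            2.0 * math.pi * x / self.coast_wavelength_m
        )

    def coast_tangent(self, x):
        """Unit tangent of the analytic coastline at alongshore position x."""
        x = np.asarray(x, dtype=float)
        if self.coast_amplitude_m == 0.0:
            dydx = np.zeros_like(x)
        else:
            dydx = (
                self.coast_amplitude_m
                * (2.0 * math.pi / self.coast_wavelength_m)
                * np.cos(2.0 * math.pi * x / self.coast_wavelength_m)
            )
        norm = np.sqrt(1.0 + dydx**2)
        return np.stack([1.0 / norm, dydx / norm], axis=-1)

    def region_polygons(self) -> list[Polygon]:
        w = self.extent_x / self.n_regions
        return [box(i * w, 0.0, (i + 1) * w, self.extent_y) for i in range(self.n_regions)]

    def region_of_x(self, x) -> np.ndarray:
        w = self.extent_x / self.n_regions
        return np.clip((np.asarray(x) / w).astype(int), 0, self.n_regions - 1)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigurationError("raster must have at least one cell")
        if self.n_regions < 1:
            raise ConfigurationError("need at least one region")
        widths = _per_region(self.width_m, self.n_regions, "width_m")
        heights = _per_region(self.height_m, self.n_regions, "height_m")
        ndvi = _per_region(self.ndvi, self.n_regions, "ndvi")
        if (widths < 0).any() or (heights < 0).any():
            raise ConfigurationError("widths and heights must be non-negative")
        if ((ndvi <= -1) | (ndvi >= 1)).any():
            raise ConfigurationError("NDVI targets must lie in (-1, 1)")
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ConfigurationError("fragmentation rate must lie in [0, 1]")
        if not 0.0 < self.red_reflectance <= 1.0:
            raise ConfigurationError("red reflectance must lie in (0, 1]")
        nir = self.red_reflectance * (1 + ndvi) / (1 - ndvi)
        if (nir > 1.0).any():
            raise ConfigurationError(
                "NDVI target unreachable: implied NIR reflectance exceeds 1; "
                "lower red_reflectance or the NDVI target"
            )
        if self.width_lognormal_sigma == 0.0:
            top = self.coast_offset + self.coast_amplitude_m + widths.max()
            if top > self.extent_y:
                raise ConfigurationError(
                    f"raster too small to contain the band: band top {top:.0f} m "
                    f"exceeds raster height {self.extent_y:.0f} m"
                )
        if self.coast_offset - self.coast_amplitude_m <= 0:
            raise ConfigurationError("coastline must lie inside the raster (no ocean strip)")


@dataclass
class StormTrack:
    """A tropical-storm track: planar polyline, peak wind, event label."""

    geometry: LineString
    wind_kn: float
    time: str = ""

    def __post_init__(self) -> None:
        if len(self.geometry.coords) < 2:
            raise ConfigurationError("storm track needs at least 2 vertices")
        if self.wind_kn < 0:
            raise ConfigurationError("wind speed must be non-negative")


@dataclass
class CoastScene:
    """One epoch's co-registered rasters plus coastline and ground truth."""

    epoch: int
    mask: RasterGrid
    height: RasterGrid
    red: RasterGrid
    nir: RasterGrid
    ocean: RasterGrid
    coastline: LineString
    regions: list[Polygon]
    truth: pd.DataFrame
    config: SceneConfig | None = None

    def __post_init__(self) -> None:
        for grid in (self.height, self.red, self.nir, self.ocean):
            self.mask.require_registered(grid)
        on_land = self.height.values[~self.mask.values.astype(bool)]
        if (on_land[on_land != self.height.nodata] > 0).any():
            raise ValueError("positive canopy height outside the mangrove mask")

    @property
    def pixel_size(self) -> float:
        return self.mask.pixel_size

    def coast_tangent_fn(self) -> Callable | None:
        return None if self.config is None else self.config.coast_tangent

    def ndvi_grid(self) -> RasterGrid:
        """Per-cell NDVI from the reflectance pair; undefined cells → nodata."""
        red, nir = self.red.values, self.nir.values
        denom = red + nir
        bad = self.red.is_nodata() | self.nir.is_nodata() | (denom <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (nir - red) / denom
        v = np.where(bad, self.red.nodata, v)
        return RasterGrid(v, self.mask.x0, self.mask.y0, self.pixel_size, self.red.nodata)


@dataclass(frozen=True)
class ChangeSpec:
    """Multiplicative per-region change between two epochs.

    Factors apply to true width, true height and target NDVI; optional
    dieback patches thin the epoch-B mask inside given polygons with the
    stated probability.
    """

    width_factor: float | Sequence[float] = 1.0
    height_factor: float | Sequence[float] = 1.0
    ndvi_factor: float | Sequence[float] = 1.0
    dieback_polygons: Sequence[Polygon] = ()
    dieback_prob: float = 0.0

    def validate(self, n_regions: int) -> None:
        for name in ("width_factor", "height_factor", "ndvi_factor"):
            f = _per_region(getattr(self, name), n_regions, name)
            if (f <= 0).any():
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0.0 <= self.dieback_prob <= 1.0:
            raise ConfigurationError("dieback probability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# generation


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def generate_scene(config: SceneConfig, seed: int = 0, epoch: int = 2019) -> CoastScene:
    """Realise a :class:`CoastScene` from a config, deterministically per seed.

    The mangrove band occupies cells whose centres fall between the
    coastline and the coastline plus the (possibly column-varying) true
    width; fragmentation then knocks out band cells independently.  NDVI
    targets are realised through the reflectance pair, not injected
    directly, so the reflectance-to-NDVI path is exercised downstream.
    """
    config.validate()
    width_rng, frag_rng = _rngs(int(seed), 2)

    C = config.pixel_size
    cols = np.arange(config.n_cols)
    rows = np.arange(config.n_rows)
    xc = (cols + 0.5) * C
    yc = (rows + 0.5) * C
    region_of_col = config.region_of_x(xc)

    widths_r = _per_region(config.width_m, config.n_regions, "width_m")
    heights_r = _per_region(config.height_m, config.n_regions, "height_m")
    ndvi_r = _per_region(config.ndvi, config.n_regions, "ndvi")

    w_col = widths_r[region_of_col]
    if config.width_lognormal_sigma > 0:
        # median-preserving lognormal multiplier, one draw per column
        w_col = w_col * np.exp(config.width_lognormal_sigma * width_rng.standard_normal(config.n_cols))
    coast = np.asarray(config.coast_y(xc))
    if (coast + w_col).max() > config.extent_y:
        raise ConfigurationError("raster too small to contain the realised band")

    yy = yc[:, None]  # (rows, 1)
    band = (yy >= coast[None, :]) & (yy < (coast + w_col)[None, :])
    mask = band.copy()
    if config.fragmentation > 0:
        gaps = frag_rng.random(mask.shape) < config.fragmentation
        mask &= ~gaps
    ocean = yy < coast[None, :]

    h_col = heights_r[region_of_col] + config.height_gradient_per_m * xc
    h_col = np.clip(h_col, 0.0, None)
    height = np.where(mask, np.broadcast_to(h_col, mask.shape), 0.0)

    v_col = ndvi_r[region_of_col]
    red = np.where(ocean, _OCEAN_RED, _LAND_RED)
    nir = np.where(ocean, _OCEAN_NIR, _LAND_NIR)
    nir_mangrove = config.red_reflectance * (1 + v_col) / (1 - v_col)
    red = np.where(mask, config.red_reflectance, red)
    nir = np.where(mask, np.broadcast_to(nir_mangrove, mask.shape), nir)

    coastline = LineString(np.column_stack([xc, coast])) if config.coast_amplitude_m else LineString(
        [(xc[0], coast[0]), (xc[-1], coast[-1])]
    )

    truth_rows = []
    for r in range(config.n_regions):
        in_r = region_of_col == r
        mask_r = mask[:, in_r]
        h_true = float(np.mean(np.broadcast_to(h_col[in_r], mask_r.shape)[mask_r])) if mask_r.any() else 0.0
        truth_rows.append(
            {
                "region_id": r,
                "width_m": float(np.mean(w_col[in_r])),
                "height_m": h_true,
                "ndvi": float(ndvi_r[r]),
            }
        )
    truth = pd.DataFrame(truth_rows)

    def grid(v, **kw):
        return RasterGrid(v, 0.0, 0.0, C, config.nodata, **kw)

    return CoastScene(
        epoch=epoch,
        mask=grid(mask),
        height=grid(height),
        red=grid(red),
        nir=grid(nir),
        ocean=grid(ocean),
        coastline=coastline,
        regions=config.region_polygons(),
        truth=truth,
        config=config,
    )


def _scaled(value, factor, n_regions: int, name: str) -> np.ndarray:
    return _per_region(value, n_regions, name) * _per_region(factor, n_regions, name)


def generate_scene_pair(
    config: SceneConfig,
    change: ChangeSpec,
    seed: int = 0,
    epochs: tuple[int, int] = (2007, 2019),
) -> tuple[CoastScene, CoastScene]:
    """Generate two co-registered epochs whose truth differs by ``change``.

    Both epochs are realised from the same random stream, so where a factor
    is 1 the corresponding structure is bit-identical across epochs; epoch-B
    ground truth equals epoch-A truth times the change factors.
    """
    config.validate()
    change.validate(config.n_regions)
    n = config.n_regions
    ndvi_b = _scaled(config.ndvi, change.ndvi_factor, n, "ndvi")
    if ((ndvi_b <= -1) | (ndvi_b >= 1)).any():
        raise ConfigurationError("ndvi_factor pushes NDVI outside (-1, 1)")
    config_b = replace(
        config,
        width_m=_scaled(config.width_m, change.width_factor, n, "width_m"),
        height_m=_scaled(config.height_m, change.height_factor, n, "height_m"),
        ndvi=ndvi_b,
    )
    scene_a = generate_scene(config, seed, epoch=epochs[0])
    scene_b = generate_scene(config_b, seed, epoch=epochs[1])

    if change.dieback_polygons and change.dieback_prob > 0:
        (rng,) = _rngs(int(seed) + 1, 1)
        mask = scene_b.mask.values.copy()
        x, y = scene_b.mask.cell_centres(mask)
        hit = np.zeros(x.size, dtype=bool)
        for poly in change.dieback_polygons:
            hit |= shapely.contains_xy(poly, x, y)
        drop = hit & (rng.random(x.size) < change.dieback_prob)
        rows, cols = np.nonzero(mask)
        mask[rows[drop], cols[drop]] = False
        scene_b.mask.values = mask
        scene_b.height.values = np.where(mask, scene_b.height.values, 0.0)

    return scene_a, scene_b


def generate_storms(
    n: int,
    wind_range: tuple[float, float],
    scene: CoastScene,
    seed: int = 0,
    at_positions: Sequence[float] | None = None,
) -> list[StormTrack]:
    """Draw ``n`` storm tracks crossing the scene's coastline.

    Each track runs from offshore (below the coastline) to inland across
    the full raster height, with jittered intermediate vertices, so every
    track intersects the coastline.  Winds are uniform in ``wind_range``
    (knots).  ``at_positions`` pins the coastline arc-length positions of
    landfall (one per storm) instead of drawing them.
    """
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    if scene.coastline.length <= 0:
        raise ConfigurationError("empty domain: coastline has zero length")
    lo, hi = wind_range
    if lo > hi or lo < 0:
        raise ConfigurationError("invalid wind range")
    (rng,) = _rngs(int(seed), 1)
    L = scene.coastline.length
    if at_positions is None:
        positions = rng.uniform(0.0, L, size=n)
    else:
        positions = np.asarray(at_positions, dtype=float)
        if positions.size != n:
            raise ConfigurationError("at_positions must have one entry per storm")
    winds = rng.uniform(lo, hi, size=n)
    xmin, ymin, xmax, ymax = scene.mask.extent
    jitter = 2.0 * scene.pixel_size

    tracks = []
    for i in range(n):
        p = scene.coastline.interpolate(float(positions[i]))
        x_land = p.x + rng.uniform(-jitter, jitter)
        line = LineString(
            [
                (p.x + rng.uniform(-jitter, jitter), ymin - scene.pixel_size),
                (p.x, p.y),
                (x_land, ymax + scene.pixel_size),
            ]
        )
        tracks.append(StormTrack(geometry=line, wind_kn=float(winds[i]), time=f"storm-{i:03d}"))
    return tracks


def with_ndvi_damage(
    scene: CoastScene, polygons: Sequence[Polygon], deltas: Sequence[float], epoch: int | None = None
) -> CoastScene:
    """Return a copy of ``scene`` with mangrove NDVI shifted inside polygons.

    The shift is applied through the NIR band (red held fixed), mirroring
    how vegetation damage shows up in imagery.  Deltas are additive NDVI
    changes, clipped so NDVI stays in (-1, 1).
    """
    if len(polygons) != len(deltas):
        raise ValueError("need one delta per polygon")
    nir = scene.nir.values.copy()
    red = scene.red.values
    mask = scene.mask.values.astype(bool)
    x, y = scene.mask.cell_centres(mask)
    rows, cols = np.nonzero(mask)
    for poly, delta in zip(polygons, deltas):
        inside = shapely.contains_xy(poly, x, y)
        if not inside.any():
            continue
        r, c = rows[inside], cols[inside]
        v = (nir[r, c] - red[r, c]) / (nir[r, c] + red[r, c])
        v2 = np.clip(v + delta, -0.99, 0.99)
        nir[r, c] = red[r, c] * (1 + v2) / (1 - v2)
    out = CoastScene(
        epoch=scene.epoch if epoch is None else epoch,
        mask=scene.mask.copy(),
        height=scene.height.copy(),
        red=scene.red.copy(),
        nir=RasterGrid(nir, scene.nir.x0, scene.nir.y0, scene.nir.pixel_size, scene.nir.nodata),
        ocean=scene.ocean.copy(),
        coastline=scene.coastline,
        regions=scene.regions,
        truth=scene.truth.copy(),
        config=scene.config,
    )
    return out


# ---------------------------------------------------------------------------
# text persistence


def scene_to_dir(scene: CoastScene, path: str | Path) -> None:
    """Write a scene as ASCII grids + GeoJSON + CSV under a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scene.mask.write_ascii(path / "mask.asc", fmt="%d")
    scene.ocean.write_ascii(path / "ocean.asc", fmt="%d")
    scene.height.write_ascii(path / "height.asc")
    scene.red.write_ascii(path / "red.asc")
    scene.nir.write_ascii(path / "nir.asc")
    with open(path / "coastline.geojson", "w") as fh:
        json.dump(
            {
                "type": "FeatureCollection",
                "features": [
                    {"type": "Feature", "geometry": mapping(scene.coastline), "properties": {}}
                ],
            },
            fh,
        )
    scene.truth.to_csv(path / "truth.csv", index=False)
    meta = {
        "epoch": scene.epoch,
        "regions": [list(p.bounds) for p in scene.regions],
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def scene_from_dir(path: str | Path) -> CoastScene:
    path = Path(path)
    mask = RasterGrid.read_ascii(path / "mask.asc", dtype=float)
    mask.values = mask.values.astype(bool)
    ocean = RasterGrid.read_ascii(path / "ocean.asc", dtype=float)
    ocean.values = ocean.values.astype(bool)
    with open(path / "coastline.geojson") as fh:
        coastline = shape(json.load(fh)["features"][0]["geometry"])
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    return CoastScene(
        epoch=int(meta["epoch"]),
        mask=mask,
        height=RasterGrid.read_ascii(path / "height.asc"),
        red=RasterGrid.read_ascii(path / "red.asc"),
        nir=RasterGrid.read_ascii(path / "nir.asc"),
        ocean=ocean,
        coastline=coastline,
        regions=[box(*b) for b in meta["regions"]],
        truth=pd.read_csv(path / "truth.csv"),
        config=None,
    )


def storms_to_geojson(tracks: Sequence[StormTrack], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(t.geometry),
            "properties": {"wind_kn": t.wind_kn, "time": t.time},
        }
        for t in tracks
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def storms_from_geojson(path: str | Path) -> list[StormTrack]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        StormTrack(
            geometry=shape(f["geometry"]),
            wind_kn=float(f["properties"]["wind_kn"]),
            time=str(f["properties"].get("time", "")),
        )
        for f in fc["features"]
    ]
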