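"""Outer-wrap coastline, perpendicular transects, and per-region statistics.

The sampling scheme: a working coastline is wrapped along the seaward edge
of the mangrove band, equally spaced transects are cast perpendicular to it
pointing landward, and each transect is walked at pixel-size steps counting
mangrove cells.  Per region, the average cross-shore mangrove width (AMW)
is the mean over mangrove-containing transects of (pixel size x mangrove
cell count); average canopy height (ACH) and mean NDVI are means over those
transects of the per-transect means — a mean of transect means, not a
pooled pixel mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .grid import RasterGrid, RegistrationError
from .scene import CoastScene

__all__ = [
    "Transect",
    "TransectSample",
    "RegionRecord",
    "wrap_coastline",
    "build_transects",
    "sample_transect",
    "aggregate_region",
    "extract_regions",
    "records_to_frame",
    "frame_to_records",
    "EmptyDomainError",
]

DEFAULT_SPACING = 1000.0  # m between transect anchors
DEFAULT_LENGTH = 30000.0  # m transect reach, covers the widest observed belts


class EmptyDomainError(ValueError):
    """No mangrove cells / no data to operate on."""


@dataclass(frozen=True)
class Transect:
    """A sampling line: anchor on the working coastline, landward unit direction."""

    index: int
    anchor: tuple[float, float]
    direction: tuple[float, float]
    length: float

    def __post_init__(self) -> None:
        dx, dy = self.direction
        if abs(math.hypot(dx, dy) - 1.0) > 1e-9:
            raise ValueError("transect direction must be a unit vector")
        if self.length <= 0:
            raise ValueError("transect length must be positive")

    def point_at(self, s: float) -> tuple[float, float]:
        return (self.anchor[0] + s * self.direction[0], self.anchor[1] + s * self.direction[1])


@dataclass
class TransectSample:
    """Per-transect extraction: mangrove cell count and mean height / NDVI."""

    index: int
    n_mangrove: int
    mean_height: float  # NaN when no mangrove cells
    mean_ndvi: float  # NaN when no mangrove cells
    contains_mangrove: bool

    def width_m(self, pixel_size: float) -> float:
        return pixel_size * self.n_mangrove


@dataclass
class RegionRecord:
    """Per-region per-epoch factor record; index fields filled later."""

    region_id: int | str
    epoch: int
    amw_m: float
    ach_m: float
    ndvi: float
    m: int  # transects cast in the region
    n: int  # transects containing mangroves
    a: float | None = None
    b: float | None = None
    mcpi: float | None = None


_RECORD_COLUMNS = ["region_id", "epoch", "amw_m", "ach_m", "ndvi", "m", "n", "a", "b", "mcpi"]


def records_to_frame(records: Sequence[RegionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=_RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[RegionRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(RegionRecord(**{k: d.get(k) for k in _RECORD_COLUMNS}))
    return out


# ---------------------------------------------------------------------------


def _ocean_is_low(ocean: RasterGrid) -> bool:
    """True when the ocean occupies the low-y side of the raster."""
    rows = np.nonzero(ocean.values.astype(bool))[0]
    land_rows = np.nonzero(~ocean.values.astype(bool))[0]
    if rows.size == 0 or land_rows.size == 0:
        return True
    return rows.mean() < land_rows.mean()


def wrap_coastline(
    mangrove_mask: RasterGrid, ocean_mask: RasterGrid, tolerance: float = 0.0
) -> LineString:
    """Trace the seaward outer envelope of the mangrove band as a polyline.

    For every raster column containing mangroves, the seaward edge of its
    seaward-most mangrove cell is taken; the resulting alongshore profile is
    simplified (Douglas-Peucker) with the given tolerance.  The polyline is
    the automated stand-in for a manually adjusted outer-wrapping coastline.
    """
    mangrove_mask.require_registered(ocean_mask)
    mv = mangrove_mask.values.astype(bool)
    if not mv.any():
        raise EmptyDomainError("no mangrove cells in the mask")
    C = mangrove_mask.pixel_size
    ocean_low = _ocean_is_low(ocean_mask)

    cols = np.nonzero(mv.any(axis=0))[0]
    xs = mangrove_mask.x0 + (cols + 0.5) * C
    if ocean_low:
        edge_rows = np.array([np.nonzero(mv[:, c])[0].min() for c in cols])
        ys = mangrove_mask.y0 + edge_rows * C  # bottom edge of seaward-most cell
    else:
        edge_rows = np.array([np.nonzero(mv[:, c])[0].max() for c in cols])
        ys = mangrove_mask.y0 + (edge_rows + 1) * C
    if xs.size == 1:
        # degenerate single-column band: span the cell's own width
        x = float(xs[0])
        line = LineString([(x - C / 2, ys[0]), (x + C / 2, ys[0])])
    else:
        line = LineString(np.column_stack([xs, ys]))
    if tolerance > 0:
        line = line.simplify(tolerance, preserve_topology=False)
    return line


def _polyline_tangent(line: LineString, s: float, h: float) -> tuple[float, float]:
    s0 = max(0.0, s - h)
    s1 = min(line.length, s + h)
    p0, p1 = line.interpolate(s0), line.interpolate(s1)
    dx, dy = p1.x - p0.x, p1.y - p0.y
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("degenerate coastline: zero-length tangent")
    return dx / norm, dy / norm


def _landward_sign(anchor, normal, ocean: RasterGrid) -> float:
    """+1 if ``normal`` points away from the ocean at this anchor, else -1."""
    C = ocean.pixel_size
    ov = ocean.values.astype(bool)
    for step in (2.0, 5.0, 10.0, 25.0, 60.0):
        probes = []
        for sign in (+1.0, -1.0):
            px = anchor[0] + sign * step * C * normal[0]
            py = anchor[1] + sign * step * C * normal[1]
            r, c = ocean.world_to_index(px, py)
            probes.append(bool(ov[r, c]) if ocean.in_bounds(r, c) else None)
        plus, minus = probes
        if plus is not None and minus is not None and plus != minus:
            return -1.0 if plus else 1.0
        if plus is not None and minus is None:
            return -1.0 if plus else 1.0
        if minus is not None and plus is None:
            return 1.0 if minus else -1.0
    # ambiguous (e.g. anchor far outside data): default to +y landward
    return 1.0 if normal[1] >= 0 else -1.0


def build_transects(
    coastline: LineString,
    ocean_mask: RasterGrid,
    spacing: float = DEFAULT_SPACING,
    length: float = DEFAULT_LENGTH,
    tangent_fn: Callable | None = None,
) -> list[Transect]:
    """Cast equally spaced landward transects perpendicular to the coastline.

    Anchors sit at arc-length positions 0, spacing, 2*spacing, ...
    (``floor(L / spacing) + 1`` of them).  The direction at each anchor is
    the local normal, oriented away from the ocean mask.  ``tangent_fn``,
    when provided (e.g. an analytic coastline derivative from the scene
    generator), overrides the finite-difference polyline tangent.
    """
    if coastline.length <= 0:
        raise ValueError("degenerate coastline with zero length")
    if spacing <= 0 or length <= 0:
        raise ValueError("spacing and length must be positive")
    L = coastline.length
    count = int(math.floor(L / spacing)) + 1
    h = max(min(spacing, L) * 1e-3, 1e-9)
    transects = []
    for i in range(count):
        s = min(i * spacing, L)
        p = coastline.interpolate(s)
        if tangent_fn is not None:
            tx, ty = np.asarray(tangent_fn(p.x), dtype=float).ravel()
        else:
            tx, ty = _polyline_tangent(coastline, s, h)
        normal = (-ty, tx)
        sign = _landward_sign((p.x, p.y), normal, ocean_mask)
        transects.append(
            Transect(
                index=i,
                anchor=(p.x, p.y),
                direction=(sign * normal[0], sign * normal[1]),
                length=length,
            )
        )
    return transects


def sample_transect(scene: CoastScene, transect: Transect) -> TransectSample:
    """Walk a transect at pixel-size steps and extract mangrove statistics.

    Steps are taken at the midpoints of successive pixel-length intervals
    along the line; each step is attributed to the cell containing it
    (nearest-cell lookup).  The mangrove cell count N excludes gaps, so the
    implied width C x N is the summed length of the mangrove segments the
    line crosses.  Height and NDVI means are over exactly the mangrove
    steps; nodata cells are skipped.
    """
    C = scene.pixel_size
    n_steps = max(int(round(transect.length / C)), 1)
    s = (np.arange(n_steps) + 0.5) * C
    xs = transect.anchor[0] + s * transect.direction[0]
    ys = transect.anchor[1] + s * transect.direction[1]
    rows, cols = scene.mask.world_to_index(xs, ys)
    ok = scene.mask.in_bounds(rows, cols)
    rows, cols = rows[ok], cols[ok]
    if rows.size == 0:
        return TransectSample(transect.index, 0, math.nan, math.nan, False)

    mangrove = scene.mask.values.astype(bool)[rows, cols]
    n = int(mangrove.sum())
    if n == 0:
        return TransectSample(transect.index, 0, math.nan, math.nan, False)
    r, c = rows[mangrove], cols[mangrove]

    hv = scene.height.values[r, c]
    hv = hv[hv != scene.height.nodata]
    mean_h = float(hv.mean()) if hv.size else math.nan

    red = scene.red.values[r, c]
    nir = scene.nir.values[r, c]
    valid = (red != scene.red.nodata) & (nir != scene.nir.nodata) & (red + nir > 0)
    mean_v = float(((nir[valid] - red[valid]) / (nir[valid] + red[valid])).mean()) if valid.any() else math.nan

    return TransectSample(transect.index, n, mean_h, mean_v, True)


def aggregate_region(
    samples: Sequence[TransectSample],
    region_id: int | str,
    epoch: int,
    pixel_size: float,
    include_empty_transects: bool = False,
) -> RegionRecord:
    """Collapse a region's transect samples into a RegionRecord.

    AMW averages C x N over mangrove-containing transects (or over all
    transects when ``include_empty_transects``, a sensitivity switch); ACH
    and NDVI are means of the per-transect means over mangrove-containing
    transects only.  A region with no mangrove-containing transect gets
    NaN factors and n = 0 — downstream stages drop it.
    """
    m = len(samples)
    containing = [s for s in samples if s.contains_mangrove]
    n = len(containing)
    if n == 0:
        return RegionRecord(region_id, epoch, math.nan, math.nan, math.nan, m, 0)
    width_pool = samples if include_empty_transects else containing
    amw = pixel_size * float(np.mean([s.n_mangrove for s in width_pool]))
    ach = float(np.nanmean([s.mean_height for s in containing]))
    ndvi = float(np.nanmean([s.mean_ndvi for s in containing]))
    return RegionRecord(region_id, epoch, amw, ach, ndvi, m, n)


def extract_regions(
    scene: CoastScene,
    regions: Sequence[Polygon] | None = None,
    spacing: float = DEFAULT_SPACING,
    length: float = DEFAULT_LENGTH,
    include_empty_transects: bool = False,
    wrap_tolerance: float | None = None,
    use_analytic_tangent: bool = True,
) -> list[RegionRecord]:
    """Run the whole sampling chain on a scene: wrap, cast, sample, aggregate.

    Each transect is attributed to the region polygon covering its anchor
    (regions are expected to tile the scene).  Only regions with at least
    one mangrove-containing transect yield a record.
    """
    if regions is None:
        regions = scene.regions
    if not regions:
        raise EmptyDomainError("empty region set")
    tol = scene.pixel_size if wrap_tolerance is None else wrap_tolerance
    coastline = wrap_coastline(scene.mask, scene.ocean, tolerance=tol)
    tangent = scene.coast_tangent_fn() if use_analytic_tangent else None
    transects = build_transects(coastline, scene.ocean, spacing, length, tangent_fn=tangent)

    by_region: dict[int, list[TransectSample]] = {i: [] for i in range(len(regions))}
    for t in transects:
        p = Point(t.anchor)
        for ri, poly in enumerate(regions):
            if poly.covers(p):
                by_region[ri].append(sample_transect(scene, t))
                break

    out = []
    for ri in range(len(regions)):
        if not by_region[ri]:
            continue
        rec = aggregate_region(
            by_region[ri], ri, scene.epoch, scene.pixel_size, include_empty_transects
        )
        if rec.n >= 1:
            out.append(rec)
    return out
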