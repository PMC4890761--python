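"""LOD1 block-model construction from footprints and an elevation cloud.

A building footprint is lifted to a prism: the top elevation is the median
z of all elevation points whose planimetric projection falls within the
footprint (the median is robust to vegetation returns and roof furniture),
the base elevation is the median z of points in a thin collar just outside
the footprint, and the volume is footprint area times the height between
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

log = logging.getLogger(__name__)


class ExtrusionError(ValueError):
    """Raised when a building cannot be reconstructed."""


@dataclass(frozen=True)
class BlockModel:
    """An extruded prism (LOD1) for one building."""

    building_id: str
    base_elevation: float
    top_elevation: float
    height: float
    volume: float


def _as_cloud(cloud) -> np.ndarray:
    arr = np.asarray(cloud, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"point cloud must be (n, 3); got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("point cloud contains non-finite coordinates")
    return arr


def _as_polygon(footprint) -> Polygon:
    if isinstance(footprint, Polygon):
        poly = footprint
    else:
        coords = list(footprint)
        if len(coords) < 3:
            raise ExtrusionError("a polygon needs at least 3 vertices")
        poly = Polygon(coords)
    if not poly.is_valid:
        raise ExtrusionError("footprint polygon is not simple (self-intersecting)")
    return poly


def polygon_area(footprint) -> float:
    """Shoelace-magnitude area of a simple polygon, orientation-independent.

    Accepts a shapely ``Polygon`` or a coordinate sequence.
    """
    poly = _as_polygon(footprint)
    area = float(poly.area)
    if area <= 0.0:
        raise ExtrusionError("polygon has zero area")
    return area


def points_in_footprint(cloud, footprint) -> np.ndarray:
    """Select the points whose (x, y) projection lies inside or on the
    boundary of the footprint (closed point-in-polygon test)."""
    arr = _as_cloud(cloud)
    poly = _as_polygon(footprint)
    if poly.area <= 0.0:
        raise ExtrusionError("degenerate (zero-area) footprint")
    if len(arr) == 0:
        return arr
    pts = shapely.points(arr[:, 0], arr[:, 1])
    shapely.prepare(poly)
    mask = shapely.intersects(poly, pts)
    return arr[mask]


def estimate_height(zs) -> float:
    """Top elevation estimate: the median of the z values over a footprint.

    For an even count this is the mean of the two central values.
    """
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise ExtrusionError("no points over footprint")
    return float(np.median(zs))


def estimate_base(cloud, footprint, buffer_width: float = 2.0) -> float:
    """Base elevation estimate: median z of points in the annulus between
    the footprint boundary and its outward buffer of ``buffer_width`` m."""
    if buffer_width <= 0:
        raise ExtrusionError("buffer_width must be > 0")
    arr = _as_cloud(cloud)
    poly = _as_polygon(footprint)
    if len(arr) == 0:
        raise ExtrusionError(
            "no points in base annulus; widen the buffer or supply the base explicitly"
        )
    pts = shapely.points(arr[:, 0], arr[:, 1])
    buffered = poly.buffer(buffer_width)
    shapely.prepare(buffered)
    shapely.prepare(poly)
    in_annulus = shapely.intersects(buffered, pts) & ~shapely.intersects(poly, pts)
    if not in_annulus.any():
        raise ExtrusionError(
            "no points in base annulus; widen the buffer or supply the base explicitly"
        )
    return float(np.median(arr[in_annulus, 2]))


def extrude(footprint_area: float, base: float, top: float,
            building_id: str = "") -> BlockModel:
    """Lift a footprint of the given area from base to top elevation."""
    if footprint_area <= 0:
        raise ExtrusionError("footprint_area must be > 0")
    if top <= base:
        raise ExtrusionError(
            f"top elevation {top} not above base {base}; building unreconstructable"
        )
    height = top - base
    return BlockModel(
        building_id=building_id,
        base_elevation=base,
        top_elevation=top,
        height=height,
        volume=footprint_area * height,
    )


def extrude_buildings(buildings, cloud, buffer_width: float = 2.0,
                      base_overrides: dict[str, float] | None = None,
                      ) -> dict[str, BlockModel]:
    """Extrude a collection of buildings against one elevation cloud.

    ``base_overrides`` maps building id to a known base elevation; an
    override wins over the annulus estimate. Buildings with no points over
    the footprint are dropped with a logged warning.
    """
    arr = _as_cloud(cloud)
    base_overrides = base_overrides or {}
    models: dict[str, BlockModel] = {}
    if len(arr):
        tree = shapely.STRtree(shapely.points(arr[:, 0], arr[:, 1]))
    else:
        tree = None
    for b in buildings:
        poly = b.footprint
        if tree is not None:
            near = tree.query(poly.buffer(buffer_width), predicate="intersects")
            local = arr[near]
        else:
            local = arr
        over = points_in_footprint(local, poly)
        if len(over) == 0:
            log.warning("building %s: no elevation points over footprint; dropped", b.id)
            continue
        top = estimate_height(over[:, 2])
        if b.id in base_overrides:
            base = base_overrides[b.id]
        else:
            try:
                base = estimate_base(local, poly, buffer_width)
            except ExtrusionError:
                log.warning("building %s: no ground points in annulus; dropped", b.id)
                continue
        try:
            models[b.id] = extrude(b.footprint_area, base, top, building_id=b.id)
        except ExtrusionError:
            log.warning("building %s: top %.2f not above base %.2f; dropped",
                        b.id, top, base)
    return models
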