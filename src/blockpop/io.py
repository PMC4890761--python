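"""File formats: GeoJSON buildings, CSV census and results, XYZ clouds.

Coordinates are planar metres throughout (a Dutch-RD-like local frame);
the GeoJSON carries a top-level note declaring the coordinates
non-geodetic. All CSV is comma-separated, UTF-8, header row, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .estimators import PopulationEstimates
from .evaluation import ResultTable
from .extrusion import BlockModel
from .hierarchy import Hierarchy
from .simulate import Building

_REQUIRED_PROPS = ("floorspace", "height", "base_elevation",
                   "residential_fraction", "neighbourhood_id")


class FormatError(ValueError):
    """Raised for malformed input files."""


def write_buildings(buildings, path) -> None:
    features = []
    for b in buildings:
        features.append({
            "type": "Feature",
            "id": b.id,
            "geometry": mapping(b.footprint),
            "properties": {
                "floorspace": b.floorspace,
                "height": b.height,
                "base_elevation": b.base_elevation,
                "residential_fraction": b.residential_fraction,
                "neighbourhood_id": b.neighbourhood_id,
            },
        })
    doc = {
        "type": "FeatureCollection",
        "coordinate_note": "planar metric coordinates (non-geodetic)",
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_buildings(path) -> list[Building]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    buildings = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise FormatError(f"feature {i}: geometry must be a Polygon, "
                              f"got {geom.get('type')!r}")
        poly = shape(geom)
        if not poly.is_valid:
            raise FormatError(f"feature {i}: polygon is not simple "
                              "(self-intersecting or degenerate)")
        props = feat.get("properties") or {}
        missing = [p for p in _REQUIRED_PROPS if p not in props]
        if missing:
            raise FormatError(f"feature {i}: missing properties {missing}")
        buildings.append(Building(
            id=str(feat.get("id", f"F{i}")),
            neighbourhood_id=str(props["neighbourhood_id"]),
            footprint=poly,
            footprint_area=float(poly.area),
            floorspace=float(props["floorspace"]),
            base_elevation=float(props["base_elevation"]),
            height=float(props["height"]),
            residential_fraction=float(props["residential_fraction"]),
        ))
    return buildings


def write_census(hierarchy: Hierarchy, path) -> None:
    hierarchy.to_frame().to_csv(path, index=False)


def read_census(path, validate: bool = True) -> Hierarchy:
    df = pd.read_csv(path, dtype={"unit_id": str, "parent_id": str})
    hierarchy = Hierarchy.from_frame(df)
    if validate:
        hierarchy.validate_populations()
    return hierarchy


def write_xyz(cloud: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(cloud, dtype=float), fmt="%.3f")


def read_xyz(path) -> np.ndarray:
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.size == 0:
        return np.empty((0, 3))
    if arr.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns (x y z), got {arr.shape[1]}")
    return arr


def write_blockmodels(models: dict[str, BlockModel], path) -> None:
    pd.DataFrame(
        {
            "building_id": m.building_id,
            "base": m.base_elevation,
            "top": m.top_elevation,
            "height": m.height,
            "volume": m.volume,
        }
        for m in models.values()
    ).to_csv(path, index=False)


def read_blockmodels(path) -> dict[str, BlockModel]:
    df = pd.read_csv(path, dtype={"building_id": str})
    return {
        row.building_id: BlockModel(
            building_id=row.building_id, base_elevation=row.base,
            top_elevation=row.top, height=row.height, volume=row.volume)
        for row in df.itertuples()
    }


def write_estimates(result: PopulationEstimates, path, seed=None) -> None:
    """Per-unit estimates as CSV plus a JSON sidecar with the experiment
    spec, coefficients and country total."""
    path = Path(path)
    result.estimates.to_csv(path, index=False)
    spec = result.spec
    side = {
        "method": spec.method,
        "source_level": spec.source_level,
        "target_level": spec.target_level,
        "lod": str(spec.lod),
        "train_fraction": spec.train_fraction,
        "seed": seed if seed is not None else spec.seed,
        "enhanced": spec.enhanced,
        "country_total": result.country_total,
    }
    if result.model is not None:
        side["coefficients"] = {
            "intercept": result.model.intercept,
            "proxy": result.model.coef_proxy,
            "mean_height": result.model.coef_mean_height,
        }
    path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def write_results(table: ResultTable, path, text_render: bool = True) -> None:
    """Grid results as CSV, a JSON report, and optionally the plain-text
    12-block rendering."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    path.with_suffix(".json").write_text(table.to_json())
    if text_render:
        path.with_suffix(".txt").write_text(table.render_text())
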