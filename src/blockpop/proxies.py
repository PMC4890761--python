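"""Residential-space proxies at nine levels of detail.

The residential capacity of a building can be graded along two axes:

* geometric — ``LOD0`` footprint area (m2), ``LOD0+`` floorspace (m2),
  ``LOD1`` prism volume (m3);
* semantic — ``a`` no use information (every building counts in full),
  ``b`` a binary residential flag (majority use), ``c`` the fractional
  residential share.

The 3 x 3 grid gives nine proxy definitions. Per statistical unit the
proxy totals are additive up the administrative hierarchy; the unit's
mean building height (used by the enhanced regression) is the plain
arithmetic mean over all retained buildings.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hierarchy import Hierarchy, HierarchyError

GEOMETRIC_LODS = ("LOD0", "LOD0+", "LOD1")
SEMANTIC_LODS = ("a", "b", "c")

#: default majority-use threshold for the binary semantic level
BINARY_THRESHOLD = 0.5

#: footprints smaller than this are sheds/garages, unlikely to be inhabited
MIN_FOOTPRINT_AREA = 20.0


class ProxyError(ValueError):
    """Raised when a proxy cannot be computed."""


@dataclass(frozen=True)
class LODSpec:
    """One cell of the geometric x semantic level-of-detail grid."""

    geometric: str
    semantic: str

    def __post_init__(self) -> None:
        if self.geometric not in GEOMETRIC_LODS:
            raise ProxyError(f"unknown geometric LOD {self.geometric!r}")
        if self.semantic not in SEMANTIC_LODS:
            raise ProxyError(f"unknown semantic LOD {self.semantic!r}")

    def __str__(self) -> str:
        return f"{self.geometric}{self.semantic}"

    @classmethod
    def parse(cls, text: str) -> "LODSpec":
        """Parse 'LOD1c', 'LOD1^c' or 'LOD0+b' style names."""
        t = text.strip().replace("^", "")
        for geo in sorted(GEOMETRIC_LODS, key=len, reverse=True):
            if t.startswith(geo) and t[len(geo):] in SEMANTIC_LODS:
                return cls(geo, t[len(geo):])
        raise ProxyError(f"cannot parse LOD name {text!r}")


#: all nine LOD configurations, geometric-major order
ALL_LODS = tuple(LODSpec(g, s) for g in GEOMETRIC_LODS for s in SEMANTIC_LODS)


@dataclass
class UnitProxy:
    """Aggregate residential-space proxy for one statistical unit."""

    unit_id: str
    lod: LODSpec
    total_proxy: float
    mean_height: float | None
    building_count: int


def filter_small(buildings, min_area: float = MIN_FOOTPRINT_AREA):
    """Drop very small buildings (sheds, garages): keep those with
    footprint_area >= min_area (strictly smaller are excluded)."""
    return [b for b in buildings if b.footprint_area >= min_area]


def building_proxy(building, lod: LODSpec, volume: float | None = None,
                   binary_threshold: float = BINARY_THRESHOLD) -> float:
    """Residential-space proxy of one building under one LOD.

    The geometric base is the footprint area, the floorspace, or the prism
    volume (taken from an extruded block model when supplied, otherwise
    footprint area x building height). The semantic factor is 1 (level a),
    an all-or-nothing majority-use indicator (level b), or the residential
    fraction itself (level c).
    """
    if lod.geometric == "LOD0":
        base = building.footprint_area
    elif lod.geometric == "LOD0+":
        base = building.floorspace
        if base is None:
            raise ProxyError(f"building {building.id}: floorspace required for LOD0+")
    else:  # LOD1
        if volume is not None:
            base = volume
        elif getattr(building, "height", None) is not None:
            base = building.footprint_area * building.height
        else:
            raise ProxyError(
                f"building {building.id}: LOD1 proxy needs a block model or height"
            )
    if lod.semantic == "a":
        factor = 1.0
    elif lod.semantic == "b":
        factor = 1.0 if building.residential_fraction >= binary_threshold else 0.0
    else:
        factor = building.residential_fraction
    return float(base) * factor


def aggregate_unit(buildings, unit_id: str, lod: LODSpec,
                   volumes: dict[str, float] | None = None,
                   binary_threshold: float = BINARY_THRESHOLD) -> UnitProxy:
    """Sum building proxies and average heights over one unit's buildings.

    ``buildings`` are assumed pre-filtered by :func:`filter_small`. The
    mean height covers all retained buildings regardless of use.
    """
    total = 0.0
    heights = []
    for b in buildings:
        vol = volumes.get(b.id) if volumes else None
        total += building_proxy(b, lod, volume=vol, binary_threshold=binary_threshold)
        if getattr(b, "height", None) is not None:
            heights.append(b.height)
    mean_height = sum(heights) / len(heights) if heights else None
    return UnitProxy(unit_id=unit_id, lod=lod, total_proxy=total,
                     mean_height=mean_height, building_count=len(buildings))


def compute_unit_proxies(buildings, hierarchy: Hierarchy, lod: LODSpec,
                         min_area: float = MIN_FOOTPRINT_AREA,
                         volumes: dict[str, float] | None = None,
                         binary_threshold: float = BINARY_THRESHOLD,
                         ) -> dict[str, UnitProxy]:
    """Neighbourhood-level proxies for every neighbourhood in the hierarchy
    (empty neighbourhoods get a zero total and undefined mean height)."""
    kept = filter_small(buildings, min_area)
    by_nbhd: dict[str, list] = {u.id: [] for u in hierarchy.units_at("neighbourhood")}
    for b in kept:
        if b.neighbourhood_id not in by_nbhd:
            raise ProxyError(f"building {b.id}: unknown neighbourhood "
                             f"{b.neighbourhood_id!r}")
        by_nbhd[b.neighbourhood_id].append(b)
    return {
        uid: aggregate_unit(blds, uid, lod, volumes=volumes,
                            binary_threshold=binary_threshold)
        for uid, blds in by_nbhd.items()
    }


def rollup_proxies(unit_proxies: dict[str, UnitProxy], hierarchy: Hierarchy,
                   level: str) -> dict[str, UnitProxy]:
    """Aggregate neighbourhood proxies to a higher level.

    Totals and building counts sum over descendants; the mean height is
    recomputed as the building-count-weighted mean.
    """
    out: dict[str, UnitProxy] = {}
    lod = next(iter(unit_proxies.values())).lod if unit_proxies else None
    for unit in hierarchy.units_at(level):
        nbhds = hierarchy.descendants_at(unit.id, "neighbourhood")
        total = 0.0
        count = 0
        height_weighted = 0.0
        height_count = 0
        for n in nbhds:
            if n.id not in unit_proxies:
                raise HierarchyError(f"no proxy for neighbourhood {n.id} "
                                     f"under {unit.id}")
            p = unit_proxies[n.id]
            total += p.total_proxy
            count += p.building_count
            if p.mean_height is not None:
                height_weighted += p.mean_height * p.building_count
                height_count += p.building_count
        mean_height = height_weighted / height_count if height_count else None
        out[unit.id] = UnitProxy(unit_id=unit.id, lod=lod, total_proxy=total,
                                 mean_height=mean_height, building_count=count)
    return out


def proxies_to_frame(unit_proxies: dict[str, UnitProxy], level: str) -> pd.DataFrame:
    rows = [
        {
            "unit_id": p.unit_id,
            "level": level,
            "lod": str(p.lod),
            "total_proxy": p.total_proxy,
            "mean_height": p.mean_height,
            "building_count": p.building_count,
        }
        for p in unit_proxies.values()
    ]
    return pd.DataFrame(rows)
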