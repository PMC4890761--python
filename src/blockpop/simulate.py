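"""Synthetic-country generator.

Emulates the logical structure of the three national datasets the method
consumes — a census hierarchy with populations (neighbourhood, district,
municipality, country), a building register with footprints, floorspace,
height and residential use, and an airborne elevation point cloud — so
that every downstream stage (extrusion, proxies, estimation, evaluation)
can be exercised end to end without any download.

The generative mechanism mirrors the dominant error source of real-world
building-based population estimation: living space per resident varies
between units, with urban neighbourhoods packing more residents into the
same floorspace than rural ones. Each neighbourhood draws its own
space-per-resident value from a log-normal whose median differs by
urban/rural status; residents per building follow as residential
floorspace divided by that draw.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawns, so a fixed :class:`SimConfig` reproduces the world bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .hierarchy import Hierarchy, HierarchyError, StatUnit


class ConfigError(ValueError):
    """Raised for invalid simulator configuration."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (half-up for x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass
class Building:
    """One structure of the synthetic building register."""

    id: str
    neighbourhood_id: str
    footprint: Polygon
    footprint_area: float
    floorspace: float
    base_elevation: float
    height: float
    residential_fraction: float
    #: simulator ground truth, unknown to any estimator
    ground_truth_residents: float = 0.0

    def __post_init__(self) -> None:
        if self.footprint_area <= 0:
            raise ConfigError(f"building {self.id}: footprint_area must be > 0")
        if self.floorspace < 0:
            raise ConfigError(f"building {self.id}: floorspace must be >= 0")
        if self.height <= 0:
            raise ConfigError(f"building {self.id}: height must be > 0")
        if not 0.0 <= self.residential_fraction <= 1.0:
            raise ConfigError(
                f"building {self.id}: residential_fraction must lie in [0, 1]"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic country.

    The defaults describe a desk-scale country: a dozen municipalities with
    a few districts and neighbourhoods each, mixed urban/rural character,
    realistic Dutch-like dwelling statistics (storey height 3 m, median
    living space 40 m2/person urban vs 65 m2/person rural) and mild
    floorspace measurement noise.
    """

    # hierarchy shape
    n_municipalities: int = 12
    districts_per_municipality: tuple[int, int] = (2, 4)
    neighbourhoods_per_district: tuple[int, int] = (3, 6)
    #: exact (municipalities, districts, neighbourhoods) totals; overrides
    #: the per-level ranges when set (used for the NL-shape hierarchy).
    exact_level_totals: tuple[int, int, int] | None = None

    # buildings
    buildings_per_neighbourhood: tuple[int, int] = (12, 40)
    urban_probability: float = 0.35
    footprint_area_log_mean: float = math.log(90.0)   # log m2
    footprint_area_log_sd: float = 0.45
    shed_probability: float = 0.12       # small non-residential outbuildings
    shed_area_range: tuple[float, float] = (4.0, 18.0)  # m2, below the 20 m2 cut
    storey_mean_urban: float = 4.0       # storeys = 1 + Poisson(mean - 1)
    storey_mean_rural: float = 1.5
    storey_height: float = 3.0           # m per storey
    floorspace_efficiency: float = 0.85  # usable share of footprint x storeys
    floorspace_noise_sd: float = 0.05    # multiplicative N(0, sd)
    res_fraction_p0: float = 0.15        # mass at 0 (non-residential)
    res_fraction_p1: float = 0.70        # mass at 1 (purely residential)
    res_fraction_beta: tuple[float, float] = (2.0, 2.0)  # mixed use share

    # occupancy
    space_per_resident_urban: float = 40.0  # m2/person, log-normal median
    space_per_resident_rural: float = 65.0
    space_per_resident_sd: float = 0.25     # sd of log, across neighbourhoods
    #: exact proportional mode: populations are made exactly proportional to
    #: residential floorspace (integer populations, no rounding slack).
    exact_proportional: bool = False

    # terrain and point cloud
    base_elevation_range: tuple[float, float] = (0.0, 30.0)  # m above datum
    point_density: float = 0.5       # points / m2
    point_noise_sd: float = 0.1      # m, vertical
    outlier_rate: float = 0.0        # vegetation returns over roofs
    outlier_extra_height: float = 8.0  # m added to outlier z

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_municipalities < 1:
            raise ConfigError("n_municipalities must be >= 1")
        for name in ("districts_per_municipality", "neighbourhoods_per_district",
                     "buildings_per_neighbourhood"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} range ({lo}, {hi}) invalid: need 1 <= lo <= hi")
        if not 0.0 <= self.urban_probability <= 1.0:
            raise ConfigError("urban_probability must lie in [0, 1]")
        if self.res_fraction_p0 < 0 or self.res_fraction_p1 < 0 \
                or self.res_fraction_p0 + self.res_fraction_p1 > 1.0:
            raise ConfigError("residential-fraction mixture weights invalid")
        if min(self.space_per_resident_urban, self.space_per_resident_rural) <= 0:
            raise ConfigError("space per resident must be positive")
        if self.point_density <= 0:
            raise ConfigError("point_density must be > 0")

    @classmethod
    def nl_shape(cls, seed: int = 0, **kwargs) -> "SimConfig":
        """Hierarchy with the Dutch shape: 393 municipalities, 2816
        districts, 12237 neighbourhoods."""
        return cls(exact_level_totals=(393, 2816, 12237), seed=seed, **kwargs)

    @classmethod
    def noiseless_proportional(cls, seed: int = 0, space_per_resident: float = 50.0,
                               **kwargs) -> "SimConfig":
        """Fully deterministic occupancy: constant space per resident,
        no floorspace noise, residential fractions restricted to {0, 1}.

        In this mode population is exactly proportional to residential
        floorspace within every unit, so floorspace-based disaggregation
        with fractional semantics recovers every census count exactly.
        """
        return cls(
            space_per_resident_urban=space_per_resident,
            space_per_resident_rural=space_per_resident,
            space_per_resident_sd=0.0,
            floorspace_noise_sd=0.0,
            res_fraction_p0=0.15,
            res_fraction_p1=0.85,
            exact_proportional=True,
            seed=seed,
            **kwargs,
        )


def _split_total(total: int, n_parents: int, rng: np.random.Generator) -> np.ndarray:
    """Partition `total` children over `n_parents` parents, each >= 1,
    with the remainder spread over a random subset of parents."""
    if total < n_parents:
        raise ConfigError(f"cannot give {n_parents} parents >= 1 child from {total}")
    base = total // n_parents
    extra = total - base * n_parents
    counts = np.full(n_parents, base, dtype=int)
    if extra:
        counts[rng.choice(n_parents, size=extra, replace=False)] += 1
    return counts


def generate_hierarchy(config: SimConfig) -> Hierarchy:
    """Build the administrative tree: one country, municipalities,
    districts, neighbourhoods, with land areas and urban flags assigned
    at neighbourhood level and summed upward. Populations are left unset
    (filled by :func:`assign_population`)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    units: list[StatUnit] = [StatUnit(id="C0", level="country", parent_id=None)]

    if config.exact_level_totals is not None:
        n_mun, n_dis, n_nbh = config.exact_level_totals
        if not (1 <= n_mun <= n_dis <= n_nbh):
            raise ConfigError("exact_level_totals must be increasing and >= 1")
        dis_counts = _split_total(n_dis, n_mun, rng)
        nbh_counts = _split_total(n_nbh, n_dis, rng)
    else:
        n_mun = config.n_municipalities
        lo, hi = config.districts_per_municipality
        dis_counts = rng.integers(lo, hi + 1, size=n_mun)
        lo, hi = config.neighbourhoods_per_district
        nbh_counts = rng.integers(lo, hi + 1, size=int(dis_counts.sum()))

    mun_ids = [f"MU{m:04d}" for m in range(n_mun)]
    units += [StatUnit(id=mid, level="municipality", parent_id="C0") for mid in mun_ids]

    dis_ids: list[str] = []
    d = 0
    for m, mid in enumerate(mun_ids):
        for _ in range(int(dis_counts[m])):
            did = f"DI{d:05d}"
            units.append(StatUnit(id=did, level="district", parent_id=mid))
            dis_ids.append(did)
            d += 1

    n = 0
    for d, did in enumerate(dis_ids):
        for _ in range(int(nbh_counts[d])):
            nid = f"NB{n:06d}"
            urban = bool(rng.random() < config.urban_probability)
            # urban neighbourhoods are smaller and denser
            med = 3.0e5 if urban else 1.5e6
            land = float(rng.lognormal(math.log(med), 0.35))
            units.append(
                StatUnit(id=nid, level="neighbourhood", parent_id=did,
                         land_area=land, urban_flag=urban)
            )
            n += 1

    hierarchy = Hierarchy(units)
    # roll land areas and urban flags up the tree
    for level in ("district", "municipality", "country"):
        for u in hierarchy.units_at(level):
            kids = hierarchy.children(u.id)
            u.land_area = sum(k.land_area for k in kids)
            u.urban_flag = sum(k.urban_flag for k in kids) * 2 > len(kids)
    return hierarchy


def _place_rectangles(areas: np.ndarray, origin: tuple[float, float],
                      rng: np.random.Generator) -> list[Polygon]:
    """Lay out non-overlapping axis-aligned rectangles of the given areas
    on a jittered grid anchored at `origin`."""
    aspect = rng.uniform(0.6, 1.6, size=len(areas))
    widths = np.sqrt(areas * aspect)
    depths = areas / widths
    pitch = float(max(widths.max(), depths.max())) + 2.0
    ncols = max(1, int(math.ceil(math.sqrt(len(areas)))))
    polys = []
    ox, oy = origin
    for i, (w, dpt) in enumerate(zip(widths, depths)):
        cx = ox + (i % ncols) * pitch
        cy = oy + (i // ncols) * pitch
        jx = rng.uniform(0.0, pitch - w - 1.0) if pitch - w > 1.0 else 0.0
        jy = rng.uniform(0.0, pitch - dpt - 1.0) if pitch - dpt > 1.0 else 0.0
        polys.append(box(cx + jx, cy + jy, cx + jx + w, cy + jy + dpt))
    return polys


def generate_buildings(hierarchy: Hierarchy, config: SimConfig) -> list[Building]:
    """Populate every neighbourhood with rectangular buildings.

    Floorspace follows footprint area x storeys x an efficiency factor with
    multiplicative noise; urban neighbourhoods draw more storeys. A share of
    buildings are small sheds (below the 20 m2 analysis cut, non-residential);
    residential fraction follows a {0, 1, Beta} mixture emulating mixed use.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    buildings: list[Building] = []
    nbhds = hierarchy.units_at("neighbourhood")
    # one grid cell per neighbourhood in a global layout; pitch generous
    # enough that neighbourhood extents never touch
    layout_cols = max(1, int(math.ceil(math.sqrt(len(nbhds)))))
    layout_pitch = 4000.0
    bid = 0
    lo, hi = config.buildings_per_neighbourhood
    for k, unit in enumerate(nbhds):
        n_b = int(rng.integers(lo, hi + 1))
        origin = ((k % layout_cols) * layout_pitch, (k // layout_cols) * layout_pitch)
        base_elev = float(rng.uniform(*config.base_elevation_range))

        is_shed = rng.random(n_b) < config.shed_probability
        areas = np.where(
            is_shed,
            rng.uniform(*config.shed_area_range, size=n_b),
            # dwellings are never below the 20 m2 shed scale
            np.maximum(rng.lognormal(config.footprint_area_log_mean,
                                     config.footprint_area_log_sd, size=n_b), 20.0),
        )
        mean_storeys = config.storey_mean_urban if unit.urban_flag else config.storey_mean_rural
        storeys = np.where(is_shed, 1,
                           1 + rng.poisson(max(mean_storeys - 1.0, 0.0), size=n_b))
        noise = rng.normal(0.0, config.floorspace_noise_sd, size=n_b) \
            if config.floorspace_noise_sd > 0 else np.zeros(n_b)
        floorspace = areas * storeys * config.floorspace_efficiency * np.clip(1.0 + noise, 0.05, None)

        u = rng.random(n_b)
        fraction = np.empty(n_b)
        p0, p1 = config.res_fraction_p0, config.res_fraction_p1
        fraction[u < p0] = 0.0
        fraction[(u >= p0) & (u < p0 + p1)] = 1.0
        mixed = u >= p0 + p1
        if mixed.any():
            a, b = config.res_fraction_beta
            draw = rng.beta(a, b, size=int(mixed.sum()))
            if config.exact_proportional:
                draw = np.round(draw)  # fractions restricted to {0, 1}
            fraction[mixed] = draw
        fraction[is_shed] = 0.0

        polys = _place_rectangles(areas, origin, rng)
        for i in range(n_b):
            buildings.append(
                Building(
                    id=f"B{bid:07d}",
                    neighbourhood_id=unit.id,
                    footprint=polys[i],
                    footprint_area=float(polys[i].area),
                    floorspace=float(floorspace[i]),
                    base_elevation=base_elev,
                    height=float(storeys[i] * config.storey_height),
                    residential_fraction=float(fraction[i]),
                )
            )
            bid += 1
    return buildings


def assign_population(buildings: list[Building], hierarchy: Hierarchy,
                      config: SimConfig) -> Hierarchy:
    """Draw per-neighbourhood space-per-resident and fill populations.

    Each neighbourhood u draws s_u from a log-normal whose median is the
    urban or rural value; residents of a building are its residential
    floorspace divided by s_u. The neighbourhood population is the
    rounded (half-up) sum; every higher level is the exact sum of its
    children, so conservation holds to the person.

    In exact-proportional mode residential floorspace is rescaled after
    rounding so that population == residential floorspace / s_u holds
    exactly with integer populations.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    by_nbhd: dict[str, list[Building]] = {}
    for b in buildings:
        by_nbhd.setdefault(b.neighbourhood_id, []).append(b)

    for unit in hierarchy.units_at("neighbourhood"):
        median = config.space_per_resident_urban if unit.urban_flag \
            else config.space_per_resident_rural
        if config.space_per_resident_sd > 0:
            s_u = float(rng.lognormal(math.log(median), config.space_per_resident_sd))
        else:
            s_u = float(median)
        unit.space_per_resident = s_u
        members = by_nbhd.get(unit.id, [])
        res_space = np.array([b.floorspace * b.residential_fraction for b in members])
        raw_total = float(res_space.sum()) / s_u if len(members) else 0.0
        pop = round_half_up(raw_total)
        unit.population = pop
        if config.exact_proportional and raw_total > 0:
            scale = pop * s_u / float(res_space.sum())
            for b in members:
                if b.residential_fraction > 0:
                    b.floorspace *= scale
                b.ground_truth_residents = b.floorspace * b.residential_fraction / s_u
        else:
            for b in members:
                b.ground_truth_residents = b.floorspace * b.residential_fraction / s_u

    for level in ("district", "municipality", "country"):
        for u in hierarchy.units_at(level):
            u.population = sum(k.population or 0 for k in hierarchy.children(u.id))
    return hierarchy


def generate_point_cloud(buildings: list[Building], config: SimConfig) -> np.ndarray:
    """Simulate airborne elevation samples as an (n, 3) array of x, y, z.

    Roof returns fall uniformly over each footprint at the building top
    plus vertical noise; ground returns scatter in a collar around each
    footprint at the base elevation; an optional fraction of roof returns
    are vegetation outliers with inflated z.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    chunks: list[np.ndarray] = []
    for b in buildings:
        minx, miny, maxx, maxy = b.footprint.bounds
        # rectangles: uniform in the bbox IS uniform in the footprint
        n_roof = int(rng.poisson(config.point_density * b.footprint_area))
        if n_roof:
            xs = rng.uniform(minx, maxx, n_roof)
            ys = rng.uniform(miny, maxy, n_roof)
            zs = np.full(n_roof, b.base_elevation + b.height)
            if config.point_noise_sd > 0:
                zs += rng.normal(0.0, config.point_noise_sd, n_roof)
            if config.outlier_rate > 0:
                hit = rng.random(n_roof) < config.outlier_rate
                zs = np.where(hit, zs + config.outlier_extra_height
                              * rng.uniform(0.5, 1.5, n_roof), zs)
            chunks.append(np.column_stack([xs, ys, zs]))
        # ground collar: ring of width 3 m around the footprint bbox
        collar_w = 3.0
        area_collar = (maxx - minx + 2 * collar_w) * (maxy - miny + 2 * collar_w) \
            - (maxx - minx) * (maxy - miny)
        n_gnd = int(rng.poisson(config.point_density * area_collar))
        if n_gnd:
            gx = np.empty(n_gnd)
            gy = np.empty(n_gnd)
            filled = 0
            while filled < n_gnd:
                cx = rng.uniform(minx - collar_w, maxx + collar_w, n_gnd - filled)
                cy = rng.uniform(miny - collar_w, maxy + collar_w, n_gnd - filled)
                keep = ~((cx > minx) & (cx < maxx) & (cy > miny) & (cy < maxy))
                k = int(keep.sum())
                gx[filled:filled + k] = cx[keep]
                gy[filled:filled + k] = cy[keep]
                filled += k
            gz = np.full(n_gnd, b.base_elevation)
            if config.point_noise_sd > 0:
                gz += rng.normal(0.0, config.point_noise_sd, n_gnd)
            chunks.append(np.column_stack([gx, gy, gz]))
    if not chunks:
        return np.empty((0, 3))
    return np.vstack(chunks)


@dataclass
class SyntheticWorld:
    """A complete generated country: hierarchy with populations, building
    register, and the configuration that produced them."""

    hierarchy: Hierarchy
    buildings: list[Building]
    config: SimConfig

    def point_cloud(self) -> np.ndarray:
        return generate_point_cloud(self.buildings, self.config)


def generate_world(config: SimConfig) -> SyntheticWorld:
    """Run the full generator: hierarchy, buildings, populations."""
    hierarchy = generate_hierarchy(config)
    buildings = generate_buildings(hierarchy, config)
    assign_population(buildings, hierarchy, config)
    return SyntheticWorld(hierarchy=hierarchy, buildings=buildings, config=config)


def buildings_to_frame(buildings: list[Building]) -> pd.DataFrame:
    """Attribute table (no geometry) for vectorised downstream math."""
    return pd.DataFrame(
        {
            "id": [b.id for b in buildings],
            "neighbourhood_id": [b.neighbourhood_id for b in buildings],
            "footprint_area": [b.footprint_area for b in buildings],
            "floorspace": [b.floorspace for b in buildings],
            "base_elevation": [b.base_elevation for b in buildings],
            "height": [b.height for b in buildings],
            "residential_fraction": [b.residential_fraction for b in buildings],
        }
    )
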