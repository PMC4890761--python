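"""Administrative hierarchy container.

A country is decomposed into municipalities, districts and neighbourhoods;
each unit carries a census population and a land area. The hierarchy is a
tree rooted at the single country unit, and populations are conserved
exactly up the tree: every non-leaf population equals the sum of its
children's populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Levels ordered from finest to coarsest.
LEVELS = ("neighbourhood", "district", "municipality", "country")

LEVEL_INDEX = {name: i for i, name in enumerate(LEVELS)}


class HierarchyError(ValueError):
    """Raised when hierarchy invariants are violated."""


@dataclass
class StatUnit:
    """A statistical (administrative) unit carrying a census population."""

    id: str
    level: str
    parent_id: str | None
    population: int | None = None
    land_area: float = 0.0
    urban_flag: bool = False
    #: average living space per resident (m2/person); filled by the
    #: simulator as ground truth, None for real data.
    space_per_resident: float | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVEL_INDEX:
            raise HierarchyError(f"unknown level {self.level!r} for unit {self.id}")
        if self.level == "country" and self.parent_id is not None:
            raise HierarchyError("country unit must not have a parent")
        if self.level != "country" and self.parent_id is None:
            raise HierarchyError(f"unit {self.id} at level {self.level} needs a parent")


class Hierarchy:
    """Forest-free tree of :class:`StatUnit` rooted at one country unit.

    Parameters
    ----------
    units
        Iterable of :class:`StatUnit`; must contain exactly one country unit
        and consistent parent links (each parent one level up).
    """

    def __init__(self, units):
        self.units: dict[str, StatUnit] = {}
        for u in units:
            if u.id in self.units:
                raise HierarchyError(f"duplicate unit id {u.id!r}")
            self.units[u.id] = u
        self._children: dict[str, list[str]] = {uid: [] for uid in self.units}
        roots = [u for u in self.units.values() if u.level == "country"]
        if len(roots) != 1:
            raise HierarchyError(f"expected exactly 1 country unit, found {len(roots)}")
        self.root = roots[0]
        for u in self.units.values():
            if u.parent_id is None:
                continue
            parent = self.units.get(u.parent_id)
            if parent is None:
                raise HierarchyError(f"unit {u.id}: parent {u.parent_id!r} not found")
            if LEVEL_INDEX[parent.level] != LEVEL_INDEX[u.level] + 1:
                raise HierarchyError(
                    f"unit {u.id} ({u.level}) has parent {parent.id} ({parent.level}); "
                    "parent must be exactly one level up"
                )
            self._children[parent.id].append(u.id)

    def __len__(self) -> int:
        return len(self.units)

    def __contains__(self, uid: str) -> bool:
        return uid in self.units

    def __getitem__(self, uid: str) -> StatUnit:
        return self.units[uid]

    def units_at(self, level: str) -> list[StatUnit]:
        """All units at a level, in insertion order."""
        if level not in LEVEL_INDEX:
            raise HierarchyError(f"unknown level {level!r}")
        return [u for u in self.units.values() if u.level == level]

    def children(self, uid: str) -> list[StatUnit]:
        return [self.units[c] for c in self._children[uid]]

    def parent(self, uid: str) -> StatUnit | None:
        pid = self.units[uid].parent_id
        return None if pid is None else self.units[pid]

    def descendants_at(self, uid: str, level: str) -> list[StatUnit]:
        """All descendants of `uid` at the given (finer) level; `uid` itself
        if it is already at that level."""
        unit = self.units[uid]
        if unit.level == level:
            return [unit]
        if LEVEL_INDEX[unit.level] < LEVEL_INDEX[level]:
            raise HierarchyError(
                f"{level} is not below {unit.level}; cannot take descendants"
            )
        out: list[StatUnit] = []
        stack = [uid]
        while stack:
            cur = stack.pop()
            for child in self._children[cur]:
                cu = self.units[child]
                if cu.level == level:
                    out.append(cu)
                else:
                    stack.append(child)
        out.sort(key=lambda u: u.id)
        return out

    def validate_populations(self) -> None:
        """Check populations sum exactly up the tree; raise listing offenders."""
        bad = []
        for u in self.units.values():
            kids = self._children[u.id]
            if not kids:
                continue
            total = sum(self.units[c].population or 0 for c in kids)
            if u.population is not None and u.population != total:
                bad.append(f"{u.id}: population {u.population} != sum of children {total}")
        if bad:
            raise HierarchyError("population conservation violated: " + "; ".join(bad))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "unit_id": u.id,
                "level": u.level,
                "parent_id": u.parent_id if u.parent_id is not None else "",
                "population": u.population,
                "land_area": u.land_area,
                "urban_flag": int(u.urban_flag),
            }
            for u in self.units.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Hierarchy":
        units = []
        for _, row in df.iterrows():
            parent = row.get("parent_id", "")
            parent = None if (pd.isna(parent) or parent == "") else str(parent)
            pop = row.get("population")
            units.append(
                StatUnit(
                    id=str(row["unit_id"]),
                    level=str(row["level"]),
                    parent_id=parent,
                    population=None if pd.isna(pop) else int(pop),
                    land_area=float(row.get("land_area", 0.0)),
                    urban_flag=bool(int(row["urban_flag"])) if "urban_flag" in row and not pd.isna(row.get("urban_flag")) else False,
                )
            )
        return cls(units)
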