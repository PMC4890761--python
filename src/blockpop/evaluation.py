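"""Evaluation of population estimates.

Estimates are scored with percentage errors — an absolute error of 1000
persons means something very different for a neighbourhood and for a
municipality — and summarised per experiment by the median absolute
percentage error, which is robust to the very large relative errors that
small units produce. A full evaluation run is a 12-task x 9-LOD grid of
108 experiments: six disaggregation scales, three local statistical
scales, and three country-total statistical scales, each at all nine
levels of detail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    DISAGGREGATION_TASKS,
    STATISTICAL_TASKS,
    DisaggregationModel,
    ExperimentSpec,
    PopulationEstimates,
    PopulationRegression,
)
from .hierarchy import Hierarchy
from .proxies import ALL_LODS, LODSpec, compute_unit_proxies, rollup_proxies

log = logging.getLogger(__name__)

#: the 12 evaluation tasks of a full grid
GRID_TASKS = (
    "D1", "D2", "D3", "D4", "D5", "D6",
    "S1", "S2", "S3",
    "S1-country", "S2-country", "S3-country",
)


class EvaluationError(ValueError):
    """Raised for undefined evaluation requests."""


def percentage_error(predicted, observed):
    """Signed percentage error (predicted - observed) / observed x 100.

    Units with observed population 0 get NaN (undefined) and are excluded
    from medians downstream; exclusions are logged, never fatal.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if (obs < 0).any():
        raise EvaluationError("observed populations must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = np.where(obs > 0, (pred - obs) / obs * 100.0, np.nan)
    n_undef = int(np.isnan(pe).sum())
    if n_undef:
        log.info("%d units with observed population 0 excluded from errors", n_undef)
    if pe.ndim == 0:
        return float(pe)
    return pe


def median_ape(errors) -> float:
    """Median of absolute percentage errors, ignoring undefined (NaN)
    entries; for an even count, the mean of the central pair."""
    e = np.asarray(errors, dtype=float)
    e = e[~np.isnan(e)]
    if e.size == 0:
        raise EvaluationError("no defined errors: all units excluded")
    return float(np.median(np.abs(e)))


def stratify_by_density(units) -> dict[str, str]:
    """Label units 'lower'/'higher' by population density relative to the
    median density. Density is observed population over land area; units
    strictly below the median are 'lower', the rest (ties included)
    'higher'.
    """
    items = list(units)
    for u in items:
        if u.land_area <= 0:
            raise EvaluationError(f"unit {u.id}: land_area must be > 0")
    dens = np.array([(u.population or 0) / u.land_area for u in items])
    med = float(np.median(dens))
    return {u.id: ("lower" if d < med else "higher") for u, d in zip(items, dens)}


def error_space_correlation(errors, space_per_resident) -> float:
    """Pearson correlation between estimation errors and average living
    space per resident — the dominant driver of error in building-based
    estimation."""
    e = np.asarray(errors, dtype=float)
    s = np.asarray(space_per_resident, dtype=float)
    mask = np.isfinite(e) & np.isfinite(s)
    e, s = e[mask], s[mask]
    if e.size < 3:
        raise EvaluationError("need at least 3 paired finite values")
    if np.std(e) == 0 or np.std(s) == 0:
        raise EvaluationError("zero variance in errors or space per resident")
    r, _ = stats.pearsonr(e, s)
    return float(r)


@dataclass
class ExperimentCell:
    """One cell of the 12 x 9 grid."""

    task: str
    lod: LODSpec
    median_ape: float
    n_units: int
    n_excluded: int
    #: signed percentage error of the country-total estimate (country
    #: variants only, where n = 1)
    signed_error: float | None = None


@dataclass
class ResultTable:
    """All 108 experiment cells plus run metadata."""

    cells: list[ExperimentCell]
    metadata: dict = field(default_factory=dict)

    def cell(self, task: str, lod: LODSpec) -> ExperimentCell:
        for c in self.cells:
            if c.task == task and c.lod == lod:
                return c
        raise KeyError(f"no cell for ({task}, {lod})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "task": c.task,
                "geometric_lod": c.lod.geometric,
                "semantic_lod": c.lod.semantic,
                "median_ape": c.median_ape,
                "n": c.n_units,
                "n_excluded": c.n_excluded,
                "signed_error": c.signed_error,
            }
            for c in self.cells
        )

    def render_text(self) -> str:
        """Twelve 3x3 blocks (geometric LOD as rows, semantic as columns),
        three tasks side by side per band."""
        bands = [
            ("(1) Disaggregation", ["D1", "D2", "D3"]),
            ("", ["D4", "D5", "D6"]),
            ("(2) Statistical approach (local units)", ["S1", "S2", "S3"]),
            ("(2) Statistical approach (country level)",
             ["S1-country", "S2-country", "S3-country"]),
        ]
        out = []
        geo_rows = ("LOD0", "LOD0+", "LOD1")
        for title, tasks in bands:
            if title:
                out.append(title)
            header = []
            for t in tasks:
                n = self.cell(t, LODSpec("LOD0", "a")).n_units
                header.append(f"{t} (n = {n})".center(24))
            out.append("      " + " | ".join(header))
            out.append("      " + " | ".join(f"{'a':>8}{'b':>8}{'c':>8}" for _ in tasks))
            for geo in geo_rows:
                row = []
                for t in tasks:
                    vals = [self.cell(t, LODSpec(geo, s)).median_ape for s in "abc"]
                    row.append("".join(f"{v:8.1f}" for v in vals))
                out.append(f"{geo:>5} " + " | ".join(row))
            out.append("")
        return "\n".join(out)

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "cells": [
                    {
                        "task": c.task,
                        "lod": str(c.lod),
                        "median_ape": c.median_ape,
                        "n": c.n_units,
                        "n_excluded": c.n_excluded,
                        "signed_error": c.signed_error,
                    }
                    for c in self.cells
                ],
            },
            indent=2,
        )


def evaluate_estimates(result: PopulationEstimates, task: str) -> ExperimentCell:
    """Score one experiment's estimates into a grid cell."""
    errors = result.percentage_errors().to_numpy()
    return ExperimentCell(
        task=task,
        lod=result.spec.lod,
        median_ape=median_ape(errors),
        n_units=len(result.estimates),
        n_excluded=result.n_excluded(),
    )


def run_experiment_grid(world, seed: int = 0, train_fraction: float = 0.1,
                        min_area: float = 20.0, enhanced: bool = False,
                        volumes: dict[str, float] | None = None) -> ResultTable:
    """Run all 108 experiments (12 tasks x 9 LODs) on a complete world.

    Proxies are computed once per LOD at neighbourhood level and rolled
    up; each statistical level uses one random training split shared
    across LODs (one sampling census per level), derived from ``seed``.
    """
    hierarchy: Hierarchy = world.hierarchy
    buildings = world.buildings
    truth = hierarchy.root.population
    cells: list[ExperimentCell] = []
    # per-level split seeds, stable across LODs
    level_seed = {lvl: seed * 1000 + i for i, lvl in
                  enumerate(("neighbourhood", "district", "municipality"))}

    for lod in ALL_LODS:
        nbhd = compute_unit_proxies(buildings, hierarchy, lod, min_area=min_area,
                                    volumes=volumes)
        by_level = {
            "neighbourhood": nbhd,
            "district": rollup_proxies(nbhd, hierarchy, "district"),
            "municipality": rollup_proxies(nbhd, hierarchy, "municipality"),
        }
        for task, (src, tgt) in DISAGGREGATION_TASKS.items():
            model = DisaggregationModel(hierarchy, by_level[tgt], task, lod)
            cells.append(evaluate_estimates(model.fit(), task))
        for task, level in STATISTICAL_TASKS.items():
            use_enhanced = enhanced and lod.geometric != "LOD0"
            reg = PopulationRegression(hierarchy, by_level[level], level, lod,
                                       train_fraction=train_fraction,
                                       enhanced=use_enhanced)
            result = reg.fit(seed=level_seed[level])
            cells.append(evaluate_estimates(result, task))
            signed = percentage_error(result.country_total, truth)
            cells.append(ExperimentCell(
                task=f"{task}-country", lod=lod, median_ape=abs(signed),
                n_units=1, n_excluded=0, signed_error=float(signed),
            ))
    table = ResultTable(cells=cells, metadata={
        "seed": seed,
        "train_fraction": train_fraction,
        "min_area": min_area,
        "enhanced": enhanced,
        "n_tasks": len(GRID_TASKS),
        "n_lods": len(ALL_LODS),
    })
    if len(table.cells) != len(GRID_TASKS) * len(ALL_LODS):
        raise EvaluationError("incomplete grid")  # pragma: no cover
    return table
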