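"""Population estimators: top-down disaggregation and bottom-up regression.

Two directions are implemented, mirroring the two classical families of
building-based population estimation:

* **Disaggregation (areal interpolation).** The known population of a
  source unit (country, municipality or district) is distributed over its
  descendant units proportionally to their residential-space proxies. Six
  source/target scale pairs are supported (D1-D6).

* **Statistical modelling.** An ordinary-least-squares relation between a
  unit's residential-space proxy and its census population is fitted on a
  random 10% sample of units at one level (a sampling census) and applied
  to the remaining 90% (S1 neighbourhoods, S2 districts, S3
  municipalities). Summing observed training populations with predicted
  test populations yields a country-total estimate. An enhanced variant
  adds the unit's mean building height as a second regressor; it is not
  available for the footprint-only geometric level, which carries no
  heights.

Both are exposed as model classes whose ``fit()`` returns a
:class:`PopulationEstimates` results object, plus the underlying
functional primitives (:func:`disaggregate`, :func:`fit_ols`, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .hierarchy import Hierarchy, LEVEL_INDEX
from .proxies import LODSpec, UnitProxy, compute_unit_proxies, rollup_proxies

log = logging.getLogger(__name__)

#: the six disaggregation tasks: source level -> target level
DISAGGREGATION_TASKS = {
    "D1": ("country", "neighbourhood"),
    "D2": ("municipality", "neighbourhood"),
    "D3": ("district", "neighbourhood"),
    "D4": ("country", "district"),
    "D5": ("municipality", "district"),
    "D6": ("country", "municipality"),
}

#: the three statistical tasks: level sampled and estimated
STATISTICAL_TASKS = {
    "S1": "neighbourhood",
    "S2": "district",
    "S3": "municipality",
}


class EstimationError(ValueError):
    """Raised for invalid estimation requests."""


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: a task, an LOD, and sampling settings."""

    method: str                 # disaggregation | statistical_local | statistical_country
    source_level: str | None
    target_level: str
    lod: LODSpec
    train_fraction: float = 0.1
    seed: int | None = None
    enhanced: bool = False

    @classmethod
    def from_task(cls, task: str, lod: LODSpec, *, country_total: bool = False,
                  train_fraction: float = 0.1, seed: int | None = None,
                  enhanced: bool = False) -> "ExperimentSpec":
        if task in DISAGGREGATION_TASKS:
            src, tgt = DISAGGREGATION_TASKS[task]
            return cls("disaggregation", src, tgt, lod)
        if task in STATISTICAL_TASKS:
            level = STATISTICAL_TASKS[task]
            method = "statistical_country" if country_total else "statistical_local"
            return cls(method, None, level, lod, train_fraction=train_fraction,
                       seed=seed, enhanced=enhanced)
        raise EstimationError(f"unknown task {task!r}; expected D1-D6 or S1-S3")


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def disaggregate(parent_population: float, weights) -> np.ndarray:
    """Distribute a parent population over children proportionally to
    non-negative weights; the children sum to the parent exactly (no
    rounding). All-zero weights leave the population unallocated: every
    child gets 0 and a warning is logged."""
    w = np.asarray(weights, dtype=float)
    if parent_population < 0:
        raise EstimationError("parent population must be >= 0")
    if (w < 0).any():
        raise EstimationError("disaggregation weights must be non-negative")
    total = w.sum()
    if total == 0:
        if parent_population > 0:
            log.warning("all weights zero: %s persons unallocatable", parent_population)
        return np.zeros_like(w)
    return parent_population * w / total


def run_disaggregation(hierarchy: Hierarchy, unit_proxies: dict[str, UnitProxy],
                       spec: ExperimentSpec) -> "PopulationEstimates":
    """Apply proportional disaggregation within each source-level parent
    over its target-level descendants, weighting by the LOD proxy."""
    if spec.method != "disaggregation":
        raise EstimationError(f"spec method {spec.method!r} is not disaggregation")
    rows = []
    for parent in hierarchy.units_at(spec.source_level):
        children = hierarchy.descendants_at(parent.id, spec.target_level)
        weights = []
        for c in children:
            if c.id not in unit_proxies:
                raise EstimationError(f"missing proxy for unit {c.id}")
            weights.append(unit_proxies[c.id].total_proxy)
        estimates = disaggregate(parent.population or 0, weights)
        for c, est in zip(children, estimates):
            rows.append((c.id, c.population, est))
    df = pd.DataFrame(rows, columns=["unit_id", "observed", "predicted"])
    return PopulationEstimates(spec=spec, estimates=df)


def split_train_test(unit_ids, fraction: float = 0.1, seed: int | None = None,
                     ) -> tuple[list[str], list[str]]:
    """Simple random split without replacement. The training size is
    round-half-up of n x fraction, clamped to at least 3; train and test
    are disjoint and exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise EstimationError("fraction must lie in (0, 1)")
    ids = list(unit_ids)
    n = len(ids)
    n_train = max(3, int(math.floor(n * fraction + 0.5)))
    if n_train >= n:
        raise EstimationError(
            f"cannot split {n} units into a {fraction:.0%} training sample of "
            f">= 3 with a non-empty test set"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


@dataclass
class RegressionModel:
    """A fitted population ~ proxy (+ mean height) linear relation."""

    intercept: float
    coef_proxy: float
    coef_mean_height: float | None
    n: int
    rss: float
    bse: dict[str, float] = field(default_factory=dict)
    sm_results: object | None = None

    @property
    def enhanced(self) -> bool:
        return self.coef_mean_height is not None


def fit_ols(proxy, population, mean_height=None, intercept: bool = True,
            ) -> RegressionModel:
    """Fit the linear relation between residential-space proxy and
    population by ordinary least squares; the enhanced variant adds the
    unit's mean building height as a second regressor."""
    x = np.asarray(proxy, dtype=float)
    y = np.asarray(population, dtype=float)
    cols = [x]
    names = ["proxy"]
    if mean_height is not None:
        h = np.asarray(mean_height, dtype=float)
        if np.isnan(h).any():
            raise EstimationError("mean_height contains undefined values")
        cols.append(h)
        names.append("mean_height")
    X = np.column_stack(cols)
    if intercept:
        X = sm.add_constant(X, has_constant="add")
        names = ["const"] + names
    p = X.shape[1]
    if len(y) < p + 1:
        raise EstimationError(f"need at least {p + 1} units to fit {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise EstimationError("design matrix is rank-deficient "
                              "(collinear or constant regressors)")
    res = sm.OLS(y, X).fit()
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    return RegressionModel(
        intercept=float(params.get("const", 0.0)),
        coef_proxy=float(params["proxy"]),
        coef_mean_height=float(params["mean_height"]) if "mean_height" in params else None,
        n=int(res.nobs),
        rss=float(res.ssr),
        bse=bse,
        sm_results=res,
    )


def predict_population(model: RegressionModel, proxy, mean_height=None) -> np.ndarray:
    """Linear prediction, clamped below at zero (populations cannot be
    negative; clamped units are logged)."""
    x = np.asarray(proxy, dtype=float)
    pred = model.intercept + model.coef_proxy * x
    if model.enhanced:
        if mean_height is None:
            raise EstimationError("enhanced model needs mean_height covariates")
        h = np.asarray(mean_height, dtype=float)
        if np.isnan(h).any():
            raise EstimationError("mean_height contains undefined values")
        pred = pred + model.coef_mean_height * h
    neg = pred < 0
    if neg.any():
        log.warning("%d negative predictions clamped to 0", int(neg.sum()))
        pred = np.where(neg, 0.0, pred)
    return pred


def estimate_country_total(hierarchy: Hierarchy, train_ids, predictions: dict[str, float],
                           level: str, pure_prediction: bool = False) -> float:
    """Country-total estimate from a sampling census: observed training
    populations plus predicted test populations. With ``pure_prediction``
    the model's predictions are summed for every unit instead."""
    train = set(train_ids)
    units = hierarchy.units_at(level)
    test_ids = [u.id for u in units if u.id not in train]
    missing = [uid for uid in (predictions.keys() if pure_prediction else test_ids)
               if uid not in predictions]
    if missing or any(uid not in predictions for uid in test_ids):
        lacking = [uid for uid in test_ids if uid not in predictions]
        raise EstimationError(f"predictions missing for test units: {lacking[:5]} ...")
    if pure_prediction:
        if any(u.id not in predictions for u in units):
            raise EstimationError("pure-prediction total needs predictions for all units")
        return float(sum(predictions[u.id] for u in units))
    total = sum(hierarchy[uid].population or 0 for uid in train)
    total += sum(predictions[uid] for uid in test_ids)
    return float(total)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

class PopulationEstimates:
    """Results of one estimation experiment.

    Carries per-unit observed and predicted populations, the experiment
    spec, and (for statistical experiments) the fitted regression and the
    country-total estimate.
    """

    def __init__(self, spec: ExperimentSpec, estimates: pd.DataFrame,
                 model: RegressionModel | None = None,
                 country_total: float | None = None,
                 train_ids: list[str] | None = None):
        self.spec = spec
        self.estimates = estimates.reset_index(drop=True)
        self.model = model
        self.country_total = country_total
        self.train_ids = train_ids

    @property
    def observed(self) -> pd.Series:
        return self.estimates["observed"]

    @property
    def predicted(self) -> pd.Series:
        return self.estimates["predicted"]

    def percentage_errors(self) -> pd.Series:
        """Signed percentage errors per unit; NaN where observed is 0
        (those units are excluded from medians)."""
        obs = self.observed.to_numpy(dtype=float)
        pred = self.predicted.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pe = np.where(obs > 0, (pred - obs) / obs * 100.0, np.nan)
        return pd.Series(pe, index=self.estimates["unit_id"], name="percentage_error")

    def median_ape(self) -> float:
        from .evaluation import median_ape
        return median_ape(self.percentage_errors().to_numpy())

    def n_excluded(self) -> int:
        return int((self.observed.to_numpy(dtype=float) == 0).sum())

    def summary(self) -> str:
        """Plain-text summary table of the experiment."""
        lines = []
        title = f"Population estimates — {self.spec.method}, LOD {self.spec.lod}"
        lines.append(title)
        lines.append("=" * len(title))
        if self.spec.method == "disaggregation":
            lines.append(f"source level:    {self.spec.source_level}")
        lines.append(f"target level:    {self.spec.target_level}")
        lines.append(f"units evaluated: {len(self.estimates)}"
                     f" ({self.n_excluded()} with observed 0 excluded from medians)")
        try:
            lines.append(f"median APE:      {self.median_ape():.1f}%")
        except ValueError:
            lines.append("median APE:      undefined (no unit with observed > 0)")
        if self.model is not None:
            m = self.model
            lines.append(f"OLS fit (n = {m.n}):")
            lines.append(f"  intercept       {m.intercept:12.4f}")
            lines.append(f"  coef proxy      {m.coef_proxy:12.6g}")
            if m.enhanced:
                lines.append(f"  coef mean height{m.coef_mean_height:12.6g}")
        if self.country_total is not None:
            lines.append(f"country total:   {self.country_total:,.0f} persons")
        return "\n".join(lines)

    def plot_observed_vs_predicted(self, ax=None, density_labels: dict | None = None):
        """Observed-vs-predicted scatter; optional colouring by a
        lower/higher density label per unit id. Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.estimates
        if density_labels:
            colors = df["unit_id"].map(lambda u: {"lower": "tab:green",
                                                  "higher": "tab:purple"}
                                       .get(density_labels.get(u), "gray"))
            ax.scatter(df["observed"], df["predicted"], s=8, c=colors, alpha=0.6)
        else:
            ax.scatter(df["observed"], df["predicted"], s=8, alpha=0.6)
        lim = max(df["observed"].max(), df["predicted"].max())
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("observed population")
        ax.set_ylabel("predicted population")
        ax.set_title(f"{self.spec.method} / {self.spec.lod}")
        return ax


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class DisaggregationModel:
    """Top-down proportional disaggregation of census populations.

    Parameters
    ----------
    hierarchy
        Administrative tree with source-level populations known.
    unit_proxies
        Target-level :class:`UnitProxy` per unit id.
    task
        One of D1-D6, or an explicit (source_level, target_level) pair.
    lod
        The level of detail the proxies were computed at.
    """

    def __init__(self, hierarchy: Hierarchy, unit_proxies: dict[str, UnitProxy],
                 task: str | tuple[str, str], lod: LODSpec):
        if isinstance(task, str):
            if task not in DISAGGREGATION_TASKS:
                raise EstimationError(f"unknown disaggregation task {task!r}")
            source, target = DISAGGREGATION_TASKS[task]
        else:
            source, target = task
            if LEVEL_INDEX[source] <= LEVEL_INDEX[target]:
                raise EstimationError("source level must be above target level")
        self.hierarchy = hierarchy
        self.unit_proxies = unit_proxies
        self.spec = ExperimentSpec("disaggregation", source, target, lod)

    @classmethod
    def from_buildings(cls, hierarchy: Hierarchy, buildings, task, lod: LODSpec,
                       min_area: float = 20.0, volumes=None) -> "DisaggregationModel":
        nbhd = compute_unit_proxies(buildings, hierarchy, lod, min_area=min_area,
                                    volumes=volumes)
        target = DISAGGREGATION_TASKS[task][1] if isinstance(task, str) else task[1]
        proxies = nbhd if target == "neighbourhood" else rollup_proxies(
            nbhd, hierarchy, target)
        return cls(hierarchy, proxies, task, lod)

    def fit(self) -> PopulationEstimates:
        return run_disaggregation(self.hierarchy, self.unit_proxies, self.spec)


class PopulationRegression:
    """Bottom-up OLS estimation from a sampling census.

    A fraction of the units at one level is treated as surveyed (the
    training sample); the fitted proxy-population relation predicts the
    remaining units. The enhanced variant adds mean building height and
    is rejected at the footprint-only geometric level, which has no
    height information.
    """

    def __init__(self, hierarchy: Hierarchy, unit_proxies: dict[str, UnitProxy],
                 level: str, lod: LODSpec, train_fraction: float = 0.1,
                 enhanced: bool = False, intercept: bool = True):
        if level not in ("neighbourhood", "district", "municipality"):
            raise EstimationError(f"cannot run a sampling census at level {level!r}")
        if enhanced and lod.geometric == "LOD0":
            raise EstimationError(
                "the mean-height enhancement is not available for LOD0: "
                "footprints carry no height information"
            )
        self.hierarchy = hierarchy
        self.unit_proxies = unit_proxies
        self.level = level
        self.lod = lod
        self.train_fraction = train_fraction
        self.enhanced = enhanced
        self.intercept = intercept

    def fit(self, seed: int | None = None) -> PopulationEstimates:
        units = self.hierarchy.units_at(self.level)
        ids = [u.id for u in units]
        train, test = split_train_test(ids, self.train_fraction, seed)
        px = self.unit_proxies

        def covariates(uids):
            proxy = np.array([px[u].total_proxy for u in uids])
            if not self.enhanced:
                return proxy, None
            heights = np.array([
                np.nan if px[u].mean_height is None else px[u].mean_height
                for u in uids
            ])
            return proxy, heights

        x_tr, h_tr = covariates(train)
        y_tr = np.array([self.hierarchy[u].population for u in train], dtype=float)
        model = fit_ols(x_tr, y_tr, mean_height=h_tr, intercept=self.intercept)

        x_te, h_te = covariates(test)
        pred = predict_population(model, x_te, mean_height=h_te)
        df = pd.DataFrame({
            "unit_id": test,
            "observed": [self.hierarchy[u].population for u in test],
            "predicted": pred,
        })
        country_total = estimate_country_total(
            self.hierarchy, train, dict(zip(test, pred)), self.level)
        spec = ExperimentSpec("statistical_local", None, self.level, self.lod,
                              train_fraction=self.train_fraction, seed=seed,
                              enhanced=self.enhanced)
        return PopulationEstimates(spec=spec, estimates=df, model=model,
                                   country_total=country_total, train_ids=train)
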