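# Methods

## Estimation model

Let `w_i^(L)` be the residential-space proxy of building `i` at LOD `L`:
a geometric base (footprint area, floorspace, or prism volume) times a
semantic factor (1; an indicator `1[f_i ≥ 0.5]` of majority residential
use; or the residential fraction `f_i` itself). Unit proxies are sums of
building proxies over the unit's retained buildings; buildings with
footprints below 20 m² are excluded everywhere, as such structures
(sheds, garages) are unlikely to be inhabited.

**Disaggregation** distributes a parent's census population `P` over its
descendant units proportionally: `p̂_u = P · w_u / Σ_v w_v`. The
children sum to the parent exactly in floating point; no rounding is
applied to estimates. If every weight under a parent is zero the
population is left unallocated (all-zero estimates, logged) rather than
divided arbitrarily.

**Statistical estimation** draws a simple random sample of a fraction
`t` (default 0.1) of the units at one level — the training size is
round-half-up of `n·t`, clamped to ≥ 3 — fits
`pop_u = β₀ + β₁ w_u (+ β₂ h̄_u) + ε_u` by ordinary least squares, and
predicts the test units, clamping negative predictions at 0 (a
population cannot be negative). The optional second regressor `h̄_u` is
the arithmetic mean height of all retained buildings in the unit,
irrespective of use; it captures the tendency of taller (denser) areas
to hold less living space per resident. It is refused at `LOD0`, which
has no height information. The country total is the sum of observed
training populations and predicted test populations (a sampling census
of 10% plus estimation of the rest); a pure-prediction variant exists
behind a flag. The OLS fit itself is delegated to statsmodels; the test
suite cross-checks it against an independent pseudo-inverse solve.

Design choices that were genuinely open:

* **Intercept:** included by default. Zero residential space plausibly
  implies zero population, so a no-intercept flag is provided, but the
  intercept guards against proxy-scale misspecification on heterogeneous
  units.
* **Binary-use rule:** a building is "residential" iff its residential
  fraction is ≥ 0.5 (majority use); the threshold is configurable since
  real registers differ in how they flag mixed-use stock.
* **Country-total convention:** observed-train + predicted-test, chosen
  because the scenario is a partial census with estimation of the
  remainder.
* **Sampling:** simple random; stratified designs are out of scope.

## Extrusion

The top of a building is the median z of the elevation points whose
planimetric projection lies inside or on the boundary of its footprint
(closed point-in-polygon test, delegated to shapely and cross-checked
against an even-odd ray-casting oracle). The even-count median is the
mean of the two central values. No outlier pre-filtering is applied
before the median: with contamination below 50% (vegetation returns,
chimneys) the median's breakdown point already bounds the error at the
inlier noise scale, which the suite verifies by simulation. The base is
the median z of points in the annulus between the footprint boundary
and its outward buffer (default width 2 m); a per-building base
elevation override wins when supplied. Buildings with no points over
the footprint, or no ground points in the annulus, are dropped from
LOD1 proxies with a logged warning. Volume is footprint area × (top −
base), exactly.

## Evaluation

Per unit, the signed percentage error is `(p̂ − p)/p × 100`; units with
`p = 0` are undefined and excluded from medians (count reported — a
convention forced by division by zero, and consistent with using medians
precisely because small units blow up relative errors). Each experiment
cell reports the median absolute percentage error. A full grid is 12
tasks × 9 LODs = 108 cells: D1–D6 disaggregation scales, S1–S3 local
statistical scales, and S1–S3 country totals, the latter holding a
single signed percentage error each (n = 1). Density stratification
labels units below the median population density "lower" and the rest,
ties included, "higher". The error-vs-living-space diagnostic is the
Pearson correlation between unit errors and average space per resident;
on worlds where space-per-resident dispersion is the only noise source
it approaches 1, since the disaggregation error is then an affine
function of the unit's space per resident.

## The synthetic country

The generator emulates the statistical structure the estimators are
sensitive to, not the cartography:

* **Hierarchy.** Defaults: 12 municipalities, 2–4 districts each, 3–6
  neighbourhoods each (~160 neighbourhoods) — large enough that every
  task has meaningful sample sizes while a 108-cell grid runs in well
  under a second. A shape-only mode reproduces the Dutch counts
  (393 / 2816 / 12237). Each neighbourhood is urban with probability
  0.35 and draws a land area (log-normal; urban median 0.3 km², rural
  1.5 km²).
* **Buildings.** 12–40 per neighbourhood; rectangular, axis-aligned,
  placed on a jittered grid so footprints never overlap (point-in-polygon
  generality is still tested on hand-built non-rectangular fixtures).
  Footprint areas are log-normal (median 90 m², σ_log 0.45, floored at
  20 m²); 12% of buildings are sheds of 4–18 m², below the analysis cut
  and never residential. Storeys are 1 + Poisson (mean 4 urban, 1.5
  rural), storey height 3 m. Floorspace = area × storeys × 0.85
  efficiency × (1 + N(0, 0.05)) noise. Residential fraction follows a
  mixture: 0 with probability 0.15, 1 with probability 0.70, otherwise
  Beta(2, 2) — the mixed-use stock.
* **Occupancy.** Each neighbourhood draws a space-per-resident `s_u`
  from a log-normal with σ_log 0.25 and median 40 m²/person (urban) or
  65 m²/person (rural) — the urban–rural contrast is the mechanism
  behind the rural-overestimation bias the estimators exhibit. Residents
  per building = residential floorspace / `s_u`; the neighbourhood
  population is the half-up-rounded sum, and every higher level is the
  exact sum of its children, so conservation holds to the person.
* **Point cloud.** Roof returns uniform over each footprint at top
  elevation + N(0, σ) with σ = 0.1 m, Poisson counts at 0.5 points/m²;
  ground returns in a 3 m collar at base elevation; an optional outlier
  fraction gets inflated z (vegetation).
* **Noiseless-proportional mode** fixes `s_u` constant, removes
  floorspace noise and restricts fractions to {0, 1}. Because
  neighbourhood rounding would break exact proportionality, this mode
  rescales residential floorspace after rounding so `pop_u · s =
  residential floorspace_u` holds exactly with integer populations;
  floorspace-based fractional disaggregation then recovers every census
  count to machine precision, which anchors the correctness tests.

What the generator does **not** emulate: real street networks or
building morphology beyond prisms, terrain relief under buildings,
vacancy (assumed homogeneous), spatially correlated land use, or the
industrial outliers that dominate errors in real registers. Passing
tests therefore demonstrate the correctness and qualitative behaviour
of the estimators (conservation, exact recovery, bias direction, error
scaling), not the absolute error levels achievable on real national
data, which depend on heterogeneity the simulator only caricatures.

## Numerical conventions

* Coordinates are planar metres (a Dutch-RD-like local frame); no
  geodesy anywhere.
* Point-in-polygon counts boundary points as inside.
* Medians of even counts average the central pair, everywhere.
* Train/test splits, worlds and clouds are reproducible from a single
  integer seed via `numpy.random.SeedSequence` spawns.
* Disaggregation under all-zero weights yields zeros with a warning;
  percentage errors at observed 0 yield exclusion, never failure; OLS
  on rank-deficient designs raises.
* Problem sizes in the test suite (4-municipality worlds for multi-seed
  statistical checks, 20–100 seeds per property) were chosen to make
  the statistical assertions stable at desk scale.
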