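# Methods

## Model structure

The simulator evaluates conservation policy on a rectangular grid of cells,
the decision units. Each cell carries farmland area *Aᵢ* (ha), base-year
yield *yᵢ* (output units·ha⁻¹·yr⁻¹), a stratum label (upland/lowland) and a
climate-yield sensitivity *κᵢ*. Land is divisible: any portion of a cell's
farmland, up to all of it, can be converted. Conversion targets are a
conservation habitat (semi-natural grassland or broadleaf woodland) or, in
the three-compartment variant, low-yield agriculture producing a fraction
λ of conventional yield.

### Occupancy

Species' probability of occurrence responds linearly to the converted
fraction of a cell, clipped to [0, 1]:

    p = clip(p0 + δ_h·f_habitat + γ·f_lowyield + β·a(t), 0, 1)

The linear-in-fraction form is the simplest interpolation between the two
land-use endpoints that a species-distribution model would score; nothing
in the framework depends on it beyond the greedy-optimality results, which
require linearity while no clipping binds. Yield uplifts do not enter the
occupancy model: small productivity gains are assumed not to affect
in-field biodiversity. The Gain in Occupancy is the difference to the
no-policy baseline summed over cells and species and averaged over the 41
inclusive calendar years 2020–2060, with the baseline evaluated
year-by-year at the same anomaly (so with β = 0 the climate terms cancel
identically).

### Allocation

* **equal** — the target is divided equally over cells; when a cell lacks
  capacity the shortfall is re-divided equally among unfilled cells
  (iterative water-filling, at most one pass per cell).
* **cost_min** — cells enrol in ascending yield order (yield proxies the
  subsidy cost of taking land out of production).
* **biodiv_max** — cells enrol in descending score order, where the score is
  the per-hectare occupancy gain Σₛδ/Aᵢ under an area target and that gain
  divided by yield under output neutrality. Dividing by yield under the
  output constraint is a deliberate design choice the source text leaves
  open ("ranked … in terms of the gain in biodiversity"): it is the ranking
  that is exactly optimal for the binding constraint, and it preserves the
  dominance of biodiversity maximization over cost minimization; a
  per-hectare ranking can invert that ordering.

Ties break by ascending cell id for determinism. Because land is divisible
and objectives are linear, each greedy walk (whole cells, fractional final
cell) solves a continuous knapsack exactly; the test suite verifies this
against `scipy.optimize.linprog` on random small instances.

Sparing at uplift *g* removes output *g/(1+g)·Σyᵢ Aᵢ* measured at base-year
yields; the equal rule reduces to the closed-form fraction *f = g/(1+g)* of
every cell. The three-compartment split reassigns exactly one-third of the
spared hectares to low-yield agriculture, taking lowest-yield hectares
first with a fractional split of the marginal cell; total spared area is
unchanged, so the land-conserved curves of pure and three-compartment
sparing coincide. One-third is measured in hectares ("lowest output" read
as lowest output per hectare); an output-measured third would be a
different, also defensible, reading.

### Economics

Annual output sums conventional farmland at yield *yᵢ(t) = yᵢ·max(0, 1 +
κᵢ·a(t))* plus low-yield land at λ of that, both scaled by (1+g). The
uplift applies as a step from the base year (the source is silent on
phasing); consequently output neutrality holds year-by-year, not merely in
aggregate, provided κ is uniform across cells. With heterogeneous κ the
allocation, fixed once against base-year yields, drifts from neutrality in
later years by order *a(t)·sd(κ)* — which is why the generator's default κ
is uniform (see below). NPV uses end-of-year flows with the base-year flow
undiscounted, at the 3.5% HM Treasury rate by default. Leakage is the NPV
of the one-sided series max(0, −Δfood): food the policy forces onto
imports. Opportunity cost is −NPV(Δfood) times a configurable unit price
(default 1; output units are abstract, covering both calorific and
monetary framings).

## Synthetic landscape generator

The generator emulates the statistical structure of a national analysis —
not its geography. Defaults (the study conditions of every seeded test):

| parameter | default | meaning |
|---|---|---|
| grid | 40 × 40 cells | 2 km-style cells, desk scale |
| n_species | 100 | at-risk species pool |
| upland_fraction | 0.3 | contiguous low-yield column block |
| yield log-mean (upland / lowland) | 0.5 / 2.0 | log-normal, sd 0.4 |
| smoothing radius | 2 cells | moving-average spatial autocorrelation |
| archetypes (wood/grass/farm/generalist) | 0.3/0.3/0.2/0.2 | response patterns |
| climate slope | 0.02 yr⁻¹ | linear anomaly, 0 in 2020 |
| κ (mean, sd) | −0.05, 0.0 | uniform yield-climate sensitivity |
| λ | 0.1 | low-yield productivity fraction |
| cell area, farmland fraction | 400 ha, U(0.2, 0.9) | farmland per cell |

Yields are drawn log-normally per stratum, smoothed with a uniform kernel,
and each stratum's realized arithmetic mean is then rescaled onto its
target mean exp(μ + σ²/2). The rescaling makes "upland mean yield <
lowland mean yield" hold for *every* seed by construction, without
rejection sampling. Species archetypes draw per-species response
magnitudes (specialists 0.2–0.6 toward their habitat, small elsewhere;
farmland specialists γ in 0.2–0.6; generalists 0.02–0.1 everywhere) with
multiplicative per-cell log-normal noise; all responses are nonnegative by
default, which makes policy gains monotone in converted area and keeps the
rule-dominance ordering exact (it follows from LP optimality while
responses are linear and unclipped). Baseline occupancies sit in roughly
0.05–0.35 so clipping almost never binds at default response sizes.

The default κ is uniform across cells (−0.05 per unit anomaly, sd 0):
per-cell heterogeneity is supported (`kappa_sd`) but breaks exact per-year
output neutrality as noted above, so it is off in the study conditions.

What the generator does **not** emulate: real geography and soils, fitted
species-distribution models (responses are parametric), farm-level economic
heterogeneity beyond yield, spatial contiguity of conservation, and any
climate structure beyond a shared scalar anomaly. Passing tests therefore
demonstrate the policy arithmetic, the optimality and dominance structure
and the accounting identities — not predictions for any real landscape.
A `GB_PRESET` records the national-scale settings (57 230 cells of 2 km, a
600 kha sharing endpoint, 1–5% uplifts, 100 species) for users supplying
real data; the synthetic sharing sweep is expressed as fractions of total
farmland (0–15% in 10 steps) because an absolute hectare endpoint has no
meaning on a desk-scale grid.

## Numerical choices

* Allocation exactness: greedy walks place the fractional final cell so
  area/output identities hold to machine precision; validation tolerances
  are 1e−9 relative.
* Water-filling terminates in at most n passes; residuals below 1e−12 of
  the target end the loop.
* Occupancy clipping is applied after the full linear response including
  the climate term, in both policy and baseline states.
* Serialization writes floats as `%.17g` and reads with pandas
  `float_precision="round_trip"`, giving value-identical round-trips; ESRI
  ASCII grids write row 0 (northernmost) first with a 2000 m default cell
  size and NODATA −9999.
* Cells with zero yield are converted whole by the output-constrained rules
  before any output budget is spent (they are free in the knapsack sense).
* Degenerate inputs: empty allocations yield zero gain and zero deltas; a
  zero target or zero uplift returns an empty allocation; an empty flow
  series is rejected.

## Problem sizes

The test suite runs desk-scale problems: the 4-cell toy fixture for all
hand-checkable numbers, 6×6 to 10×10 seeded landscapes for property sweeps
(200 seeds for the neutrality suite), ≤ 6-cell instances for the 500-case
LP cross-check, and the 40×40 / 100-species default landscape for the
dominance and spatial-pattern regressions. These sizes were chosen so the
whole analysis re-runs from scratch in seconds while exercising every code
path; all scale linearly in cells × species × years.

## Known limitations

* Occupancy responses are exogenous parameters, not fitted models; there is
  no feedback from converted neighbours (no agglomeration or contiguity).
* Leakage is reported in food-output units only; converting it to overseas
  habitat or species impacts is out of scope.
* The biodiversity-max rule does not re-rank after partial selection; under
  the linear unclipped response this is irrelevant, but with strong
  clipping a re-ranking variant could differ.
* Output neutrality is defined at base-year yields; with heterogeneous
  climate-yield sensitivities it is exact only in the base year.
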