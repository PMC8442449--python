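# Methods

`magnav` implements a simulation experiment for testing geomagnetic
navigation strategies during long-distance bird migration: biased
correlated random walks (CRW) and correlated random bridges (CRB) are
driven over daily geomagnetic rasters by strategy-specific probability
surfaces, compared against empirical GPS tracks with three similarity
measures, and the strategies tallied over the best-scoring decile of a
pooled simulation batch.

## Data model and preprocessing

Tracks are planar projected fixes (metres). Preprocessing reproduces
the standard migratory-flight cleaning chain, in this fixed order:
exclusion circles of 500 km around the northernmost fix (breeding
area) and 700 km around the southernmost and westernmost fixes
(wintering area); a 6 km/h ground-speed filter in which a fix survives
if *either* adjacent segment is at or above threshold (this removes
stationary stopover clusters without truncating flight onset); a
minimum path length of 1500 km (summed segments, not displacement);
and linear interpolation onto an hourly lattice. The order of the
filters is a documented choice — the cleaning stages are individually
standard but their sequence is not fixed by convention; exclusion
first keeps the speed filter from being anchored by staging-area
fixes.

Geomagnetic cue grids (intensity F in nT, inclination I in degrees,
horizontal component H = F·cos I in nT) are single-band GeoTIFF
rasters on a shared planar grid, one file per cue per day, nominal
cell size 5 km. The grid origin is the centre of cell [0, 0] and the
row index increases with decreasing y. Point queries interpolate
bilinearly between cell centres (nearest-cell lookup is available for
exact cell-sampled behaviour). No reprojection is ever performed; the
CRS is carried as free-text metadata.

## Movement kernel

The empirical kernel consists of a joint histogram of (step length,
turning angle) pooled across animals, plus lag-1 difference histograms
of step length and (wrapped) turning angle computed within animals
only. A candidate step's probability mass is the product of the three
histogram masses — the simplest composition that preserves both the
marginal movement structure and one-step persistence of speed and
turning. Defaults are 30 length bins on [0, L_max] and 24 angular bins
on (−π, π]; both are configurable, and small samples warrant coarser
bins (see the recovery scenario below). When the lag-1 terms
annihilate every candidate (disjoint supports), sampling falls back to
the joint histogram alone, and as a last resort to a uniform draw over
the reachable window; both fallbacks are logged.

## Step sampling

Each simulated step considers the window of cells within L_max (the
largest observed step) of the walker. The movement surface is the
kernel mass of the (L, φ) that reaches each cell centre **divided by
the step length** (floored at half a cell): this converts the
per-(L, φ) mass into a probability per unit area, so that sampling
cells — whose number at distance L grows proportionally to L — exactly
reproduces the kernel's step-length law. The strategy bias surface is
evaluated on the same cells, and the sampling distribution is

    w ∝ movement^α · bias^β        (α = 0.5, β = 1 by default)

normalised over the window. The default corresponds to taking the
square root of the movement raster against the full-strength bias
raster, deliberately over-weighting the geomagnetic signal relative
to movement persistence. The chosen cell's position is jittered
uniformly within the cell (cell-centre mode available for exact
reproducibility); the realised displacement is capped at L_max plus
one length-bin width. Before exponentiation the bias is rescaled to
its window maximum — the sampling distribution is unchanged and large
β cannot underflow. The initial heading is the bearing to the
highest-valued bias cell within one step's reach (ties: nearest, then
row-major; flat or non-positive bias falls back to the bearing to the
target), plus a uniform error on ±π/12 (wrapped-normal optional). The
first step has no predecessor; its lag-1 conditioning uses the
kernel's mean step length and a zero previous turn.

Bias surfaces are rebuilt every step from the current day's grids and
the walker's position. Days advance every 24 steps from departure; if
a simulation outlasts the supplied field series the last day is
reused. The constant-heading calibration angle θ* is refreshed once
per simulated day, at the day's first step.

## The five strategies

* **no bias** — uniform 1 (control).
* **taxis** — linear scaling of the day's cue raster: global minimum
  → 1, maximum → 0 (autumn runs from high to low geomagnetic values;
  an inversion flag serves spring).
* **constant heading** — the angle at the bird between the direction
  to the cue grid's global extreme (max or min, per configuration) and
  the direction of travel is held near θ*, the mean such angle over
  points sampled at cell resolution on the straight segment bird →
  target; probability falls linearly, 180° away → 0. The vertex of
  the angle is the bird (one of two defensible readings; the other
  puts it at the extreme).
* **bi-gradient map** — per cue, probability 1 at the cue value of the
  target point, falling linearly over the raster's daily range
  (clipped at 0); the two single-cue rasters multiply.
* **combination** — the single-cue map raster of the first cue times
  the constant-heading raster of the second cue; the heading component
  uses the grid minimum (autumn) since the configuration table does
  not carry an extreme flag for combinations. The ordered cue pair is
  read as (map cue, heading cue), which yields exactly the six ordered
  pairs of the experiment.

The full experiment enumerates 19 configurations: 1 control, 3 taxis,
6 constant-heading (max/min × 3 cues), 3 bi-gradient pairs, 6 ordered
combination pairs.

## Bridges

The CRB multiplies a pull-to-target weight into the sampling
distribution: with k steps remaining, a cell at distance d from the
target is weighted by a normal density of the required mean progress
d/(k−1) under the kernel's step-length mean with a √(k−1)-shrunk sd
(floored at 1% of L_max; weights are computed in log space and
max-shifted so near-degenerate kernels cannot underflow). Cells
needing more than (k−1)·L_max are infeasible; inside the engine the
budget is additionally shrunk by half a cell diagonal so within-cell
jitter can never break it. The final step is placed on the target
exactly. The pull shape is a normal approximation to the
remaining-steps displacement budget; the feasibility cut is exact. On
coarse grids the feasibility lens can occasionally contain no cell
centre; such stranded replicates are redrawn from the same generator
stream (bounded attempts), preserving seed determinism.

## Similarity and evaluation

Three measures compare each simulation with its matched empirical
track: mean pointwise distance; unnormalised dynamic time warping
(Euclidean local cost, symmetric unit-slope moves, no window — chosen
for oracle-checkability against exhaustive path enumeration; rank use
downstream makes normalisation immaterial for equal-length pairs); and
the dynamic interaction index, per step the cosine of the heading
difference times 1 − (|d₁−d₂|/(d₁+d₂))^δ with δ = 1, averaged over
steps (both displacements zero → factor 1; exactly one zero → 0).

Each measure is modelled against the model label with a linear mixed
model (REML) carrying a random intercept per animal; cell-means coding
makes each fixed-effect coefficient the label's adjusted mean.
Singular fits fall back to cell means with animal-clustered standard
errors, flagged in the output. Within each strategy the variant with
the most favourable adjusted estimate on a configurable reference
measure (default: mean distance) is retained, the retained models are
pooled, and the best ⌊10%⌋ by each measure is tallied by strategy.
Ties rank by a stable sort on (score, animal, replicate). Under the
null (no informative bias) each of the five strategies is expected to
hold 20% of the retained set.

## Synthetic data

The generator emulates the study's inputs so the whole pipeline runs
without downloads. The field is a planar pseudo-dipole: F, I and H
decline monotonically with distance from a simulated pole corner
(F 63,000 → 24,000 nT, I 90° → 10°, H derived), with optional uniform
daily drift on F, cellwise storm noise (truncated at 3 sd), per-day
pole wander, and an optional convex radial profile for F (linear by
default; the convex profile keeps the *relative* F gradient roughly
constant across the domain, as a dipole's nonlinear falloff does). At
default scale the mean F gradient is of order 10 nT/km over the
domain diagonal. The generator does not emulate: spherical geometry,
declination, realistic storm spatial structure, or sub-daily field
dynamics — so passing tests support the pipeline's correctness on
smooth monotone fields, not geophysical fidelity.

Tracks come in two modes. Corridor mode emits hourly fixes along a
fixed heading at a mean speed with seeded heading and log-normal speed
noise (autumn defaults: 14 animals, up to 72 h, ~28 km/h, 1500–3000 km).
Strategy mode generates tracks with the package's own CRW engine under
a chosen strategy at high bias weight (β = 5) plus positional jitter —
the basis of parameter-recovery experiments.

### Fixture scenarios and problem sizes

* **smoke** — 3 animals, 24 hourly steps, 60×60 grid of 10 km cells:
  wiring checks in seconds.
* **study-scale** — 14 animals, 72 steps, 100×100 grid of 20 km cells
  with drift and storm noise: reproduces the study's batch bookkeeping
  (1400 simulations per model, 8400 for the six constant-heading
  variants, 7000 pooled, 700 retained) in a few minutes on one CPU.
* **recovery-taxis** — 6 animals, 48 steps at 12 km/h on a 320×320
  grid of 2.5 km cells; tracks generated under intensity-taxis at
  β = 5. Three design choices make the recovery experiment
  *identifiable*, and each was forced by a structural failure mode
  observed with the naive design:
  1. *Raster fine relative to the step* (cell ≈ step/5). On coarse
     rasters the reachable window collapses to a handful of cells and
     no bias can steer at all.
  2. *Coarse kernel bins* (12 length × 4 angle). The movement kernel
     is indifferent within a 90° sector, leaving the bias angular
     freedom to steer each step; fine angular bins on a few hundred
     pooled steps leave one or two supported cells per window and no
     freedom. The convex F profile (k = 35) keeps the relative
     gradient strong along the whole corridor; steeper profiles push
     the cellwise F differences below float64 resolution.
  3. *A day-boundary dog-leg* (the pole jumps ~650 km between days,
     rotating the gradient by ~130°). In a static radial field the
     taxis route runs straight at the field minimum, so the
     direction-to-extreme and the direction-to-(observed)-endpoint
     coincide — and the endpoint-pursuing strategies (constant
     heading, combination), which are handed the empirical endpoint by
     design, act as lower-variance oracles that always win. With the
     dog-leg, endpoint pursuit bisects the turn and runs ~60° off the
     observed leg on *both* days, while gradient-followers reproduce
     both legs. Recovery candidates are simulated at the generating
     weighting (β = 5): the experiment asks whether the evaluation
     procedure re-identifies the generating strategy, so candidates
     run under the generating configuration.

  On this fixture the strong generating signal also leaves a residue
  under the bridge: CRB top-decile proportions are near-uniform on the
  distance measures at the study weighting (β = 1), while the
  heading-sensitive interaction index still detects the taxis
  signature. The bridge-null property is therefore stated for the
  distance-based ranking.

## Numerical choices

* Histogram binning matches `np.histogram`'s left-closed edges,
  including a 1e-9 relative nudge against floating-point round-off at
  exact edges (π at a bin edge truncating into the wrong bin).
* Angles are radians in (−π, π], mathematical convention, everywhere.
* Extremum ties break to the smallest (row, column) in row-major
  order; ranking ties to a stable sort; best-variant ties to the
  lexicographically smallest label. All logged.
* Batch replicates draw from `SeedSequence([seed, strategy, animal,
  replicate, retry])` substreams, so any subset of a batch is
  reproducible in isolation.
* Degenerate inputs (constant grids for taxis/bi-gradient, a bird at
  the target or at the extreme for constant heading) raise explicit
  errors rather than returning flat surfaces.

## Known limitations

The movement kernel carries only lag-1 persistence, so simulated
tracks diffuse more than real migrations over multi-day horizons. The
synthetic field's cues are mutually redundant (all radial from one
pole), which makes cue-level attribution (F vs I vs H) weaker than in
real geometry. The bridge pull is an approximation, not an exact
bridge law. Real-data ingestion assumes pre-projected planar
coordinates; no geodesy is performed.
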