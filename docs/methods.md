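# Methods

`greenshift` models the climatic scope for, and migration constraints
on, the expansion of trees and shrubs in an isolated Arctic region.  It
chains six stages: gridded-climate handling, occurrence hygiene, a
thermal treeline model, a climatic-niche model ensemble, range-dynamics
analyses, and reciprocal climate-analog mapping.  A synthetic-data
module generates climate worlds and virtual species with known truth so
every stage is testable without external downloads.

## Grids and bioclimatic predictors

All rasters are regular geographic lattices, cell-centre registered with
row 0 northernmost.  Distances use the haversine formula on a sphere of
radius 6371.0088 km (the WGS84 authalic radius); cell areas use the
exact spherical quadrilateral formula, so area sums respect the
poleward shrinking of cells without a projected coordinate system.
Missing data are NaN and propagate: an operation on a missing cell
yields missing, never zero.

Three predictors drive the niche models: mean summer temperature
(June–August by default; configurable, the study regions being Northern
Hemisphere), temperature of the coldest month (minimum over the twelve
monthly means), and the annual precipitation sum.

Resolution changes are conservative: disaggregation block-replicates
each parent into factor² children (no interpolation, so values are
never invented), and aggregation averages the non-missing children.
Scenario climates are transferred to a finer baseline by the
delta-change (anomaly) method: monthly temperature anomalies are added,
monthly precipitation is scaled by the scenario/reference ratio, and
both are interpolated bilinearly from coarse to fine cell centres.
Where the coarse reference precipitation is ≤ 0.1 mm the ratio is
ill-conditioned and the anomaly is applied additively instead.  Coarse
cells with missing values contribute a neutral anomaly (0 °C, ratio 1)
so coastal gaps do not poison the interpolation; missing fine-baseline
cells stay missing regardless.

I/O: ESRI ASCII grid and single-layer GeoTIFF (values at full double
precision; georeferencing via the pixel-scale and tie-point tags) for
2-D layers, NetCDF for full monthly stacks with mask and reference
elevation.  NetCDF files carry the exact lattice origin and cell size
as attributes because coordinate arrays alone round-trip with float
error.

## Occurrence hygiene

The positional ambiguity of a record reported with `d_lat`/`d_lon`
decimal digits is the haversine distance between (lat, lon) and
(lat + 0.5·10⁻ᵈ, lon + 0.5·10⁻ᵈ) — the half-step of the last printed
digit in both axes jointly.  A single combined measure was chosen over
per-axis maxima; at 8 km (the default filter, matching ~5′ climate
data) the two conventions rarely disagree, and the combined measure is
what the block audit verifies.  Records with ambiguity above the
threshold are dropped, the count logged.

Spatial thinning bins records into a square block lattice (default
100 km) built in a Lambert azimuthal equal-area projection anchored at
the data centroid, with the central block centred on the anchor so a
tight cluster at the centroid shares a block.  At most `max_per_block`
records are retained per block by a seeded uniform draw without
replacement.  Range-outline presences and pseudo-absences are sampled
one point per occupied block, inside the outline and outside it (but
within the continental mask) respectively; polygon boundaries are
densified before projection so projected edges track the geographic
boundary instead of cutting chords.

## Treeline model

Tree life-form persistence at a location requires a growing season of
at least 94 days with daily mean temperature ≥ 0.9 °C whose mean is at
least 6.4 °C.  Daily series come from linear interpolation between
month mid-points on a fixed 365-day calendar (December wrapping to
January); the mid-point of each month reproduces that month's mean.
The series is shifted along an elevation scan (0–2000 m in 25 m steps)
with a constant adiabatic lapse rate of 0.55 K / 100 m, and the highest
qualifying elevation is the cell's potential treeline.

Numerical choices worth noting:

* Equality qualifies at both thresholds ("a minimum of", "at least").
  The season-mean comparison carries a 1 × 10⁻⁹ °C guard because the
  floating-point mean of n identical qualifying days can round a hair
  below their common value; the guard is ~7 orders of magnitude below
  any climatological signal.
* The growing season is *all* qualifying days by default.  A
  `longest_run` option restricts it to the longest contiguous block of
  qualifying days (circular over the year boundary) for users who
  prefer the contiguous-season convention of the underlying treeline
  literature.
* The scan can be referenced to the elevation at which each cell's
  climate is valid (`use_reference_elevation=True`, the default, using
  the reference DEM carried by the climate grid) or to sea level, which
  reproduces a literal 0–2000 m a.s.l. scan.

A DEM that nests within the climate lattice (any integer factor) turns
the treeline surface into a below-treeline mask: ice-free land at or
below the local treeline.  Finer DEMs resolve sub-cell valleys and
therefore never shrink, and typically grow, the below-treeline area —
the package's tests construct exactly this behaviour.  Counting
agreement across boolean layers (e.g. several GCMs' masks) is a plain
per-cell sum.

## Niche-model ensemble

Suitability models implement `fit(X, y, sample_weight)` /
`predict_score(X)`.  Two are implemented in-repo because their details
matter to the method:

* **Rectilinear envelope** — per-predictor [q, 1−q] presence quantiles
  (default q = 0.05; q = 0 is the literal min/max box).  Score =
  fraction of predictors inside their interval.
* **Weighted logistic regression** — maximises the weighted binomial
  log-likelihood by IRLS with predictors standardized internally using
  weighted moments, so duplicating a record while halving its weight
  leaves the fit unchanged.  Presences and pseudo-absences are weighted
  to contribute equally (presence weight 1, absence weight n_p/n_a).
  Complete separation or non-convergence triggers a warning and a
  small-ridge penalized refit.

The five-algorithm suite is completed by scikit-learn adapters (random
forest, histogram gradient boosting, quadratic-feature logistic
regression); exact parity with any particular SDM toolbox's internals
is a non-goal — the bespoke content is the weighting, thresholding and
ensembling around the pluggable interface.

Evaluation uses a stratified 80/20 calibration/validation split
(redrawn if a partition lacks a class).  Continuous scores are
binarized at the threshold maximising the weighted true skill statistic
(TSS = sensitivity + specificity − 1) over the candidate set
{mid-points of adjacent distinct scores} ∪ {extremes}, ties resolved
toward the lowest threshold.  The threshold is chosen on the
calibration scores and applied to the hold-out, on which AUC (weighted
rank statistic, ties averaged), TSS and sensitivity are reported.
Aggregation of per-fit metrics across algorithms or species is left to
the caller.

K binary projections sum to a model-agreement count; a cell is
ensemble-suitable when at least 3 models agree (the majority rule).
Projections are restricted to a region mask (land within the study
region).  Species richness is the per-cell sum of per-species majority
layers; richness change is future minus current.

## Range dynamics

A suitability time series (one binary grid per time slice, slices
strictly ordered, labels in kyr BP or calendar decades) yields
suitable-cell counts, the first slice at which at least `min_cells`
cells are suitable, and — against a pollen-dated arrival — the
immigration lag in years, lag = (first_suitable − arrival) × 1000 on
the BP axis.  An arrival predating first suitability raises an error
rather than returning a negative lag.

The distance view measures, for every suitable target cell, the
distance to the nearest cell of the current range: either the direct
great-circle distance (default — the simple distance-based convention)
or a barrier-aware shortest path over the 8-neighbour cell graph with
great-circle edge lengths (Dijkstra, multi-source), motivated by
coastal geometries where ice and sea interrupt straight lines.  From
the distance map follow likely-colonized area (distance ≤
rate × horizon), migration-lag maps (distance / rate) and required-rate
maps (distance / horizon); the species-level "time to reach all
suitable area" is the cellwise maximum (the median is also reported).
The identities lag × rate = distance and rate × horizon ≥ distance on
colonized cells hold to a single floating-point rounding.

The spread automaton advances occupancy in decadal steps over per-step
suitability grids.  Per step: occupied cells persist only while
suitable; each occupied cell older than the maturity delay exerts
colonization pressure on every empty, suitable, non-barrier cell within
the kernel.  Kernel distance classes use Chebyshev cell distance (class
1 = the 8 neighbours), so a probability-1 radius-1 kernel advances the
front exactly like an 8-neighbour breadth-first search — the test
oracle.  Independent per-source Bernoulli draws are aggregated per
target as 1 − Π_d (1 − p_d)^{n_d} with one seeded uniform draw per
target cell, which is distributionally identical to per-pair draws and
replays bit-identically under a fixed seed.  Long-distance dispersal
events and propagule-pressure accumulation are out of scope.

## Climate analogs

Two cells are climate analogs at niche breadth b (% of the domain
range) when |v_cell,j − v_focal,j| ≤ (b/100)·R_j/2 for every predictor
j, with R_j the value range over the pooled analysis domain of both
regions.  The symmetric shared-range window makes the relation
symmetric and nested in b (5% ⊆ 25% ⊆ 50%); a percentile-based window
would break symmetry and is noted but not implemented.  A variable
that is constant over the whole domain has no meaningful window and is
rejected.  For each focal cell the analog area in the counterpart
region is the spherical-area sum of its analog cells as a percentage
of a reference area (default: the counterpart's ice-free land), and
the distance to the nearest analog cell is the haversine distance
(absent when no analog exists).  The comparison is exhaustive,
chunked to bound memory; at this package's problem sizes (10³–10⁴
cells per region) the full cross-product is cheap, so the bucket
pre-binning optimisation sometimes used for continental grids is not
implemented — any accelerated variant would be contract-bound to
reproduce the exhaustive result exactly.

## Synthetic worlds and virtual species

The generator emulates the structure the pipeline consumes, not
atmospheric physics.  Monthly temperature is

    T(m) = base − gradient·(lat − lat_min) − lapse·elevation
           + amplitude·cos(2π(m − 7)/12) + ε

with July the warmest month; precipitation is a positive field with a
monotone latitudinal trend; the DEM is smoothed uniform random relief.
Defaults sketch a subarctic coastal region: 20° of latitude from the
boreal zone into the high Arctic, 0.7 °C per degree latitude, a 12 °C
seasonal half-range, the standard 0.55 K/100 m lapse, up to ~800 m of
relief and 0.5 °C of monthly noise.  The configured lapse is exactly
recoverable by regressing generated temperature on elevation when the
noise is off — a generator self-check.  Warming trajectories apply
spatially uniform offsets per labelled slice, emulating a glacial
baseline through Holocene slices into future decades.

Virtual species have rectilinear (box) niches in the three predictors.
Presences are drawn from truth-suitable land cells (uniformly or
weighted by a bias surface), jittered within the cell, then rounded to
per-record digit counts from a configurable digit model — emulating the
precision heterogeneity of aggregated occurrence archives.  Every
presence is truth-suitable before degradation, by construction.

One recovery-test subtlety: in a world where every predictor is a
function of latitude alone, the predictors are collinear and only the
binding edge of a box niche is identifiable from presences.  The
envelope-recovery test therefore uses a world whose temperature varies
with relief and whose precipitation varies west→east, making the joint
predictor support a full rectangle so all four bounds bind.  Passing
tests on these worlds demonstrate correctness of the machinery, not
realism of GCM fields: uniform-offset warming has no spatial pattern,
precipitation trends are monotone, and there is no interannual
variability, foehn wind, soil or disturbance structure.

## Problem sizes and reproducibility

Tests and the acceptance script run on 10×10 to 50×50 grids, 200-cell
oracle samples, 500-presence virtual species and 1000-instance
threshold-oracle sweeps — sizes at which every oracle (literal
day-by-day treeline scan, exhaustive TSS search, BFS ball, pairwise
haversine) is exact and fast.  All randomness flows through explicit
integer seeds (NumPy `default_rng`); the acceptance script derives
per-stage sub-seeds from its `--seed` via `SeedSequence`.

## Known limitations

Ice extent is held fixed across time slices; suitability between
decadal slices is held constant within each step; the automaton has no
demography, competition or long-distance dispersal; the treeline model
ignores microtopography, foehn winds and soil; analog windows are
rectilinear per-variable, not multivariate distances.  CLI map output
is data-only (ASCII/GeoTIFF/NetCDF grids); cartographic styling is out
of scope.
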