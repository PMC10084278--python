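# Methods

This note records the models, conventions, and design decisions behind
`lucfrontier`, in the order the pipeline uses them.

## Grids and geometry

All layers share a `GridGeometry`: a row-major grid anchored at the
upper-left corner in projected planar metres, default cell size 30 m (so
one cell is 0.09 ha). Cell `(r, c)` has its centre at
`(origin_x + (c+0.5)·s, origin_y − (r+0.5)·s)`. Distances are planar
Euclidean between cell centres or points; no geodesy. Cells that are
nodata in either epoch are excluded from transitions, sampling, map
comparison and metrics — the conservative choice, recorded here because
other conventions (e.g. treating nodata as nonforest) would change edge
and core counts.

Interchange formats are deliberately plain text: single-band ESRI ASCII
grids for categorical and continuous rasters (lossless round trip —
integers exactly, floats at shortest-repr precision), GeoJSON for point
sets, CSV/JSON for tables and reports.

## Synthetic scenes

The generator emulates the data situation of a deforestation frontier at
desk scale. Its defaults are the package's study conditions:

* **Geometry** 200×200 cells at 30 m (6 × 6 km, 36 km²).
* **Land cover at t0** forest where a spatially autocorrelated field
  (Gaussian-smoothed white noise, re-standardised to mean 0 / sd 1)
  exceeds the quantile matching `forest_fraction_t0 = 0.7`; the remainder
  is agriculture except small water/wetland/built/bare-soil blobs
  (≈4.5% of cells in total) carved from a second smooth field so
  multi-class transitions and disagreement are exercised.
* **Covariates** one layer per standard variable role: five correlated
  fields (elevation, slope, soil moisture, precipitation, crop
  suitability; ranges 450–1200 m), distances to two random road
  transects, a river, a rail transect, cities (Poisson, 0.1 km⁻²), fires
  (2 km⁻²) and mines (0.2 km⁻²); fire density in a 1-km disc; three
  nearest-seed zones ("municipalities") carrying unallocated-land share,
  cattle, population and poverty draws; PADDD and settlement indicator
  blobs; a central protected-area disc covering 25% of the landscape with
  two surrounding rings. Point-process draws are forced to at least one
  point so distance layers stay defined on tiny scenes.
* **Buffer rings** default to 1 km and 2 km. The field design they mirror
  uses 10-km and 20-km rings around a ~10⁴-km² reserve; at 36 km² those
  widths would put every cell in the first ring, so the desk-scale scene
  scales them to keep all four zone codes populated. The library
  default for `buffer_zones` itself remains (10 km, 20 km).
* **Conversion process** continuous covariates enter the model stack
  z-scored over valid cells, with the (mean, sd) frozen in layer
  provenance. True coefficients (defaults: intercept `logit(0.05)`;
  elevation −0.4, slope −0.25, soil moisture −0.25, distance-to-road
  −0.3, distance-to-agriculture −0.5, fire density +0.4, unallocated land
  +0.3, nonforest neighbourhood +0.4, first buffer ring +0.3) are on that
  standardized scale — large enough to be detectable at the ~3–4·10³
  samples a desk-scale scene yields, small enough that the mean per-pixel
  conversion probability stays ≈0.05 per epoch, the empirically typical
  frontier rate the generator targets. Each forest cell converts
  independently; nonforest cells never change between epochs.

What the generator does **not** emulate: classification error, cloud
gaps, temporally explicit fire spread, road-network growth, regrowth
dynamics, or spatially correlated conversion shocks. Passing tests
therefore demonstrate the correctness of the machinery under a correctly
specified independence model, not robustness to the misspecification real
maps carry.

## Sampling and screening

The estimation sample takes forest-at-t0 cells at every k-th row and
column (spacing must be an integer multiple of the cell size; origin fixed
at cell (0,0) for determinism). The outcome is 1 only for
forest→agriculture; forest converting to other classes stays in the
sample as 0. Coordinates are attached both raw and centred/extent-scaled
(`x_coord`, `y_coord`) for use as spatial-trend covariates. The library
default spacing is 300 m; the package's own experiments use 90 m on
desk-scale scenes to reach ~4,000 grid candidates, since 300 m on a 6-km
landscape leaves too few rows for stable fits.

Screening is iterative: while any pair of screened covariates has
|Pearson r| above the threshold (default 0.66) with two-sided p < 0.05,
the highest-|r| offending pair is resolved by dropping its lower-priority
member (priority defaults to the given name order). With thousands of
rows essentially every |r| > 0.66 pair is also significant, so the p
condition rarely binds — it matters only for small samples.

## Logistic fits and comparison

Fits are maximum-likelihood binomial GLMs with logit link (statsmodels),
standard errors from the information matrix. The null log-likelihood is
the closed form `n₁ ln p̄ + n₀ ln(1−p̄)`. Separation is surfaced as an
error naming the suspect terms rather than returning divergent
coefficients. McFadden's adjusted pseudo-R² is `1 − (lnL − K)/lnL₀` with
K the number of non-intercept terms. Formal tests are restricted to
nested pairs (likelihood ratio against chi-square); non-nested model
pairs are compared descriptively by adjusted pseudo-R² only, because a
chi-square reference has no basis there.

The four presets are term lists, not code paths: a "classical" set
(terrain, accessibility distances, suitability, population, neighbourhood,
buffer rings), a "frontier-narrative" set (distance to agriculture, fire
variables, mines, rail, land-tenure proxies, buffer rings), their union,
and a refined union (terms significant at 0.05 in the classical fit plus
a configurable important-narrative list). Constant-in-sample indicators
are dropped with a warning; coordinate covariates are included when they
survive screening.

## Projection and allocation

`simulate_ensemble` draws S independent landscapes (default 1000) from the
fitted probabilities, accumulating per-cell conversion counts and per-
simulation loss areas (chunked so the random stream is identical for any
chunk size). `allocate_quota` converts exactly
`round(quota_area / cell_area)` forest cells, ranked by ensemble count,
then fitted probability, then row-major index — the tie-break is
deterministic and summarised in the result. The quota defaults to the
prior epoch's observed conversion area ("area" policy); a "rate" policy
applying the prior forest→agriculture rate to the current forest area is
also available. Forward steps freeze coefficients and covariate scaling
and recompute only the dynamic layers (distance to existing agriculture;
nonforest neighbourhood share) from the current map; regrowth is not
simulated — predicted maps only remove forest.

## Map comparison

Disagreement uses the crosstab proportions p: per class g, quantity
`|p_g· − p_·g|` and allocation `2·min(p_g· − p_gg, p_·g − p_gg)`; halved
sums give the map-level components, and quantity + allocation equals
`1 − Σ p_gg` to machine precision (property-tested). The comparison spans
all classes of the full maps by default; a mask argument restricts it
(e.g. to the prior forest extent). Because the quota equals the observed
converted area, pipeline quantity disagreement is ~0 by construction and
allocation carries the discriminating signal between models.

## Fragmentation metrics

Patches are maximal 8-connected components. Perimeter counts cell faces
against a different class **or the map border**, × cell size; core cells
require the full 8-neighbourhood (edge depth 1 cell) same-class and
in-map, so border-adjacent cells are never core. The landscape-area
denominator for PLAND, CPLAND and division is all non-nodata cells. Per-
patch fractal dimension is `2·ln(0.25 p)/ln a` (p in m, a in m²; exactly 1
for squares), PAFRAC is `2 / slope` of the least-squares regression of
`ln a` on `ln p` across patches and is reported as NaN with a reason when
fewer than two patches or zero perimeter variance make it undefined.
Reported spreads are population standard deviations over patches. Edge
depth and the border-as-edge convention are configurable decisions;
changing them shifts core-area metrics noticeably on small landscapes.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; scene generation
spawns per-component child seeds from one master seed, and the pipeline
derives ensemble seeds from its config seed, so a config reproduces its
outputs byte-for-byte. The package's own experiments use 200×200 scenes,
90-m sampling, S = 1000 and (for the model-comparison experiment) three
scene replicates, averaging fit and disagreement summaries across them —
one desk-scale scene leaves the comparison between two well-specified
models within a few cells of a tie, and averaging is the appropriate
design at that effect size. Coefficient-recovery coverage is reported
against ±2 fitted SE over 50 scene replicates; at ~170 conversion events
per scene the Wald intervals are known to run slightly below their
asymptotic 95% level, so per-term coverage estimates in the high 80s to
high 90s are the expected finite-sample behaviour, not evidence of bias
(the estimates themselves centre on the true values).

## Known limitations

* No spatial random effects or autologistic terms: residual spatial
  structure beyond the covariates and sampling spacing is unmodelled.
* Allocation is a global ranking; it cannot express demand by region.
* ASCII-grid I/O targets moderate rasters; very large scenes should be
  generated in memory rather than round-tripped through text.
* The refined preset inherits the significance threshold's arbitrariness;
  it is a configuration convenience, not a model-selection procedure.
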