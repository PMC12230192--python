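# Methods

This note documents the models, estimators, numerical choices and
limitations behind `gibmove`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and geodesy

A *fix* is a timestamped WGS84 position with a source tag (GPS or
class-3 Argos; both are treated identically after validation, as the
study design pools them). Timestamps without an explicit offset are
interpreted as UTC+05:30, the study region's local time, because the
tag's fix schedule (05:30–19:30) is defined in local hours. Cleaning
drops exact duplicate rows and repeated timestamps, rejects
out-of-range coordinates with their row numbers, and requires at least
two valid fixes.

Step lengths and bearings are computed on the WGS84 ellipsoid with
Vincenty's inverse method (verified in the tests against frozen values
from the Karney geodesic implementation in R's `geosphere`, agreement
below 0.1 mm at study-scale distances). Density estimation, clustering
and habitat geometry need a metric plane; the working CRS is UTM zone
43N (EPSG:32643), implemented as a Krüger-series transverse Mercator
(order n⁶; round-trip error < 0.01 m). The projection was chosen from
the study extent (75–76.5°E); longitudes outside 72–78°E trigger a
warning, not an error.

Seasons follow the regional calendar: summer Mar–Jun, monsoon Jul–Sep,
post-monsoon Oct–Nov, winter Dec–Feb.

## Movement metrics

A step belongs to the calendar date (local time) of its start fix, and
the overnight 19:30→05:30 gap is an ordinary step. This convention
makes the daily decomposition exactly conservative — Σ(daily
distances) = Σ(step lengths) with no residual — which is asserted
exactly in the tests. Days with a single fix contribute no step and
are omitted from daily summaries (so they do not enter the daily
mean); a future flag could count them as zero-distance days, which
would lower the mean.

Turning angles are signed differences of consecutive forward azimuths
wrapped to (−180°, 180°], undefined for a trajectory's first step. The
mean resultant length R̄ = |mean(e^{iθ})| summarises directional
persistence (R̄ = 1 for straight-line movement; under uniform angles
E[R̄] ≈ √π/(2√n)).

Powerline crossings count, per step segment, the number of distinct
polylines the segment intersects (endpoint contact included).

## Power-law (Lévy) fitting

Step lengths are continuous distances, so the continuous power law is
used: density p(x) = ((μ−1)/x_min)(x/x_min)^{−μ} for x ≥ x_min, μ > 1.
With the cutoff fixed, the MLE is the Hill estimator
μ̂ = 1 + n/Σln(x_i/x_min). With the cutoff free, every observed value
is scanned as a candidate cutoff (tails smaller than `min_tail`,
default 10, excluded) and the cutoff minimising the KS distance
between the tail's empirical CDF and the fitted CDF is selected, ties
toward the smaller cutoff — the standard empirical-tail procedure.
The estimator is exactly scale-invariant, matches a brute-force
likelihood grid search to 10⁻⁴, and the scan matches an exhaustive
KS oracle (tests). The degenerate case is a tail with no spread above
the cutoff (Σln = 0), for which the exponent is undefined and an error
is raised; two equal values *above* a lower cutoff are a valid
two-point tail.

Classification defaults: `levy` for 1 < μ ≤ 2.75, `near_brownian` for
2.75 < μ ≤ 3.25, `out_of_range` otherwise. The 2.75/3.25 thresholds
operationalise the qualitative reading of exponents near 3 as
Brownian-like (2.89 classifies as near-Brownian, 2.44 as Lévy); both
are configurable. No bootstrap goodness-of-fit p-value is computed by
default. No model competition against exponential or lognormal
alternatives is performed; `ks_D` and the CCDF points are exported for
visual log–log assessment instead.

## Utilization distributions

The UD is estimated with a bivariate Gaussian product kernel of
isotropic bandwidth h on a regular grid (default cell 250 m) in the
projected plane, normalised so cell masses sum to one. The default
bandwidth is the bivariate-normal reference
h = n^{−1/6}·√((s²_x+s²_y)/2) (sample variances, n−1 denominator);
isopleth areas depend on h strongly, so h is recorded in every output
and can be overridden. The grid extends 5h beyond the data — with a 3h
margin the truncated kernel mass (≈1%) visibly shrinks the 95%
isopleth, with 5h the truncation error is below 10⁻⁵ and the
single-point 95% area matches the closed form 2πh²ln20 to 0.1%
(acceptance check). KDE evaluation is separable (two 1-D kernel
matrices and one matrix product), so study-size inputs run in
milliseconds.

The p-isopleth is the smallest set of highest-density cells with
cumulative mass ≥ p, found by a stable descending sort; stability
makes isopleths exactly nested across levels. Connected components
use 8-connectivity; areas are cell counts × cell area.

Monthly overlap evaluates per-month UDs on one common grid (per-month
reference bandwidths by default; the grid margin uses the largest).
The default index is the area-Jaccard of the p = 0.95 isopleth
regions, area(A∩B)/area(A∪B), a symmetric area-overlap measure; the
volume of intersection Σmin(UD_A,UD_B) and Bhattacharyya affinity
Σ√(UD_A·UD_B) are also implemented, and reports name the index used.
The directional variant area(A∩B)/area(A) is not reported. Months
with fewer than 5 fixes are skipped (a degenerate KDE is worse than a
gap).

## Sequential clustering

A single chronological pass: each fix joins the nearest open candidate
whose running centroid is within `radius_m` and whose last admission
is within `window_days` (compared on timestamps, i.e. 96 h for 4
days); otherwise it seeds a new candidate. Centroids are running means
updated after each admission; candidates close after a window with no
admission; candidates with ≥ `min_fixes` members are emitted in
start-time order. Ties in centroid distance go to the earliest-seeded
candidate, making the pass deterministic. Membership is disjoint;
closed clusters are never merged. The exact internal rules of
published sequential-clustering tools (centroid recalculation timing,
merge behaviour) vary, so cluster counts on real data may differ
slightly from other implementations; the parameters are therefore
recorded in every report. Defaults: radius 2702 m (the tracked bird's
reported average daily displacement — kept as printed even though it
differs from the reported 5.39 km/day mean), window 4 days, minimum
28 fixes (four days of a 7-fix schedule).

Footprints: members are split into temporally contiguous episodes
(new episode when the inter-member gap exceeds the window or a member
is > 2·radius from the episode's running centroid), and the footprint
is the union of radius-disks at episode centroids. A single-episode
cluster is one disk of area πr² ≈ 22.94 km² at the default radius;
revisited sites yield multi-disk footprints with larger areas. Disks
are buffered at 64 quadrant segments (area error ≈ 2.5·10⁻⁵,
well within the 0.5% checked in tests).

## Habitat summaries

Raster statistics use the cell-centre rule (a cell counts iff its
centre is inside the footprint): deterministic, order-independent, and
the common zonal-statistics default; land-cover percentages then sum
to exactly 100. Road density is clipped road length (km) over
footprint area (km²); powerline distance is the minimum
boundary-to-line distance, zero when a line crosses the footprint,
missing (logged) when no lines are supplied. NDVI is averaged over
footprint cells from the dated layer nearest the cluster's start date,
ties resolved toward the earlier layer. Table-level summaries report
per-column means and SDs over the population of clusters with the n−1
denominator; with one cluster the SD is undefined (NaN). The packaged
ten-row reference cluster table reproduces its published mean and SD
rows to two decimals under exactly these conventions (the published
0.72 km/km² road-density figure quoted elsewhere in the source study's
discussion is inconsistent with its own table, whose rows give 0.38).

## Synthetic data

The trajectory generator emulates the study conditions: 7 fixes/day at
05:30, 07:30, 09:30, 11:30, 13:30, 17:30, 19:30 local, seasonal
exponents {summer 2.44, monsoon 2.20, post-monsoon 2.89, winter 1.74},
uniform headings, and optional fix missingness. Step lengths are drawn
from a truncated (bounded) Pareto by inverse CDF:
x = x_min(1 − u(1 − R^{−α}))^{−1/α} with α = μ−1, R = x_max/x_min.
The upper bound (default 40 km) reflects the finite study landscape
and keeps simulated maximum daily sums near the observed ~39 km; the
lower cutoff default x_min = 150 m was set so that the seasonal-mix
mean daily displacement comes out near the observed ~5.4 km/day (the
mean step scales linearly with x_min). Upper truncation biases the
pure-power-law MLE upward by ~+0.01 at μ = 2.1 (R = 267), well inside
the recovery tolerances used. Stationary phases override the Lévy
draw entirely — fixes are placed uniformly in a disk of radius x_min
around the phase centre — giving clean ground truth for the clustering
oracle tests. The simulator emits GPS-schedule fixes only; the tag's
alternate-day Argos fixes have no stated temporal pattern and are not
emulated.

The landscape generator thresholds a smoothed Gaussian random field at
requested class proportions (default mix ~48% open, 45% crop, small
builtup/water/others, matching a semi-arid cropland–grassland mosaic),
rank-maps further smooth fields into an NDVI range (default
0.15–0.45), and lays a few jittered crossing polylines as powerlines
and roads. Everything is reproducible from the seed.

What the synthetic data does *not* emulate: spatially autocorrelated
habitat selection, Argos location error, behaviour-dependent fix
failure, directional persistence, or movement responses to the
landscape (steps ignore land cover entirely). Passing tests therefore
demonstrate correctness of the estimators and pipeline under the
stated generative model, not ecological validity on real telemetry.

## Problem sizes and determinism

Tests and the acceptance script use study-scale problem sizes chosen
as representative rather than exhaustive: n = 3345 steps (the study's
fix count) for exponent recovery averaged over 20 seeds, 20,000 draws
for distributional checks, ~2900-fix year-long simulations for
pipeline and conservation checks, and 50 m cells for the closed-form
KDE comparison. All randomness flows through `numpy` Generators seeded
explicitly; the pipeline writes the seed and configuration into
`manifest.json`, and rerunning with the same seed reproduces stage
outputs byte-for-byte.

## Known limitations

- Single-animal design throughout; no population-level inference.
- No Argos error-ellipse filtering or state-space smoothing before
  analysis; no autocorrelated-KDE or Brownian-bridge UD estimators.
- The KS cutoff scan can choose different cutoffs than other fitting
  packages on the same data, moving μ̂ by more than the sampling error;
  fixing the cutoff is recommended for cross-package comparisons.
- Rasters are plain-text ASCII grids in the working CRS; georeferenced
  GeoTIFF export would require a GDAL-based stack.
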