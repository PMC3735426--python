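# Methods

`streetmorph` implements a battery of built-environment morphometrics around
residential dwellings, and a Bayesian two-level logistic analysis relating
them to a binary psychological-distress outcome (GHQ-30 score >= 5), validated
end-to-end on a synthetic town with known generating parameters.

## Street-segment graph

Street centerlines are cleaned into a segment graph deterministically:
endpoints within a snap tolerance (default 0.1 m) are merged into nodes at the
cluster centroid, zero-length and exact-duplicate segments are dropped, and
loops or parallel edges are rejected unless explicitly allowed. An optional
pass fuses chains across degree-2 nodes while the accumulated angular
deviation stays below 5 degrees (off by default). Inputs must be planar
metres; coordinate sets whose bounding box fits in [-180, 180] x [-90, 90]
are assumed to be unprojected degrees and rejected.

The turn cost between two segments meeting at a node is the absolute angular
deviation from straight continuation (0 = collinear, 90 = right angle,
180 = reversal), computed from the polyline vertices adjacent to the node, so
it is invariant to stored vertex order. Metric distance between two segments
is midpoint-to-midpoint: half of each segment's length plus the shortest
node-to-node path; this convention is a package choice (several are
defensible) and is applied consistently everywhere a radius is evaluated.

## Space-syntax metrics

**Connectivity** is the number of distinct other segments sharing an endpoint
node.

**Movement potential** (angular betweenness, "choice") at radius *r*: for
every unordered pair of distinct segments whose metric distance is <= *r*,
all least-cumulative-angular-cost paths between them are found; each
*intermediate* segment of a path receives 1/t, where t is the number of tied
paths; origins and destinations receive nothing. Conventions, fixed here
because the literature varies:

* the radius restricts only the origin-destination set; path choice is
  radius-independent, which makes per-segment raw counts non-decreasing in
  the radius (a property the tests assert);
* ties are split equally (1/t) and detected at an absolute tolerance of 1e-9
  on cumulative cost;
* pairs are unordered and counted once; contributions are unweighted by
  segment length.

Ties need care when turn costs are exactly zero (perfectly collinear
continuations): two equal-cost segments joined by a zero-cost edge are then
mutual predecessors and the tied-paths relation is no longer acyclic. The
implementation runs Dijkstra for costs, rebuilds the full tied-predecessor
relation afterwards, and uses a Brandes-style accumulation over the
topological order when one exists; when zero-cost plateaus create cycles it
falls back to exact depth-first enumeration of all tied simple paths (with a
step cap — practically relevant only for perfectly regular fixtures, since
generic geometry never produces exact ties). Both routes are checked against
an independent exhaustive-enumeration oracle on hundreds of random graphs.

Raw counts and `log10(1 + raw)` are both emitted; the log variant is what
enters z-scoring in the models, matching the scale of the published
descriptive ranges for these variables (about 1.8-4.3).

## Catchments and morphometrics

The neighbourhood unit is a 1 km **street-network ("sausage") buffer**: the
origin is projected onto its nearest segment (it must lie within 200 m of the
network), every centerline point within network distance 1 km of that access
point is collected (partial segments included), and the covered portions are
buffered to a corridor of half-width 50 m (round caps) and unioned. The
half-width is a package default — the construction of the buffer polygon is
not standardised anywhere — and is configurable; buffer area is reported
gross (roads and water are not netted out).

Within the buffer: the **land-use mix** index is the normalised entropy
`-sum_k p_k ln(p_k) / ln 5` of intersected parcel areas over the closed
five-category classification (residential, retail, community services,
business & offices, recreation & leisure); zero shares contribute zero, so a
single-use buffer scores 0 and equal five-way shares score 1. **Destination
densities** are simple counts inside the polygon per km² of buffer area, per
category (bus stops, retail, community services, recreation & leisure,
business & offices). **Slope variability** is the standard deviation of a
slope raster (degrees) over the buffer.

At the dwelling itself: **dwelling-centred density** is a hard count of
dwelling points within a 30 m disc, focal dwelling included (hence a minimum
of 1, consistent with the published range of 1-40); **dwelling type** is one
of detached / semi-detached / terraced / flat; **plot exposure** counts
footprint faces whose midpoints lie within 2 m of public space, categorised
0 / 1 / 2+. **Greenness** is mean NDVI over a 500 m Euclidean ("airline")
circular buffer.

Zonal statistics use the cell-centre inclusion rule (a cell belongs to a zone
iff its centre does), ignore nodata, and use the population (n) denominator
for the standard deviation; these choices make exhaustive per-cell
recomputation a valid oracle. Rasters are read and written as ESRI ASCII
grids, a plain-text format sufficient for single-band regular grids.

Each dwelling inherits the syntax metrics of its nearest street segment:
log-scale movement potential at the local (1200 m), city (3000 m) and global
radii, and the raw connectivity count.

## Outcome and covariate coding

* case = GHQ-30 >= 5 (the instrument's standard cut-point);
* land-use mix -> tertiles cut at the empirical 1/3 and 2/3 quantiles, with
  boundary ties to the lower tertile (fixed for determinism); T1 is the
  reference;
* the four syntax variables, slope SD and NDVI -> z-scores with the sample
  (n-1) standard deviation, computed after listwise deletion so each column
  has mean 0 / sd 1 over the analysis sample;
* dwelling type (reference detached) and plot exposure (reference one face)
  -> indicator columns; levels absent from the analysis sample are dropped
  rather than emitted as all-zero (singular) columns;
* age (years), alcohol (ml/week) and the dwelling/destination densities are
  continuous in their native units;
* social class: six Registrar-General groups collapsed to three levels
  (I/II/III-non-manual reference, III-manual, IV/V); education: three levels
  (none/apprenticeship reference);
* morbidity = any of six chronic vascular condition flags;
* area deprivation: six domain scores (0-100) passed through as-is; the
  'access to services' domain is rejected if supplied (collinear with the
  street-accessibility measures by construction).

Model 1 = built-environment block + individual covariates; Model 2 = slope,
NDVI and the six deprivation domains + individual covariates; Model 3 = the
union. A flag re-runs Models 1/3 without the land-use-mix tertiles (a
collinearity check). Every assembly emits a machine-readable coding manifest
and logs the number of rows dropped.

## Two-level logistic MCMC

The model is `logit P(y_ij = 1) = b0 + x_ij' b + u_j`, `u_j ~ N(0, s_u^2)`,
respondents i nested in areas j. Priors: Normal(0, 10^2) on fixed effects and
half-Normal(0, 2) on s_u; an inverse-gamma(0.001, 0.001) prior on the
variance is available as a sensitivity option. The sampler is
Metropolis-within-Gibbs: component-wise random walks on the fixed effects, a
joint vectorised random-walk update of all area intercepts (areas touch
disjoint rows, so acceptances are independent), and a random walk on
log s_u. Proposal scales adapt towards 44% acceptance during burn-in only;
the monitored kernel is fixed, so results are bit-reproducible given the
seed. Defaults are 5,000 burn-in + 50,000 monitored iterations thinned by 5;
the tests use shorter chains (hundreds of burn-in, 1-2k monitored) sized to
the small models they fit.

Reported per coefficient: posterior mean and sd, OR = exp(mean), the
exponentiated central 95% interval, and a two-sided posterior tail
probability `p = 2 min(Pr(b>0), Pr(b<0))` (reported as below 2/chain-length
when the chain never crosses zero). Model fit is summarised by
`DIC = mean deviance + p_D`, with `p_D` = mean deviance minus the deviance at
the posterior means of all parameters including the area intercepts.
Diagnostics are split-chain Rhat and an autocorrelation-based effective
sample size; fits flag (but do not fail on) Rhat > 1.1. Degenerate designs
error early: rank-deficient matrices name the collinear columns, and
perfectly separating covariates trigger a warning plus a heavy-tailed
Cauchy(0, 2.5) prior fallback. Fixing s_u^2 = 0 reduces the model to
single-level logistic regression, which the tests check against an
independent maximum-likelihood fit.

## Synthetic town

The generator produces the full study: street grid with jitter and diagonal
shortcuts (angular heterogeneity); a five-category parcel mosaic whose
non-residential probability combines a dense mixed-use core with smooth
noise, calibrated so buffer-level land-use mix spans roughly 0.03-0.21 across
dwellings; destination points placed preferentially in matching parcels;
smooth slope (0-9 degrees) and NDVI (-0.06 to 0.33) fields; rows of dwellings
with oriented footprints along residential streets (plot exposure computed
geometrically from the real operation); 34 areas defined by nearest-dwelling
seeds so every area has dwellings; and 687 respondents with per-area counts
in 6-47 (mean about 20). Respondent covariates are drawn from documented
distributions (age truncated-normal 73.5 +/- 4.3 on 65-84; alcohol
half-normal; chronic condition flags at fixed baseline rates; area
deprivation domain scores normal around published-scale means, clipped to
0-100). These mimic the shape of a real cohort; they do not reproduce any
individual-level dependence structure (e.g. correlation between class,
education and morbidity), so passing recovery tests demonstrates the
estimator and plumbing, not epidemiological realism.

Outcomes are injected on the *transformed* exposure scale (tertile
indicators, z-scores), so the generating coefficients are directly comparable
to fitted ones. Given the drawn area effects, the intercept is solved by
bisection so the expected prevalence matches the target (default 19.4%)
within 1e-4; GHQ-30 scores are then drawn consistently with the case
indicator. The default effect vector puts protective effects on the high
land-use-mix tertile, local movement potential and terraced housing, and a
harmful effect on slope variability and global movement potential, with
between-area variance 0.05.

Scale choices made for desk-scale runs, stated as package defaults: the
default town is a 14 x 14 grid at 230 m spacing (about 3 x 3 km, ~400
segments, 2,400 dwellings), and the slope raster is generated at 25 m
resolution (NDVI at 30 m). Test problem sizes: recovery simulations use 34
areas x ~20 respondents with 50 outcome replicates (100 for the null
check); betweenness oracles run on 200 random graphs of up to 12 segments.

## Known limitations

* The centerline simplification is a deterministic snap/dedup pipeline, not
  a reconstruction of manually drawn "longest line of sight" maps; numeric
  identity with proprietary space-syntax software is not claimed or sought.
* Only GeoJSON (vectors) and ESRI ASCII grid (rasters) are read/written.
* Betweenness on graphs with large exactly-collinear plateaus falls back to
  path enumeration, which is exponential in plateau size.
* The variance component of the two-level model mixes slowly when the truth
  is near zero; short chains can flag Rhat > 1.1 on s_u^2 even when the
  fixed effects have converged. The published-scale defaults (50k monitored
  draws) do not exhibit this.
* Missing data are handled by listwise deletion only; no imputation.
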