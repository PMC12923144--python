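# Methods

This note documents the models and procedures implemented in `marisdm`,
the parameters that matter, the numerical conventions, and what the
synthetic-world tests do and do not demonstrate about real data.

## Occurrence harmonization

Occurrence records from heterogeneous sources are reduced to a common
ternary quality flag: 1 (verified), 0 (erroneous), blank (unassessed).
Sources that already carry a binary flag (AquaMaps-style) pass it through
unchanged. Sources with a rich flag vocabulary (OBIS-style) are mapped so
that only physically impossible placements — on land, missing coordinates,
zero coordinates, implausible locations — force a 0; soft flags (depth
anomalies, missing depth) are preserved verbatim in `original_flags` but do
not force a verdict. Flag-less sources (GBIF-style) stay blank throughout.
The erroneous-flag vocabulary is configurable because flag strings vary by
source snapshot; the default set is
`{on_land, no_coords, zero_coords, implausible_location}`.

Coordinates are rounded to 4 decimal places **before** duplicate grouping,
so the dedup key is the rounded coordinate. Rounding is round-half-even
(numpy's default); the alternative half-up convention differs only at the
5th decimal. Records at exactly (0,0) and outside [−180,180]×[−90,90] are
removed with a logged count, never an exception. Deduplication groups on
(taxon, lon, lat, year, month) — missing year/month group as their own
key — and keeps the most complete record (has flag + has basis-of-record),
with ties broken by source priority (aquamaps > obis > gbif) and then input
order, purely for determinism.

## Three-axis habitat classification

*Distance to bottom* is a fixed label mapping (pelagic / pelagic-oceanic /
bathypelagic / pelagic-neritic → pelagic; demersal / benthopelagic /
bathydemersal → demersal; benthic / reef-associated → benthic); unknown or
missing labels are hard errors — trait imputation from higher taxa is out
of scope. *Distance to coast* uses the share of valid records inside the
coastal (0–800 m) zone: ≥ 90% neritic, ≤ 10% oceanic, otherwise generalist.
Both cuts are inclusive (the oceanic rule is implemented as the symmetric
≤ 10%), guarded by a 1e-12 tolerance against float representation of the
0.10 boundary. *Distance to surface* intersects the trait depth range with
fixed zone bounds; the pelagic range is first widened by 30 m (floored at
0 m) to absorb reporting imprecision; sea-floor ranges are used as given.
Zone bounds are closed on both sides, so an interval touching a boundary
exactly (e.g. a buffered maximum of 200 m) overlaps both zones. When
benthic/demersal species lack a depth range, zones holding > 10% of valid
records (sea-floor depth sampled from bathymetry at the record location)
are used instead.

## Range construction

Degree buffering is literal in lon/lat space (1° for the biogeographical
range, 10° for the potential range), with mitred joins and square caps so a
rectangular map expands exactly per axis. No geodesic correction is
applied; near the poles 1° of longitude is much shorter than 111 km, a
known and accepted distortion of the degree-buffer convention. The ocean
basin constraint labels connected components of the ocean raster
(4-connectivity) and keeps the components the pre-buffer range touches;
basin polygons are exact unions of grid-cell rectangles, so clipping to
them also removes all land. Spherical polygon areas are computed in the
equal-area transform (lon, sin lat), exact for polygon edges that follow
meridians and parallels — which grid-derived polygons do.

The derived-range province filter keeps units whose **individual** share of
occurrences strictly exceeds 3.3% (≈ 1/30th); Arctic sub-units use 0.5%.
An alternative cumulative reading — drop the smallest provinces while their
combined share stays ≤ 3.3% — is available via `share_mode="cumulative"`;
the per-unit rule is the default because it is the reading under which the
worked share arithmetic (e.g. 2/82 = 2.4% dropped) is reproduced. A
single-record bounding box is inflated by one grid cell per degenerate axis
so it remains valid geometry.

Spatial thinning applies no thinning at n ≤ 1000, 20 km for
1000 < n ≤ 5000, and 30 km above; the greedy pass visits records in a
seed-shuffled order, keeps a record and suppresses all neighbours within
the thinning distance (chord-equivalent radius on a k-d tree of unit
vectors), which guarantees the pairwise minimum-distance property exactly.

## Training set

Pseudo-occurrences are generated only when an expert range map exists and
verified records number under 1000: candidate cells are range-map cells
whose sea-floor depth lies inside the species depth range (all cells when
no range is known), minus cells already holding a real occurrence (so the
generated points strictly add environmental information); the sample is
min(1000, ⌊0.4·N⌋) cells without replacement. Environmental thinning snaps
every layer to its bin size (oxygen 10 mmol·m⁻³, temperature 0.05 °C, pH
0.1, productivity 0.5 mmol·m⁻³, salinity 0.1 psu, velocity 0.02 m·s⁻¹,
depth 5 m), keys each cell by its snapped tuple, and keeps one record per
key uniformly at random under the seed. Snapping is to the **nearest**
multiple by default (floor mode available); real occurrences and
pseudo-occurrences are pooled before thinning.

Pseudo-absence counts default to the presence count (balanced design).
The pelagic strategy excludes the surface range envelope — per-variable
2.5–97.5 percentile bounds (linear-interpolation percentiles) of the
presence environments — and requires **all** variables outside their
bounds. On small worlds that strict rule can leave too few cells; the
implementation then relaxes to "any variable outside" with a logged
warning rather than failing, a documented extension of the rule. The
benthic/demersal strategy samples cells whose great-circle distance
(haversine, R = 6371 km) to the nearest presence lies in [80, 1000] km.
Both strategies sample uniformly without replacement inside the potential
range and are seed-deterministic.

## Ensemble

The training weights give presences 0.7 of the total case weight (the
prevalence setting), applied as per-row `sample_weight` where the estimator
supports it. Two estimators (the neural network and the discriminant
analysis) do not accept fit weights; for those the same weighting is
applied through seeded weighted bootstrap resampling of the training rows,
with a guard ensuring both classes survive.

Environment-blocked cross-validation activates above 1000 unique
environments: for each modelling variable, five folds are formed as
quantile blocks along that variable, computed separately within the
presence and absence classes so every fold holds both classes in ~1/5
proportion — each fold is a distinct environmental stratum, and the plan
has (variables × 5) assignments per algorithm (30 for six variables, 300
runs over ten algorithms). Below that cut, random stratified 5-fold CV with
3 repeats (15 assignments) is used. A fold that cannot hold both classes is
an error rather than a silent skip.

The ten algorithm slots and their implementations:

| id | family | implementation |
|---|---|---|
| glm | linear | logistic regression on linear + quadratic terms |
| gam | additive | per-variable cubic B-spline basis + logistic link |
| rf | bagged trees | random forest (100 trees) |
| ann | neural network | single-hidden-layer perceptron (8 units) |
| fda | discriminant | linear discriminant analysis on a quadratic basis |
| cta | single tree | depth-limited classification tree |
| gbm | boosted trees | gradient-boosted trees (100 stages) |
| maxnet | entropy/background | L1 logistic over linear+quadratic+hinge features |
| xgboost | boosted trees | extreme gradient boosting (100 rounds) |
| mars | adaptive splines | hinge basis at quantile knots + L1 term selection |

The gam, mars and maxnet slots are in-family reconstructions built on the
spline/penalized-regression primitives of scikit-learn: the additive model
is a spline-basis logistic fit, the adaptive-spline model replaces forward
knot selection with L1 shrinkage over a dense hinge basis, and the
maximum-entropy model uses its penalized-logistic-regression equivalence
over maxent-style feature classes. Defaults are fixed, sensible settings;
a `tuning_hook(algorithm_id, estimator)` callback allows per-algorithm
hyperparameter search without changing the surface.

Evaluation sweeps thresholds over the distinct predicted values (presence
declared at prediction ≥ threshold) and reports TSS and CSI at the
TSS-maximizing threshold plus the threshold-free rank AUC. Runs with
TSS > 0.6 (strict) are retained. Ensemble products: the **unweighted** mean
of retained-run suitabilities (a deliberate choice — weighting by
validation scores would systematically favour the flexible
machine-learning members, which overfit current conditions and extrapolate
worse); the committee average, the fraction of retained runs voting
presence at their own TSS-maximizing thresholds (1 and 0 exactly at
unanimity); and the coefficient of variation (population SD / mean, 0
where the mean is 0, with sub-1e-12 dispersions clamped to exactly 0 so
identical runs report zero disagreement). Calibration ranges are
per-variable min/max over the training rows and feed the clamping mask
(per-cell count of out-of-range variables).

## Projection and change

Projection is confined to the potential range (cells outside are masked).
Binarization uses the ensemble-level TSS-maximizing threshold by default
with an inclusive ≥ cut. Invasion is future-suitable ∧ present-unsuitable;
extinction the reverse; both are disjoint by construction and expressed as
percent of the potential range's spherical area, cell areas computed as
R²·Δλ·(sin φ₂ − sin φ₁). Richness maps are per-cell sums of binary maps
(optionally normalized by the maximum) and can be coarsened by per-block
maximum for comparison against lower-resolution richness datasets.

## Resolution and regridding

The working resolution follows the modelled share of global ocean cells:
≤ 1/3 → 0.05°, (1/3, 2/3] → 0.1°, > 2/3 → 0.2°. Aggregation averages
ocean cells per block (a block of all-missing cells stays missing);
disaggregation interpolates bilinearly between coarse cell centres with
constant extension at the domain edge, and the missing-value mask
propagates block-wise.

## Synthetic worlds

The generator emulates the pipeline's inputs, not the ocean: a rectangular
domain (default 40° × 60° at 0.5°) with a continent of ~15% of the area
along the eastern edge behind a seeded wiggly coastline; bathymetry
increasing with distance from the coast (shelf then slope, capped at
7500 m, so all four sea-floor depth zones exist); a latitudinal temperature
gradient (28 °C at the equator, −0.4 °C per degree of latitude) plus
smoothed seeded noise; oxygen anti-correlated with temperature;
productivity decaying offshore; weak salinity and pH gradients. Future
stacks add spatially uniform deltas; the default temperature deltas
(+0.86/+1.51/+2.89 °C by the 2090s for the low/moderate/high scenarios,
×0.55 by the 2050s) follow the projected global mean SST rises of the three
scenario families. Provinces are latitudinal bands; depth zones are cut
from bathymetry at 800/3500/6500 m.

Species niches are truncated-Gaussian products over environmental variables
(default: temperature sd 3 °C, salinity sd 1.5 psu, centred on the
conditions at a chosen latitude); the historical trapezoidal response is a
documented alternative kernel shape not currently implemented. The true
range is the cell set with suitability above a cutoff (default 0.5).
Occurrences are drawn proportional to true suitability and jittered within
the cell; error injection adds land points, (0,0) points, exact duplicates,
out-of-range strays (ocean cells beyond the 1° buffer a range map would
add, so re-flagging can catch them) and blanked dates, each at a binomial
rate, with ground truth recorded per row. Default rates (5% land, 2% zero
coordinates, 5% duplicates, 5% strays, 10% missing dates) sit in the range
reported for aggregated biodiversity databases.

What passing on these worlds shows: the pipeline's rules and the
ensemble's recovery machinery are implemented correctly, and the ensemble
can re-identify a smooth, stationary niche from noisy presences. What it
does not show: robustness to real-world sampling bias structure, spatially
correlated measurement error, non-Gaussian niches, dispersal limitation, or
coastline-resolution artefacts — all of which are absent by construction.

## Problem sizes and determinism

Default study sizes — a 120 × 80 grid, 400–800 occurrence records, ~400
unique-environment presences, balanced pseudo-absences, 300 model runs —
were chosen so a full per-species workflow completes in about a minute on
one CPU while still triggering the environment-blocked (not the fallback
random) cross-validation path. Every stochastic step (thinning order,
environmental thinning survivor choice, pseudo-absence draws, resampling,
estimator seeds) consumes an explicit seed, and reruns with the same seed
are bit-identical.

## Known limitations

Degree buffering ignores meridian convergence; basin connectivity is
4-connected at raster resolution and does not admit cross-basin dispersal
corridors; only two vertical strata (surface, benthic) are represented, so
depth-stratified pelagic species are modelled on surface conditions;
polygon I/O is GeoJSON and raster I/O plain-text ASCII grids, chosen for
portability over compactness; and hyperparameter tuning is a hook with
fixed defaults rather than a built-in search.
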