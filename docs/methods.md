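# Methods

## Model and procedure

`geodens` simulates and analyses an adaptive field protocol for
measuring the spatial density of users of proximity-based social apps.
The pipeline has four stages, each a library module:

1. **Population** (`geodens.population`): a marked planar point pattern
   of app users over a polygonal study region. The generating process is
   an inhomogeneous Poisson process: a sum of isotropic Gaussian hotspot
   components (each with a center, spread in miles, expected count and a
   race mark) plus a uniform per-race background rate (users/mi²).
   Component counts are Poisson with the stated means and points falling
   outside the region are resampled, so truncation does not bias counts.
   Ages come from per-race two-component truncated-normal mixtures;
   missingness of race and age is independent Bernoulli thinning applied
   after generation, so "missing race" exists as its own category in the
   data and is only collapsed to "other" at analysis time.
2. **Sampling** (`geodens.sampling`): at each stop, capture the k = 50
   nearest profiles or all within r_max = 2 miles, whichever is fewer.
   The adaptive radius is the distance to the k-th nearest user (ties at
   that distance are all included) or r_max in the sparse branch; the
   next stop is that radius further along the route (arc length). The
   population is frozen during a traversal, and a user may be captured
   at several overlapping stops — the protocol aggregates per stop and
   does not deduplicate across stops.
3. **Density** (`geodens.density`): per-stop counts standardized to a
   1-mile-radius reference circle (weight = count / radius², i.e. users
   per circle of area π mi²), then a weighted KDE on a raster grid: each
   stop contributes a kernel whose integrated volume equals its weight,
   and cell values are kernel sums at cell centers in users/mi².
4. **Comparison** (`geodens.compare`): cellwise map algebra between
   co-registered surfaces — difference (null 0), ratio (null 1, NODATA
   where the denominator is 0), per-surface extreme masks
   (value > mean + n·SD, strict inequality), and the three-valued
   indicator difference I(A extreme) − I(B extreme) ∈ {−1, 0, 1}.

## Assumptions

- Planar geometry in miles throughout. App-reported distances are linear
  (feet/miles), so a local planar frame is the natural coordinate
  system; there is no lat/lon or projection handling.
- Single snapshot: the population does not churn between stops of a
  route. Real app populations vary by time of day and day of week; the
  simulator averages over that by construction.
- Capture is exhaustive and error-free within the adaptive radius, and
  self-reported marks are taken at face value.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `k` | 50 | profiles | max captures per stop |
| `r_max` | 2.0 | miles | max capture radius; also the sparse-area step |
| `bandwidth_mi` | 2.0 | miles | kernel scale; 1 mile also of interest (sharper peaks, more empty area) |
| `kernel` | gaussian-truncated | — | alternative: `quartic` (biweight, support = 1 bandwidth), the classic GIS density kernel |
| `cell_size` | 0.1 | miles | raster cell; ≤ bandwidth/4 keeps center-evaluation error negligible |
| `n_sd` | 2 | — | extreme threshold = mean + n_sd·SD of the surface's own cells |
| `age_bins` | 18/25/31 | years | groups 18-24, 25-30, >30; the alternative 18/26/31 convention (18-25, 26-30) is supported |
| `weight_mode` | standardized | — | kernel weights = per-circle standardized counts; `raw` uses raw counts |

## Numerical choices

- **Gaussian kernel truncation.** The default kernel is a bivariate
  normal truncated at 3 bandwidths **and renormalized** so each stop's
  kernel integrates exactly to its weight. Untruncated, 3σ retains only
  98.89% of mass; renormalizing makes the mass-conservation identity
  Σ(cell·area) = Σ(weights) hold to discretization error (< 1%) while
  raising the peak by a factor 1/0.98889 ≈ 1.011 over the closed form
  w/(2πh²). Tests assert the renormalized closed form exactly and the
  untruncated limit to 1.2%.
- Kernels are evaluated at cell centers only (standard raster practice);
  the raster follows the ESRI ASCII grid convention (row 0 = top row,
  `xllcorner`/`yllcorner` = lower-left corner, NODATA −9999).
- Surface statistics use the **population** (divide-by-N) standard
  deviation over non-NODATA cells inside the region mask, zeros
  included — the raster-statistics convention of GIS tools, and the
  "entire sample space" reading of the threshold rule.
- Distance ties at the k-th rank are all captured (capture may exceed k
  on ties); this makes `observe` deterministic and input-order
  independent. An optional quantization mode rounds distances to whole
  feet below 1 mile and 0.01 mile above, emulating app display
  granularity; the default is exact Euclidean distance.
- If ≥ k users coincide with a stop the observed radius is 0; routes
  advance by max(radius, 0.01 mile) so traversal always terminates.
  Continuous populations never hit this guard.
- Ratio surfaces map zero denominators to NODATA rather than ±inf so
  rasters stay writable as plain text.
- Numbers serialize with 6 significant digits (`%g`), making
  write→read→write byte-identical for every format.

## Design choices where the design was open

- **Standardized vs raw kernel weights.** Weighting stops by their
  standardized per-circle counts is the default because it is the only
  choice consistent with standardizing at all — two stops seeing the
  same true density but different radii should contribute equally. Raw
  counts remain available (`weight_mode="raw"`) because the worked
  8-white/4-black example of per-point counting in the source protocol
  reads most naturally as raw counting.
- **Strict inequality** at the extreme threshold ("> mean + 2 SD"): a
  constant surface therefore has no extreme cells.
- **No cross-stop deduplication**: users captured from overlapping
  circles count at each stop, mirroring per-stop aggregation in the
  field; deduplication would require profile identity across stops,
  which screenshots of real apps do not reliably give.
- Age bins: both published conventions exist (Methods-style 18-24/25-30
  vs Results-style 18-25/26-30); bin edges are configurable and the
  default is the former. Neither is asserted as canonical.

## The demo scenario, and what passing tests do and do not show

`demo_scenario()` is an 11.5 × 11.5-mile square city (132.25 mi²) with
~2666 expected profiles: a shared central hotspot, white density
extending north-east, two black hotspots south-west, other-race users
uniform, race missingness 5.51% and age missingness 22.24%. Expected
post-missingness race fractions are 58.63% white / 30.38% black / 5.48%
other / 5.51% missing; age mixtures give medians near 33 (white) and 28
(black) years. A 7-sweep serpentine route yields ~78 adaptive stops with
right-skewed per-stop densities (median ≈ 17, mean ≈ 37 users/mi²).

The generator emulates hotspot clustering, racial segregation of
intensity, realistic subgroup fractions and missingness. It does **not**
emulate: temporal churn of app users, reporting error in distances or
marks, road-network constraints on where users live, or correlation
between missingness and location/race. Parameter-recovery results
(Spearman ≥ 0.7 between true intensity and the estimated 2-mile surface
at 200 interior cells) therefore show the estimator works under the
stated point-process model, not that any particular field estimate is
unbiased.

## Problem sizes

Tests run the demo scenario once (≈2600 users, ≈78 stops, 115×115 grid
at 0.1-mile cells); oracle comparisons use ≤ 10 stops on coarse grids;
Monte-Carlo checks use 200–500 replicates of small populations. The
CLI end-to-end test uses a 600-user, 0.25-mile-cell configuration.

## Known limitations

- Rejection sampling of hotspot components assumes a non-negligible
  overlap between each component and the region; a component centered
  far outside its region raises an error rather than looping forever.
- `coverage_fraction` and the KDE are grid approximations; their error
  scales with resolution and cell size respectively.
- Surfaces estimated from overlapping circles double-count multiply
  captured users, so absolute surface volumes exceed the true population
  count in densely re-sampled areas; comparisons between strata are
  unaffected (both inherit the same sampling intensity).
- No statistical significance testing of hotspots and no kriging or
  other geostatistical interpolation; the estimator is deliberately the
  weighted KDE.
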