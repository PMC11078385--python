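# Methods

## Radiometric model

Digital numbers relate to backscatter through a per-scene absolute
calibration constant `A`: linear intensity `σ = DN²/A²`, reported as
`σ_dB = 20·log10(DN/A)`.  The mapping is monotone and invertible
(`DN = A·10^(dB/20)`); `DN = 0` is mapped to nodata rather than −∞.
Multiplicative speckle is modelled as `I = σ·G` with `G ~ Gamma(L, 1/L)`
(mean 1), `L` the equivalent number of looks (default 4, typical of
multi-looked GRD products).  Averaging in dB therefore carries an
analytic bias `E[10·log10 G] = (10/ln10)(ψ(L) − ln L)` ≈ −0.57 dB at
L = 4; it is identical for all classes, so midpoint thresholds and the
classification are unaffected, but tests that recover configured class
means from unfiltered dB account for it explicitly.

## Refined Lee filter

MMSE estimate `x̂ = ȳ + b(y − ȳ)` with gain
`b = clip(var_x/var_y, 0, 1)` and
`var_x = (var_y − ȳ²σ_v²)/(1 + σ_v²)`, `σ_v² = 1/L`.  Window statistics
come from one of nine candidate windows: eight edge-aligned directional
half-windows, plus the full square window for pixels whose neighbourhood
shows no significant edge.  Edge significance compares the largest 3×3
sub-window mean gradient against `edge_k·|centre|·sqrt(2/(L·s²))` — the
expected gradient magnitude from speckle alone over s×s sub-window means
— with `edge_k = 2.5` (≈1% false-edge rate under the Gaussian
approximation).  The full-window branch matters: without it the filter
under-smooths homogeneous areas and loses to a plain boxcar on mixed
scenes; with it the filter beats the boxcar on striped step-edge scenes
while preserving constant fields exactly.  Filtering is applied to linear
intensity (DN²) before calibration; since `A` is a per-scene scalar the
order commutes with the division by `A²`.

## Coregistration

Integer-pixel exhaustive search of normalized cross-correlation over
±`max_shift` (default off; ±5 in tests).  Ties are broken by smaller
shift magnitude, then lexicographically.  The returned shift, applied to
the moving raster, maximizes NCC with the reference; exposed margins
become nodata and are excluded from all later statistics via nodata
propagation.

## Features and thresholds

Per-polarization temporal means use all valid dates per pixel (a pixel is
nodata only if nodata at every date).  `SAR_add` is the dB sum of the two
mean polarizations; NDVI is unclipped, with zero-denominator pixels set
to nodata.  The median rule places each cut at the midpoint of the two
adjacent training-class means.  Derivation fails loudly if a class is
missing or the class ordering is incompatible with the tree (e.g. water
not darkest); equal NDVI means degrade to a warning.  Boundary policy:
the NDVI test is strict `>`, the SAR tests strict `<`, so a value exactly
on a cut falls through to the later branch.

## Sampling and statistics

Regions (not pixels) are the sampling unit: the 70/30 split is stratified
by class at the region level with `floor(0.7·n + 0.5)` training regions
per class, so pixels from one region never straddle the split.  Class
statistics use population (ddof = 0) moments.  The Jeffries–Matusita
distance `2(1 − e^{−B})` uses the Bhattacharyya distance with the pooled
half-sum covariance; singular covariances (e.g. constant features) raise
rather than returning a misleading 2.0.

## Accuracy

Confusion matrices are oriented rows = reference, columns = predicted.
`OA = trace/n`; `kappa = (p₀ − p_e)/(1 − p_e)` with
`p_e = Σ rowᵢ·colᵢ/n²`; PA/UA are the diagonal over row/column sums, NaN
when undefined.  Mapped area is `pixels·pixel_size²/10⁶` km²; relative
error is `100·(mapped − reference)/reference`.

## Synthetic scene generator

Binary-space-partition landscape with target class proportions (default
wheat 0.5, other vegetation 0.2, building 0.2, water 0.1) and patch sizes
6–24 px on a 128×128, 10 m grid.  Radiometry (dB means per class and
date): wheat VH follows a −23…−19 dB phenological trajectory around
−21 dB, VV half the amplitude around −14; other vegetation −17/−13;
building −12/−10; water −30/−18.  Optical reflectances give class NDVI
≈ 0.25 (wheat), 0.65 (other vegetation), 0.10 (building), −0.30 (water)
with small Gaussian band noise.  ROIs are pure 3×3 squares placed
non-overlapping on speckle-independent eroded class masks (60/30/60/30
per class, supporting the 126/54 region split).  All randomness derives
from `SeedSequence([seed, k])` sub-streams, so landscape, speckle,
optics and sampling are independently reproducible.

What it does **not** emulate: topographic/incidence-angle variation,
spatially correlated speckle, mixed pixels, phenological within-class
variability beyond the configured date trajectory, atmospheric effects in
the optical bands, and geolocation error beyond integer-pixel shifts.

## Numerical choices

- Filter window 7×7 with 3×3 sub-windows (offset 2): the standard
  configuration; tests that compare against truth reduce effective sample
  sizes by the window area (n/49) to account for the induced spatial
  correlation.
- `edge_k = 2.5` balances edge preservation against speckle-triggered
  false edges; the striped-edge test fixture (period-10 stripes, 5×
  contrast, 100×100) shows a robust win over the boxcar across seeds.
- Nodata: −9999.0 for float rasters, 255 for class maps; propagation is
  strict (any nodata input → nodata output) except temporal means.
- GeoTIFFs carry ModelPixelScale/ModelTiepoint/GDAL_NODATA tags plus a
  JSON description with CRS id and units; class maps are uint8 with a
  JSON legend sidecar.

## Limitations

- Thresholds assume the class ordering wheat-between-water-and-building
  on SAR_add and wheat-below-other-vegetation on NDVI; scenes violating
  it are rejected at derivation, not silently misclassified.
- The tree is fixed-topology by design; it does not learn structure from
  data and will not adapt to more classes.
- Integer-pixel registration only; sub-pixel misregistration appears as
  edge blur.
- Patch corners are blended by any windowed filter, so a few boundary
  pixels can change class even in noise-free runs; accuracy is assessed
  on sample regions, which are drawn from patch interiors.
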