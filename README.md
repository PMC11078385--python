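# sarwheat

Winter-wheat extraction from time-series dual-polarization SAR backscatter
and a single optical NDVI scene, using a fixed-topology threshold decision
tree.

## The method

Winter wheat in early spring is hard to separate from other land cover in
a single image, but its temporal backscatter trajectory and its spring
NDVI are distinctive.  The workflow implemented here:

1. **Preprocess** nine dual-pol (VH + VV) SAR acquisitions spanning the
   growing season: integer-pixel coregistration to the first scene,
   refined Lee speckle filtering on linear intensity, radiometric
   calibration to sigma-nought in dB (`σ⁰ = 20·log10(DN/A)`).
2. **Composite & features**: temporal mean of each polarization over the
   nine dates; the radar index `SAR_add = mean VH + mean VV` (dB); NDVI
   `(NIR − Red)/(NIR + Red)` from one optical scene near heading stage.
3. **Samples**: pure regions of interest for four classes (winter wheat,
   other vegetation, building, water), split 70/30 at the region level
   into training and validation.
4. **Thresholds** by the median rule: each decision cut is the midpoint
   of the two adjacent training-class means (wheat/other-vegetation on
   NDVI; water/wheat and wheat/building on SAR_add).
5. **Classify** every pixel with the fixed tree — NDVI above the cut is
   other vegetation; otherwise SAR_add below the water cut is water,
   below the building cut is winter wheat, else building.
6. **Assess**: confusion matrix on the validation regions, overall
   accuracy, kappa, producer's/user's accuracy, mapped wheat area and its
   relative error against a reference area.

A synthetic scene generator (`sarwheat.synth`) reproduces the study
conditions — gamma-distributed speckle at ENL 4, class radiometry with
phenology-driven wheat trajectories, noisy optical bands — so the whole
chain can be exercised and validated without external data.

## Quick start

Library:

```python
from sarwheat import PipelineConfig, SceneConfig, run_pipeline

res = run_pipeline(PipelineConfig(synthetic=SceneConfig(seed=1), seed=1,
                                  out_dir="out"))
print(res.thresholds)
print(res.report.render_text())
```

CLI (each stage is also available separately — see `sarwheat --help`):

```
sarwheat simulate --out scene --seed 1
sarwheat run-all --out out --seed 1
```

Running `examples/03_classify_and_assess.py` prints (seed 1):

```
derived thresholds:
  NDVI cut         0.449
  water cut       -41.13 dB
  building cut    -28.67 dB
...
                OA  100.00%
             Kappa    1.00
```

The derived cuts sit within sampling error of the analytic midpoints of
the configured class radiometry (0.45, −41.5 dB, −28.5 dB), and with ≥5 dB
class gaps the nine-date composite separates the classes essentially
perfectly (all pairwise Jeffries–Matusita distances ≈ 2.0).

## Layout

- `src/sarwheat/raster.py` — grid/raster model, GeoTIFF I/O, mosaic, crop
- `src/sarwheat/preprocess.py` — coregistration, refined Lee, calibration,
  temporal compositing
- `src/sarwheat/features.py` — SAR_add, NDVI, feature stack, RGB composite
- `src/sarwheat/samples.py` — sample regions, stratified split, class
  statistics, J-M distance, GeoJSON I/O
- `src/sarwheat/dtree.py` — median-rule thresholds and the decision tree
- `src/sarwheat/accuracy.py` — confusion matrix, OA/kappa/PA/UA, areas
- `src/sarwheat/synth.py` — synthetic landscape/SAR/optical generator
- `src/sarwheat/pipeline.py`, `cli.py` — orchestration and the CLI
- `examples/` — narrative walk-throughs of each stage
- `docs/methods.md` — model details, parameter choices, limitations
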