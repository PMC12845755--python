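# pomoct

Dual-resolution X-ray CT analysis of apple tissue architecture, for
researchers in fruit physiology and postharvest science who want to turn CT
scans of intact fruit into quantitative anatomy: voxelwise porosity maps,
anatomical-region statistics, cellular morphometrics, and a composite
quality index. Because raw orchard scan sets are rarely shareable, the
package ships first-class synthetic phantom generators with exact ground
truth, so every analysis step is validated by parameter recovery.

## What it computes

**Grey value → porosity.** Reconstructed CT grey values (signed 16-bit) are
mapped linearly onto porosity percent through two reference materials —
apple juice (0 % porosity) and external air (100 %):

    φ(g) = 100 · (g_juice − g) / (g_juice − g_air)

with default anchors g_juice = 49 and g_air = −1007. The model is exact at
both anchors and strictly decreasing in grey value.

**Macro scale (≈339 µm in-plane, 0.5 mm slices).** Otsu thresholding and
26-connected labeling separate up to three fruits per scene; internal gas
cavities are folded in by 3D hole filling. The porosity map is banded into
the anatomical hierarchy — seeds (0–10 %), core (5–15 %), cortex (15–30 %),
cavities (≈100 %) — and summarized per region and per fruit, with line
profiles, slice maps, one-way ANOVA + Tukey HSD across treatments, and
macro–micro correlation.

**Micro scale (6.6 µm isotropic, 0.5 mm ROI).** After contrast enhancement,
a three-class multi-level Otsu separates bright cell bodies, the cell-wall/
juice matrix, and dark gas pores. Cells and pores are detected as 3D blobs
(distance-transform watershed splits touching objects) and summarized by
equivalent-sphere diameter d = 2·(3V/4π)^(1/3), counts, cell density with
half-weighted boundary correction, and gas volume fraction. Paired
sunny/shady ROIs are compared with paired t-tests.

**Quality index.** Traits are Z-scored (z = (x − μ)/σ, population σ), a PCA
of the correlation structure yields loadings, weights follow
w_i ∝ Σ_{j≤k} |loading_ij|·varfrac_j (normalized to Σw=1), and each sample
scores

    Q = Σ_i w_i · z_i

Traits are grouped A/B/C by which of the first two components dominates
their loading, and per-treatment min–max scaled means are exported for
radar charts.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
phantoms and write tables under `results/`:

```sh
python analysis/01_simulate_phantoms.py
python analysis/02_porosity_analysis.py
python analysis/03_microstructure.py
python analysis/04_quality_index.py
```

`02_porosity_analysis.py` plants whole-fruit porosity means of
24.70 / 26.44 / 29.06 % at the three crop-load levels (high/standard/low,
nine fruits each), pushes every fruit through the forward grey-value model
(noise σ = 10 grey units) and back through segmentation + calibration, and
prints:

```
recovered whole-fruit porosity by crop load:
             mean    std
high       24.854  0.363
low        29.095  0.259
standard   26.369  0.661
one-way ANOVA: F = 195.9, p = 1.36e-15
regional porosity hierarchy (%):
region  mean_porosity_pct  voxel_count
cortex              21.96        96412
  core               9.46         2687
  seed               4.79          675
cavity              99.62         2290
```

i.e. the planted crop-load ordering is recovered to ~0.15 points and the
regional porosity hierarchy (seed < core < cortex ≪ cavity) emerges from
the banded map. `03_microstructure.py` recovers a planted mean cell
diameter of 68.8 µm exactly, a +1.71-point sunny−shady porosity offset as
+1.70 points (paired p ≈ 3×10⁻⁷), and a macro–micro Pearson correlation of
0.86 across 18 samples. `04_quality_index.py` reports the first two
principal components carrying 75 % of trait variance and a mean quality
index Q of −0.46 / −0.01 / +0.48 for high / standard / low crop load.

A thin CLI mirrors the library (`pomoct simulate|calibrate|segment|
porosity|profile|micro|quality|run`); `pomoct run` executes the macro
pipeline end to end and writes a seeded, reproducible `summary.json`.

## Layout

- `src/pomoct/` — library: `volume_io`, `calibration`, `segmentation`,
  `porosity`, `microstructure`, `quality`, `phantoms`, `studies`,
  `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing `results/`
- `tests/` — unit, property and acceptance suites (phantom-backed)
- `docs/methods.md` — models, parameter choices, and limitations
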