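# fibertension

Quantitative image analysis of the **tensional state of fibronectin fibers**
in multiplexed immunofluorescence images of breast tissue, for researchers
studying extracellular-matrix mechanobiology in the tumor microenvironment.

Fibronectin fibers in healthy stroma are held under cell-generated tension.
The peptide probe FnBPA5 binds fibronectin with nanomolar affinity only when
the fiber is *relaxed* — stretching destroys its binding motif — so
co-staining with FnBPA5 and a polyclonal fibronectin (FN) antibody turns a
fluorescence image into a fiber-tension map. This package implements the
full analysis chain around that read-out:

* **Pixel quantification** — Otsu-thresholded positive-pixel masks; the
  tension summary `100 · |FnBPA5⁺ ∩ FN⁺| / |FN⁺|` (pixel ratio); TNC / CD34
  pixel densities; per-pixel FnBPA5/FN ratiometric maps.
* **Collagen organization** — Frangi vesselness to identify SHG⁺ collagen
  fibers and structure-tensor coherency C = (λmax−λmin)/(λmax+λmin) averaged
  over fiber pixels (wavy healthy collagen scores low, aligned tumor
  bundles score high).
* **Cell phenotyping** — DAPI nucleus detection (Otsu + watershed on the
  distance transform), per-cell marker means over nucleus + 1.5 µm ring, and
  composite phenotypes such as Ki67⁺&panCK⁺ carcinoma cells or CD4⁺&FoxP3⁺
  Tregs, as percentages of all cells.
* **Spatial proximity** — exact-distance-transform distances from nucleus
  centers to the nearest FnBPA5⁺ pixel, 1 µm-binned profiles (0–20 µm), the
  fraction of cells within 10 µm, and a two-stage statistic (α-SMA⁺ cells
  near untensed fibers → distance to CD34⁺ vessels) that separates CAFs from
  vessel-lining smooth-muscle cells.
* **Cohort statistics** — normality-gated test selection (four normality
  tests; t test / Mann-Whitney / ANOVA+Tukey / Kruskal-Wallis+Dunn), profile
  ANOVA, a linear-contrast trend test, and Pearson correlation.
* **Synthetic tissue generator** — healthy / DCIS / invasive grade-2 /
  grade-3 presets producing multi-channel images *with exhaustive ground
  truth* (pre-noise masks, fiber orientations, cell lists with phenotypes
  and true distances), so every stage is verifiable without patient data.

See `docs/methods.md` for models, parameters and numerical choices.

## Worked example

```python
import fibertension as ft

config = ft.AnalysisConfig(pixel_size=0.5)   # µm per pixel

healthy  = ft.generate_tissue("healthy",     seed=0)
invasive = ft.generate_tissue("invasive_G2", seed=0)

for sample in (healthy, invasive):
    r = ft.run_sample(sample.image, config)
    print(f"{sample.image.condition_label:12s}"
          f"  FnBPA5/FN ratio {r['fnbpa5_ratio_pct']:5.1f}%"
          f"  (truth {100 * sample.truth.fnbpa5_fraction:5.1f}%)"
          f"  TNC {r['tnc_density_pct']:5.1f}%"
          f"  coherency {r['mean_coherency']:.2f}")
```

prints

```
healthy       FnBPA5/FN ratio   7.9%  (truth   8.0%)  TNC   4.8%  coherency 0.72
invasive_G2   FnBPA5/FN ratio  35.5%  (truth  35.7%)  TNC  14.9%  coherency 0.89
```

Reading: in the healthy sample only ~8% of fibronectin-positive pixels bind
the tension probe (fibers are stretched), versus ~36% in the invasive
sample (fibers have relaxed); the recovered ratios match the generator's
ground truth to within a fraction of a percentage point. TNC accumulates
where fibers are untensed, and collagen coherency rises from wavy (0.72) to
aligned (0.89). `run_cohort` aggregates such per-sample results into group
comparisons, the FnBPA5–TNC correlation and a reproducibility manifest.

A CLI wraps the same functions:

```sh
fibertension synth --preset invasive_G2 --seed 0 --out sample_dir
fibertension run-sample --image sample_dir/image.ome.tiff --out result.json
fibertension run-cohort --spec healthy=5,invasive_G2=5 --seed 0 --out results/
fibertension stats --samples results/samples.csv --out stats.csv
```

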