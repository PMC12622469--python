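# nephroimc

Spatial single-cell analysis of imaging mass cytometry (IMC) cohorts for
immune-checkpoint-inhibitor–associated nephrotoxicity (ICI-AN), built as a
tested, reusable pipeline plus a synthetic cohort generator that supplies a
known answer for every stage.

## The problem

ICI-AN kidney biopsies show dense tubulointerstitial immune infiltration —
resident macrophages, CD8⁺ T cells and fibroblasts co-localizing in recurrent
niches — accompanied by tubular injury and interstitial fibrosis, and these
tissue features track clinical markers (serum creatinine, eGFR, CRP, the
tubular injury index, urinary CXCL9). Quantifying that requires a chain of
image and spatial statistics: spillover compensation and denoising of the
40-channel metal-tag images, single-cell segmentation with artifact
filtering, arcsinh normalization and clustering into cell populations,
per-mm² density comparison, cellular-neighborhood (CN) analysis, spatial
permutation tests, and correlation with clinical covariates. Patient IMC
data of this kind are rarely deposited, so the package pairs the pipeline
with a generator that emulates the study design (10 control + 10 case
biopsies; 40 vs 80 ROIs; 12 cell populations over a 40-marker panel;
planted spatial attraction; group fibrosis fractions 5.60 ± 1.4 % vs
24.27 ± 5.68 %) and validates every stage against the planted truth.

## Methods at a glance

- **Preprocess** — per-pixel spillover inversion (`observed = true·S`,
  negatives clipped), 3×3 median filter, percentile contrast rescale to
  0–255 (visualization/thresholding only).
- **Segment** — 8-connected nuclear components (≥ 9 px) paired to membrane
  components, watershed territories, and the artifact filter that drops
  cells whose nuclear-to-membrane centroid distance exceeds 15 px.
- **Phenotype** — `x → asinh(x/5)`, per-marker 99th-percentile cap, min–max
  scaling; per-sample median batch centering; kNN-graph Leiden clustering;
  automatic annotation against population templates; densities in cells/mm².
- **Spatial** — per-cell composition of the k = 10 nearest neighbors,
  k-means (k = 15) CN classes, Voronoi maps, label-permutation
  attraction/repulsion tests (z-score + empirical p, BH-adjusted), and
  0–10/10–20/20–30 µm patch counts.
- **Clinical** — TII (0–5 scale over ≥ 10 high-power fields),
  Shapiro–Wilk/Levene-dispatched two- and multi-group tests,
  Pearson/Spearman-dispatched correlation matrices, creatinine
  normalization, and the |log2FC| > 1.5 & FDR < 0.05 DE-table filter.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/03_phenotype_cells.py
python analysis/04_spatial_neighborhoods.py
python analysis/05_clinical_correlations.py
```

On the desk-scale cohort (seed 7: 4+4 samples, 48 ROIs, 16 751 cells) this
prints, among other things:

```
20 clusters -> 12 annotated populations; ARI vs planted types = 1.000
CN9 (fibroblast+resident_macrophage+cd8_t) is the trio-enriched neighborhood
CN9 per-ROI abundance: case 0.075 vs control 0.030 (one-sided Mann-Whitney p = 2.72e-05)
urinary CXCL9 vs resident-macrophage density: r = 0.905 (p = 2.01e-03, spearman, n = 8)
```

i.e. phenotyping recovers all 12 planted populations exactly; the
neighborhood class dominated by the macrophage/CD8/fibroblast trio is the
one enriched in the case group; and macrophage density correlates with
urinary CXCL9 with the planted positive sign. `analysis/02_segment_rois.py`
demonstrates the raw-image path (render → compensate → filter → segment →
quantify) on a few ROIs.

The same stages are scriptable through the CLI
(`nephroimc simulate|preprocess|segment|spatial|stats|run`), e.g.
`nephroimc run --preset desk --seed 7 --out out/`.

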