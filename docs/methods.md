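# Methods

This note documents the models, defaults and numerical choices behind
`nephroimc`, and what the synthetic validation does and does not show.

## Synthetic cohort model

The generator reproduces the statistical skeleton of an ICI-AN biopsy
study: two groups (control, case), per-sample ROIs, 12 cell populations
over a 40-antibody panel, spatial co-clustering of an immune-stromal trio,
and clinical covariates driven by immune density.

**Design counts.** Default: 10 control + 10 case samples, 4 ROIs per
control and 8 per case (40 vs 80 ROIs). ROI dimensions are not fixed by
the emulated design (acquisitions cover whole biopsy sections), so the
package picks
600×600 µm as the default, 300×300 µm for the `desk` preset (4+4 samples)
used in tests and examples, and 1000×1000 µm for `study-scale`. All
coordinates are in µm, origin top-left, 1 µm pixels, pixel centers at
(i+0.5, j+0.5) µm.

**Placement.** Each population is a homogeneous Poisson process at its
group-specific density (cells/mm², Table below is in
`synthetic.default_templates`). Control totals ≈ 3000/mm², case ≈
4400/mm², with immune/stromal populations enriched in the case group and
epithelium mildly reduced — chosen to sit in the range of nucleated-cell
densities seen in renal IMC and to make density, not frequency, the
discriminating readout. Attraction rules are realized as a Thomas-type
cluster process: the coupled populations share Poisson parents (expected
offspring per parent = `strength`, default 8) and scatter around them with
Gaussian σ = radius/2 (default radius 15 µm). This preserves each
population's marginal density. Repulsion is hard-core sequential placement
with bounded retries (explicit `SimulationError` when the density cannot
be packed at the requested radius). The default rule set couples resident
macrophages, CD8⁺ T cells and fibroblasts — the niche the CN analysis is
expected to rediscover. Rules apply in both groups; the group contrast
comes from densities alone, which is sufficient to reproduce the
case-enrichment of the trio neighborhood.

A caveat worth knowing: a label-permutation interaction test compares the
label arrangement against the fixed point pattern, so if *only* the
coupled types are present their labels are exchangeable and the test has
no power by construction. Attraction is detectable exactly when
unclustered background populations exist — as they do in tissue and in the
default cohort.

**Marker signal.** Templates are arbitrary-unit mean intensities: all
populations share DNA/histone positivity, each has a unique defining
marker (pairwise-distinct argmax) plus supporting lineage markers.
Per-cell expression is the template multiplied by mean-preserving
log-normal noise (CV 0.3 per channel, a typical IMC dispersion).
Rendering paints a nuclear disk (radius 2–4 px by population) plus a 2-px
membrane annulus; non-nuclear channels are uniform over the footprint and
nuclear channels are confined to the nucleus but rescaled by the
footprint/nucleus pixel ratio, so the territory mean equals the cell's
expression vector on every channel — this makes the
render→quantify round trip exact when noise is off, which the tests
exploit. The spillover matrix is forward-applied and Poisson shot noise
added (at 4× sub-integer resolution so low intensities are not
over-quantized).

**Spillover.** No published matrix values are available, so the default is
nearest-mass crosstalk: 3 % into M+1, 1 % into M−1 — the 1–5 % range
typical of lanthanide panels. Magnitude is a free parameter, not a claim.

**Clinical model.** Serum creatinine, CRP, TII and serum CXCL9 are
increasing linear functions of the macrophage+CD8+fibroblast density sum;
urinary CXCL9 depends on resident-macrophage density only; eGFR decreases
with the same burden. Additive Gaussian noise SDs are set so the default
cohort yields positive, significant Spearman correlations — the *sign* is
the contract, not the magnitude. Intercepts/coefficients put control
samples near clinically normal values (Cr ≈ 72 µmol/L, eGFR ≈ 97) and
case samples in the injured range (Cr ≈ 130, eGFR ≈ 43). Fibrosis is
drawn per sample from the group normal (control 5.60 ± 1.4 %, case
24.27 ± 5.68 %) truncated to [0, 100].

**What the generator does not emulate:** tubule/glomerular morphology,
optics or ablation artifacts, cell-shape variation, spatially varying
density fields, or batch effects beyond per-sample shifts. Passing tests
show the *statistics* behave correctly on data matching the model's
assumptions; they do not certify segmentation accuracy on real tissue
texture.

## Pipeline choices

- **Spillover convention**: rows = source channel (`observed = true·S`);
  compensation solves the per-pixel linear system and clips negatives.
- **Quantification** uses compensated, median-filtered intensities; the
  0–255 contrast rescale feeds only visualization and mask thresholding,
  so expression statistics are never distorted by it.
- **Segmentation** replaces the deep-learning segmenter with the
  connectivity pipeline: Otsu on the nuclear (DNA) max-projection,
  8-connected components ≥ 9 px, membrane pairing via a 2-px dilation,
  watershed territories on inverted nuclear intensity constrained to the
  membrane footprint, 5-px disk fallback for unpaired nuclei, and the
  15-px centroid-distance artifact filter ("exceeds" read strictly, so
  exactly 15 px is retained; unpaired cells carry distance 0 and pass).
  The stage is pluggable — external label masks can be quantified
  directly. On dense cohorts with overlapping cells recall drops (~0.6 on
  the desk cohort); the ≥ 0.9 recall/precision contract holds for
  non-overlapping fixtures, which is what the validation targets.
- **Phenotyping**: arcsinh cofactor 5 (mass-cytometry convention; the
  study states none), cap at the cohort-wide 99th percentile per marker,
  then min–max. Batch unit = sample; correction is median alignment
  (shift-only, rank-preserving) standing in for Harmony, with a no-op mode
  and an injection point for externally corrected matrices. Clustering is
  a Euclidean 30-NN graph with Jaccard shared-neighbor weights and Leiden
  modularity at resolution 1.0; this deliberately over-partitions, and
  clusters are merged by annotation (best z-scored Pearson correlation to
  a template, threshold 0.3, below which a cluster is "unassigned").
- **Spatial**: CN profiles use pure centroid 10-NN within ROI, ties broken
  by cell id; CN k-means (k-means++, 10 restarts, fixed seed) runs on the
  pooled cohort so classes are comparable across samples; class names are
  the top-3 enriched populations vs the cohort mean. The permutation null
  shuffles labels within ROI at fixed positions; two-sided empirical
  p = (1 + #extreme)/(n_perm + 1) (never 0, floor 1/(n_perm+1)); per-ROI
  results aggregate to cohort level by A-cell-count-weighted means with
  weighted-Stouffer p combination and Benjamini–Hochberg across ordered
  pairs (Bonferroni is reserved for Dunn post hocs, matching the study's
  usage). Patch bins are half-open [lo, hi).
- **Clinical statistics**: dispatch α = 0.05 for Shapiro–Wilk and Levene;
  Mann–Whitney is exact for n ≤ 20 without ties, tie-corrected normal
  approximation otherwise; Dunn's pairwise z-tests use pooled mean ranks
  with tie correction and Bonferroni. TII bins are closed so the scale is
  exhaustive: 0; (0,10%); [10,25%]; (25,50%]; (50,75%]; (75,100%] — exactly
  10 % scores 2, forced by the "<10 %" wording of bin 1. eGFR is consumed
  as given, never computed.

## Determinism and problem sizes

Every stochastic step keys off a single spec/config seed through named
`SeedSequence` streams (per-ROI placement, expression, rendering noise,
clinical). Identical specs give byte-identical ground truth (SHA-256 of
the tables is recorded in the manifest).

Validation runs use deliberately reduced sizes: the desk preset
(4+4 samples, 300×300 µm, ≈ 17 k cells) for population recovery and
end-to-end runs; 200 simulated ROIs of 80 cells for the permutation-test
type-I calibration (empirical false-positive rate 0.03–0.035 at α = 0.05);
20 seeds for attraction power and fibrosis calibration; 5 seeds for
multi-seed recovery checks. These sizes were chosen so the full suite
completes in minutes while keeping each check's sampling error well inside
its asserted bound.

## Known limitations

- The automated annotation assumes templates for every population present;
  unexpected phenotypes land in "unassigned" rather than a novel cluster
  report.
- CN class numbering is seed-dependent (k-means label permutation);
  analyses should address classes via their enrichment names.
- The segmentation stage is a classical stand-in: on real IMC texture a
  learned segmenter (imported via the pluggable mask path) will outperform
  it.
- Interaction aggregation assumes ROIs are exchangeable within a cohort;
  no mixed-effects structure is modelled at the ROI level.
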