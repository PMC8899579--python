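# Methods

`msifusion` implements a multimodal tissue-imaging workflow that fuses
DESI mass spectrometry imaging (MSI) with imaging mass cytometry (IMC) on
the same section: IMC gives single-cell phenotypes and tissue classes at
subcellular resolution over a limited field; MSI gives label-free drug and
metabolite ion images over the whole section on a coarse anisotropic grid
(50 µm × 75 µm pixels, negative mode, m/z 250–1000). The fusion transfers
the IMC-derived tissue classes onto every MSI pixel so that drug signal can
be quantified per tissue compartment, and cell populations can be related
to local drug content.

## Data model

* **MSIDataset** — peak-reduced spectra as an `n_pixels × n_peaks` matrix
  on a rectangular grid. Pixel `(ix, iy)` covers the half-open rectangle
  `[ix·50, (ix+1)·50) × [iy·75, (iy+1)·75)` µm; a point on a pixel's lower
  edge belongs to that pixel. Peak picking/centroiding is assumed done
  upstream; imzML (processed or continuous) is read and written via pyimzML.
* **CellTable** — one row per segmented cell: centroid (µm, IMC frame),
  area, and mean intensity for the 27-marker panel. Marker names are
  normalized case-insensitively through an alias table ("F4/80", "αSMA",
  "EpCam (CD326)" …).
* **AffineTransform2D** — invertible map from IMC µm to MSI µm
  (`y = A x + b`), serialized as JSON.
* **TissueLabelMap** — per-pixel label in {tumor, connective, necrosis,
  background, unassigned} with per-pixel provenance (vote, knn,
  kmeans_background, truth).

## Preprocessing

Background pixels are found by k-means (k = 2) on standardized features
(log TIC plus the five highest-variance peak channels); the cluster with
the lowest mean TIC is background, guarded by a minimum 5-fold TIC contrast
so that genuinely uniform datasets are treated as all tissue rather than
half-discarded. Spectra are TIC-normalized (per-pixel sum = 1); zero-TIC
tissue pixels cannot be normalized and are dropped from the mask with a
warning. Ion images sum all peaks within `|m/z − center| ≤ tol`; the drug
image can be ratioed against the structural-analogue reference ion at
m/z 520.2492 ± 0.005, with pixels below a reference floor (default: 1st
percentile of positive reference intensities) invalidated instead of
producing unstable ratios.

## Gating and cell tissue classes

Marker positivity is an inclusive threshold (`intensity ≥ threshold`,
mirroring manual gating). The six myeloid rules (macrophage, M1, M2,
immature monocyte, dendritic cell, neutrophil) are boolean combinations of
positivity flags with "F4/80+ or CD68+" as a disjunctive core. Gating is
multi-label; one primary label is resolved by fixed precedence (most
specific first): neutrophil > dendritic cell > M2 > M1 > immature
monocyte > macrophage. The subset rules (M1, M2, …) are applied literally
by default — they do not inherit the base macrophage exclusions (CD11c−,
Ly6G−); a flag (`inherit_base_exclusions`) switches to the stricter
reading, skipping any exclusion that would contradict a subset's own
literals.

Cell tissue classes (tumor / connective / necrosis) come from a random
forest (200 trees, seeded) on log1p marker intensities, trained on labeled
cells; any classifier meeting the same held-out accuracy would do, the
forest is simply a robust default for tabular marker data.

## Registration

All registration happens in physical µm. Representative images are the MSI
TIC image and a binned raster of the cells' summed marker intensity
(25 µm pitch). Because the MSI pixels are anisotropic, both images are
resampled to a common isotropic 25 µm grid before optimization. Stage one
is classic intensity-based similarity registration (SimpleITK,
multi-resolution shrink 4/2/1, full sampling so the result is
deterministic; Mattes mutual information with 32 bins, or normalized
cross-correlation — the pipeline default, since the two representative
images share content by construction).

Stage one is accurate to roughly one MSI pixel: the cell raster is a
Poisson sample (a few cells per bin) and the two modalities weight tissue
compartments differently, which displaces the similarity-metric optimum by
tens of µm. Stage two therefore refines against the cell *point pattern*
directly: MSI pixels are clustered on their normalized spectra (k-means,
k = 8 — unsupervised, no tissue labels involved), each cluster's cell
density is estimated under the current transform, and the four similarity
parameters (rotation, log-scale, translation, parametrized about the cell
centroid) are fitted by maximizing the inhomogeneous-Poisson log-likelihood
of the mapped cell positions, with cells pushed off-grid scored at a small
background density (10⁻³ cells/mm²). A deterministic coarse-to-fine pattern
search (64 µm → 0.25 µm equivalent steps) avoids the plateaus of the
piecewise-constant likelihood; density estimation and optimization
alternate three times. On the synthetic benchmark this brings the mean
corner error from ~40–70 µm to ≲ 12 µm — under a quarter of an MSI x-pixel.
A least-squares landmark mode (≥ 3 point pairs) is also provided for fully
deterministic tests.

Cells are then mapped to pixel indices with the half-open floor convention;
out-of-grid cells are retained but flagged and excluded from pixel-level
analyses, so no cell is silently dropped.

## Label transfer

A pixel takes a tissue class only when **strictly more than half** of the
cells falling in it carry that class (an exact 50/50 split stays
unassigned). The vote-labeled pixels, plus a background class drawn from
the k-means background mask (capped at the median per-class vote count to
avoid swamping), train a k-nearest-neighbor classifier (k = 30, Euclidean)
on TIC-normalized, per-peak standardized spectra; the drug, reference and
metabolite channels are excluded from the features by default so that the
tissue classification is not circularly driven by the analyte being
quantified (toggleable). Prediction covers the entire grid, including
regions the IMC never imaged. Ties are broken by the smallest aggregate
neighbor distance, then by fixed class order (tumor, connective, necrosis,
background). Per-class mean intensities of ions of interest are arithmetic
means over each class's pixels.

## Cross-modal analysis

Marker maps are per-pixel means of a marker (or counts of a
phenotype-positive population) over the cells in each pixel; pixels with no
cell are treated as missing rather than zero (a flagged alternative), and
Pearson correlations are computed over jointly valid pixels. Regions of
interest are chosen to maximize the within-ROI interquartile range of drug
intensity — the rectangle containing both high and low drug content.
High/low stratification splits a region at its median drug intensity
(strictly above → high), with a quantile option; the median is
parameter-free and halves the region by construction. Enrichment is
reported as phenotype cell density (cells/mm², using the nominal
3,750 µm² pixel area) in the high vs low mask and their ratio; a zero
low-mask density yields an infinity flag rather than a number.

## Compartment quantification

The drug fraction of compartment c is `Σ drug over pixels of class c /
Σ drug over all tissue-class pixels` — background excluded, necrosis
included in the denominator by default (it is tissue; excludable). The
fraction is invariant to any positive rescaling of the drug image, hence
identical for raw and reference-normalized images up to the ratio's spatial
weighting. "Stroma" is operationalized as the connective-tissue class. The
timecourse summary reports per-timepoint mean/sd of each class fraction and
of mean drug intensity over the whole section and the tumor compartment
only; a least-squares regression of fraction on time provides the drift
test.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
every planted quantity recorded as ground truth:

* **Geometry** — an elliptical tissue boundary (axes 92% of the grid)
  inside a 128 × 128 grid of 50 × 75 µm pixels; tissue partitioned by the
  Voronoi tessellation of 40 uniformly seeded points. Voronoi cells are
  allocated to tumor/connective/necrosis (priors 0.5/0.3/0.2) by a greedy
  largest-deficit rule, so empirical fractions track the priors within a
  few percent while the mosaic stays random and spatially contiguous —
  correlation and enrichment need spatial autocorrelation to be
  non-trivial.
* **Spectra** — 34 peaks: 31 structural channels whose per-class templates
  are a shared log-normal base profile times a class factor whose log-sd
  scales with `template_separation` (default 1.0), plus three named
  channels (drug, reference analogue at m/z 520.2492, metabolite at
  m/z 478). Noise is multiplicative log-normal (σ = 0.35 structural,
  σ = 0.2 drug/metabolite): MSI intensities are nonnegative and
  right-skewed. Background pixels sit at a flat 0.02 level (≈ 0.1% of
  tissue TIC).
* **Cells** — inhomogeneous Poisson placement at 800 / 800 / 150 cells/mm²
  in tumor / connective / necrosis with class-specific phenotype mixes
  (tumor dominated by tumor cells; stroma by fibroblasts, endothelium and
  myeloid populations; necrosis by necrotic debris and neutrophils).
  Marker log-intensities are normal (sd 0.4) around ln 30 for a
  phenotype's signature markers and ln 0.3 otherwise — the default
  positivity threshold 3.0 is the geometric midpoint. Tissue-context
  boosts (GLUT1/pNDRG1 in tumor, cleaved caspase-3/γH2AX in necrosis)
  make cell tissue classes learnable from markers, reflecting that
  microenvironmental markers vary by compartment, not only by lineage.
* **Drug coupling** — a smoothed random subfield splits the stroma into
  "hot" and "cold" halves; M2 density is 5.1-fold (endothelial 1.8-fold)
  higher in hot stroma with the compartment-wide mean preserved. The
  noise-free drug field is `baseline(class) + 0.05 · E[M2 density]`, so the
  drug partitions into macrophage-rich stroma; the coupling uses the
  expected (noise-free) M2 intensity field rather than a kernel-density
  estimate of the realized cells, which keeps the planted fraction and
  folds exact while being identical in expectation. Tumor-pixel values are
  rescaled so that exactly 45% of the noise-free signal lies in tumor
  (configurable); the recorded planted fraction is recomputed from the
  field itself.
* **Frames** — cells are emitted in an IMC frame related to the MSI frame
  by a planted similarity transform (10°, scale 1.05, translation
  (250, −150) µm).
* **Determinism** — all randomness flows from one seed through named
  `numpy` `SeedSequence` spawns (tissue, hot-field, spectra, cells,
  markers); identical configs give bit-identical datasets.

A separate helper plants an exact bivariate-normal marker/ion pixel pair at
a chosen Pearson ρ for correlation-recovery tests; within the full
generator the model-implied correlation between expected M2 density and the
noise-free drug field is recorded instead (it depends on the geometry
realization).

What the generator does **not** emulate: raw profile spectra, isotope
patterns and detector physics; cell segmentation errors and marker
spillover; deformable (non-affine) distortion between modalities;
within-class spectral gradients beyond the planted drug/metabolite
structure. Passing tests therefore demonstrate the correctness and
statistical calibration of the estimators under the stated model, not
robustness to segmentation artifacts or nonlinear tissue deformation.

## Problem sizes and tolerances

The default benchmark is one 128 × 128 section (≈ 16k pixels, ≈ 27k
cells); unit tests use 32–64 px grids, and the timecourse analysis uses
64 × 64 sections (3 models × 3 timepoints × 3 sections). Registration is
accepted at < 25 µm mean corner error over the moving image's corners
(half an MSI x-pixel); fraction recovery at ±0.02 (truth labels) / ±0.05
(predicted labels); enrichment at ±20% relative; correlation inside the
Fisher-z 99% sampling interval at n = 10⁴. Degenerate inputs (constant
images, zero-TIC pixels, single-class training sets, empty m/z windows,
zero-area masks) raise descriptive errors or produce flagged missing
values rather than NaNs propagating silently.

## Known limitations

* The kNN feature space assumes the spectra themselves separate tissue
  classes; heavily batch-affected data would need harmonization first.
* The point-pattern registration refinement estimates a similarity
  transform only; affine shear is available in stage one but not refined.
* Enrichment folds are density ratios; with very few cells in a mask the
  Poisson noise of the numerator dominates, and the infinity flag on empty
  low masks is deliberate.
* Percent-positive summaries and correlations are reported without
  spatial-autocorrelation-corrected inference.
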