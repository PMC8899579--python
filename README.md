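# msifusion

Multimodal fusion of DESI mass spectrometry imaging (MSI) with imaging mass
cytometry (IMC) for compartment-resolved drug quantification in tumor
tissue.

MSI maps a drug and its metabolites label-free over a whole tissue section,
but at 50 × 75 µm pixels it cannot say *which cells* the signal sits in.
IMC resolves single cells with a 27-marker antibody panel, but only over
small fields and with no drug channel. Acquiring both on the same section
and fusing them answers questions neither modality can alone: how much of
the delivered drug reaches the tumor-cell compartment versus the stroma,
and which cell populations co-locate with high local drug content. The
package is aimed at imaging/pharmacology groups running such paired
experiments, and ships a fully synthetic benchmark with known ground truth
so every stage is testable without any instrument data.

## Method

1. **Preprocess** — k-means background removal; TIC normalization; ion
   images `I(x) = Σ_{|m/z − c| ≤ tol} s(x, m/z)`, optionally ratioed to a
   structural-analogue reference ion (m/z 520.2492 ± 0.005).
2. **Gate** — marker positivity by inclusive thresholds; boolean phenotype
   rules, e.g. M2 macrophage = CD45⁺ CD11b⁺ (F4/80⁺ ∨ CD68⁺) CD163⁺ CD206⁺;
   cell tissue classes (tumor / connective / necrosis) by a seeded random
   forest on marker intensities.
3. **Register** — estimate the IMC→MSI similarity transform from
   representative images (mutual information or cross-correlation,
   multi-resolution), then refine it by maximizing the
   inhomogeneous-Poisson likelihood of the cell point pattern under an
   unsupervised spectral-cluster density map — accurate to ≈ 10 µm on the
   benchmark.
4. **Transfer labels** — an MSI pixel takes class c iff strictly more than
   50% of its cells carry c; the partial labeling plus a k-means background
   class trains kNN (k = 30) on normalized spectra, which then labels every
   pixel, including regions IMC never imaged.
5. **Correlate & quantify** — Pearson correlation of marker maps with ion
   images; median split of stromal drug intensity with phenotype
   density-fold enrichment (high vs low drug); compartment drug fractions
   `f_c = Σ_c drug / Σ_tissue drug` and their timecourse.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

```python
from msifusion import *
from msifusion.pipeline import PipelineConfig, run_pipeline, run_synth

run_synth(SyntheticConfig(seed=23), "scratch/bundle")   # paired MSI + IMC + truth
st = run_pipeline(PipelineConfig(bundle_dir="scratch/bundle",
                                 out_dir="scratch/out", seed=23))
s = st.summary
print(s["register"]["mean_corner_error_um"])            # 2.4
print(s["classify"]["knn_accuracy_vs_truth"])           # 1.0
print(s["correlate"]["enrichment"]["M2_macrophage"])    # 4.54
print(s["quantify"]["fractions_predicted_labels"]["tumor"])  # 0.449
```

The four numbers mean: the recovered IMC→MSI transform is within 2.4 µm
(mean corner displacement) of the planted one; every MSI pixel received the
correct tissue class; M2 macrophages are ≈ 4.5-fold denser in high-drug
stroma (planted: 5.1, recovered within the ±20% sampling tolerance); and
44.9% of the drug signal falls in the tumor compartment (planted: 45%).

The same workflow is available from the shell
(`msifusion synth | preprocess | gate | register | classify | correlate |
quantify | run-all`), and the numbered drivers under `analysis/` run each
stage as a narrative step, writing tables to `results/`:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_preprocess_msi.py
...
python analysis/07_drug_compartments.py
```

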