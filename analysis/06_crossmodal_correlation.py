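#!/usr/bin/env python
"""Cross-modal analysis on the benchmark: correlate marker maps with the
drug ion image, pick the most heterogeneous drug ROI, split the stroma at
the median drug intensity, and quantify phenotype enrichment in high- vs
low-drug stroma against the planted folds (5.1x M2, 1.8x endothelial).

Writes results/06_correlations.csv and results/06_enrichment.csv.
"""

import os

import pandas as pd

from msifusion import (DRUG_MZ, apply_thresholds, assign_phenotypes,
                       default_thresholds, extract_ion_image, load_bundle,
                       pearson_map_correlation, phenotype_enrichment,
                       rasterize_marker, select_heterogeneous_roi,
                       stratify_high_low, transform_cells)
from msifusion.imc import DEFAULT_PRECEDENCE, DEFAULT_RULES
from msifusion.pipeline import ENDOTHELIAL_RULE

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
RESULTS = os.path.join(ROOT, "results")
BUNDLE = os.path.join(ROOT, "scratch", "benchmark_bundle")

MARKERS = ("CD68", "CD206", "CD163", "Collagen1", "CD31", "Ecadherin")
PHENOTYPES = ("M2_macrophage", "M1_macrophage", "macrophage",
              "dendritic_cell", "neutrophil", "endothelial")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    b = load_bundle(BUNDLE)
    cells = assign_phenotypes(apply_thresholds(b.cells, default_thresholds()),
                              rules=DEFAULT_RULES + (ENDOTHELIAL_RULE,),
                              precedence=DEFAULT_PRECEDENCE + ("endothelial",))
    cells = transform_cells(cells, b.truth.transform, b.msi)
    drug = extract_ion_image(b.msi, DRUG_MZ, 0.005)
    shape = (b.msi.ny, b.msi.nx)

    corr_rows = []
    for m in MARKERS:
        res = pearson_map_correlation(rasterize_marker(cells, m, shape), drug)
        corr_rows.append({"marker": m, "pearson_r": res.r,
                          "n_pixels": res.n_pixels})
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(os.path.join(RESULTS, "06_correlations.csv"), index=False)

    roi = select_heterogeneous_roi(drug, (32, 32), stride=8)
    stroma = b.truth.label_map.mask("connective")
    hi, lo = stratify_high_low(drug, stroma)
    enr = phenotype_enrichment(cells, hi, lo, drug.pixel_area_mm2,
                               list(PHENOTYPES))
    enr = enr.assign(planted_fold=[b.truth.planted_enrichment_folds.get(p, 1.0)
                                   for p in enr["phenotype"]])
    enr.to_csv(os.path.join(RESULTS, "06_enrichment.csv"), index=False)

    print(corr.to_string(index=False))
    print(f"most heterogeneous 32x32 drug ROI at (ix, iy)=({roi[0]}, {roi[1]})")
    print(enr.to_string(index=False))
    m2 = enr.set_index("phenotype").loc["M2_macrophage", "fold"]
    print(f"M2 macrophages are {m2:.1f}-fold denser in high-drug stroma "
          f"(planted: {b.truth.planted_enrichment_folds['M2_macrophage']})")


if __name__ == "__main__":
    main()
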