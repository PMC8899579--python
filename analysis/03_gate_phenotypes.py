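#!/usr/bin/env python
"""Gate the IMC cells: marker thresholds, the six myeloid phenotype rules,
random-forest cell tissue classification, and percent-positive summaries
over the whole tissue and the tumor-cell compartment only.

Writes results/03_phenotype_counts.csv and results/03_percent_positive.csv.
"""

import os

import numpy as np
import pandas as pd

from msifusion import (apply_thresholds, assign_phenotypes,
                       classify_cell_tissue, default_thresholds, load_bundle,
                       percent_positive)
from msifusion.imc import CellTable

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
RESULTS = os.path.join(ROOT, "results")
BUNDLE = os.path.join(ROOT, "scratch", "benchmark_bundle")

SUMMARY_MARKERS = ("CD68", "CD206", "CD31", "Ly6G", "aSMA", "Collagen1", "Ki67")


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    bundle = load_bundle(BUNDLE)
    cells = assign_phenotypes(apply_thresholds(bundle.cells, default_thresholds()))

    # supervised tissue classes from a 20% truth-labeled training subsample
    truth = bundle.truth.cell_truth
    merged = cells.data.merge(truth[["cell_id", "tissue_class"]], on="cell_id")
    rng = np.random.default_rng(23)
    train_sel = rng.random(len(merged)) < 0.2
    train = CellTable(merged.assign(tissue_class=merged["tissue_class"].where(train_sel)),
                      cells.markers)
    cells = classify_cell_tissue(train, cells, seed=23)
    holdout = float((cells.data["tissue_class"].to_numpy(str)[~train_sel]
                     == merged["tissue_class"].to_numpy(str)[~train_sel]).mean())

    counts = cells.data["phenotype"].value_counts().rename_axis("phenotype")
    counts.to_frame("n_cells").to_csv(os.path.join(RESULTS, "03_phenotype_counts.csv"))

    tumor_mask = cells.data["tissue_class"].to_numpy(str) == "tumor"
    rows = []
    for m in SUMMARY_MARKERS:
        rows.append({"marker": m,
                     "pct_positive_whole_tissue": percent_positive(cells, m),
                     "pct_positive_tumor_compartment":
                         percent_positive(cells, m, region_mask=tumor_mask)})
    pp = pd.DataFrame(rows)
    pp.to_csv(os.path.join(RESULTS, "03_percent_positive.csv"), index=False)

    print(f"gated {len(cells)} cells; RF held-out tissue accuracy {holdout:.3f}")
    print(counts.to_string())
    print(pp.to_string(index=False))


if __name__ == "__main__":
    main()
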