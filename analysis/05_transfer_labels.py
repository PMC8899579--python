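#!/usr/bin/env python
"""Transfer tissue labels from IMC cells to all MSI pixels: strict majority
vote on co-registered, classified cells, then kNN (k = 30) over the
normalized spectra with a k-means background class; summarize per-class
mean intensities of the ions of interest.

Writes results/05_label_transfer.csv, results/05_class_summary.csv and the
predicted label map as indexed TIFF + legend.
"""

import os

import pandas as pd

from msifusion import (DRUG_MZ, METABOLITE_MZ, REFERENCE_MZ, load_bundle,
                       majority_vote_labels, fit_predict_knn,
                       class_mean_intensities, estimate_transform,
                       refine_transform_poisson, representative_image_imc,
                       representative_image_msi, transform_cells,
                       apply_thresholds, assign_phenotypes, default_thresholds)
from msifusion.export import save_label_map_tiff, provenance_counts
from msifusion.fusion import BACKGROUND
from msifusion.msi import detect_background

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
RESULTS = os.path.join(ROOT, "results")
BUNDLE = os.path.join(ROOT, "scratch", "benchmark_bundle")

IONS = [("drug", DRUG_MZ, 0.005), ("reference", REFERENCE_MZ, 0.005),
        ("metabolite", METABOLITE_MZ, 0.005)]
ANALYTE_WINDOWS = [(mz, 0.01) for _, mz, _ in IONS]


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    b = load_bundle(BUNDLE)
    b.msi.tissue_mask = detect_background(b.msi, seed=0)

    cells = assign_phenotypes(apply_thresholds(b.cells, default_thresholds()))
    cells.data = cells.data.merge(
        b.truth.cell_truth[["cell_id", "tissue_class"]], on="cell_id")

    fixed = representative_image_msi(b.msi)
    moving = representative_image_imc(b.cells)
    t0, _ = estimate_transform(fixed, moving, metric="correlation", seed=0)
    t1, _ = refine_transform_poisson(b.msi, b.cells, t0, seed=0)
    cells = transform_cells(cells, t1, b.msi)

    vote = majority_vote_labels(cells, (b.msi.ny, b.msi.nx))
    full = fit_predict_knn(b.msi, vote, background_mask=~b.msi.mask_image(),
                           k=30, exclude_mz=ANALYTE_WINDOWS, seed=0)

    truth_labels = b.truth.label_map.labels
    voted = vote.labels > BACKGROUND
    rows = [
        {"quantity": "n_vote_labeled_pixels", "value": int(voted.sum())},
        {"quantity": "vote_accuracy_vs_truth",
         "value": float((vote.labels[voted] == truth_labels[voted]).mean())},
        {"quantity": "knn_pixel_accuracy_vs_truth",
         "value": float((full.labels == truth_labels).mean())},
    ]
    lt = pd.DataFrame(rows)
    lt.to_csv(os.path.join(RESULTS, "05_label_transfer.csv"), index=False)

    summary = class_mean_intensities(b.msi, full, IONS)
    summary.to_csv(os.path.join(RESULTS, "05_class_summary.csv"))
    save_label_map_tiff(full, os.path.join(RESULTS, "05_label_map.tiff"),
                        os.path.join(RESULTS, "05_label_map_legend.csv"))
    provenance_counts(full).to_csv(
        os.path.join(RESULTS, "05_label_provenance.csv"), index=False)

    print(lt.to_string(index=False))
    print(summary.table.to_string())


if __name__ == "__main__":
    main()
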