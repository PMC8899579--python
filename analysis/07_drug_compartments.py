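#!/usr/bin/env python
"""Compartment-resolved drug quantification over a simulated timecourse.

Three synthetic tumor models with different stromal drug partitioning
(tumor-compartment shares of ~10%, ~20% and ~45% of total drug signal) are
simulated at 2, 4 and 24 h (3 sections each, drug fractions constant in
time), quantified with kNN-predicted label maps, and summarized per
timepoint; a regression of tumor fraction on time tests for drift.

Writes results/07_timecourse.csv and results/07_trend.csv.
"""

import os
import zlib

import pandas as pd

from msifusion import (DRUG_MZ, SyntheticConfig, drug_fraction_by_class,
                       extract_ion_image, fit_predict_knn, generate_dataset,
                       majority_vote_labels, timecourse_summary,
                       transform_cells, fraction_time_trend)
from msifusion.synthetic import METABOLITE_MZ, REFERENCE_MZ

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
RESULTS = os.path.join(ROOT, "results")

MODELS = {"high_stroma_A": 0.10, "high_stroma_B": 0.20, "low_stroma": 0.45}
TIMEPOINTS = (2.0, 4.0, 24.0)
N_SECTIONS = 3
ANALYTE_WINDOWS = [(DRUG_MZ, 0.01), (REFERENCE_MZ, 0.01), (METABOLITE_MZ, 0.01)]


def quantify_section(model: str, target: float, t_h: float, rep: int):
    seed = zlib.crc32(f"{model}|{t_h}|{rep}".encode()) % 100_000
    cfg = SyntheticConfig(grid_nx=64, grid_ny=64, seed=seed,
                          target_tumor_drug_fraction=target)
    b = generate_dataset(cfg)
    cells = b.cells.copy()
    cells.data = cells.data.merge(
        b.truth.cell_truth[["cell_id", "tissue_class"]], on="cell_id")
    cells = transform_cells(cells, b.truth.transform, b.msi)
    vote = majority_vote_labels(cells, (b.msi.ny, b.msi.nx))
    labels = fit_predict_knn(b.msi, vote, background_mask=~b.msi.mask_image(),
                             k=30, exclude_mz=ANALYTE_WINDOWS, seed=seed)
    drug = extract_ion_image(b.msi, DRUG_MZ, 0.005)
    return drug_fraction_by_class(drug, labels,
                                  section_id=f"{model}_t{t_h:g}_r{rep}",
                                  timepoint_h=t_h)


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    all_rows = []
    trend_rows = []
    for model, target in MODELS.items():
        sections = [quantify_section(model, target, t, r)
                    for t in TIMEPOINTS for r in range(N_SECTIONS)]
        tc = timecourse_summary(sections).assign(model=model,
                                                 planted_tumor_fraction=target)
        all_rows.append(tc)
        slope, p = fraction_time_trend(sections, "tumor")
        trend_rows.append({"model": model, "planted_tumor_fraction": target,
                           "slope_per_h": slope, "p_value": p})
        mean_tumor = tc.loc[tc["tissue_class"] == "tumor", "mean_fraction"].mean()
        print(f"{model}: mean tumor drug fraction {mean_tumor:.3f} "
              f"(planted {target}); time trend p = {p:.2f}")
    pd.concat(all_rows).to_csv(os.path.join(RESULTS, "07_timecourse.csv"),
                               index=False)
    trend = pd.DataFrame(trend_rows)
    trend.to_csv(os.path.join(RESULTS, "07_trend.csv"), index=False)
    print(trend.to_string(index=False))
    print("no model shows a significant change of the tumor-compartment "
          "share over time" if (trend["p_value"] > 0.05).all() else
          "at least one model shows a time trend — inspect 07_trend.csv")


if __name__ == "__main__":
    main()
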