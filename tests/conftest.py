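"""Shared fixtures: the synthetic benchmark dataset and derived artifacts.

Everything is generated programmatically at test time from seeded configs;
session scope keeps the expensive chains (gating, label transfer) shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from msifusion import (SyntheticConfig, generate_dataset, default_thresholds,
                       apply_thresholds, assign_phenotypes, transform_cells,
                       majority_vote_labels, fit_predict_knn,
                       DRUG_MZ, REFERENCE_MZ, METABOLITE_MZ)

ANALYTE_WINDOWS = [(DRUG_MZ, 0.01), (REFERENCE_MZ, 0.01), (METABOLITE_MZ, 0.01)]


@pytest.fixture(scope="session")
def bench_bundle():
    """The default synthetic benchmark: 128×128 grid, 3 tissue classes +
    background, planted transform / fractions / enrichments, seed 23."""
    return generate_dataset(SyntheticConfig(seed=23))


@pytest.fixture(scope="session")
def bench_cells(bench_bundle):
    """Benchmark cells gated (default thresholds + rules) and mapped to MSI
    pixels with the truth transform, with truth tissue classes attached."""
    b = bench_bundle
    cells = apply_thresholds(b.cells, default_thresholds())
    cells = assign_phenotypes(cells)
    cells.data = cells.data.merge(
        b.truth.cell_truth[["cell_id", "tissue_class"]], on="cell_id")
    return transform_cells(cells, b.truth.transform, b.msi)


@pytest.fixture(scope="session")
def bench_label_map(bench_bundle, bench_cells):
    """Full kNN tissue label map of the benchmark (vote seeds, k = 30)."""
    b = bench_bundle
    vote = majority_vote_labels(bench_cells, (b.msi.ny, b.msi.nx))
    return fit_predict_knn(b.msi, vote, background_mask=~b.msi.mask_image(),
                           k=30, exclude_mz=ANALYTE_WINDOWS, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
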