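"""Cross-modal analysis: marker rasterization, Pearson correlation, ROI
selection, high/low drug stratification and phenotype enrichment."""

import numpy as np
import pandas as pd
import pytest

from msifusion.crossmodal import (CrossmodalError, fisher_z_interval,
                                  pearson_map_correlation, phenotype_enrichment,
                                  rasterize_marker, select_heterogeneous_roi,
                                  stratify_high_low)
from msifusion.imc import CellTable
from msifusion.msi import IonImage
from msifusion.synthetic import (DRUG_MZ, generate_correlated_maps)
from msifusion.msi import extract_ion_image


def cells_at(entries, extra_cols=None):
    """entries: (ix, iy, marker_value)."""
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(entries))],
        "x_um": 0.0, "y_um": 0.0,
        "CD68": [e[2] for e in entries],
        "pixel_ix": [e[0] for e in entries],
        "pixel_iy": [e[1] for e in entries],
        "in_bounds": True,
    })
    if extra_cols:
        df = df.assign(**extra_cols)
    return CellTable(df, markers=["CD68"])


def ion(values, valid=None):
    values = np.asarray(values, float)
    return IonImage(values, np.ones_like(values, bool) if valid is None else valid,
                    mz_center=DRUG_MZ, mz_tol=0.005)


class TestRasterize:
    def test_mean_aggregation(self):
        m = rasterize_marker(cells_at([(0, 0, 7.0)]), "CD68", (2, 2))
        assert m[0, 0] == 7.0 and np.isnan(m[1, 1])
        m = rasterize_marker(cells_at([(1, 0, 3.0), (1, 0, 5.0)]), "CD68", (1, 2))
        assert m[0, 1] == 4.0

    def test_phenotype_count_mode(self):
        ct = cells_at([(0, 0, 1.0), (0, 0, 1.0)],
                      extra_cols={"pheno_M2_macrophage": True})
        m = rasterize_marker(ct, "phenotype:M2_macrophage", (1, 1))
        assert m[0, 0] == 2.0

    def test_unknown_channel(self):
        with pytest.raises(Exception, match="unknown"):
            rasterize_marker(cells_at([(0, 0, 1.0)]), "NotAMarker", (1, 1))


class TestPearson:
    def test_perfect_and_inverted(self):
        a = np.arange(12, dtype=float).reshape(3, 4)
        assert pearson_map_correlation(a, ion(a)).r == pytest.approx(1.0)
        assert pearson_map_correlation(-a + 100.0, ion(a)).r == pytest.approx(-1.0)

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 5, (10, 10))
        b = rng.uniform(0, 5, (10, 10))
        r0 = pearson_map_correlation(a, ion(b)).r
        r1 = pearson_map_correlation(3.5 * a + 2.0, ion(1.7 * b + 0.4)).r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_missing(self):
        res = pearson_map_correlation(np.ones((3, 3)), ion(np.arange(9.).reshape(3, 3)))
        assert np.isnan(res.r) and "variance" in res.reason

    def test_planted_rho_seed5(self):
        """ρ = 0.7 planted on 10⁴ pixels recovered inside [0.65, 0.75]."""
        a, b = generate_correlated_maps((100, 100), 0.7, seed=5)
        res = pearson_map_correlation(a, ion(b))
        assert 0.65 <= res.r <= 0.75 and res.n_pixels == 10_000

    def test_fisher_interval_shape(self):
        lo, hi = fisher_z_interval(0.7, 10_000, 0.99)
        assert lo < 0.7 < hi and hi - lo < 0.06


class TestRoi:
    def test_uniform_ties_first_in_scan_order(self):
        roi = select_heterogeneous_roi(ion(np.ones((6, 6))), (3, 3))
        assert roi == (0, 0, 3, 3)

    def test_full_grid(self):
        assert select_heterogeneous_roi(ion(np.ones((4, 5))), (5, 4)) == (0, 0, 5, 4)

    def test_straddles_blob_edge(self):
        img = np.zeros((12, 12))
        img[:, 8:] = 10.0  # high-drug block on the right
        ix0, iy0, w, h = select_heterogeneous_roi(ion(img), (4, 4))
        block = img[iy0:iy0 + h, ix0:ix0 + w]
        assert (block == 0).any() and (block == 10.0).any()

    def test_too_large_rejected(self):
        with pytest.raises(CrossmodalError, match="exceeds"):
            select_heterogeneous_roi(ion(np.ones((3, 3))), (4, 4))


class TestStratify:
    def test_median_split(self):
        img = ion(np.array([[1.0, 2.0, 3.0, 4.0]]))
        hi, lo = stratify_high_low(img, np.ones((1, 4), bool))
        assert hi.tolist() == [[False, False, True, True]]
        assert lo.tolist() == [[True, True, False, False]]

    def test_quantile_split(self):
        img = ion(np.array([[1.0, 2.0, 3.0, 4.0]]))
        hi, lo = stratify_high_low(img, np.ones((1, 4), bool),
                                   method="quantile", quantile=0.75)
        assert hi.sum() == 1 and hi[0, 3]

    def test_masks_partition_region(self):
        rng = np.random.default_rng(11)
        img = ion(rng.uniform(0, 9, (8, 8)))
        region = rng.random((8, 8)) < 0.6
        hi, lo = stratify_high_low(img, region)
        assert not (hi & lo).any()
        np.testing.assert_array_equal(hi | lo, region)

    def test_constant_region_rejected(self):
        with pytest.raises(CrossmodalError, match="no contrast"):
            stratify_high_low(ion(np.ones((2, 2))), np.ones((2, 2), bool))

    def test_recovers_planted_hot_zones(self, bench_bundle):
        """Median split of the stromal drug image recovers the planted
        high/low zones with ≥95% agreement."""
        b = bench_bundle
        drug = extract_ion_image(b.msi, DRUG_MZ, 0.005)
        stroma = b.truth.label_map.mask("connective")
        hi, lo = stratify_high_low(drug, stroma)
        hot = b.truth.hot_mask
        agree = ((hi & hot) | (lo & ~hot))[stroma].mean()
        assert agree >= 0.95


class TestEnrichment:
    def area(self):
        return 3750.0 / 1e6  # 50 × 75 µm pixel in mm²

    def masks(self, n=8):
        hi = np.zeros((1, 2 * n), bool)
        lo = np.zeros_like(hi)
        hi[0, :n] = True
        lo[0, n:] = True
        return hi, lo

    def make_cells(self, n_hi, n_lo):
        entries = [(i % 8, 0, 1.0) for i in range(n_hi)]
        entries += [(8 + i % 8, 0, 1.0) for i in range(n_lo)]
        return cells_at(entries, extra_cols={"pheno_M2_macrophage": True})

    def test_fold_arithmetic(self):
        hi, lo = self.masks()
        out = phenotype_enrichment(self.make_cells(10, 2), hi, lo, self.area(),
                                   ["M2_macrophage"])
        assert out["fold"].iloc[0] == pytest.approx(5.0)

    def test_equal_densities_fold_one(self):
        hi, lo = self.masks()
        out = phenotype_enrichment(self.make_cells(4, 4), hi, lo, self.area(),
                                   ["M2_macrophage"])
        assert out["fold"].iloc[0] == pytest.approx(1.0)

    def test_zero_low_density_flagged_infinite(self):
        hi, lo = self.masks()
        out = phenotype_enrichment(self.make_cells(3, 0), hi, lo, self.area(),
                                   ["M2_macrophage"])
        assert np.isinf(out["fold"].iloc[0])

    def test_overlapping_masks_rejected(self):
        hi, lo = self.masks()
        with pytest.raises(CrossmodalError, match="overlap"):
            phenotype_enrichment(self.make_cells(1, 1), hi, hi, self.area(),
                                 ["M2_macrophage"])

    def test_fold_stable_under_subsampling(self, bench_bundle, bench_cells):
        """Uniform 50% cell subsampling leaves the expected fold unchanged:
        the mean fold over 20 subsample seeds stays within ±10% of the
        full-table fold."""
        b = bench_bundle
        drug = extract_ion_image(b.msi, DRUG_MZ, 0.005)
        stroma = b.truth.label_map.mask("connective")
        hi, lo = stratify_high_low(drug, stroma)
        area = drug.pixel_area_mm2
        full = phenotype_enrichment(bench_cells, hi, lo, area,
                                    ["M2_macrophage"])["fold"].iloc[0]
        folds = []
        for s in range(20):
            rng = np.random.default_rng(s)
            sub = CellTable(
                bench_cells.data[rng.random(len(bench_cells)) < 0.5],
                bench_cells.markers)
            folds.append(phenotype_enrichment(sub, hi, lo, area,
                                              ["M2_macrophage"])["fold"].iloc[0])
        assert abs(np.mean(folds) - full) / full < 0.10
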