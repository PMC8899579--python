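"""The synthetic-data generator: tissue mosaics, MSI spectra, cell point
patterns, planted ground truth, determinism and bundle I/O."""

import numpy as np
import pytest

from msifusion.fusion import LABEL_CODES
from msifusion.imc import apply_thresholds, assign_phenotypes
from msifusion.synthetic import (DRUG_MZ, METABOLITE_MZ, REFERENCE_MZ,
                                 SyntheticConfig, SyntheticConfigError,
                                 default_thresholds,
                                 generate_cells, generate_correlated_maps,
                                 generate_dataset, generate_tissue_map,
                                 load_bundle, write_bundle)

SMALL = dict(grid_nx=32, grid_ny=32)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"grid_nx": 4},
        {"class_priors": (0.5, 0.3, 0.3)},
        {"class_priors": (1.2, -0.1, -0.1)},
        {"cell_density_per_class": {"tumor": -1.0}},
        {"marker_log_sd": -0.1},
        {"phenotype_mix_per_class": {"tumor": {"tumor_cell": 0.5}}},
        {"phenotype_mix_per_class": {"tumor": {"not_a_phenotype": 1.0}}},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(**kw)

    def test_correlated_maps_rho_domain(self):
        with pytest.raises(SyntheticConfigError):
            generate_correlated_maps((4, 4), 1.0, seed=0)


class TestTissueMap:
    def test_degenerate_prior_all_tumor(self):
        tm = generate_tissue_map(SyntheticConfig(class_priors=(1.0, 0.0, 0.0),
                                                 seed=0, **SMALL))
        tissue = tm.labels > LABEL_CODES["background"]
        assert tissue.any()
        assert (tm.labels[tissue] == LABEL_CODES["tumor"]).all()

    def test_fractions_track_priors(self):
        priors = (0.5, 0.3, 0.2)
        tm = generate_tissue_map(SyntheticConfig(class_priors=priors, seed=7))
        tissue = (tm.labels > LABEL_CODES["background"]).sum()
        for cls, p in zip(("tumor", "connective", "necrosis"), priors):
            frac = tm.mask(cls).sum() / tissue
            assert abs(frac - p) <= 0.10

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(seed=5, **SMALL)
        a = generate_tissue_map(cfg)
        b = generate_tissue_map(SyntheticConfig(seed=5, **SMALL))
        np.testing.assert_array_equal(a.labels, b.labels)


class TestMSIGeneration:
    def test_zero_noise_matches_template_exactly(self):
        cfg = SyntheticConfig(peak_noise_sigma=0.0, drug_noise_sigma=0.0,
                              seed=2, **SMALL)
        b = generate_dataset(cfg)
        templates = cfg.templates()
        tumor_px = b.truth.label_map.labels.ravel() == LABEL_CODES["tumor"]
        named = [np.argmin(np.abs(cfg.mz_axis - mz))
                 for mz in (DRUG_MZ, REFERENCE_MZ, METABOLITE_MZ)]
        structural = [j for j in range(cfg.mz_axis.size) if j not in named]
        got = b.msi.intensities[tumor_px][:, structural]
        np.testing.assert_allclose(got, np.broadcast_to(
            templates["tumor"][structural], got.shape))

    def test_drug_baseline_ordering(self):
        cfg = SyntheticConfig(
            drug_baseline={"tumor": 1.0, "connective": 50.0, "necrosis": 0.5},
            target_tumor_drug_fraction=None, seed=4, **SMALL)
        b = generate_dataset(cfg)
        drug_col = int(np.argmin(np.abs(cfg.mz_axis - DRUG_MZ)))
        lab = b.truth.label_map.labels.ravel()
        conn = b.msi.intensities[lab == LABEL_CODES["connective"], drug_col].mean()
        tum = b.msi.intensities[lab == LABEL_CODES["tumor"], drug_col].mean()
        assert conn > tum

    def test_background_tic_below_one_percent(self, bench_bundle):
        b = bench_bundle
        tic = b.msi.tic()
        tissue = b.truth.label_map.labels.ravel() > 0
        assert tic[~tissue].mean() < 0.01 * np.median(tic[tissue])

    def test_missing_template_rejected(self):
        cfg = SyntheticConfig(seed=1, **SMALL)
        cfg.peak_templates = {"tumor": np.ones(cfg.mz_axis.size)}
        from msifusion.synthetic import generate_msi
        with pytest.raises(SyntheticConfigError, match="template"):
            generate_msi(generate_tissue_map(cfg), cfg)


class TestCells:
    def test_zero_density_class_has_no_cells(self):
        cfg = SyntheticConfig(cell_density_per_class={"tumor": 300.0,
                                                      "connective": 300.0,
                                                      "necrosis": 0.0},
                              seed=6, **SMALL)
        tm = generate_tissue_map(cfg)
        _, truth = generate_cells(tm, cfg)
        assert not (truth["tissue_class"] == "necrosis").any()

    def test_degenerate_mix_gates_pure_m2(self):
        """Noise-free markers + an all-M2 stromal mix: every connective
        cell passes the M2 gate."""
        cfg = SyntheticConfig(
            phenotype_mix_per_class={
                "tumor": {"tumor_cell": 1.0},
                "connective": {"M2_macrophage": 1.0},
                "necrosis": {"necrotic": 1.0}},
            marker_log_sd=0.0, m2_enrichment_fold=1.0, seed=8, **SMALL)
        tm = generate_tissue_map(cfg)
        cells, truth = generate_cells(tm, cfg)
        gated = assign_phenotypes(apply_thresholds(cells, default_thresholds()))
        conn = truth["tissue_class"] == "connective"
        assert conn.any()
        assert (gated.data.loc[conn.to_numpy(), "phenotype"] == "M2_macrophage").all()

    def test_poisson_count_expectation(self):
        """100 cells/mm² uniformly over the full 128×128 grid of 50×75 µm
        pixels: E[N] = 100 × 6.4 × 9.6 = 6,144; observed within 3 sd."""
        cfg = SyntheticConfig(
            class_priors=(1.0, 0.0, 0.0),
            tissue_ellipse_frac=(10.0, 10.0),  # ellipse covers the whole grid
            cell_density_per_class={"tumor": 100.0, "connective": 0.0,
                                    "necrosis": 0.0},
            phenotype_mix_per_class={"tumor": {"tumor_cell": 1.0}},
            seed=9)
        tm = generate_tissue_map(cfg)
        assert (tm.labels == LABEL_CODES["tumor"]).all()
        cells, _ = generate_cells(tm, cfg)
        expected = 100.0 * (128 * 0.050) * (128 * 0.075)
        assert expected == 6144.0
        assert abs(len(cells) - expected) <= 3 * np.sqrt(expected)

    def test_cells_land_in_tissue_under_truth_transform(self, bench_bundle):
        b = bench_bundle
        pts = b.truth.transform.apply(b.cells.data[["x_um", "y_um"]].to_numpy())
        ix = np.floor(pts[:, 0] / 50.0).astype(int)
        iy = np.floor(pts[:, 1] / 75.0).astype(int)
        assert (b.truth.label_map.labels[iy, ix] > 0).all()


class TestPlantedTruth:
    def test_planted_fraction_matches_noise_free_field(self, bench_bundle):
        b = bench_bundle
        D0 = b.truth.drug_noise_free
        tissue = b.truth.label_map.labels > 0
        tumor = b.truth.label_map.mask("tumor")
        assert b.truth.planted_tumor_drug_fraction == pytest.approx(
            D0[tumor].sum() / D0[tissue].sum(), abs=1e-12)
        assert b.truth.planted_tumor_drug_fraction == pytest.approx(0.45, abs=1e-9)

    def test_planted_folds_recorded(self, bench_bundle):
        folds = bench_bundle.truth.planted_enrichment_folds
        assert folds["M2_macrophage"] == 5.1
        assert folds["endothelial"] == 1.8

    def test_m2_density_mean_preserving(self, bench_bundle):
        """Hot-field modulation changes where M2 cells sit, not how many:
        the stroma-wide expected density equals density × mix share."""
        b = bench_bundle
        conn = b.truth.label_map.mask("connective")
        expected = (b.config.cell_density_per_class["connective"]
                    * b.config.phenotype_mix_per_class["connective"]["M2_macrophage"])
        assert b.truth.expected_m2_density[conn].mean() == pytest.approx(expected, rel=1e-9)


class TestDeterminismAndIO:
    def test_bit_identical_regeneration(self):
        cfg_kw = dict(seed=42, **SMALL)
        a = generate_dataset(SyntheticConfig(**cfg_kw))
        b = generate_dataset(SyntheticConfig(**cfg_kw))
        np.testing.assert_array_equal(a.msi.intensities, b.msi.intensities)
        np.testing.assert_array_equal(a.truth.label_map.labels, b.truth.label_map.labels)
        assert a.cells.data.equals(b.cells.data)
        assert a.config.config_hash() == b.config.config_hash()

    def test_different_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(seed=1, **SMALL))
        b = generate_dataset(SyntheticConfig(seed=2, **SMALL))
        assert not np.array_equal(a.msi.intensities, b.msi.intensities)

    def test_bundle_round_trip(self, tmp_path):
        bundle = generate_dataset(SyntheticConfig(seed=3, **SMALL))
        out = str(tmp_path / "bundle")
        write_bundle(bundle, out)
        back = load_bundle(out)
        np.testing.assert_array_equal(back.msi.mz_axis, bundle.msi.mz_axis)
        np.testing.assert_allclose(back.msi.intensities, bundle.msi.intensities,
                                   rtol=1e-6)
        np.testing.assert_array_equal(back.truth.label_map.labels,
                                      bundle.truth.label_map.labels)
        assert back.truth.planted_tumor_drug_fraction == pytest.approx(
            bundle.truth.planted_tumor_drug_fraction)
        assert len(back.cells) == len(bundle.cells)
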