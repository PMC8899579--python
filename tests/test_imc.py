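"""Cell-table gating: thresholds, the six myeloid phenotype rules,
supervised tissue classification and percent-positive summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msifusion.imc import (CellTable, IMCError, MARKER_PANEL, PhenotypeRule,
                           apply_thresholds, assign_phenotypes,
                           canonical_marker, classify_cell_tissue,
                           percent_positive, DEFAULT_RULES)
from msifusion.synthetic import SyntheticConfig, generate_cells, generate_tissue_map


def cells_from_positive(rows: list[dict[str, float]]) -> CellTable:
    """Build a gated cell table from per-row marker intensity dicts
    (markers absent from a dict sit at 0)."""
    df = pd.DataFrame([{m: row.get(m, 0.0) for m in MARKER_PANEL} for row in rows])
    df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    df.insert(1, "x_um", 0.0)
    df.insert(2, "y_um", 0.0)
    df.insert(3, "area_um2", 100.0)
    return apply_thresholds(CellTable(df), {m: 1.0 for m in MARKER_PANEL})


HI = 10.0  # comfortably above every threshold


class TestThresholds:
    def test_boundary_inclusive(self):
        df = pd.DataFrame({"cell_id": ["a", "b"], "x_um": 0.0, "y_um": 0.0,
                           "CD45": [5.0, 4.99]})
        out = apply_thresholds(CellTable(df), {"CD45": 5.0})
        assert out.data["positive_CD45"].tolist() == [True, False]

    def test_zero_threshold_all_positive(self):
        ct = cells_from_positive([{"CD45": 0.0}, {"CD45": 7.0}])
        out = apply_thresholds(ct, {"CD45": 0.0})
        assert out.data["positive_CD45"].all()

    def test_unknown_marker_named(self):
        ct = cells_from_positive([{}])
        with pytest.raises(IMCError, match="NotAMarker"):
            apply_thresholds(ct, {"NotAMarker": 1.0})

    def test_missing_threshold_detected_at_gating(self):
        df = pd.DataFrame({"cell_id": ["a"], "x_um": 0.0, "y_um": 0.0,
                           "CD45": [5.0]})
        partial = apply_thresholds(CellTable(df), {"CD45": 1.0})
        with pytest.raises(IMCError, match="CD11b"):
            DEFAULT_RULES[0].evaluate(partial)


class TestPhenotypeRules:
    @pytest.mark.parametrize("markers,expected", [
        # macrophage: CD45+ CD11b+ (F4/80 or CD68)+ CD11c- Ly6G-
        ({"CD45": HI, "CD11b": HI, "F4/80": HI}, "macrophage"),
        # neutrophil: CD45+ CD11b+ F4/80- CD68- Ly6G+
        ({"CD45": HI, "CD11b": HI, "Ly6G": HI}, "neutrophil"),
        # M2: CD45+ CD11b+ (F4/80 or CD68)+ CD163+ CD206+
        ({"CD45": HI, "CD11b": HI, "CD68": HI, "CD163": HI, "CD206": HI},
         "M2_macrophage"),
        # dendritic: CD45+ CD11b+ (F4/80 or CD68)+ CD11c+
        ({"CD45": HI, "CD11b": HI, "CD68": HI, "CD11c": HI}, "dendritic_cell"),
        # immature monocyte: CD45+ CD11b+ (F4/80 or CD68)+ Ly6G+ CD11c-
        ({"CD45": HI, "CD11b": HI, "F4/80": HI, "Ly6G": HI}, "immature_monocyte"),
        ({}, "none"),
        ({"CD45": HI}, "none"),
    ])
    def test_primary_labels(self, markers, expected):
        out = assign_phenotypes(cells_from_positive([markers]))
        assert out.data["phenotype"].iloc[0] == expected

    def test_multilabel_m2_is_also_macrophage(self):
        out = assign_phenotypes(cells_from_positive(
            [{"CD45": HI, "CD11b": HI, "F4/80": HI, "CD163": HI, "CD206": HI}]))
        row = out.data.iloc[0]
        assert row["pheno_M2_macrophage"] and row["pheno_macrophage"]
        assert row["phenotype"] == "M2_macrophage"  # precedence: subset first

    def test_disjunctive_core_required(self):
        # CD163+ CD206+ without F4/80 or CD68 must not gate M2
        out = assign_phenotypes(cells_from_positive(
            [{"CD45": HI, "CD11b": HI, "CD163": HI, "CD206": HI}]))
        assert not out.data["pheno_M2_macrophage"].iloc[0]

    def test_inherit_base_exclusions_flag(self):
        # an M1-pattern cell that is also CD11c+: gated M1 under the literal
        # reading, rejected when subset rules inherit the CD11c- exclusion
        cell = {"CD45": HI, "CD11b": HI, "F4/80": HI, "MHCII": HI, "CD11c": HI}
        literal = assign_phenotypes(cells_from_positive([cell]))
        strict = assign_phenotypes(cells_from_positive([cell]),
                                   inherit_base_exclusions=True)
        assert literal.data["pheno_M1_macrophage"].iloc[0]
        assert not strict.data["pheno_M1_macrophage"].iloc[0]

    def test_rule_sign_conflict_rejected(self):
        with pytest.raises(IMCError, match="both"):
            PhenotypeRule("bad", (("CD45", True), ("CD45", False)))

    def test_assignment_is_pure_function_of_flags(self):
        rng = np.random.default_rng(7)
        rows = [{m: float(rng.choice([0.0, HI])) for m in MARKER_PANEL}
                for _ in range(100)]
        a = assign_phenotypes(cells_from_positive(rows)).data["phenotype"]
        b = assign_phenotypes(cells_from_positive(rows)).data["phenotype"]
        assert (a == b).all()


class TestMarkerAliases:
    @pytest.mark.parametrize("alias,canonical", [
        ("f4/80", "F4/80"), ("F480", "F4/80"), ("αSMA", "aSMA"),
        ("collagen 1", "Collagen1"), ("EpCam (CD326)", "EpCAM"),
        ("e-cadherin", "Ecadherin"),
    ])
    def test_alias(self, alias, canonical):
        assert canonical_marker(alias) == canonical


class TestClassifyCellTissue:
    def test_memorizes_training_cell(self):
        rng = np.random.default_rng(8)
        rows = []
        labels = []
        for cls, base in (("tumor", 50.0), ("connective", 1.0)):
            for _ in range(25):
                rows.append({"Ecadherin": base + rng.normal(0, 0.1),
                             "Collagen1": 51.0 - base + rng.normal(0, 0.1)})
                labels.append(cls)
        train = cells_from_positive(rows)
        train.data = train.data.assign(tissue_class=labels)
        out = classify_cell_tissue(train, train, seed=0)
        assert (out.data["tissue_class"].to_numpy() == np.array(labels)).all()

    def test_noise_free_separable_exact(self):
        cfg = SyntheticConfig(grid_nx=32, grid_ny=32, marker_log_sd=0.0, seed=3)
        tm = generate_tissue_map(cfg)
        cells, truth = generate_cells(tm, cfg)
        cells.data = cells.data.assign(tissue_class=truth["tissue_class"])
        held = cells.copy()
        acc = (classify_cell_tissue(cells, held, seed=0).data["tissue_class"]
               == truth["tissue_class"]).mean()
        assert acc == 1.0

    def test_generator_default_holdout_accuracy(self):
        cfg = SyntheticConfig(grid_nx=48, grid_ny=48, seed=11)
        tm = generate_tissue_map(cfg)
        cells, truth = generate_cells(tm, cfg)
        rng = np.random.default_rng(11)
        sel = rng.random(len(cells)) < 0.5
        train = CellTable(cells.data[sel].assign(tissue_class=truth.loc[sel, "tissue_class"]),
                          cells.markers)
        pred = classify_cell_tissue(train, cells, seed=11)
        acc = (pred.data["tissue_class"].to_numpy(str)[~sel]
               == truth["tissue_class"].to_numpy(str)[~sel]).mean()
        assert acc >= 0.90

    def test_single_class_training_rejected(self):
        ct = cells_from_positive([{"CD45": HI}] * 30)
        ct.data = ct.data.assign(tissue_class="tumor")
        with pytest.raises(IMCError, match="2 tissue classes"):
            classify_cell_tissue(ct, ct, seed=0)


class TestPercentPositive:
    def test_basic_and_region(self):
        rows = [{"CD31": HI}] * 4 + [{}] * 6
        ct = cells_from_positive(rows)
        assert percent_positive(ct, "CD31") == 40.0
        assert percent_positive(ct, "CD31", region_mask=np.arange(10) < 4) == 100.0
        assert np.isnan(percent_positive(ct, "CD31", region_mask=np.zeros(10, bool)))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_gating_monotone_in_threshold(self, seed, t1, t2):
        """Raising a threshold never increases percent-positive."""
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"cell_id": [f"c{i}" for i in range(40)],
                           "x_um": 0.0, "y_um": 0.0,
                           "CD45": rng.uniform(0, 5, 40)})
        ct = CellTable(df)
        p_lo = percent_positive(apply_thresholds(ct, {"CD45": lo}), "CD45")
        p_hi = percent_positive(apply_thresholds(ct, {"CD45": hi}), "CD45")
        assert p_hi <= p_lo
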