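"""IMC single-cell tables: ingestion, thresholding, phenotype gating and
supervised tissue classification.

Cells enter as tables (one row per segmented cell) with centroids in µm in
the IMC coordinate frame and a mean intensity per antibody channel of the
27-marker mouse tumor-microenvironment panel. Marker positivity is a simple
inclusive threshold per marker (thresholds are set by the analyst, mirroring
manual gating practice), and immune phenotypes are boolean combinations of
positivity flags. The six myeloid gating rules shipped as defaults:

====================  =====================================================
phenotype             rule
====================  =====================================================
macrophage            CD45+ CD11b+ (F4/80+ or CD68+) CD11c− Ly6G−
M1_macrophage         CD45+ CD11b+ (F4/80+ or CD68+) MHCII+
M2_macrophage         CD45+ CD11b+ (F4/80+ or CD68+) CD163+ CD206+
immature_monocyte     CD45+ CD11b+ (F4/80+ or CD68+) Ly6G+ CD11c−
dendritic_cell        CD45+ CD11b+ (F4/80+ or CD68+) CD11c+
neutrophil            CD45+ CD11b+ F4/80− CD68− Ly6G+
====================  =====================================================

Rules are multi-label; a single primary label is resolved by a declared
precedence (most specific first). Tissue classes (tumor / connective /
necrosis) are assigned per cell by a supervised classifier trained on
labeled cells.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

TISSUE_CLASSES = ("tumor", "connective", "necrosis")

#: The 27-channel antibody panel (canonical marker names).
MARKER_PANEL = (
    "aSMA", "Vimentin", "Collagen1", "CD68", "CleavedCaspase3", "PanCK",
    "Ly6G", "Desmin", "CD11c", "CD11b", "F4/80", "CD163", "Ecadherin",
    "pNDRG1", "GLUT1", "pAMPK", "CD31", "EpCAM", "Ki67", "CD206", "Arg1",
    "pS6", "TTF1", "gH2AX", "MHCII", "CD45", "pHH3",
)

_EXTRA_ALIASES = {
    "alphasma": "aSMA", "sma": "aSMA", "collagen1": "Collagen1",
    "coli": "Collagen1", "cleavedcaspase3": "CleavedCaspase3",
    "ccasp3": "CleavedCaspase3", "cc3": "CleavedCaspase3",
    "pancytokeratin": "PanCK", "panck": "PanCK", "ecadherin": "Ecadherin",
    "cd326": "EpCAM", "epcamcd326": "EpCAM", "gammah2ax": "gH2AX",
    "yh2ax": "gH2AX", "mhciiiaie": "MHCII", "iaie": "MHCII", "f480": "F4/80",
}


def _norm_key(name: str) -> str:
    name = name.replace("α", "alpha").replace("γ", "gamma")
    return re.sub(r"[^0-9a-z]", "", name.lower())


_CANONICAL = { _norm_key(m): m for m in MARKER_PANEL } | _EXTRA_ALIASES


def canonical_marker(name: str) -> str:
    """Map a marker name (any case/punctuation, common aliases) to its
    canonical panel spelling; unknown names are returned stripped."""
    return _CANONICAL.get(_norm_key(name), name.strip())


class IMCError(ValueError):
    """Raised on malformed cell tables, thresholds, or gating rules."""


_RESERVED = {"cell_id", "x_um", "y_um", "area_um2", "phenotype", "tissue_class",
             "x_msi_um", "y_msi_um", "pixel_ix", "pixel_iy", "in_bounds"}


@dataclass
class CellTable:
    """Single-cell IMC table wrapping a pandas DataFrame.

    Columns: ``cell_id``, ``x_um``, ``y_um``, ``area_um2``, one column per
    marker, and (after the respective steps) ``positive_<marker>`` booleans,
    ``pheno_<name>`` booleans, ``phenotype``, ``tissue_class``, and the MSI
    pixel assignment columns added by the registration module.
    """

    data: pd.DataFrame
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("cell_id", "x_um", "y_um"):
            if col not in df.columns:
                raise IMCError(f"cell table missing required column {col!r}")
        if df["cell_id"].duplicated().any():
            raise IMCError("cell_id values must be unique")
        if not self.markers:
            self.markers = [c for c in df.columns
                            if c not in _RESERVED and not c.startswith(("positive_", "pheno_"))
                            and pd.api.types.is_numeric_dtype(df[c])]
        for m in self.markers:
            if (df[m] < 0).any():
                raise IMCError(f"negative intensities in marker {m!r}")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "CellTable":
        return CellTable(self.data.copy(), list(self.markers))

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str) -> "CellTable":
        df = pd.read_csv(path)
        df.columns = [canonical_marker(c) if _norm_key(c) in _CANONICAL else c
                      for c in df.columns]
        return cls(df)

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)

    def require_positivity(self, markers: list[str]) -> None:
        missing = [m for m in markers if f"positive_{m}" not in self.data.columns]
        if missing:
            raise IMCError(f"positivity not applied for marker(s): {', '.join(missing)}")


@dataclass(frozen=True)
class PhenotypeRule:
    """Boolean gating rule: all of ``requires_all`` (signed literals) and,
    if given, at least one positive marker of ``requires_any``."""

    name: str
    requires_all: tuple[tuple[str, bool], ...]
    requires_any: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        signs: dict[str, bool] = {}
        for marker, sign in self.requires_all:
            if signs.get(marker, sign) != sign:
                raise IMCError(f"rule {self.name!r} requires {marker} both + and −")
            signs[marker] = sign
        for marker in self.requires_any:
            if signs.get(marker, True) is False:
                raise IMCError(f"rule {self.name!r} requires {marker} both + and −")

    def markers(self) -> list[str]:
        return [m for m, _ in self.requires_all] + list(self.requires_any)

    def evaluate(self, cells: CellTable) -> np.ndarray:
        cells.require_positivity(self.markers())
        df = cells.data
        ok = np.ones(len(df), dtype=bool)
        for marker, sign in self.requires_all:
            flag = df[f"positive_{marker}"].to_numpy(bool)
            ok &= flag if sign else ~flag
        if self.requires_any:
            any_ok = np.zeros(len(df), dtype=bool)
            for marker in self.requires_any:
                any_ok |= df[f"positive_{marker}"].to_numpy(bool)
            ok &= any_ok
        return ok


_MYELOID_CORE = (("CD45", True), ("CD11b", True))
_F480_OR_CD68 = ("F4/80", "CD68")

DEFAULT_RULES = (
    PhenotypeRule("macrophage", _MYELOID_CORE + (("CD11c", False), ("Ly6G", False)), _F480_OR_CD68),
    PhenotypeRule("M1_macrophage", _MYELOID_CORE + (("MHCII", True),), _F480_OR_CD68),
    PhenotypeRule("M2_macrophage", _MYELOID_CORE + (("CD163", True), ("CD206", True)), _F480_OR_CD68),
    PhenotypeRule("immature_monocyte", _MYELOID_CORE + (("Ly6G", True), ("CD11c", False)), _F480_OR_CD68),
    PhenotypeRule("dendritic_cell", _MYELOID_CORE + (("CD11c", True),), _F480_OR_CD68),
    PhenotypeRule("neutrophil", _MYELOID_CORE + (("F4/80", False), ("CD68", False), ("Ly6G", True))),
)

#: Primary-label resolution order, most specific first.
DEFAULT_PRECEDENCE = (
    "neutrophil", "dendritic_cell", "M2_macrophage", "M1_macrophage",
    "immature_monocyte", "macrophage",
)


def apply_thresholds(cells: CellTable, thresholds: dict[str, float]) -> CellTable:
    """Set ``positive_<marker> = intensity ≥ threshold`` (inclusive).

    Only thresholded markers gain positivity flags; gating a rule whose
    marker lacks a threshold raises an error naming the marker.
    """
    out = cells.copy()
    new_cols = {}
    for marker, thr in thresholds.items():
        marker = canonical_marker(marker)
        if marker not in out.data.columns:
            raise IMCError(f"threshold given for unknown marker {marker!r}")
        new_cols[f"positive_{marker}"] = out.data[marker] >= thr
    out.data = out.data.assign(**new_cols)
    return out


def _inherit_exclusions(rule: PhenotypeRule, base: PhenotypeRule) -> PhenotypeRule:
    own = {m: s for m, s in rule.requires_all}
    extra = [(m, s) for m, s in base.requires_all
             if not s and m not in own and m not in rule.requires_any]
    if not extra:
        return rule
    return PhenotypeRule(rule.name, rule.requires_all + tuple(extra), rule.requires_any)


def assign_phenotypes(
    cells: CellTable,
    rules: tuple[PhenotypeRule, ...] = DEFAULT_RULES,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
    inherit_base_exclusions: bool = False,
) -> CellTable:
    """Gate every cell against every rule (multi-label) and resolve a
    primary label by precedence; unmatched cells get ``"none"``.

    ``inherit_base_exclusions`` optionally propagates the base macrophage
    rule's negative literals (CD11c−, Ly6G−) into subset rules where they do
    not conflict with the subset's own literals — the literal reading of the
    gating scheme (the default) keeps each rule as written.
    """
    if inherit_base_exclusions:
        base = next((r for r in rules if r.name == "macrophage"), None)
        if base is not None:
            rules = tuple(
                r if r.name in ("macrophage", "neutrophil") else _inherit_exclusions(r, base)
                for r in rules
            )
    out = cells.copy()
    flags = {f"pheno_{r.name}": r.evaluate(out) for r in rules}
    primary = np.full(len(out), "none", dtype=object)
    order = [n for n in precedence if f"pheno_{n}" in flags]
    order += [r.name for r in rules if r.name not in order]
    for name in reversed(order):
        primary[flags[f"pheno_{name}"]] = name
    out.data = out.data.assign(**flags, phenotype=primary)
    return out


def classify_cell_tissue(
    train: CellTable,
    cells: CellTable,
    feature_markers: list[str] | None = None,
    seed: int = 0,
    n_estimators: int = 200,
) -> CellTable:
    """Assign a tissue class to every cell with a random forest trained on
    labeled cells' marker intensities (log1p-transformed)."""
    if "tissue_class" not in train.data.columns:
        raise IMCError("training table lacks tissue_class labels")
    labels = train.data["tissue_class"].dropna()
    counts = labels.value_counts()
    if counts.size < 2:
        raise IMCError("training set must contain at least 2 tissue classes")
    if (counts < 20).any():
        warnings.warn(f"fewer than 20 training cells for class(es): "
                      f"{', '.join(counts.index[counts < 20])}")
    feats = feature_markers or [m for m in train.markers if m in cells.data.columns]
    rows = train.data.loc[labels.index]
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(np.log1p(rows[feats].to_numpy(float)), labels.to_numpy(str))
    out = cells.copy()
    out.data = out.data.assign(
        tissue_class=clf.predict(np.log1p(out.data[feats].to_numpy(float)))
    )
    return out


def percent_positive(
    cells: CellTable, marker: str, region_mask: np.ndarray | None = None
) -> float:
    """Percentage of cells positive for ``marker`` within an optional
    per-cell region mask; NaN when the region holds no cells."""
    marker = canonical_marker(marker)
    cells.require_positivity([marker])
    flags = cells.data[f"positive_{marker}"].to_numpy(bool)
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        flags = flags[region_mask]
    if flags.size == 0:
        return float("nan")
    return 100.0 * flags.mean()
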