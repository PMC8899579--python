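"""Compartment-resolved drug quantification.

Given a drug ion image and a tissue label map, computes the fraction of the
total drug signal falling in each tissue compartment (tumor, connective
tissue = stroma, necrosis), normalized to the total signal over all tissue
pixels — so the fractions are invariant to any global intensity scale and
to whether the drug image was reference-normalized. A timecourse summary
aggregates fractions across sections and timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import TissueLabelMap
from .imc import TISSUE_CLASSES
from .msi import IonImage


class CompartmentError(ValueError):
    pass


@dataclass
class CompartmentFractions:
    """Per-section drug signal shares by tissue compartment."""

    fractions: dict[str, float]
    total_drug_signal: float
    mean_drug_tissue: float = float("nan")
    mean_drug_tumor: float = float("nan")
    section_id: str = ""
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise CompartmentError(f"fractions sum to {total}, not 1")
        if self.total_drug_signal < 0:
            raise CompartmentError("total drug signal must be nonnegative")


def drug_fraction_by_class(
    drug: IonImage,
    labels: TissueLabelMap,
    classes: tuple[str, ...] = TISSUE_CLASSES,
    section_id: str = "",
    timepoint_h: float = 0.0,
) -> CompartmentFractions:
    """Share of total drug ion signal in each tissue class.

    ``fraction_c = Σ drug over pixels of class c / Σ drug over all pixels of
    the listed classes``; background is excluded from the denominator.
    Necrosis is included by default (pass ``classes=("tumor", "connective")``
    to exclude it).
    """
    if drug.values.shape != labels.shape:
        raise CompartmentError("drug image and label map are on different grids")
    vals = np.where(drug.valid_mask, drug.values, 0.0)
    sums = {c: float(vals[labels.mask(c)].sum()) for c in classes}
    total = sum(sums.values())
    if total <= 0:
        raise CompartmentError("zero total drug signal over tissue")
    tissue = np.zeros(labels.shape, bool)
    for c in classes:
        tissue |= labels.mask(c)
    tumor = labels.mask("tumor")
    return CompartmentFractions(
        fractions={c: sums[c] / total for c in classes},
        total_drug_signal=total,
        mean_drug_tissue=float(vals[tissue].mean()) if tissue.any() else float("nan"),
        mean_drug_tumor=float(vals[tumor].mean()) if tumor.any() else float("nan"),
        section_id=section_id,
        timepoint_h=timepoint_h,
    )


def timecourse_summary(sections: list[CompartmentFractions]) -> pd.DataFrame:
    """Per-timepoint mean/sd of each class fraction and of the mean drug
    intensity over the whole section and the tumor compartment only.

    Rows are ordered by timepoint then class; sd is NaN for single sections.
    """
    if not sections:
        raise CompartmentError("no sections given")
    rows = []
    for s in sections:
        for cls, frac in s.fractions.items():
            rows.append({"timepoint_h": s.timepoint_h, "tissue_class": cls,
                         "fraction": frac, "mean_drug_tissue": s.mean_drug_tissue,
                         "mean_drug_tumor": s.mean_drug_tumor,
                         "section_id": s.section_id})
    df = pd.DataFrame(rows)
    out = (df.groupby(["timepoint_h", "tissue_class"])
             .agg(mean_fraction=("fraction", "mean"),
                  sd_fraction=("fraction", "std"),
                  mean_drug_tissue=("mean_drug_tissue", "mean"),
                  sd_drug_tissue=("mean_drug_tissue", "std"),
                  mean_drug_tumor=("mean_drug_tumor", "mean"),
                  sd_drug_tumor=("mean_drug_tumor", "std"),
                  n_sections=("fraction", "size"))
             .reset_index()
             .sort_values(["timepoint_h", "tissue_class"], kind="stable")
             .reset_index(drop=True))
    return out


def fraction_time_trend(
    sections: list[CompartmentFractions], tissue_class: str = "tumor"
) -> tuple[float, float]:
    """Least-squares slope of a class's fraction against time across
    sections, with its p-value — the test of whether the compartment share
    drifts over the timecourse."""
    t = np.array([s.timepoint_h for s in sections], float)
    y = np.array([s.fractions[tissue_class] for s in sections], float)
    if np.unique(t).size < 2:
        raise CompartmentError("need at least 2 distinct timepoints")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.pvalue)
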