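"""End-to-end orchestration: preprocess → gate → register → vote → kNN →
correlate → quantify, over a synthetic (or user-supplied) bundle directory.

Each stage is a function over a shared :class:`PipelineState`; ``run_pipeline``
executes stages in order up to a requested stage and writes per-stage
artifacts plus a single deterministic ``summary.json``. When the bundle
carries generator ground truth, accuracy against truth is reported at every
stage where it is defined.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossmodal, fusion, imc, msi, registration
from .compartments import drug_fraction_by_class
from .imc import CellTable, PhenotypeRule
from .synthetic import (DRUG_MZ, METABOLITE_MZ, REFERENCE_MZ, SyntheticBundle,
                        SyntheticConfig, default_thresholds, generate_dataset,
                        load_bundle, write_bundle)

STAGES = ("preprocess", "gate", "register", "classify", "correlate", "quantify")

#: CD31-positive, CD45-negative endothelial gate used for the vasculature
#: side of the enrichment analysis (not part of the six myeloid rules).
ENDOTHELIAL_RULE = PhenotypeRule("endothelial", (("CD31", True), ("CD45", False)))

DEFAULT_IONS = (("drug", DRUG_MZ, 0.005),
                ("reference", REFERENCE_MZ, 0.005),
                ("metabolite", METABOLITE_MZ, 0.005))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run settings; defaults match the synthetic benchmark conditions."""

    bundle_dir: str
    out_dir: str
    thresholds: dict[str, float] = field(default_factory=default_thresholds)
    train_fraction: float = 0.2          # cells given truth labels for RF training
    knn_k: int = 30
    exclude_analyte_from_knn: bool = True
    registration_model: str = "similarity"
    registration_metric: str = "correlation"
    registration_refine: bool = True
    ions: tuple = DEFAULT_IONS
    correlation_markers: tuple[str, ...] = ("CD68", "CD206", "Collagen1", "CD31", "Ecadherin")
    enrichment_phenotypes: tuple[str, ...] = ("M2_macrophage", "M1_macrophage",
                                              "macrophage", "dendritic_cell",
                                              "neutrophil", "endothelial")
    seed: int = 0

    def validate(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not os.path.isdir(self.bundle_dir):
            raise FileNotFoundError(f"bundle directory {self.bundle_dir!r} not found")
        for _, _, tol in self.ions:
            if tol <= 0:
                raise ValueError("ion m/z tolerances must be positive")


@dataclass
class PipelineState:
    config: PipelineConfig
    bundle: SyntheticBundle
    ds: msi.MSIDataset | None = None
    ds_raw: msi.MSIDataset | None = None
    cells: CellTable | None = None
    transform: registration.AffineTransform2D | None = None
    reg_report: registration.RegistrationReport | None = None
    vote_map: fusion.TissueLabelMap | None = None
    label_map: fusion.TissueLabelMap | None = None
    drug_image: msi.IonImage | None = None
    summary: dict = field(default_factory=dict)


def run_synth(config: SyntheticConfig, outdir: str) -> SyntheticBundle:
    """Generate a synthetic bundle and write it to disk with a manifest."""
    bundle = generate_dataset(config)
    write_bundle(bundle, outdir)
    return bundle


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_preprocess(st: PipelineState) -> None:
    ds = st.bundle.msi
    mask = msi.detect_background(ds, seed=st.config.seed)
    ds = msi.MSIDataset(ds.mz_axis, ds.intensities, ds.pixel_coords, ds.nx, ds.ny,
                        ds.pixel_size_x_um, ds.pixel_size_y_um, tissue_mask=mask)
    st.ds_raw = ds
    st.ds = msi.tic_normalize(ds)
    # ion images for quantification come from the raw intensities
    name, mz, tol = st.config.ions[0]
    st.drug_image = msi.extract_ion_image(st.ds_raw, mz, tol)
    truth = st.bundle.truth
    info = {"n_tissue_pixels": int(mask.sum())}
    if truth is not None:
        truth_tissue = truth.label_map.labels.ravel() > fusion.BACKGROUND
        info["tissue_mask_agreement"] = float((mask == truth_tissue).mean())
    st.summary["preprocess"] = info


def _stage_gate(st: PipelineState) -> None:
    cfg = st.config
    cells = imc.apply_thresholds(st.bundle.cells, cfg.thresholds)
    cells = imc.assign_phenotypes(cells, rules=imc.DEFAULT_RULES + (ENDOTHELIAL_RULE,),
                                  precedence=imc.DEFAULT_PRECEDENCE + ("endothelial",))
    truth = st.bundle.truth
    if truth is not None and truth.cell_truth is not None:
        merged = cells.data.merge(truth.cell_truth[["cell_id", "tissue_class"]],
                                  on="cell_id", how="left")
        rng = np.random.default_rng(cfg.seed)
        train_sel = rng.random(len(merged)) < cfg.train_fraction
        train = CellTable(merged.assign(
            tissue_class=merged["tissue_class"].where(train_sel)), cells.markers)
        cells = imc.classify_cell_tissue(train, cells, seed=cfg.seed)
        truth_cls = merged["tissue_class"].to_numpy(str)
        acc = float((cells.data["tissue_class"].to_numpy(str)[~train_sel]
                     == truth_cls[~train_sel]).mean())
        info = {"rf_holdout_accuracy": acc, "n_train_cells": int(train_sel.sum())}
    elif "tissue_class" in cells.data.columns:
        labeled = cells.data["tissue_class"].notna()
        train = CellTable(cells.data[labeled], cells.markers)
        cells = imc.classify_cell_tissue(train, cells, seed=cfg.seed)
        info = {"n_train_cells": int(labeled.sum())}
    else:
        raise imc.IMCError("no tissue training labels available for cell classification")
    st.cells = cells
    info["phenotype_counts"] = {k: int(v) for k, v in
                                cells.data["phenotype"].value_counts().items()}
    st.summary["gate"] = info


def _stage_register(st: PipelineState) -> None:
    cfg = st.config
    fixed = registration.representative_image_msi(st.ds_raw)
    moving = registration.representative_image_imc(st.cells)
    t, report = registration.estimate_transform(
        fixed, moving, model=cfg.registration_model, metric=cfg.registration_metric,
        seed=cfg.seed)
    if cfg.registration_refine:
        t, report = registration.refine_transform_poisson(
            st.ds, st.cells, t, seed=cfg.seed)
    st.transform, st.reg_report = t, report
    st.cells = registration.transform_cells(st.cells, t, st.ds)
    info = {"converged": bool(report.converged),
            "metric_value": float(report.similarity_metric_value),
            "n_out_of_bounds_cells": int((~st.cells.data["in_bounds"]).sum())}
    truth = st.bundle.truth
    if truth is not None and truth.transform is not None:
        info["mean_corner_error_um"] = registration.mean_corner_error_um(
            t, truth.transform, moving)
    st.summary["register"] = info


def _stage_classify(st: PipelineState) -> None:
    cfg = st.config
    shape = (st.ds.ny, st.ds.nx)
    st.vote_map = fusion.majority_vote_labels(st.cells, shape)
    exclude = [(mz, tol) for _, mz, tol in cfg.ions] if cfg.exclude_analyte_from_knn else None
    st.label_map = fusion.fit_predict_knn(
        st.ds, st.vote_map, background_mask=~st.ds.mask_image(),
        k=cfg.knn_k, exclude_mz=exclude, seed=cfg.seed)
    summary = fusion.class_mean_intensities(st.ds_raw, st.label_map,
                                            [tuple(i) for i in cfg.ions])
    info = {"n_vote_pixels": int((st.vote_map.labels > fusion.BACKGROUND).sum()),
            "class_fractions": st.label_map.class_fractions()}
    truth = st.bundle.truth
    if truth is not None:
        tl, pl = truth.label_map.labels, st.label_map.labels
        info["knn_accuracy_vs_truth"] = float((tl == pl).mean())
        voted = st.vote_map.labels > fusion.BACKGROUND
        if voted.any():
            info["vote_accuracy_vs_truth"] = float(
                (st.vote_map.labels[voted] == tl[voted]).mean())
    st.summary["classify"] = info
    st._class_summary = summary  # type: ignore[attr-defined]


def _stage_correlate(st: PipelineState) -> None:
    cfg = st.config
    shape = (st.ds.ny, st.ds.nx)
    drug = st.drug_image
    corr = {}
    for marker in cfg.correlation_markers:
        m = crossmodal.rasterize_marker(st.cells, marker, shape, agg="mean")
        res = crossmodal.pearson_map_correlation(m, drug)
        corr[marker] = {"r": res.r, "n_pixels": res.n_pixels}
    stroma = st.label_map.mask("connective")
    high, low = crossmodal.stratify_high_low(drug, stroma)
    enr = crossmodal.phenotype_enrichment(
        st.cells, high, low, drug.pixel_area_mm2, list(cfg.enrichment_phenotypes))
    info = {"correlations": corr,
            "enrichment": {row["phenotype"]: row["fold"] for _, row in enr.iterrows()}}
    truth = st.bundle.truth
    if truth is not None and truth.hot_mask is not None and truth.hot_mask.any():
        hot = truth.hot_mask.astype(bool)
        region = high | low
        agree = ((high & hot) | (low & ~hot))[region].mean()
        info["high_low_mask_agreement_vs_truth"] = float(agree)
    st.summary["correlate"] = info
    st._enrichment = enr  # type: ignore[attr-defined]


def _stage_quantify(st: PipelineState) -> None:
    drug = st.drug_image
    pred = drug_fraction_by_class(drug, st.label_map)
    info = {"fractions_predicted_labels": pred.fractions,
            "total_drug_signal": pred.total_drug_signal,
            "mean_drug_tissue": pred.mean_drug_tissue,
            "mean_drug_tumor": pred.mean_drug_tumor}
    truth = st.bundle.truth
    if truth is not None:
        true = drug_fraction_by_class(drug, truth.label_map)
        info["fractions_truth_labels"] = true.fractions
        info["planted_tumor_drug_fraction"] = truth.planted_tumor_drug_fraction
    st.summary["quantify"] = info


_STAGE_FN = {"preprocess": _stage_preprocess, "gate": _stage_gate,
             "register": _stage_register, "classify": _stage_classify,
             "correlate": _stage_correlate, "quantify": _stage_quantify}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else str(f)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, until: str = "quantify") -> PipelineState:
    """Run pipeline stages in order up to ``until`` and write artifacts.

    On a stage failure the partial outputs written so far are retained and a
    :class:`PipelineError` naming the stage is raised.
    """
    config.validate()
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    os.makedirs(config.out_dir, exist_ok=True)
    bundle = load_bundle(config.bundle_dir)
    st = PipelineState(config=config, bundle=bundle)
    st.summary["seed"] = config.seed
    st.summary["config_hash"] = bundle.config.config_hash()
    last = STAGES.index(until)
    for stage in STAGES[: last + 1]:
        try:
            _STAGE_FN[stage](st)
        except Exception as exc:
            _write_outputs(st, failed_stage=stage)
            raise PipelineError(stage, exc) from exc
    _write_outputs(st)
    return st


def _write_outputs(st: PipelineState, failed_stage: str | None = None) -> None:
    out = st.config.out_dir
    if st.cells is not None:
        st.cells.to_csv(os.path.join(out, "cells_processed.csv"))
    if st.transform is not None:
        st.transform.to_json(os.path.join(out, "transform.json"))
    if st.label_map is not None:
        st.label_map.to_csv(os.path.join(out, "label_map.csv"))
    cs = getattr(st, "_class_summary", None)
    if cs is not None:
        cs.to_csv(os.path.join(out, "class_mean_intensities.csv"))
    enr = getattr(st, "_enrichment", None)
    if enr is not None:
        enr.to_csv(os.path.join(out, "enrichment.csv"), index=False)
    if "quantify" in st.summary:
        rows = [{"tissue_class": c, "fraction": f}
                for c, f in st.summary["quantify"]["fractions_predicted_labels"].items()]
        pd.DataFrame(rows).to_csv(os.path.join(out, "drug_fractions.csv"), index=False)
    summary = dict(st.summary)
    if failed_stage:
        summary["failed_stage"] = failed_stage
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
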