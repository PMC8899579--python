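"""Paired synthetic MSI + IMC data with full ground truth.

Emulates the statistical structure the fusion pipeline assumes, so every
downstream stage can be exercised against a known answer without any
external data:

* a contiguous tissue mosaic (Voronoi tessellation of seeded points inside
  an elliptical tissue boundary) with tumor / connective / necrosis
  compartments at configurable priors, surrounded by background;
* peak-reduced, negative-mode MSI spectra: one class-specific peak template
  per compartment with multiplicative log-normal noise, plus three named
  ion channels — a drug ion, its structural-analogue reference ion at
  m/z 520.2492, and a drug metabolite — with the drug intensity coupled to
  the local expected M2-macrophage density (nanomedicine accumulating in
  macrophage-rich stroma);
* an IMC-like single-cell table: inhomogeneous Poisson cell placement with
  class-dependent density, per-class phenotype mixes, log-normal marker
  intensities from per-phenotype signature models plus tissue-context
  effects (hypoxia/metabolic markers up in tumor, apoptosis/DNA-damage
  markers up in necrosis), emitted in a separate IMC coordinate frame
  related to the MSI frame by a known similarity transform;
* a "hot" stromal subfield in which M2 (and endothelial) cell density is
  enriched by a planted fold, and into which the drug ion preferentially
  partitions — the ground truth for the high-vs-low drug enrichment
  analysis.

All randomness flows from one seed through named `numpy` SeedSequence
spawns, so identical configs give bit-identical datasets.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .fusion import LABEL_CODES, PROV_TRUTH, TissueLabelMap
from .imc import MARKER_PANEL, CellTable, TISSUE_CLASSES
from .msi import MSIDataset, load_imzml, write_imzml
from .registration import AffineTransform2D

# Named ion channels. The reference analogue m/z is the value used for
# normalization throughout; the metabolite sits at the nominal m/z 478
# channel; the drug ion m/z is a synthetic [M-H]- placeholder (the assay's
# real transition is instrument-specific and not part of this model).
DRUG_MZ = 506.2318
REFERENCE_MZ = 520.2492
METABOLITE_MZ = 478.2289

PHENOTYPES = (
    "tumor_cell", "fibroblast", "endothelial", "necrotic", "macrophage",
    "M1_macrophage", "M2_macrophage", "immature_monocyte", "dendritic_cell",
    "neutrophil",
)

#: Signature (positive) markers per phenotype; all other panel markers sit
#: at the negative baseline.
PHENOTYPE_SIGNATURES: dict[str, tuple[str, ...]] = {
    "tumor_cell": ("Ecadherin", "PanCK", "EpCAM", "Ki67", "pS6"),
    "fibroblast": ("aSMA", "Collagen1", "Vimentin", "Desmin"),
    "endothelial": ("CD31", "aSMA", "Vimentin"),
    "necrotic": ("CleavedCaspase3", "gH2AX"),
    "macrophage": ("CD45", "CD11b", "F4/80", "CD68"),
    "M1_macrophage": ("CD45", "CD11b", "F4/80", "CD68", "MHCII"),
    "M2_macrophage": ("CD45", "CD11b", "F4/80", "CD68", "CD163", "CD206", "Arg1"),
    "immature_monocyte": ("CD45", "CD11b", "F4/80", "Ly6G"),
    "dendritic_cell": ("CD45", "CD11b", "CD68", "CD11c", "MHCII"),
    "neutrophil": ("CD45", "CD11b", "Ly6G"),
}

#: Tissue-context effects: multiplicative (log-space) boosts applied to a
#: cell's markers according to the compartment it sits in, independent of
#: phenotype — what makes cell tissue classes learnable from markers.
CONTEXT_LOG_BOOST: dict[str, dict[str, float]] = {
    "tumor": {"GLUT1": np.log(20.0), "pNDRG1": np.log(10.0)},
    "connective": {},
    "necrosis": {"CleavedCaspase3": np.log(30.0), "gH2AX": np.log(20.0)},
}

_DEFAULT_MIX = {
    "tumor": {"tumor_cell": 0.88, "fibroblast": 0.02, "endothelial": 0.02,
              "macrophage": 0.02, "M1_macrophage": 0.01, "M2_macrophage": 0.01,
              "dendritic_cell": 0.02, "neutrophil": 0.01, "immature_monocyte": 0.01},
    "connective": {"fibroblast": 0.36, "endothelial": 0.12, "macrophage": 0.10,
                   "M1_macrophage": 0.04, "M2_macrophage": 0.20,
                   "dendritic_cell": 0.04, "neutrophil": 0.05,
                   "immature_monocyte": 0.04, "tumor_cell": 0.05},
    "necrosis": {"necrotic": 0.72, "neutrophil": 0.12, "macrophage": 0.08,
                 "M2_macrophage": 0.03, "immature_monocyte": 0.05},
}

_DEFAULT_DENSITY = {"tumor": 800.0, "connective": 800.0, "necrosis": 150.0}
_DEFAULT_DRUG_BASELINE = {"tumor": 4.0, "connective": 2.0, "necrosis": 0.5}


class SyntheticConfigError(ValueError):
    pass


def default_mz_axis(n_structural: int = 31, rng_seed: int = 1906) -> np.ndarray:
    """Negative-mode peak-list axis over m/z 250–1000: the three named ion
    channels plus ``n_structural`` structural (lipid-like) peaks placed
    reproducibly away from the named channels."""
    rng = np.random.default_rng(rng_seed)
    named = np.array([METABOLITE_MZ, DRUG_MZ, REFERENCE_MZ])
    peaks = []
    while len(peaks) < n_structural:
        mz = rng.uniform(250.0, 1000.0)
        if np.all(np.abs(named - mz) > 1.0) and all(abs(p - mz) > 1.0 for p in peaks):
            peaks.append(round(mz, 4))
    return np.unique(np.concatenate([named, np.array(peaks)]))


def default_templates(
    mz_axis: np.ndarray, separation: float = 1.0, rng_seed: int = 1906
) -> dict[str, np.ndarray]:
    """Per-class mean structural peak intensities.

    A shared log-normal base profile is modulated per class by a log-normal
    factor whose spread scales with ``separation`` — the knob controlling
    between-class spectral distance (0 makes classes spectrally identical).
    The named ion channels are zeroed here; they are filled by the drug /
    reference / metabolite models.
    """
    rng = np.random.default_rng(rng_seed)
    base = np.exp(rng.normal(np.log(8.0), 0.8, size=mz_axis.size))
    templates = {}
    for cls in TISSUE_CLASSES:
        factor = np.exp(separation * rng.normal(0.0, 0.7, size=mz_axis.size))
        t = base * factor
        for mz in (DRUG_MZ, REFERENCE_MZ, METABOLITE_MZ):
            t[np.abs(mz_axis - mz) < 1e-6] = 0.0
        templates[cls] = t
    return templates


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults define the benchmark conditions."""

    grid_nx: int = 128
    grid_ny: int = 128
    pixel_size_x_um: float = 50.0
    pixel_size_y_um: float = 75.0
    n_tissue_regions: int = 40
    class_priors: tuple[float, float, float] = (0.5, 0.3, 0.2)  # tumor, connective, necrosis
    tissue_ellipse_frac: tuple[float, float] = (0.92, 0.92)

    # MSI model
    mz_axis: np.ndarray | None = None
    peak_templates: dict[str, np.ndarray] | None = None
    template_separation: float = 1.0
    peak_noise_sigma: float = 0.35
    background_level: float = 0.02
    drug_baseline: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DRUG_BASELINE))
    drug_m2_coeff: float = 0.05          # drug intensity per (M2 cell / mm²)
    drug_noise_sigma: float = 0.2
    target_tumor_drug_fraction: float | None = 0.45
    reference_level: float = 50.0
    metabolite_yield: float = 0.3

    # cell model
    cell_density_per_class: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DENSITY))
    phenotype_mix_per_class: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in _DEFAULT_MIX.items()})
    m2_enrichment_fold: float = 5.1
    endothelial_enrichment_fold: float = 1.8
    hot_smooth_px: float = 4.0
    marker_log_sd: float = 0.4
    positive_log_mean: float = float(np.log(30.0))
    negative_log_mean: float = float(np.log(0.3))
    marker_models: dict[str, dict[str, tuple[float, float]]] | None = None

    # IMC↔MSI frame relation (truth)
    transform_rotation_deg: float = 10.0
    transform_scale: float = 1.05
    transform_translation_um: tuple[float, float] = (250.0, -150.0)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_axis is None:
            self.mz_axis = default_mz_axis()
        else:
            self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.grid_nx < 8 or self.grid_ny < 8:
            raise SyntheticConfigError("grid dimensions must be at least 8")
        p = np.asarray(self.class_priors, float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise SyntheticConfigError("class_priors must be a length-3 probability vector")
        for cls, mix in self.phenotype_mix_per_class.items():
            v = np.array(list(mix.values()), float)
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise SyntheticConfigError(f"phenotype mix for {cls!r} must sum to 1")
            unknown = set(mix) - set(PHENOTYPES)
            if unknown:
                raise SyntheticConfigError(f"unknown phenotype(s) {unknown} for class {cls!r}")
        if any(d < 0 for d in self.cell_density_per_class.values()):
            raise SyntheticConfigError("cell densities must be nonnegative")
        if self.marker_log_sd < 0 or self.peak_noise_sigma < 0 or self.drug_noise_sigma < 0:
            raise SyntheticConfigError("noise dispersions must be nonnegative")
        if self.transform_scale == 0:
            raise SyntheticConfigError("transform scale must be nonzero (invertible)")

    # -- derived quantities ---------------------------------------------
    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_x_um * self.pixel_size_y_um / 1e6

    def transform_truth(self) -> AffineTransform2D:
        return AffineTransform2D.from_similarity(
            rotation_deg=self.transform_rotation_deg,
            scale=self.transform_scale,
            translation_um=tuple(self.transform_translation_um),
        )

    def templates(self) -> dict[str, np.ndarray]:
        if self.peak_templates is not None:
            return self.peak_templates
        return default_templates(self.mz_axis, self.template_separation)

    def resolved_marker_models(self) -> dict[str, dict[str, tuple[float, float]]]:
        """Per-phenotype (log-mean, log-sd) for every panel marker."""
        if self.marker_models is not None:
            return self.marker_models
        models = {}
        for pheno in PHENOTYPES:
            sig = PHENOTYPE_SIGNATURES[pheno]
            models[pheno] = {
                m: ((self.positive_log_mean if m in sig else self.negative_log_mean),
                    self.marker_log_sd)
                for m in MARKER_PANEL
            }
        return models

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mz_axis"] = np.asarray(self.mz_axis).tolist()
        if self.peak_templates is not None:
            d["peak_templates"] = {k: np.asarray(v).tolist() for k, v in self.peak_templates.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if d.get("mz_axis") is not None:
            d["mz_axis"] = np.asarray(d["mz_axis"], float)
        if d.get("peak_templates") is not None:
            d["peak_templates"] = {k: np.asarray(v, float) for k, v in d["peak_templates"].items()}
        for key in ("class_priors", "tissue_ellipse_frac", "transform_translation_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator, the oracle for every test."""

    label_map: TissueLabelMap
    transform: AffineTransform2D
    hot_mask: np.ndarray                      # (ny, nx) bool: high-drug stroma
    drug_noise_free: np.ndarray               # (ny, nx) noise-free drug field
    expected_m2_density: np.ndarray           # (ny, nx) cells/mm²
    planted_tumor_drug_fraction: float
    planted_enrichment_folds: dict[str, float]
    planted_marker_ion_correlations: dict[str, float]
    cell_truth: pd.DataFrame                  # cell_id, tissue_class, phenotype


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    msi: MSIDataset
    cells: CellTable
    truth: SyntheticTruth


def _rngs(config: SyntheticConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    names = ("tissue", "hot", "msi", "cells", "markers")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def _pixel_centers(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (µm) as (ny, nx) meshes."""
    x = (np.arange(config.grid_nx) + 0.5) * config.pixel_size_x_um
    y = (np.arange(config.grid_ny) + 0.5) * config.pixel_size_y_um
    return np.meshgrid(x, y)


# ---------------------------------------------------------------------------
# Tissue label map
# ---------------------------------------------------------------------------

def generate_tissue_map(config: SyntheticConfig) -> TissueLabelMap:
    """Voronoi mosaic of tissue compartments inside an elliptical boundary.

    Voronoi cells of uniformly seeded points are allocated to classes by a
    greedy largest-deficit rule against ``class_priors`` (largest regions
    first), giving contiguous compartments whose empirical pixel fractions
    track the priors closely while the geometry stays random.
    """
    rng = _rngs(config)["tissue"]
    X, Y = _pixel_centers(config)
    W = config.grid_nx * config.pixel_size_x_um
    H = config.grid_ny * config.pixel_size_y_um
    ax = config.tissue_ellipse_frac[0] * W / 2
    ay = config.tissue_ellipse_frac[1] * H / 2
    tissue = ((X - W / 2) / ax) ** 2 + ((Y - H / 2) / ay) ** 2 <= 1.0

    seeds = np.column_stack([rng.uniform(0, W, config.n_tissue_regions),
                             rng.uniform(0, H, config.n_tissue_regions)])
    pts = np.column_stack([X[tissue], Y[tissue]])
    region = np.full((config.grid_ny, config.grid_nx), -1, dtype=int)
    region[tissue] = cKDTree(seeds).query(pts)[1]

    areas = np.bincount(region[tissue], minlength=config.n_tissue_regions)
    total = areas.sum()
    priors = np.asarray(config.class_priors, float)
    allocated = np.zeros(3)
    region_class = np.zeros(config.n_tissue_regions, dtype=int)
    for r in np.argsort(areas)[::-1]:
        deficit = priors * total - allocated
        c = int(np.argmax(deficit))
        region_class[r] = c
        allocated[c] += areas[r]

    labels = np.full((config.grid_ny, config.grid_nx), LABEL_CODES["background"], np.int8)
    class_codes = np.array([LABEL_CODES[c] for c in TISSUE_CLASSES], np.int8)
    labels[tissue] = class_codes[region_class[region[tissue]]]
    prov = np.full(labels.shape, PROV_TRUTH, np.int8)
    return TissueLabelMap(labels, prov)


# ---------------------------------------------------------------------------
# Stromal "hot" field and expected cell densities
# ---------------------------------------------------------------------------

def generate_hot_mask(truth_map: TissueLabelMap, config: SyntheticConfig) -> np.ndarray:
    """Smooth random subfield of the connective compartment (median split of
    a Gaussian-filtered noise field) marking the high-drug / M2-enriched
    stroma zones."""
    rng = _rngs(config)["hot"]
    fieldv = gaussian_filter(rng.standard_normal(truth_map.shape), config.hot_smooth_px)
    conn = truth_map.mask("connective")
    hot = np.zeros(truth_map.shape, bool)
    if conn.any():
        hot[conn] = fieldv[conn] > np.median(fieldv[conn])
    return hot


def expected_phenotype_density(
    truth_map: TissueLabelMap, hot_mask: np.ndarray, config: SyntheticConfig
) -> dict[str, np.ndarray]:
    """Expected cells/mm² per phenotype per pixel (the Poisson intensity).

    In the connective compartment, the M2 and endothelial intensities are
    modulated by the hot field with the planted folds while preserving the
    compartment-wide mean density, so overall composition matches the mix.
    """
    fields = {p: np.zeros(truth_map.shape) for p in PHENOTYPES}
    folds = {"M2_macrophage": config.m2_enrichment_fold,
             "endothelial": config.endothelial_enrichment_fold}
    for cls in TISSUE_CLASSES:
        m = truth_map.mask(cls)
        if not m.any():
            continue
        dens = config.cell_density_per_class.get(cls, 0.0)
        for pheno, frac in config.phenotype_mix_per_class.get(cls, {}).items():
            lam = dens * frac
            if cls == "connective" and pheno in folds and folds[pheno] != 1.0:
                p_hot = hot_mask[m].mean()
                fold = folds[pheno]
                lo = lam / (1.0 - p_hot + fold * p_hot)
                fields[pheno][m & ~hot_mask] = lo
                fields[pheno][m & hot_mask] = fold * lo
            else:
                fields[pheno][m] = lam
    return fields


# ---------------------------------------------------------------------------
# MSI generation
# ---------------------------------------------------------------------------

def drug_noise_free_field(
    truth_map: TissueLabelMap,
    m2_density: np.ndarray,
    config: SyntheticConfig,
) -> tuple[np.ndarray, float]:
    """Noise-free drug ion field and the planted tumor drug fraction.

    ``D0 = baseline[class] + m2_coeff · expected M2 density``; when a target
    tumor fraction is set, tumor-pixel values are rescaled so that exactly
    that share of the total noise-free signal falls in the tumor compartment.
    Returns the field and ``Σ D0(tumor) / Σ D0(tissue)`` computed from it.
    """
    D0 = np.zeros(truth_map.shape)
    tissue = np.zeros(truth_map.shape, bool)
    for cls in TISSUE_CLASSES:
        m = truth_map.mask(cls)
        tissue |= m
        D0[m] = config.drug_baseline.get(cls, 0.0) + config.drug_m2_coeff * m2_density[m]
    tumor = truth_map.mask("tumor")
    target = config.target_tumor_drug_fraction
    if target is not None and tumor.any() and D0[tumor].sum() > 0:
        other = D0[tissue & ~tumor].sum()
        if other > 0 and 0 < target < 1:
            alpha = (target / (1 - target)) * other / D0[tumor].sum()
            D0[tumor] *= alpha
    total = D0[tissue].sum()
    planted = float(D0[tumor].sum() / total) if total > 0 else float("nan")
    return D0, planted


def generate_msi(
    truth_map: TissueLabelMap,
    config: SyntheticConfig,
    m2_density: np.ndarray | None = None,
) -> MSIDataset:
    """Peak-reduced MSI dataset over the full grid.

    Structural peaks follow the class template with multiplicative
    log-normal noise; the drug channel follows the noise-free drug field,
    the reference channel a spatially flat tissue level, and the metabolite
    channel a fixed yield of the drug field, each with their own noise.
    Background pixels get near-zero intensities across all channels.
    """
    templates = config.templates()
    missing = [c for c in TISSUE_CLASSES
               if truth_map.mask(c).any() and c not in templates]
    if missing:
        raise SyntheticConfigError(f"no peak template for present class(es): {missing}")
    if m2_density is None:
        hot = generate_hot_mask(truth_map, config)
        m2_density = expected_phenotype_density(truth_map, hot, config)["M2_macrophage"]

    rng = _rngs(config)["msi"]
    ny, nx = truth_map.shape
    n_px, n_peaks = ny * nx, config.mz_axis.size
    mean = np.full((n_px, n_peaks), config.background_level)
    flat_labels = truth_map.labels.ravel()
    for cls in TISSUE_CLASSES:
        sel = flat_labels == LABEL_CODES[cls]
        if sel.any():
            mean[sel] = templates[cls][None, :]

    D0, _ = drug_noise_free_field(truth_map, m2_density, config)
    tissue = np.isin(flat_labels, [LABEL_CODES[c] for c in TISSUE_CLASSES])
    drug_col = int(np.argmin(np.abs(config.mz_axis - DRUG_MZ)))
    ref_col = int(np.argmin(np.abs(config.mz_axis - REFERENCE_MZ)))
    met_col = int(np.argmin(np.abs(config.mz_axis - METABOLITE_MZ)))
    mean[:, drug_col] = np.where(tissue, D0.ravel(), config.background_level)
    mean[:, ref_col] = np.where(tissue, config.reference_level, config.background_level)
    mean[:, met_col] = np.where(tissue, config.metabolite_yield * D0.ravel(),
                                config.background_level)

    noise = np.ones_like(mean)
    if config.peak_noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, config.peak_noise_sigma, size=mean.shape))
    if config.drug_noise_sigma > 0:
        dn = np.exp(rng.normal(0.0, config.drug_noise_sigma, size=(n_px, 2)))
    else:
        dn = np.ones((n_px, 2))
    intensities = mean * noise
    intensities[:, drug_col] = mean[:, drug_col] * dn[:, 0]
    intensities[:, met_col] = mean[:, met_col] * dn[:, 1]

    iy, ix = np.divmod(np.arange(n_px), nx)
    return MSIDataset(
        mz_axis=config.mz_axis,
        intensities=np.clip(intensities, 0.0, None),
        pixel_coords=np.column_stack([ix, iy]),
        nx=nx, ny=ny,
        pixel_size_x_um=config.pixel_size_x_um,
        pixel_size_y_um=config.pixel_size_y_um,
        tissue_mask=tissue,
    )


# ---------------------------------------------------------------------------
# Cell generation
# ---------------------------------------------------------------------------

def generate_cells(
    truth_map: TissueLabelMap,
    config: SyntheticConfig,
    density_fields: dict[str, np.ndarray] | None = None,
) -> tuple[CellTable, pd.DataFrame]:
    """Poisson cell point pattern with phenotype-dependent markers.

    Cells are placed pixel-wise by an inhomogeneous Poisson process on the
    expected per-phenotype density fields, positioned uniformly within their
    pixel in the MSI frame, then emitted in the IMC frame (the inverse of
    the truth transform). Marker intensities are log-normal draws from the
    per-phenotype models plus tissue-context boosts. Returns the cell table
    (IMC frame, no truth columns) and the truth table (cell_id, tissue
    class, phenotype).
    """
    t = config.transform_truth()
    if density_fields is None:
        hot = generate_hot_mask(truth_map, config)
        density_fields = expected_phenotype_density(truth_map, hot, config)

    rng_c = _rngs(config)["cells"]
    rng_m = _rngs(config)["markers"]
    area = config.pixel_area_mm2
    ny, nx = truth_map.shape

    recs_ix, recs_iy, recs_pheno = [], [], []
    for pheno in PHENOTYPES:
        lam = density_fields.get(pheno)
        if lam is None or not np.any(lam > 0):
            continue
        counts = rng_c.poisson(lam * area)
        iy, ix = np.nonzero(counts)
        reps = counts[iy, ix]
        recs_ix.append(np.repeat(ix, reps))
        recs_iy.append(np.repeat(iy, reps))
        recs_pheno.append(np.full(int(reps.sum()), pheno, dtype=object))

    if recs_ix:
        ix = np.concatenate(recs_ix)
        iy = np.concatenate(recs_iy)
        pheno = np.concatenate(recs_pheno)
    else:
        ix = iy = np.array([], int)
        pheno = np.array([], object)
    n = ix.size

    x_msi = (ix + rng_c.uniform(0, 1, n)) * config.pixel_size_x_um
    y_msi = (iy + rng_c.uniform(0, 1, n)) * config.pixel_size_y_um
    imc_xy = t.inverse().apply(np.column_stack([x_msi, y_msi])) if n else np.empty((0, 2))
    tissue_class = np.array([{v: k for k, v in LABEL_CODES.items()}.get(c, "background")
                             for c in truth_map.labels[iy, ix]], dtype=object) if n else np.array([], object)

    models = config.resolved_marker_models()
    marker_cols = {}
    for m in MARKER_PANEL:
        mu = np.array([models[p][m][0] for p in pheno], float) if n else np.array([])
        sd = np.array([models[p][m][1] for p in pheno], float) if n else np.array([])
        for cls, boosts in CONTEXT_LOG_BOOST.items():
            if m in boosts and n:
                mu = mu + np.where(tissue_class == cls, boosts[m], 0.0)
        marker_cols[m] = np.exp(mu + sd * rng_m.standard_normal(n)) if n else np.array([])

    df = pd.DataFrame({
        "cell_id": [f"cell_{i:06d}" for i in range(n)],
        "x_um": imc_xy[:, 0] if n else [],
        "y_um": imc_xy[:, 1] if n else [],
        "area_um2": np.exp(rng_m.normal(np.log(100.0), 0.3, n)) if n else [],
        **marker_cols,
    })
    truth_df = pd.DataFrame({
        "cell_id": df["cell_id"],
        "tissue_class": tissue_class,
        "phenotype": pheno,
        "pixel_ix_truth": ix,
        "pixel_iy_truth": iy,
    })
    return CellTable(df, markers=list(MARKER_PANEL)), truth_df


# ---------------------------------------------------------------------------
# Orchestration, thresholds, bundles
# ---------------------------------------------------------------------------

def default_thresholds() -> dict[str, float]:
    """Positivity thresholds matched to the marker model geometry: the
    midpoint (geometric) between the negative and positive populations."""
    return {m: 3.0 for m in MARKER_PANEL}


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the paired MSI + IMC dataset with full ground truth."""
    label_map = generate_tissue_map(config)
    hot = generate_hot_mask(label_map, config)
    fields = expected_phenotype_density(label_map, hot, config)
    D0, planted_fraction = drug_noise_free_field(label_map, fields["M2_macrophage"], config)
    msi = generate_msi(label_map, config, m2_density=fields["M2_macrophage"])
    cells, cell_truth = generate_cells(label_map, config, density_fields=fields)

    tissue = label_map.labels > LABEL_CODES["background"]
    m2 = fields["M2_macrophage"]
    if tissue.sum() >= 3 and np.std(m2[tissue]) > 0 and np.std(D0[tissue]) > 0:
        corr = float(np.corrcoef(m2[tissue], D0[tissue])[0, 1])
    else:
        corr = float("nan")

    truth = SyntheticTruth(
        label_map=label_map,
        transform=config.transform_truth(),
        hot_mask=hot,
        drug_noise_free=D0,
        expected_m2_density=m2,
        planted_tumor_drug_fraction=planted_fraction,
        planted_enrichment_folds={"M2_macrophage": config.m2_enrichment_fold,
                                  "endothelial": config.endothelial_enrichment_fold},
        planted_marker_ion_correlations={"M2_density": corr},
        cell_truth=cell_truth,
    )
    return SyntheticBundle(config=config, msi=msi, cells=cells, truth=truth)


def generate_correlated_maps(
    shape: tuple[int, int],
    rho: float,
    seed: int,
    mean: float = 10.0,
    sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair of pixel maps whose values are bivariate normal with planted
    Pearson correlation ρ — the exact-oracle input for correlation
    recovery tests (shifted positive; Pearson r is shift-invariant)."""
    if not -1.0 < rho < 1.0:
        raise SyntheticConfigError("rho must be in (−1, 1)")
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    z = rng.standard_normal((n, 2))
    a = z[:, 0]
    b = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
    A = np.clip(mean + sd * a, 0.0, None).reshape(shape)
    B = np.clip(mean + sd * b, 0.0, None).reshape(shape)
    return A, B


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir: str) -> None:
    """Write the bundle: imzML (+ binary .ibd), cell CSV, truth sidecars
    (label map CSV, transform JSON, scalar truth YAML, cell truth CSV),
    and a manifest with the seed and config hash."""
    os.makedirs(outdir, exist_ok=True)
    write_imzml(bundle.msi, os.path.join(outdir, "msi.imzML"))
    bundle.cells.to_csv(os.path.join(outdir, "cells.csv"))
    bundle.truth.label_map.to_csv(os.path.join(outdir, "truth_labels.csv"))
    bundle.truth.transform.to_json(os.path.join(outdir, "truth_transform.json"))
    bundle.truth.cell_truth.to_csv(os.path.join(outdir, "cell_truth.csv"), index=False)
    pd.DataFrame(bundle.truth.hot_mask.astype(int)).to_csv(
        os.path.join(outdir, "truth_hot_mask.csv"), index=False, header=False)
    pd.DataFrame(bundle.truth.drug_noise_free).to_csv(
        os.path.join(outdir, "truth_drug_field.csv"), index=False, header=False)
    scalars = {
        "planted_tumor_drug_fraction": bundle.truth.planted_tumor_drug_fraction,
        "planted_enrichment_folds": bundle.truth.planted_enrichment_folds,
        "planted_marker_ion_correlations": bundle.truth.planted_marker_ion_correlations,
    }
    with open(os.path.join(outdir, "truth.yaml"), "w") as fh:
        yaml.safe_dump(scalars, fh)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump({"seed": bundle.config.seed,
                   "config_hash": bundle.config.config_hash()}, fh, indent=2)


def load_bundle(outdir: str) -> SyntheticBundle:
    with open(os.path.join(outdir, "config.yaml")) as fh:
        config = SyntheticConfig.from_dict(yaml.safe_load(fh))
    msi = load_imzml(os.path.join(outdir, "msi.imzML"),
                     pixel_size_x_um=config.pixel_size_x_um,
                     pixel_size_y_um=config.pixel_size_y_um)
    cells = CellTable.from_csv(os.path.join(outdir, "cells.csv"))
    label_map = TissueLabelMap.from_csv(os.path.join(outdir, "truth_labels.csv"))
    label_map.provenance[:] = PROV_TRUTH
    with open(os.path.join(outdir, "truth.yaml")) as fh:
        scalars = yaml.safe_load(fh)
    truth = SyntheticTruth(
        label_map=label_map,
        transform=AffineTransform2D.from_json(os.path.join(outdir, "truth_transform.json")),
        hot_mask=pd.read_csv(os.path.join(outdir, "truth_hot_mask.csv"),
                             header=None).to_numpy(bool),
        drug_noise_free=pd.read_csv(os.path.join(outdir, "truth_drug_field.csv"),
                                    header=None).to_numpy(float),
        expected_m2_density=np.zeros(label_map.shape),
        planted_tumor_drug_fraction=float(scalars["planted_tumor_drug_fraction"]),
        planted_enrichment_folds=scalars["planted_enrichment_folds"],
        planted_marker_ion_correlations=scalars["planted_marker_ion_correlations"],
        cell_truth=pd.read_csv(os.path.join(outdir, "cell_truth.csv")),
    )
    return SyntheticBundle(config=config, msi=msi, cells=cells, truth=truth)
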