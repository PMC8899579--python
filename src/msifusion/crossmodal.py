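"""Cross-modal correlation and drug-stratified phenotype enrichment.

Realizes IMC markers as pixel-aligned maps (mean marker intensity or
phenotype-positive cell counts per MSI pixel), correlates them with MSI ion
images (Pearson), selects heterogeneous regions of interest on the drug ion
image, splits regions into high- and low-drug halves, and quantifies
phenotype cell-density enrichment between the halves — the analysis that
asks which cell populations co-locate with high local drug content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imc import CellTable, IMCError, canonical_marker
from .msi import IonImage


class CrossmodalError(ValueError):
    pass


def _require_pixels(cells: CellTable) -> pd.DataFrame:
    for col in ("pixel_ix", "pixel_iy", "in_bounds"):
        if col not in cells.data.columns:
            raise CrossmodalError("cells lack pixel indices; run transform_cells first")
    return cells.data[cells.data["in_bounds"]]


def rasterize_marker(
    cells: CellTable,
    channel: str,
    shape: tuple[int, int],
    agg: str = "mean",
) -> np.ndarray:
    """Per-pixel aggregate of a marker (``agg="mean"``) or phenotype count
    (``channel="phenotype:<name>"``) over the cells in each MSI pixel.

    Pixels containing no cell are NaN (the marker map is undefined there).
    """
    df = _require_pixels(cells)
    ny, nx = shape
    out = np.full(shape, np.nan)
    if channel.startswith("phenotype:"):
        name = channel.split(":", 1)[1]
        col = f"pheno_{name}"
        if col not in df.columns:
            raise IMCError(f"unknown phenotype {name!r}")
        vals = df[col].to_numpy(float)
        agg = "sum"
    else:
        name = canonical_marker(channel)
        if name not in df.columns:
            raise IMCError(f"unknown marker {channel!r}")
        vals = df[name].to_numpy(float)
    flat = df["pixel_iy"].to_numpy(int) * nx + df["pixel_ix"].to_numpy(int)
    sums = np.bincount(flat, weights=vals, minlength=ny * nx).astype(float)
    counts = np.bincount(flat, minlength=ny * nx).astype(float)
    occupied = counts > 0
    if agg == "mean":
        res = np.where(occupied, sums / np.where(occupied, counts, 1), np.nan)
    elif agg == "sum":
        res = np.where(occupied, sums, np.nan)
    elif agg == "count":
        res = np.where(occupied, counts, np.nan)
    else:
        raise CrossmodalError(f"unknown aggregation {agg!r}")
    out = res.reshape(ny, nx)
    return out


@dataclass
class CorrelationResult:
    name: str
    r: float
    n_pixels: int
    method: str = "pearson"
    reason: str = ""


def pearson_map_correlation(
    map_a: np.ndarray, ion: IonImage | np.ndarray, mask: np.ndarray | None = None
) -> CorrelationResult:
    """Pearson correlation between a marker map and an ion image over
    jointly valid (finite, masked, in-tissue) pixels."""
    a = np.asarray(map_a, dtype=float)
    if isinstance(ion, IonImage):
        b, bvalid = ion.values, ion.valid_mask
    else:
        b, bvalid = np.asarray(ion, dtype=float), np.isfinite(ion)
    if a.shape != b.shape:
        raise CrossmodalError("map shapes differ")
    valid = np.isfinite(a) & np.isfinite(b) & bvalid
    if mask is not None:
        valid &= np.asarray(mask, bool)
    n = int(valid.sum())
    if n < 3:
        return CorrelationResult("", float("nan"), n, reason="fewer than 3 valid pixels")
    av, bv = a[valid], b[valid]
    if av.std() == 0 or bv.std() == 0:
        return CorrelationResult("", float("nan"), n, reason="zero variance")
    r, _ = stats.pearsonr(av, bv)
    return CorrelationResult("", float(r), n)


def fisher_z_interval(rho: float, n: int, confidence: float = 0.99) -> tuple[float, float]:
    """Sampling interval for a Pearson r around a true ρ at sample size n."""
    z = np.arctanh(rho)
    half = stats.norm.ppf(0.5 + confidence / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def select_heterogeneous_roi(
    drug: IonImage,
    roi_size_px: tuple[int, int],
    stride: int = 1,
) -> tuple[int, int, int, int]:
    """Scan candidate rectangles and return the one maximizing the
    interquartile range of valid drug intensity (ix0, iy0, w, h) — the
    region containing both high and low drug content. Ties resolve to the
    first candidate in scan order (row-major)."""
    w, h = roi_size_px
    ny, nx = drug.values.shape
    if w > nx or h > ny:
        raise CrossmodalError(f"ROI {w}×{h} exceeds grid {nx}×{ny}")
    best, best_iqr = None, -np.inf
    vals = np.where(drug.valid_mask, drug.values, np.nan)
    for iy in range(0, ny - h + 1, stride):
        for ix in range(0, nx - w + 1, stride):
            block = vals[iy:iy + h, ix:ix + w]
            finite = block[np.isfinite(block)]
            if finite.size < 2:
                continue
            q75, q25 = np.percentile(finite, [75, 25])
            if q75 - q25 > best_iqr:
                best_iqr, best = q75 - q25, (ix, iy, w, h)
    if best is None:
        raise CrossmodalError("no candidate ROI contains valid drug pixels")
    return best


def stratify_high_low(
    drug: IonImage,
    region_mask: np.ndarray,
    method: str = "median",
    quantile: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a region's pixels into high- and low-drug masks.

    ``method="median"`` splits at the within-region median (strictly above
    → high); ``method="quantile"`` splits at the given quantile. The two
    masks are disjoint and their union is the valid region.
    """
    region = np.asarray(region_mask, bool) & drug.valid_mask
    vals = drug.values[region]
    if vals.size < 2:
        raise CrossmodalError("region must contain at least 2 valid pixels")
    if vals.max() == vals.min():
        raise CrossmodalError("no contrast: drug intensity constant in region")
    if method == "median":
        thr = np.median(vals)
    elif method == "quantile":
        thr = np.quantile(vals, quantile)
    else:
        raise CrossmodalError(f"unknown stratification method {method!r}")
    high = region & (drug.values > thr)
    low = region & ~high
    return high, low


@dataclass
class EnrichmentResult:
    phenotype: str
    density_high_per_mm2: float
    density_low_per_mm2: float
    fold: float  # inf flags an undefined ratio (no cells in the low mask)

    @property
    def fold_defined(self) -> bool:
        return np.isfinite(self.fold)


def phenotype_enrichment(
    cells: CellTable,
    mask_high: np.ndarray,
    mask_low: np.ndarray,
    pixel_area_mm2: float,
    phenotypes: list[str],
) -> pd.DataFrame:
    """Cell density (per mm²) of each phenotype in the high- vs low-drug
    masks and the high/low fold change.

    Densities use the nominal MSI pixel area (50 × 75 µm² = 3,750 µm² by
    default geometry); cells out of bounds of the grid are in neither mask.
    A zero low-mask density yields ``fold = inf`` (flag, not a number to
    aggregate).
    """
    mask_high = np.asarray(mask_high, bool)
    mask_low = np.asarray(mask_low, bool)
    if (mask_high & mask_low).any():
        raise CrossmodalError("high/low masks overlap")
    df = _require_pixels(cells)
    ny, nx = mask_high.shape
    flat = df["pixel_iy"].to_numpy(int) * nx + df["pixel_ix"].to_numpy(int)
    in_high = mask_high.ravel()[flat]
    in_low = mask_low.ravel()[flat]
    area_high = mask_high.sum() * pixel_area_mm2
    area_low = mask_low.sum() * pixel_area_mm2
    rows = []
    for name in phenotypes:
        col = f"pheno_{name}"
        if col not in df.columns:
            raise IMCError(f"unknown phenotype {name!r}")
        pos = df[col].to_numpy(bool)
        d_hi = pos[in_high].sum() / area_high if area_high > 0 else float("nan")
        d_lo = pos[in_low].sum() / area_low if area_low > 0 else float("nan")
        fold = d_hi / d_lo if d_lo > 0 else float("inf")
        rows.append(EnrichmentResult(name, float(d_hi), float(d_lo), float(fold)))
    return pd.DataFrame([r.__dict__ for r in rows])
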