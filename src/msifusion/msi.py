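"""MSI data model and preprocessing.

Holds the peak-reduced DESI-MSI data as a pixel × peak intensity matrix on a
rectangular grid with anisotropic pixels (50 µm in x, 75 µm in y by default),
and provides the standard preprocessing steps the downstream fusion expects:
k-means background removal, TIC normalization, ion-image extraction within an
m/z window, and normalization of one ion image to a reference ion.

Pixel convention: 0-based, row-major; pixel (ix, iy) spans the half-open
rectangle [ix·sx, (ix+1)·sx) × [iy·sy, (iy+1)·sy) in µm, so a point at
x = ix·sx lies in pixel ix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter
from sklearn.cluster import KMeans

DEFAULT_PIXEL_SIZE_X_UM = 50.0
DEFAULT_PIXEL_SIZE_Y_UM = 75.0


class MSIError(ValueError):
    """Raised on malformed MSI inputs or invalid preprocessing requests."""


@dataclass
class MSIDataset:
    """Peak-reduced MSI dataset on a rectangular pixel grid.

    Parameters
    ----------
    mz_axis
        Strictly increasing peak centroids in Th, shape ``(n_peaks,)``.
    intensities
        Nonnegative matrix, shape ``(n_pixels, n_peaks)``.
    pixel_coords
        Integer ``(ix, iy)`` indices per pixel, shape ``(n_pixels, 2)``;
        each pair unique and within ``[0, nx) × [0, ny)``.
    nx, ny
        Grid dimensions.
    tissue_mask
        Boolean per-pixel mask; ``True`` marks tissue. Defaults to all-tissue
        until :func:`detect_background` is applied.
    """

    mz_axis: np.ndarray
    intensities: np.ndarray
    pixel_coords: np.ndarray
    nx: int
    ny: int
    pixel_size_x_um: float = DEFAULT_PIXEL_SIZE_X_UM
    pixel_size_y_um: float = DEFAULT_PIXEL_SIZE_Y_UM
    tissue_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=int)
        if self.tissue_mask is None:
            self.tissue_mask = np.ones(self.n_pixels, dtype=bool)
        else:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.mz_axis.ndim != 1 or self.intensities.ndim != 2:
            raise MSIError("mz_axis must be 1-D and intensities 2-D")
        if self.intensities.shape != (self.n_pixels, self.n_peaks):
            raise MSIError(
                f"intensities shape {self.intensities.shape} does not match "
                f"({self.n_pixels} pixels, {self.n_peaks} peaks)"
            )
        if np.any(np.diff(self.mz_axis) <= 0):
            raise MSIError("mz_axis must be strictly increasing")
        if np.any(self.intensities < 0):
            raise MSIError("intensities must be nonnegative")
        if self.pixel_coords.shape != (self.n_pixels, 2):
            raise MSIError("pixel_coords must have shape (n_pixels, 2)")
        ix, iy = self.pixel_coords[:, 0], self.pixel_coords[:, 1]
        if ix.size and (ix.min() < 0 or iy.min() < 0 or ix.max() >= self.nx or iy.max() >= self.ny):
            raise MSIError("pixel coordinates outside grid")
        flat = iy * self.nx + ix
        if np.unique(flat).size != flat.size:
            raise MSIError("duplicate pixel coordinates")
        if self.tissue_mask.shape != (self.n_pixels,):
            raise MSIError("tissue_mask must be per-pixel")

    # -- basic accessors -------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return self.pixel_coords.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.mz_axis.shape[0]

    def tic(self) -> np.ndarray:
        """Total ion current per pixel (sum over peaks)."""
        return self.intensities.sum(axis=1)

    def to_image(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-pixel vector onto the (ny, nx) grid."""
        values = np.asarray(values)
        img = np.full((self.ny, self.nx), fill, dtype=float)
        img[self.pixel_coords[:, 1], self.pixel_coords[:, 0]] = values
        return img

    def mask_image(self) -> np.ndarray:
        """Tissue mask as a (ny, nx) boolean image (off-grid pixels False)."""
        img = np.zeros((self.ny, self.nx), dtype=bool)
        img[self.pixel_coords[:, 1], self.pixel_coords[:, 0]] = self.tissue_mask
        return img

    def peaks_in_window(self, mz_center: float, mz_tol: float) -> np.ndarray:
        return np.nonzero(np.abs(self.mz_axis - mz_center) <= mz_tol)[0]


@dataclass
class IonImage:
    """2-D map of summed intensity within one m/z window."""

    values: np.ndarray  # (ny, nx)
    valid_mask: np.ndarray  # (ny, nx) bool
    mz_center: float
    mz_tol: float
    pixel_size_x_um: float = DEFAULT_PIXEL_SIZE_X_UM
    pixel_size_y_um: float = DEFAULT_PIXEL_SIZE_Y_UM
    normalization_tag: str = "raw"  # raw | tic | reference_ion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise MSIError("values and valid_mask shapes differ")
        if np.any(self.values[self.valid_mask] < 0):
            raise MSIError("ion image negative on valid pixels")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_x_um * self.pixel_size_y_um / 1e6


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def write_imzml(ds: MSIDataset, path: str) -> None:
    """Write the dataset as processed-mode imzML (per-spectrum peak lists)."""
    with ImzMLWriter(path, mode="processed") as w:
        for i in range(ds.n_pixels):
            ix, iy = ds.pixel_coords[i]
            # imzML coordinates are 1-based
            w.addSpectrum(ds.mz_axis, ds.intensities[i], (int(ix) + 1, int(iy) + 1, 1))


def load_imzml(
    path: str,
    pixel_size_x_um: float | None = None,
    pixel_size_y_um: float | None = None,
    mz_decimals: int = 5,
) -> MSIDataset:
    """Load a processed- or continuous-mode imzML file.

    Spectra may carry per-pixel peak lists; the dataset's m/z axis is the
    union of all centroids after rounding to ``mz_decimals``. Pixel sizes
    are taken from file metadata when present, else from the arguments,
    else the DESI defaults (50 × 75 µm).
    """
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # pragma: no cover - delegated parsing
        raise MSIError(f"failed to parse imzML file {path!r}: {exc}") from exc

    coords = []
    spectra = []
    for i in range(len(parser.coordinates)):
        try:
            mzs, ints = parser.getspectrum(i)
        except Exception as exc:
            raise MSIError(f"malformed spectrum at index {i}: {exc}") from exc
        x, y = parser.coordinates[i][0], parser.coordinates[i][1]
        coords.append((x - 1, y - 1))
        spectra.append((np.round(np.asarray(mzs, float), mz_decimals), np.asarray(ints, float)))

    if not coords:
        raise MSIError("imzML file contains no spectra")
    if len(set(coords)) != len(coords):
        dup = [c for c in set(coords) if coords.count(c) > 1][0]
        raise MSIError(f"duplicate pixel coordinate {dup} in imzML file")

    axis = np.unique(np.concatenate([mz for mz, _ in spectra]))
    index = {mz: j for j, mz in enumerate(axis)}
    inten = np.zeros((len(coords), axis.size))
    for i, (mzs, ints) in enumerate(spectra):
        for mz, v in zip(mzs, ints):
            inten[i, index[mz]] += v

    sx = pixel_size_x_um or float(parser.imzmldict.get("pixel size x", 0)) or DEFAULT_PIXEL_SIZE_X_UM
    sy = pixel_size_y_um or float(parser.imzmldict.get("pixel size y", 0)) or DEFAULT_PIXEL_SIZE_Y_UM
    pc = np.array(coords, dtype=int)
    return MSIDataset(
        mz_axis=axis,
        intensities=inten,
        pixel_coords=pc,
        nx=int(pc[:, 0].max()) + 1,
        ny=int(pc[:, 1].max()) + 1,
        pixel_size_x_um=sx,
        pixel_size_y_um=sy,
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def detect_background(
    ds: MSIDataset,
    k: int = 2,
    n_top_peaks: int = 5,
    min_contrast: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Flag background pixels by k-means and return the tissue mask.

    Pixels are clustered on standardized features (log TIC plus the
    ``n_top_peaks`` highest-variance peak channels). The cluster with the
    lowest mean TIC is background, provided the highest-TIC cluster exceeds
    it by at least ``min_contrast``-fold; otherwise the dataset is treated
    as all tissue (a minimum-contrast guard for uniform inputs).
    """
    if ds.n_pixels <= k:
        raise MSIError(f"need more than k={k} pixels to cluster")
    tic = ds.tic()
    if not np.any(tic > 0):
        raise MSIError("no tissue detected: all spectra are zero")

    order = np.argsort(ds.intensities.var(axis=0))[::-1][:n_top_peaks]
    feats = np.column_stack([np.log1p(tic), np.log1p(ds.intensities[:, order])])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
    cluster_tic = np.array([tic[km.labels_ == c].mean() for c in range(k)])
    lo, hi = cluster_tic.min(), cluster_tic.max()
    if hi < min_contrast * max(lo, np.finfo(float).tiny) and lo > 0:
        return np.ones(ds.n_pixels, dtype=bool)
    background = km.labels_ == int(np.argmin(cluster_tic))
    return ~background


def tic_normalize(ds: MSIDataset) -> MSIDataset:
    """Divide each pixel's peak vector by its TIC.

    Tissue pixels with zero TIC cannot be normalized; they are dropped from
    the tissue mask with a warning. Idempotent: renormalizing a normalized
    dataset leaves it unchanged.
    """
    tic = ds.tic()
    mask = ds.tissue_mask.copy()
    bad = mask & (tic <= 0)
    if np.any(bad):
        warnings.warn(f"dropping {int(bad.sum())} zero-TIC tissue pixel(s) from mask")
        mask[bad] = False
    safe = np.where(tic > 0, tic, 1.0)
    return replace(
        ds,
        intensities=ds.intensities / safe[:, None],
        tissue_mask=mask,
        normalization="tic",
    )


def extract_ion_image(
    ds: MSIDataset, mz_center: float, mz_tol: float, fill: float = 0.0
) -> IonImage:
    """Sum intensities of all peaks with |mz − center| ≤ tol per pixel.

    Pixels outside the tissue mask are marked invalid (their values are
    still computed; consumers should honor ``valid_mask``).
    """
    sel = ds.peaks_in_window(mz_center, mz_tol)
    if sel.size == 0:
        nearest = ds.mz_axis[np.argsort(np.abs(ds.mz_axis - mz_center))[:3]]
        raise MSIError(
            f"no peaks within {mz_center} ± {mz_tol} Th; nearest peaks: "
            + ", ".join(f"{m:.4f}" for m in nearest)
        )
    vec = ds.intensities[:, sel].sum(axis=1)
    return IonImage(
        values=ds.to_image(vec, fill=fill),
        valid_mask=ds.mask_image(),
        mz_center=mz_center,
        mz_tol=mz_tol,
        pixel_size_x_um=ds.pixel_size_x_um,
        pixel_size_y_um=ds.pixel_size_y_um,
        normalization_tag="tic" if ds.normalization == "tic" else "raw",
    )


def spectral_features(
    ds: MSIDataset, exclude_mz: list[tuple[float, float]] | None = None
) -> np.ndarray:
    """Per-pixel feature matrix for pixel-level learning: TIC-normalized,
    per-peak standardized intensities.

    Peaks within the ``exclude_mz`` (center, tol) windows — typically the
    drug, its reference and its metabolite — are dropped so that tissue
    classification is not driven by the analyte being quantified.
    """
    norm = ds if ds.normalization == "tic" else tic_normalize(ds)
    keep = np.ones(ds.n_peaks, dtype=bool)
    for mz, tol in exclude_mz or []:
        keep &= np.abs(ds.mz_axis - mz) > tol
    X = norm.intensities[:, keep]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def normalize_to_reference(
    drug: IonImage, ref: IonImage, min_ref: float | None = None
) -> IonImage:
    """Per-pixel ratio of a drug ion image to a reference (structural
    analogue) ion image.

    Pixels where the reference falls below ``min_ref`` are invalidated
    rather than producing unstable ratios. ``min_ref`` defaults to the 1st
    percentile of positive reference intensities on valid pixels.
    """
    if drug.values.shape != ref.values.shape:
        raise MSIError("drug and reference images are on different grids")
    if min_ref is None:
        pos = ref.values[ref.valid_mask & (ref.values > 0)]
        min_ref = float(np.percentile(pos, 1)) if pos.size else np.finfo(float).tiny
    valid = drug.valid_mask & ref.valid_mask & (ref.values >= min_ref)
    out = np.zeros_like(drug.values)
    out[valid] = drug.values[valid] / ref.values[valid]
    return IonImage(
        values=out,
        valid_mask=valid,
        mz_center=drug.mz_center,
        mz_tol=drug.mz_tol,
        pixel_size_x_um=drug.pixel_size_x_um,
        pixel_size_y_um=drug.pixel_size_y_um,
        normalization_tag="reference_ion",
    )
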