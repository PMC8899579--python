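"""Cross-modality co-registration.

Builds representative single-channel images for both modalities (TIC for
MSI, a binned cell raster for IMC), estimates the affine/similarity map
between the IMC and MSI physical frames by intensity-based registration
(SimpleITK, Mattes mutual information, multi-resolution), and transfers
cell centroids into MSI pixel indices.

All registration happens in physical µm. The anisotropic MSI pixels
(50 × 75 µm) are handled by resampling both representative images onto a
common isotropic working grid (25 µm by default) before optimization, since
intensity similarity metrics assume square pixels. A fully deterministic
landmark (point-pair least-squares) mode is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from sklearn.cluster import KMeans

from .imc import CellTable, IMCError, canonical_marker
from .msi import MSIDataset, spectral_features


class RegistrationError(ValueError):
    pass


@dataclass
class AffineTransform2D:
    """Invertible 2-D affine map ``y = linear @ x + translation`` between
    physical frames (µm), by convention from the IMC frame to the MSI frame."""

    linear: np.ndarray
    translation: np.ndarray
    frame_from: str = "IMC_um"
    frame_to: str = "MSI_um"

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise RegistrationError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_similarity(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation_um: tuple[float, float] = (0.0, 0.0),
        **kw,
    ) -> "AffineTransform2D":
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(scale * rot, np.asarray(translation_um, float), **kw)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(inv, -inv @ self.translation,
                                 frame_from=self.frame_to, frame_to=self.frame_from)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self ∘ other (apply ``other`` first)."""
        return AffineTransform2D(self.linear @ other.linear,
                                 self.linear @ other.translation + self.translation,
                                 frame_from=other.frame_from, frame_to=self.frame_to)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"linear": self.linear.tolist(),
                       "translation": self.translation.tolist(),
                       "frame_from": self.frame_from, "frame_to": self.frame_to},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "AffineTransform2D":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["linear"]), np.array(d["translation"]),
                   frame_from=d["frame_from"], frame_to=d["frame_to"])


@dataclass
class RegistrationReport:
    similarity_metric_value: float
    converged: bool
    mean_landmark_error_um: float = float("nan")
    stop_condition: str = ""


@dataclass
class RasterImage:
    """Single-channel image with physical geometry: ``origin`` is the
    physical position (µm) of the *center* of pixel (0, 0)."""

    values: np.ndarray  # (ny, nx)
    origin: tuple[float, float]
    spacing: tuple[float, float]  # (sx, sy) µm
    low_contrast: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def extent_corners(self) -> np.ndarray:
        """Physical corners (outer pixel edges) of the image, shape (4, 2)."""
        ny, nx = self.values.shape
        x0 = self.origin[0] - self.spacing[0] / 2
        y0 = self.origin[1] - self.spacing[1] / 2
        x1, y1 = x0 + nx * self.spacing[0], y0 + ny * self.spacing[1]
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


def representative_image_msi(ds: MSIDataset) -> RasterImage:
    """TIC image on the MSI grid rescaled to [0, 1]."""
    if ds.n_pixels == 0:
        raise RegistrationError("empty MSI dataset")
    img = ds.to_image(ds.tic(), fill=0.0)
    lo, hi = img.min(), img.max()
    low_contrast = hi <= lo
    if not low_contrast:
        img = (img - lo) / (hi - lo)
    return RasterImage(img, origin=(ds.pixel_size_x_um / 2, ds.pixel_size_y_um / 2),
                       spacing=(ds.pixel_size_x_um, ds.pixel_size_y_um),
                       low_contrast=low_contrast)


def representative_image_imc(
    cells: CellTable,
    channel: str = "total_intensity",
    pitch_um: float = 25.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> RasterImage:
    """Binned raster of a cell channel in the IMC frame, rescaled to [0, 1].

    ``channel`` is ``"total_intensity"`` (sum over all markers, the default
    representative content), ``"count"`` (cell density), or a marker name.
    """
    if len(cells) == 0:
        raise RegistrationError("empty cell table")
    x = cells.data["x_um"].to_numpy(float)
    y = cells.data["y_um"].to_numpy(float)
    if channel == "count":
        w = np.ones_like(x)
    elif channel == "total_intensity":
        w = cells.data[cells.markers].to_numpy(float).sum(axis=1)
    else:
        name = canonical_marker(channel)
        if name not in cells.data.columns:
            raise IMCError(f"unknown channel {channel!r}")
        w = cells.data[name].to_numpy(float)
    if bounds is None:
        bounds = (x.min(), y.min(), x.max(), y.max())
    x0, y0, x1, y1 = bounds
    nx = max(int(np.ceil((x1 - x0) / pitch_um)), 1)
    ny = max(int(np.ceil((y1 - y0) / pitch_um)), 1)
    ixs = np.clip(((x - x0) / pitch_um).astype(int), 0, nx - 1)
    iys = np.clip(((y - y0) / pitch_um).astype(int), 0, ny - 1)
    img = np.zeros((ny, nx))
    np.add.at(img, (iys, ixs), w)
    hi = img.max()
    low_contrast = hi <= img.min()
    if hi > 0:
        img = img / hi
    return RasterImage(img, origin=(x0 + pitch_um / 2, y0 + pitch_um / 2),
                       spacing=(pitch_um, pitch_um), low_contrast=low_contrast)


# ---------------------------------------------------------------------------
# Intensity-based estimation
# ---------------------------------------------------------------------------

def _to_sitk(img: RasterImage, working_pitch: float | None) -> sitk.Image:
    im = sitk.GetImageFromArray(img.values.astype(np.float64))
    im.SetSpacing(tuple(float(s) for s in img.spacing))
    im.SetOrigin(tuple(float(o) for o in img.origin))
    if working_pitch is None or img.spacing == (working_pitch, working_pitch):
        return im
    # resample to the isotropic working grid covering the same extent
    nx = int(np.ceil(img.values.shape[1] * img.spacing[0] / working_pitch))
    ny = int(np.ceil(img.values.shape[0] * img.spacing[1] / working_pitch))
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((working_pitch, working_pitch))
    res.SetSize((nx, ny))
    res.SetOutputOrigin((img.origin[0] - img.spacing[0] / 2 + working_pitch / 2,
                         img.origin[1] - img.spacing[1] / 2 + working_pitch / 2))
    res.SetInterpolator(sitk.sitkLinear)
    res.SetDefaultPixelValue(0.0)
    return res.Execute(im)


def _probe_affine(t: sitk.Transform) -> AffineTransform2D:
    """Extract the affine map realized by a SimpleITK transform by probing
    three points (robust to center-of-rotation conventions)."""
    o = np.array(t.TransformPoint((0.0, 0.0)))
    ex = np.array(t.TransformPoint((1.0, 0.0))) - o
    ey = np.array(t.TransformPoint((0.0, 1.0))) - o
    return AffineTransform2D(np.column_stack([ex, ey]), o)


def estimate_transform(
    fixed: RasterImage,
    moving: RasterImage,
    model: str = "similarity",
    metric: str = "mattes",
    init: AffineTransform2D | None = None,
    working_pitch_um: float = 25.0,
    n_bins: int = 32,
    seed: int = 0,
) -> tuple[AffineTransform2D, RegistrationReport]:
    """Estimate the moving→fixed (IMC→MSI) map by intensity registration.

    Multi-resolution (shrink 4/2/1) with Mattes mutual information
    (``n_bins`` histogram bins, full sampling — deterministic) or
    ``metric="correlation"``. ``model`` is ``"similarity"``
    (rotation + isotropic scale + translation, the default) or ``"affine"``.
    Returns the estimated transform from the moving image's frame to the
    fixed image's frame together with a convergence report.
    """
    for name, img in (("fixed", fixed), ("moving", moving)):
        if img.values.std() == 0:
            raise RegistrationError(f"no contrast in {name} image")

    fi = _to_sitk(fixed, working_pitch_um)
    mi = _to_sitk(moving, working_pitch_um)

    if model == "similarity":
        tx = sitk.Similarity2DTransform()
    elif model == "affine":
        tx = sitk.AffineTransform(2)
    else:
        raise RegistrationError(f"unknown transform model {model!r}")

    if init is not None:
        # init maps moving→fixed; sitk wants fixed→moving (resampling convention)
        inv = init.inverse()
        if model == "similarity":
            tx = sitk.Similarity2DTransform()
            tx.SetMatrix(tuple(inv.linear.ravel()))
            tx.SetTranslation(tuple(inv.translation))
        else:
            tx.SetMatrix(tuple(inv.linear.ravel()))
            tx.SetTranslation(tuple(inv.translation))
        initial = sitk.Transform(tx)
    else:
        initial = sitk.CenteredTransformInitializer(
            fi, mi, tx, sitk.CenteredTransformInitializerFilter.MOMENTS
        )

    reg = sitk.ImageRegistrationMethod()
    if metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=n_bins)
    elif metric == "correlation":
        reg.SetMetricAsCorrelation()
    else:
        raise RegistrationError(f"unknown metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)  # all pixels: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=False)

    final = reg.Execute(fi, mi)
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "Maximum number of iterations" not in stop
    # final maps fixed→moving; the IMC→MSI map is its inverse
    est = _probe_affine(final).inverse()
    est.frame_from, est.frame_to = "IMC_um", "MSI_um"
    report = RegistrationReport(
        similarity_metric_value=float(reg.GetMetricValue()),
        converged=converged, stop_condition=stop,
    )
    return est, report


def estimate_transform_landmarks(
    points_imc: np.ndarray, points_msi: np.ndarray
) -> tuple[AffineTransform2D, RegistrationReport]:
    """Deterministic least-squares affine fit to ≥ 3 point pairs."""
    src = np.atleast_2d(np.asarray(points_imc, float))
    dst = np.atleast_2d(np.asarray(points_msi, float))
    if src.shape != dst.shape or src.shape[0] < 3:
        raise RegistrationError("need at least 3 matching point pairs")
    A = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    t = AffineTransform2D(coef[:2].T, coef[2])
    resid = t.apply(src) - dst
    err = float(np.linalg.norm(resid, axis=1).mean())
    return t, RegistrationReport(similarity_metric_value=err, converged=True,
                                 mean_landmark_error_um=err)


def refine_transform_poisson(
    ds: MSIDataset,
    cells: CellTable,
    init: AffineTransform2D,
    n_clusters: int = 8,
    n_outer: int = 3,
    background_density: float = 1e-3,
    seed: int = 0,
) -> tuple[AffineTransform2D, RegistrationReport]:
    """Refine an IMC→MSI similarity transform against the cell point pattern.

    The intensity-based estimate is limited by the raster noise of the cell
    image and by contrast mismatch between modalities. This refinement uses
    the cells directly: MSI pixels are clustered on their spectra (k-means,
    unsupervised — no tissue labels involved), each cluster's cell density
    is estimated under the current transform, and the similarity parameters
    are then optimized to maximize the inhomogeneous-Poisson log-likelihood
    of the mapped cell positions under that piecewise-constant density
    field. Density estimation and optimization alternate ``n_outer`` times.

    Optimization is a deterministic coarse-to-fine pattern search over
    (rotation, log-scale, translation) about the cell centroid; cells mapped
    off the grid are scored at ``background_density`` (cells/mm²), which
    penalizes transforms pushing cells off tissue.
    """
    C = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(
        spectral_features(ds, None)).labels_
    cluster_img = np.full((ds.ny, ds.nx), -1, dtype=int)
    cluster_img[ds.pixel_coords[:, 1], ds.pixel_coords[:, 0]] = C
    sx, sy = ds.pixel_size_x_um, ds.pixel_size_y_um
    area_c = np.bincount(C, minlength=n_clusters) * sx * sy / 1e6  # mm²

    xy = cells.data[["x_um", "y_um"]].to_numpy(float)
    if len(xy) == 0:
        raise RegistrationError("empty cell table")
    c0 = xy.mean(axis=0)
    r_max = max(float(np.abs(xy - c0).max()), 1.0)
    log_bg = np.log(background_density)

    def t_from(p: np.ndarray) -> AffineTransform2D:
        th, ls, tx, ty = p
        lin = np.exp(ls) * np.array([[np.cos(th), -np.sin(th)],
                                     [np.sin(th), np.cos(th)]])
        return AffineTransform2D(lin, c0 + np.array([tx, ty]) - lin @ c0)

    def params_from(t: AffineTransform2D) -> np.ndarray:
        s = np.sqrt(abs(np.linalg.det(t.linear)))
        th = np.arctan2(t.linear[1, 0], t.linear[0, 0])
        tr = t.apply(c0)[0] - c0
        return np.array([th, np.log(s), tr[0], tr[1]])

    t = init
    nll_val = np.inf
    for _ in range(n_outer):
        pts = t.apply(xy)
        jx = np.floor(pts[:, 0] / sx).astype(int)
        jy = np.floor(pts[:, 1] / sy).astype(int)
        ok = (jx >= 0) & (jx < ds.nx) & (jy >= 0) & (jy < ds.ny)
        counts = np.bincount(cluster_img[jy[ok], jx[ok]], minlength=n_clusters)
        rho = np.maximum(counts / np.maximum(area_c, 1e-12), background_density)
        log_density = np.log(rho)[cluster_img]
        log_density[cluster_img < 0] = log_bg

        def nll(p: np.ndarray) -> float:
            q = t_from(p).apply(xy)
            kx = np.floor(q[:, 0] / sx).astype(int)
            ky = np.floor(q[:, 1] / sy).astype(int)
            inb = (kx >= 0) & (kx < ds.nx) & (ky >= 0) & (ky < ds.ny)
            ll = np.full(len(q), log_bg)
            ll[inb] = log_density[ky[inb], kx[inb]]
            return -float(ll.sum())

        p = params_from(t)
        f = nll(p)
        step = 64.0  # µm; angle/scale steps scaled to the same displacement
        scales = np.array([1.0 / r_max, 1.0 / r_max, 1.0, 1.0])
        while step >= 0.25:
            improved = True
            while improved:
                improved = False
                for i in range(4):
                    for sgn in (1.0, -1.0):
                        q = p.copy()
                        q[i] += sgn * step * scales[i]
                        fq = nll(q)
                        if fq < f:
                            p, f, improved = q, fq, True
            step /= 2
        t = t_from(p)
        nll_val = f
    report = RegistrationReport(similarity_metric_value=nll_val, converged=True,
                                stop_condition="pattern search step < 0.25 µm")
    return t, report


def mean_corner_error_um(
    estimated: AffineTransform2D,
    truth: AffineTransform2D,
    region: RasterImage | np.ndarray,
) -> float:
    """Mean displacement (µm) between the two transforms over the corners
    of a region (a RasterImage extent or an (n, 2) point array)."""
    pts = region.extent_corners() if isinstance(region, RasterImage) else np.atleast_2d(region)
    return float(np.linalg.norm(estimated.apply(pts) - truth.apply(pts), axis=1).mean())


def transform_cells(
    cells: CellTable, t: AffineTransform2D, grid: MSIDataset
) -> CellTable:
    """Map cell centroids into the MSI frame and assign pixel indices.

    Adds ``x_msi_um``/``y_msi_um``, ``pixel_ix``/``pixel_iy`` (half-open
    floor convention) and ``in_bounds``. Out-of-grid cells are retained but
    flagged, so no cell is silently dropped.
    """
    pts = t.apply(cells.data[["x_um", "y_um"]].to_numpy(float))
    ix = np.floor(pts[:, 0] / grid.pixel_size_x_um).astype(int)
    iy = np.floor(pts[:, 1] / grid.pixel_size_y_um).astype(int)
    inb = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    out = cells.copy()
    out.data = out.data.assign(x_msi_um=pts[:, 0], y_msi_um=pts[:, 1],
                               pixel_ix=ix, pixel_iy=iy, in_bounds=inb)
    return out
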