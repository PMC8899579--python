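"""IMC-seeded tissue classification of MSI pixels (label transfer).

The central fusion step: co-registered, tissue-classified IMC cells seed
MSI pixel labels by a strict majority vote (a pixel takes a class only when
strictly more than half of the cells falling in it carry that class); the
partial labeling, together with a background class from k-means, trains a
k-nearest-neighbor classifier (k = 30 by default) on the pixels' normalized
spectra; prediction then covers the entire MSI grid, including regions the
IMC never imaged. Per-class mean ion intensities summarize ions of interest
over the resulting compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .imc import CellTable, TISSUE_CLASSES
from .msi import MSIDataset, extract_ion_image, spectral_features

#: Integer codes for the label map. ``unassigned`` marks pixels the vote
#: left open; after kNN prediction every pixel carries one of the four
#: real classes.
UNASSIGNED = -1
BACKGROUND, TUMOR, CONNECTIVE, NECROSIS = 0, 1, 2, 3

LABEL_NAMES = {UNASSIGNED: "unassigned", BACKGROUND: "background",
               TUMOR: "tumor", CONNECTIVE: "connective", NECROSIS: "necrosis"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}
#: Fixed class order used for deterministic tie-breaking.
CLASS_ORDER = (TUMOR, CONNECTIVE, NECROSIS, BACKGROUND)

PROV_NONE, PROV_VOTE, PROV_KNN, PROV_KMEANS_BACKGROUND, PROV_TRUTH = 0, 1, 2, 3, 4
PROVENANCE_NAMES = {PROV_NONE: "none", PROV_VOTE: "vote", PROV_KNN: "knn",
                    PROV_KMEANS_BACKGROUND: "kmeans_background", PROV_TRUTH: "truth"}


class FusionError(ValueError):
    pass


@dataclass
class TissueLabelMap:
    """Per-pixel categorical tissue label field with provenance."""

    labels: np.ndarray  # (ny, nx) int8
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.provenance is None:
            self.provenance = np.full(self.labels.shape, PROV_NONE, dtype=np.int8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.int8)
        if self.provenance.shape != self.labels.shape:
            raise FusionError("labels and provenance shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_CODES[name]

    def class_fractions(self, classes=TISSUE_CLASSES) -> dict[str, float]:
        """Pixel fraction per class among all pixels of those classes."""
        counts = {c: int(self.mask(c).sum()) for c in classes}
        total = sum(counts.values())
        return {c: counts[c] / total if total else float("nan") for c in classes}

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.labels).to_csv(path, index=False, header=False)

    @classmethod
    def from_csv(cls, path: str) -> "TissueLabelMap":
        return cls(pd.read_csv(path, header=None).to_numpy(np.int8))


def majority_vote_labels(cells: CellTable, shape: tuple[int, int]) -> TissueLabelMap:
    """Label each MSI pixel by a strict majority of its cells' classes.

    A pixel is assigned class c iff strictly more than 50% of the in-bounds
    cells landing in it carry class c; pixels with no cells or no strict
    majority stay ``unassigned`` (an exact 50/50 split is NOT a majority).
    """
    for col in ("tissue_class", "pixel_ix", "pixel_iy", "in_bounds"):
        if col not in cells.data.columns:
            raise FusionError(f"cell table lacks column {col!r}; run tissue "
                              "classification and transform_cells first")
    ny, nx = shape
    labels = np.full(shape, UNASSIGNED, dtype=np.int8)
    prov = np.full(shape, PROV_NONE, dtype=np.int8)
    df = cells.data[cells.data["in_bounds"] & cells.data["tissue_class"].notna()]
    if len(df):
        counts = (df.groupby(["pixel_iy", "pixel_ix"])["tissue_class"]
                    .value_counts().unstack(fill_value=0))
        totals = counts.sum(axis=1)
        top = counts.max(axis=1)
        winner = counts.idxmax(axis=1)
        has_majority = top * 2 > totals
        for (iy, ix), cls in winner[has_majority].items():
            labels[iy, ix] = LABEL_CODES[cls]
            prov[iy, ix] = PROV_VOTE
    return TissueLabelMap(labels, prov)


def fit_predict_knn(
    ds: MSIDataset,
    partial: TissueLabelMap,
    background_mask: np.ndarray | None = None,
    k: int = 30,
    exclude_mz: list[tuple[float, float]] | None = None,
    cap_background: bool = True,
    seed: int = 0,
) -> TissueLabelMap:
    """Extend a partial (vote) labeling to every MSI pixel with kNN.

    Training pixels are the vote-labeled ones plus a background class taken
    from ``background_mask`` (pixels flagged non-tissue by k-means; defaults
    to the complement of ``ds.tissue_mask``). Background training pixels are
    capped at the median per-class vote count to avoid swamping the vote
    classes. Prediction covers the entire grid. Ties are broken by smallest
    aggregate neighbor distance, then by fixed class order.
    """
    ny, nx = partial.shape
    if (ny, nx) != (ds.ny, ds.nx):
        raise FusionError("label map and MSI grid dimensions differ")
    X_all = spectral_features(ds, exclude_mz)
    flat_ix = ds.pixel_coords[:, 1] * nx + ds.pixel_coords[:, 0]
    lab_flat = partial.labels.ravel()[flat_ix]

    train_idx = np.nonzero(lab_flat > BACKGROUND)[0]
    train_lab = lab_flat[train_idx]

    if background_mask is None:
        background_mask = ~ds.mask_image()
    bg_idx = np.nonzero(np.asarray(background_mask, bool).ravel()[flat_ix])[0]
    if bg_idx.size:
        if cap_background and train_idx.size:
            per_class = np.bincount(train_lab)[1:]
            cap = int(np.median(per_class[per_class > 0]))
            if bg_idx.size > cap:
                rng = np.random.default_rng(seed)
                bg_idx = rng.choice(bg_idx, size=cap, replace=False)
        train_idx = np.concatenate([train_idx, bg_idx])
        train_lab = np.concatenate([train_lab, np.full(bg_idx.size, BACKGROUND, np.int8)])

    classes = np.unique(train_lab)
    if classes.size < 2:
        raise FusionError("kNN training needs at least 2 classes among labeled pixels")
    if train_idx.size < k:
        raise FusionError(
            f"only {train_idx.size} labeled training pixels for k={k}; use a smaller k"
        )

    nn = NearestNeighbors(n_neighbors=k).fit(X_all[train_idx])
    dist, nbr = nn.kneighbors(X_all)
    nbr_lab = train_lab[nbr]  # (n_pixels, k)

    order = np.array([c for c in CLASS_ORDER if c in classes])
    votes = np.stack([(nbr_lab == c).sum(axis=1) for c in order], axis=1)
    agg = np.stack([np.where(nbr_lab == c, dist, 0.0).sum(axis=1) for c in order], axis=1)
    best = votes.max(axis=1, keepdims=True)
    # among top-voted classes prefer the smallest aggregate distance, then
    # the earlier class in the fixed order (stable argmin)
    agg_masked = np.where(votes == best, agg, np.inf)
    pred = order[np.argmin(agg_masked, axis=1)]

    labels = np.full((ny, nx), UNASSIGNED, dtype=np.int8)
    labels[ds.pixel_coords[:, 1], ds.pixel_coords[:, 0]] = pred
    prov = np.full((ny, nx), PROV_KNN, dtype=np.int8)
    prov[partial.provenance == PROV_VOTE] = PROV_VOTE
    bg_coords = flat_ix[bg_idx] if bg_idx.size else np.array([], int)
    prov.ravel()[bg_coords] = PROV_KMEANS_BACKGROUND
    return TissueLabelMap(labels, prov)


@dataclass
class ClassSummary:
    """Per-class pixel counts and mean ion intensities."""

    table: pd.DataFrame  # index: class name; columns: pixel_count, <ion>...

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index_label="tissue_class")


def class_mean_intensities(
    ds: MSIDataset,
    labels: TissueLabelMap,
    ions: list[tuple[str, float, float]],
    classes: tuple[str, ...] = TISSUE_CLASSES + ("background",),
) -> ClassSummary:
    """Arithmetic mean intensity of each ion of interest per tissue class.

    ``ions`` is a list of (name, mz_center, mz_tol). Classes with zero
    pixels get NaN means. Pixel counts over the listed classes sum to the
    number of pixels carrying any of those labels.
    """
    images = {name: extract_ion_image(ds, mz, tol) for name, mz, tol in ions}
    rows = {}
    for cls in classes:
        m = labels.mask(cls)
        row = {"pixel_count": int(m.sum())}
        for name, img in images.items():
            row[name] = float(img.values[m].mean()) if m.any() else float("nan")
        rows[cls] = row
    return ClassSummary(pd.DataFrame.from_dict(rows, orient="index"))
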