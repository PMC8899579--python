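"""Export helpers: ion images as single-channel TIFF/CSV, label maps as
indexed TIFF with a CSV legend, boolean masks as TIFF."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .fusion import LABEL_NAMES, PROVENANCE_NAMES, TissueLabelMap
from .msi import IonImage


def save_ion_image_tiff(img: IonImage, path: str) -> None:
    """Float32 TIFF of the ion image; invalid pixels are NaN."""
    values = np.where(img.valid_mask, img.values, np.nan).astype(np.float32)
    tifffile.imwrite(path, values,
                     metadata={"mz_center": img.mz_center, "mz_tol": img.mz_tol,
                               "normalization": img.normalization_tag})


def save_ion_image_csv(img: IonImage, path: str) -> None:
    pd.DataFrame(np.where(img.valid_mask, img.values, np.nan)).to_csv(
        path, index=False, header=False)


def save_label_map_tiff(labels: TissueLabelMap, path: str,
                        legend_path: str | None = None) -> None:
    """Indexed uint8 TIFF (codes shifted so 'unassigned' is 0) plus an
    optional CSV legend mapping pixel values to class names."""
    tifffile.imwrite(path, (labels.labels.astype(np.int16) + 1).astype(np.uint8))
    if legend_path:
        rows = [{"pixel_value": code + 1, "tissue_class": name}
                for code, name in sorted(LABEL_NAMES.items())]
        pd.DataFrame(rows).to_csv(legend_path, index=False)


def save_mask_tiff(mask: np.ndarray, path: str) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8) * 255)


def provenance_counts(labels: TissueLabelMap) -> pd.DataFrame:
    codes, counts = np.unique(labels.provenance, return_counts=True)
    return pd.DataFrame({"provenance": [PROVENANCE_NAMES[int(c)] for c in codes],
                         "n_pixels": counts})
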