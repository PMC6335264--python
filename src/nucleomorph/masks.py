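"""Labeled segmentation masks with physical pixel size.

A :class:`LabelMask` is the package's common currency between segmentation,
scoring, the transport assay and trajectory analysis: a 2D non-negative
integer image (0 = background, k > 0 = object k) plus the pixel size in
micrometres. Coordinates are 0-based ``(row, col)``; objects use
8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import GeometryError, ParameterError

__all__ = ["LabelMask"]


@dataclass
class LabelMask:
    labels: np.ndarray
    pixel_size_um: float
    # ids flagged by upstream stages (e.g. cells with no cytoplasmic signal)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise GeometryError("label image must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise GeometryError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise GeometryError("labels must be non-negative")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")

    # -- basic queries ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted object ids present in the mask (background excluded)."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    def mask_of(self, label_id: int) -> np.ndarray:
        """Boolean mask of one object (full-field)."""
        m = self.labels == int(label_id)
        if not m.any():
            raise GeometryError(f"label {label_id} not present in mask")
        return m

    def bbox_of(self, label_id: int, pad_px: int = 1) -> tuple[slice, slice]:
        """Padded bounding-box slices of one object.

        The pad guarantees a background border inside the crop so distance
        transforms computed on the crop equal those on the full field.
        """
        obj = ndi.find_objects((self.labels == int(label_id)).astype(np.int8))
        if not obj or obj[0] is None:
            raise GeometryError(f"label {label_id} not present in mask")
        (sr, sc) = obj[0]
        h, w = self.labels.shape
        return (
            slice(max(sr.start - pad_px, 0), min(sr.stop + pad_px, h)),
            slice(max(sc.start - pad_px, 0), min(sc.stop + pad_px, w)),
        )

    def area_um2(self, label_id: int) -> float:
        return float(np.count_nonzero(self.labels == int(label_id))) * self.pixel_size_um**2

    def object_table(self) -> pd.DataFrame:
        """Per-object table: id, centroid (row, col, px) and area (um^2)."""
        ids = self.ids
        if ids.size == 0:
            return pd.DataFrame(columns=["id", "centroid_row", "centroid_col", "area_um2"])
        centroids = ndi.center_of_mass(np.ones_like(self.labels), self.labels, ids)
        areas = ndi.sum_labels(np.ones_like(self.labels), self.labels, ids)
        return pd.DataFrame(
            {
                "id": ids.astype(int),
                "centroid_row": [c[0] for c in centroids],
                "centroid_col": [c[1] for c in centroids],
                "area_um2": np.asarray(areas, dtype=float) * self.pixel_size_um**2,
            }
        )


def match_labels(found: LabelMask, truth: LabelMask) -> pd.DataFrame:
    """Greedy IoU matching between two label masks.

    Returns a table with columns ``found_id, truth_id, iou`` sorted by
    descending IoU; each id appears at most once. Used to validate
    segmentation against synthetic ground truth.
    """
    if found.shape != truth.shape:
        raise GeometryError("masks must share shape")
    pairs: dict[tuple[int, int], int] = {}
    both = (found.labels > 0) & (truth.labels > 0)
    fv = found.labels[both]
    tv = truth.labels[both]
    for f, t in zip(fv, tv):
        pairs[(int(f), int(t))] = pairs.get((int(f), int(t)), 0) + 1
    f_area = {int(i): int(np.count_nonzero(found.labels == i)) for i in found.ids}
    t_area = {int(i): int(np.count_nonzero(truth.labels == i)) for i in truth.ids}
    rows = [
        (f, t, inter / (f_area[f] + t_area[t] - inter))
        for (f, t), inter in pairs.items()
    ]
    rows.sort(key=lambda r: -r[2])
    used_f: set[int] = set()
    used_t: set[int] = set()
    out = []
    for f, t, iou in rows:
        if f in used_f or t in used_t:
            continue
        used_f.add(f)
        used_t.add(t)
        out.append((f, t, iou))
    return pd.DataFrame(out, columns=["found_id", "truth_id", "iou"])
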