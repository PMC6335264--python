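"""Nucleus and cell-body segmentation.

Nuclear area is defined from the DAPI channel: smooth, threshold (Otsu by
default), fill holes, drop debris, split touching nuclei by a
distance-transform watershed, and discard objects touching the image
border (fraction and depth scores are undefined on truncated nuclei).
Cell bodies are obtained from a cytoplasmic channel (e.g. beta3-tubulin)
by a nucleus-seeded watershed, so every cell label matches its nucleus
label and is a superset of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .errors import InputError
from .masks import LabelMask

__all__ = ["SegmentationConfig", "segment_nuclei", "segment_cell_body"]


@dataclass
class SegmentationConfig:
    threshold: str | float = "otsu"   # "otsu" or a fixed intensity value
    smooth_sigma_um: float = 0.2
    min_area_um2: float = 20.0        # excludes debris
    split_min_distance_um: float = 6.0
    fill_holes: bool = True
    clear_border: bool = True


def _threshold(image: np.ndarray, how: str | float) -> np.ndarray:
    if isinstance(how, str):
        if how != "otsu":
            raise InputError(f"unknown threshold method {how!r}")
        if np.ptp(image) == 0:
            return np.zeros(image.shape, dtype=bool)
        return image > threshold_otsu(image)
    return image > float(how)


def _local_maxima_markers(dist: np.ndarray, fg: np.ndarray, min_distance_px: int) -> np.ndarray:
    """Watershed markers: distance-transform maxima at least min_distance apart."""
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        dist, min_distance=max(min_distance_px, 1), labels=cc_label(fg, connectivity=2)
    )
    markers = np.zeros(dist.shape, dtype=np.int32)
    for k, (r, c) in enumerate(coords, start=1):
        markers[r, c] = k
    return markers


def segment_nuclei(
    dapi: np.ndarray,
    pixel_size_um: float,
    config: SegmentationConfig | None = None,
) -> LabelMask:
    """Label nuclei in a DAPI image.

    Returns an empty mask (0 labels) on an all-zero image; raises
    :class:`InputError` on non-finite pixels.
    """
    if config is None:
        config = SegmentationConfig()
    dapi = np.asarray(dapi, dtype=np.float32)
    if dapi.ndim != 2:
        raise InputError("dapi must be a single-channel 2D image")
    if not np.isfinite(dapi).all():
        raise InputError("dapi contains non-finite pixels")
    if not dapi.any():
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), pixel_size_um)

    sigma_px = config.smooth_sigma_um / pixel_size_um
    smooth = gaussian(dapi, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else dapi
    fg = _threshold(smooth, config.threshold)
    if config.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    min_px = max(int(round(config.min_area_um2 / pixel_size_um**2)), 1)
    fg = remove_small_objects(fg, max_size=min_px - 1)
    if not fg.any():
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), pixel_size_um)

    dist = ndi.distance_transform_edt(fg)
    markers = _local_maxima_markers(
        dist, fg, int(round(config.split_min_distance_um / pixel_size_um))
    )
    if markers.max() == 0:
        labels = cc_label(fg, connectivity=2).astype(np.int32)
    else:
        labels = watershed(-dist, markers, mask=fg).astype(np.int32)
    if config.clear_border:
        labels = clear_border(labels)
    # re-apply the size filter (border clearing / splitting can leave slivers)
    keep = np.bincount(labels.ravel())
    small = np.flatnonzero(keep < min_px)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMask(labels.astype(np.int32), pixel_size_um)


def segment_cell_body(
    cyto: np.ndarray,
    nuclei: LabelMask,
    config: SegmentationConfig | None = None,
) -> LabelMask:
    """Label cell bodies around segmented nuclei.

    The cytoplasmic channel is thresholded and each foreground pixel is
    assigned to the nearest nucleus by a nucleus-seeded watershed on the
    distance-to-nucleus map; labels match nucleus ids and every cell is a
    superset of its nucleus. Nuclei with no surrounding cytoplasmic
    foreground keep a cell equal to the nucleus and are recorded in
    ``flags["no_cytoplasm"]``.
    """
    if config is None:
        config = SegmentationConfig()
    cyto = np.asarray(cyto, dtype=np.float32)
    if cyto.shape != nuclei.shape:
        raise InputError("cyto image and nucleus mask must share shape")
    if not np.isfinite(cyto).all():
        raise InputError("cyto contains non-finite pixels")
    sigma_px = config.smooth_sigma_um / nuclei.pixel_size_um
    smooth = gaussian(cyto, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else cyto
    fg = _threshold(smooth, config.threshold)
    fg = fg | (nuclei.labels > 0)
    dist_to_nuc = ndi.distance_transform_edt(nuclei.labels == 0)
    cells = watershed(dist_to_nuc, nuclei.labels, mask=fg).astype(np.int32)
    cells[nuclei.labels > 0] = nuclei.labels[nuclei.labels > 0]
    no_cyto = [
        int(i)
        for i in nuclei.ids
        if not np.any((cells == i) & (nuclei.labels != i))
    ]
    return LabelMask(cells, nuclei.pixel_size_um, flags={"no_cytoplasm": no_cyto})
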