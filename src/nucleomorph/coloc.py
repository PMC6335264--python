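"""Masked colocalization: Pearson correlation of two channels on a mask.

Used for somatodendritic mislocalization readouts (e.g. tau vs MAP2): the
paired pixel intensities of two channels, restricted to a cell-body mask,
are summarized by plain Pearson's R. No Costes thresholding or
randomization test is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantChannelError, GeometryError, InputError
from .masks import LabelMask

__all__ = ["pearson_r", "coloc_table"]


def pearson_r(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two channels over the masked pixels."""
    a = np.asarray(a)
    b = np.asarray(b)
    mask = np.asarray(mask) > 0
    if a.shape != b.shape or a.shape != mask.shape:
        raise InputError("channels and mask must share shape")
    if mask.sum() < 2:
        raise GeometryError("mask must contain at least 2 pixels")
    x = a[mask].astype(np.float64)
    y = b[mask].astype(np.float64)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("channels must be finite on the mask")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantChannelError("constant channel on mask: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def coloc_table(a: np.ndarray, b: np.ndarray, cells: LabelMask) -> pd.DataFrame:
    """Per-cell Pearson R table (cell_id, pearson_r, n_pixels).

    Cells where a channel is constant are reported with NaN.
    """
    rows = []
    for cid in map(int, cells.ids):
        m = cells.labels == cid
        try:
            r = pearson_r(a, b, m)
        except ConstantChannelError:
            r = float("nan")
        rows.append({"cell_id": cid, "pearson_r": r, "n_pixels": int(m.sum())})
    return pd.DataFrame(rows, columns=["cell_id", "pearson_r", "n_pixels"])
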