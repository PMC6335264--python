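"""Nucleocytoplasmic transport reporter assay.

Transport integrity is read out from a dual reporter: NES:GFP is exported
from the nucleus (cytoplasmic at steady state) and NLS:RFP is imported
(nuclear at steady state). The per-cell statistic is the background-
corrected nuclear-to-cytoplasmic mean-intensity ratio of each reporter;
a transport defect raises nucGFP:cytGFP toward 1 and lowers
nucRFP:cytRFP toward 1. Mean (not integrated) intensity is used so that
the unequal areas of automatically segmented compartments cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError, NoCytoplasmError, ParameterError
from .masks import LabelMask

__all__ = ["CellTransport", "measure_nc_ratio", "assay_field", "transport_table"]


@dataclass
class CellTransport:
    cell_id: int
    nc_ratio_nes: float
    nc_ratio_nls: float
    nucleus_mean_nes: float
    cyto_mean_nes: float
    nucleus_mean_nls: float
    cyto_mean_nls: float
    background: float


def measure_nc_ratio(
    channel: np.ndarray,
    nucleus_mask: np.ndarray,
    cyto_mask: np.ndarray,
    background: float = 0.0,
) -> float:
    """Background-corrected nuclear/cytoplasmic mean-intensity ratio."""
    if background < 0:
        raise ParameterError("background must be >= 0")
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cyto_mask = np.asarray(cyto_mask, dtype=bool)
    if not nucleus_mask.any() or not cyto_mask.any():
        raise GeometryError("nucleus and cytoplasm masks must be nonempty")
    if (nucleus_mask & cyto_mask).any():
        raise GeometryError("nucleus and cytoplasm masks must be disjoint")
    channel = np.asarray(channel)
    nuc_mean = float(channel[nucleus_mask].mean())
    cyto_mean = float(channel[cyto_mask].mean())
    if cyto_mean <= background:
        raise NoCytoplasmError("no cytoplasmic signal above background")
    return (nuc_mean - background) / (cyto_mean - background)


def estimate_background(channel: np.ndarray, cells: LabelMask) -> float:
    """Median intensity outside every cell mask (the default background)."""
    outside = cells.labels == 0
    if not outside.any():
        return 0.0
    return float(np.median(np.asarray(channel)[outside]))


def assay_field(
    nes: np.ndarray,
    nls: np.ndarray,
    cells: LabelMask,
    nuclei: LabelMask,
    background_method: str | float = "outside_cells",
) -> tuple[list[CellTransport], list[int]]:
    """Per-cell N/C ratios for both reporters across a field.

    The cytoplasm of each cell is its cell mask minus its nucleus mask.
    Cells whose cytoplasm is empty or indistinguishable from background
    are excluded and returned in the second element.
    """
    nes = np.asarray(nes)
    nls = np.asarray(nls)
    if nes.shape != cells.shape or nls.shape != cells.shape:
        raise InputError("channels and masks must share shape")
    if set(map(int, nuclei.ids)) - set(map(int, cells.ids)):
        raise InputError("every nucleus id must have a cell id")
    if isinstance(background_method, str):
        if background_method != "outside_cells":
            raise InputError(f"unknown background method {background_method!r}")
        bg_nes = estimate_background(nes, cells)
        bg_nls = estimate_background(nls, cells)
    else:
        bg_nes = bg_nls = float(background_method)

    results: list[CellTransport] = []
    excluded: list[int] = []
    for cid in map(int, nuclei.ids):
        bbox = cells.bbox_of(cid, pad_px=1)
        cell = cells.labels[bbox] == cid
        nuc = nuclei.labels[bbox] == cid
        cyto = cell & ~nuc
        if not cyto.any():
            excluded.append(cid)
            continue
        try:
            r_nes = measure_nc_ratio(nes[bbox], nuc, cyto, bg_nes)
            r_nls = measure_nc_ratio(nls[bbox], nuc, cyto, bg_nls)
        except NoCytoplasmError:
            excluded.append(cid)
            continue
        results.append(
            CellTransport(
                cell_id=cid,
                nc_ratio_nes=r_nes,
                nc_ratio_nls=r_nls,
                nucleus_mean_nes=float(nes[bbox][nuc].mean()),
                cyto_mean_nes=float(nes[bbox][cyto].mean()),
                nucleus_mean_nls=float(nls[bbox][nuc].mean()),
                cyto_mean_nls=float(nls[bbox][cyto].mean()),
                background=bg_nes,
            )
        )
    if not results and nuclei.n_objects:
        raise NoCytoplasmError("no measurable cells in the field")
    return results, excluded


def transport_table(results: list[CellTransport]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])
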