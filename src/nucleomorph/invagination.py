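"""Nuclear-lamina invagination scoring.

The core measurement of the pipeline. Lamin signal inside each DAPI-defined
nucleus is partitioned into *boundary* (within a thin band along the
nuclear outline) and *invaginated* (deeper inside). Two classifiers are
provided, matching the two scoring conventions used on fixed neurons and
post-mortem tissue:

* **fraction rule** — a nucleus is invagination-positive when the fraction
  of its lamin signal that lies beyond the boundary band strictly exceeds
  a threshold (default 0.3);
* **depth rule** — a nucleus is positive ("folded") when lamin signal
  penetrates at least a minimum Euclidean distance into the interior
  (default 3 um), measured on the distance transform of the nucleus mask.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import GeometryError, InputError, NoLaminSignalError, ParameterError
from .masks import LabelMask

__all__ = [
    "ScoringConfig",
    "LaminPartition",
    "NucleusMeasurement",
    "FieldSummary",
    "partition_lamin",
    "invaginated_fraction",
    "classify_by_fraction",
    "max_invagination_depth",
    "classify_by_depth",
    "summarize_field",
    "score_field",
]

FRACTION_THRESHOLD_DEFAULT = 0.3
MIN_DEPTH_UM_DEFAULT = 3.0
RIM_WIDTH_UM_DEFAULT = 0.5


@dataclass
class ScoringConfig:
    rim_width_um: float = RIM_WIDTH_UM_DEFAULT
    fraction_threshold: float = FRACTION_THRESHOLD_DEFAULT
    min_depth_um: float = MIN_DEPTH_UM_DEFAULT
    fraction_mode: str = "intensity"      # "intensity" or "area"
    lamin_threshold: str | float = "otsu"  # per-nucleus Otsu or fixed value


@dataclass
class LaminPartition:
    """Thresholded lamin pixels of one nucleus, split at the rim band.

    Pixel sets are stored as ``(rows, cols)`` index arrays on the full
    field; ``boundary`` and ``interior`` are disjoint by construction.
    """

    nucleus_id: int
    boundary: tuple[np.ndarray, np.ndarray]
    interior: tuple[np.ndarray, np.ndarray]
    threshold_value: float
    rim_width_um: float


@dataclass
class NucleusMeasurement:
    nucleus_id: int
    area_um2: float
    invaginated_fraction: float
    max_depth_um: float
    positive_fraction_rule: bool
    positive_depth_rule: bool


@dataclass
class FieldSummary:
    n_nuclei: int
    n_positive: int
    percent_positive: float
    rule: str


def _nucleus_crop(nuclei: LabelMask, nucleus_id: int, pad_px: int):
    bbox = nuclei.bbox_of(nucleus_id, pad_px=pad_px)
    return bbox, (nuclei.labels[bbox] == nucleus_id)


def partition_lamin(
    nuclei: LabelMask,
    nucleus_id: int,
    lamin: np.ndarray,
    rim_width_um: float = RIM_WIDTH_UM_DEFAULT,
    lamin_threshold: str | float = "otsu",
) -> LaminPartition:
    """Split the lamin signal of one nucleus into boundary vs invaginated.

    Lamin-positive pixels (per-nucleus Otsu over a neighbourhood one rim
    width around the nucleus, or a fixed threshold) whose distance to the
    nuclear boundary is at most ``rim_width_um`` are assigned to the
    boundary; positive pixels deeper inside the nucleus are invaginated.
    A nucleus with no lamin-positive pixels raises
    :class:`NoLaminSignalError` so callers can exclude and log it.
    """
    if rim_width_um <= 0:
        raise ParameterError("rim_width_um must be > 0")
    lamin = np.asarray(lamin)
    if lamin.shape != nuclei.shape:
        raise InputError("lamin image and nucleus mask must share shape")
    px = nuclei.pixel_size_um
    rim_px = rim_width_um / px
    pad = int(np.ceil(rim_px)) + 2
    bbox, nuc = _nucleus_crop(nuclei, nucleus_id, pad)
    crop = lamin[bbox]

    # distance into the nucleus from its boundary (um); 0 outside
    edt_um = ndi.distance_transform_edt(nuc) * px
    # neighbourhood for thresholding: nucleus dilated by the rim band
    dist_out = ndi.distance_transform_edt(~nuc) * px
    neighbourhood = nuc | (dist_out <= rim_width_um)
    values = crop[neighbourhood]
    if isinstance(lamin_threshold, str):
        if lamin_threshold != "otsu":
            raise InputError(f"unknown lamin threshold {lamin_threshold!r}")
        if np.ptp(values) == 0:
            raise NoLaminSignalError(f"nucleus {nucleus_id}: constant lamin signal")
        thr = float(threshold_otsu(values))
        # Otsu ties across the empty gap between the background and rim
        # modes resolve to the gap's lower edge; one isodata step centers
        # the cut so stray background pixels cannot cross it.
        lo, hi = values[values <= thr], values[values > thr]
        if lo.size and hi.size:
            thr = float(lo.mean() + hi.mean()) / 2.0
    else:
        thr = float(lamin_threshold)
    positive = neighbourhood & (crop > thr)
    if not positive.any():
        raise NoLaminSignalError(f"nucleus {nucleus_id}: no lamin-positive pixels")

    boundary = positive & (edt_um <= rim_width_um)
    interior = positive & (edt_um > rim_width_um)
    r0, c0 = bbox[0].start, bbox[1].start
    bi = np.nonzero(boundary)
    ii = np.nonzero(interior)
    return LaminPartition(
        nucleus_id=nucleus_id,
        boundary=(bi[0] + r0, bi[1] + c0),
        interior=(ii[0] + r0, ii[1] + c0),
        threshold_value=thr,
        rim_width_um=rim_width_um,
    )


def invaginated_fraction(
    p: LaminPartition, lamin: np.ndarray, mode: str = "intensity"
) -> float:
    """Fraction of total lamin signal that is invaginated, in [0, 1].

    ``intensity`` mode weights pixels by the lamin image; ``area`` mode
    counts pixels.
    """
    lamin = np.asarray(lamin)
    n_b, n_i = len(p.boundary[0]), len(p.interior[0])
    if n_b + n_i == 0:
        raise NoLaminSignalError(f"nucleus {p.nucleus_id}: empty partition")
    if mode == "area":
        return n_i / (n_b + n_i)
    if mode != "intensity":
        raise InputError(f"unknown fraction mode {mode!r}")
    # float64 accumulation keeps the boundary/interior split exactly
    # conservative for float32 channels
    s_i = float(lamin[p.interior].sum(dtype=np.float64)) if n_i else 0.0
    s_b = float(lamin[p.boundary].sum(dtype=np.float64)) if n_b else 0.0
    return s_i / (s_i + s_b)


def classify_by_fraction(
    f: float, threshold: float = FRACTION_THRESHOLD_DEFAULT
) -> bool:
    """Fraction rule: positive iff the invaginated fraction strictly
    exceeds the threshold."""
    if not 0.0 <= f <= 1.0:
        raise InputError("fraction must be in [0, 1]")
    return f > threshold


def max_invagination_depth(
    nuclei: LabelMask,
    nucleus_id: int,
    interior: tuple[np.ndarray, np.ndarray],
    pixel_size_um: float | None = None,
) -> float:
    """Maximum penetration depth (um) of invaginated lamin.

    The Euclidean distance transform of the nucleus mask (distance of each
    interior pixel to the nuclear boundary) evaluated at the invaginated
    lamin pixels; 0 for an empty interior set.
    """
    px = pixel_size_um if pixel_size_um is not None else nuclei.pixel_size_um
    if px <= 0:
        raise ParameterError("pixel_size_um must be > 0")
    if len(interior[0]) == 0:
        return 0.0
    bbox, nuc = _nucleus_crop(nuclei, nucleus_id, pad_px=2)
    if not nuc.any():
        raise GeometryError(f"nucleus {nucleus_id} mask is empty")
    edt = ndi.distance_transform_edt(nuc)
    r = np.asarray(interior[0]) - bbox[0].start
    c = np.asarray(interior[1]) - bbox[1].start
    ok = (r >= 0) & (r < nuc.shape[0]) & (c >= 0) & (c < nuc.shape[1])
    if not ok.any():
        return 0.0
    return float(edt[r[ok], c[ok]].max()) * px


def classify_by_depth(d: float, min_depth_um: float = MIN_DEPTH_UM_DEFAULT) -> bool:
    """Depth rule: positive iff lamin penetrates at least ``min_depth_um``
    into the nuclear interior (inclusive)."""
    if d < 0:
        raise InputError("depth must be >= 0")
    return d >= min_depth_um


def summarize_field(
    measurements: list[NucleusMeasurement], rule: str = "fraction"
) -> FieldSummary:
    """Percentage of invagination-positive nuclei in one imaging field."""
    if not measurements:
        raise InputError("no nuclei to summarize")
    if rule == "fraction":
        n_pos = sum(m.positive_fraction_rule for m in measurements)
    elif rule == "depth":
        n_pos = sum(m.positive_depth_rule for m in measurements)
    else:
        raise InputError(f"unknown rule {rule!r}")
    n = len(measurements)
    return FieldSummary(n, n_pos, 100.0 * n_pos / n, rule)


def score_field(
    nuclei: LabelMask,
    lamin: np.ndarray,
    config: ScoringConfig | None = None,
) -> tuple[list[NucleusMeasurement], list[int]]:
    """Score every nucleus of a field under both criteria.

    Returns the per-nucleus measurements and the ids excluded for having
    no lamin signal.
    """
    if config is None:
        config = ScoringConfig()
    measurements: list[NucleusMeasurement] = []
    excluded: list[int] = []
    for nid in nuclei.ids:
        nid = int(nid)
        try:
            part = partition_lamin(
                nuclei, nid, lamin, config.rim_width_um, config.lamin_threshold
            )
        except NoLaminSignalError:
            excluded.append(nid)
            continue
        frac = invaginated_fraction(part, lamin, config.fraction_mode)
        depth = max_invagination_depth(nuclei, nid, part.interior)
        measurements.append(
            NucleusMeasurement(
                nucleus_id=nid,
                area_um2=nuclei.area_um2(nid),
                invaginated_fraction=frac,
                max_depth_um=depth,
                positive_fraction_rule=classify_by_fraction(frac, config.fraction_threshold),
                positive_depth_rule=classify_by_depth(depth, config.min_depth_um),
            )
        )
    return measurements, excluded


def measurements_table(measurements: list[NucleusMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in measurements])
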