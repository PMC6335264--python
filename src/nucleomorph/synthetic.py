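"""Ground-truthed synthetic fluorescence-microscopy fields.

Renders 2D confocal-like fields of neuronal nuclei and somata with the
statistical structure the downstream analysis assumes:

* elliptical nuclei with mild low-order boundary irregularity, each
  optionally carrying curved nuclear-lamina invaginations of controlled
  depth (penetration into the interior, um) and width;
* a lamin channel concentrated on the nuclear rim and along invagination
  folds; a DAPI channel filling nucleus interiors;
* NES:GFP / NLS:RFP reporter channels whose nuclear/cytoplasmic
  partitioning interpolates linearly, via a transport-defect mixing
  parameter ``delta``, between compartmentalized (delta=0) and fully
  mixed (delta=1);
* a cytoplasmic tubulin channel over the soma;
* EB3-like persistent-walk comet tracks, a controlled fraction of which
  enter the nucleus;
* Poisson shot noise plus Gaussian read noise and a constant offset.

Every field carries pixel-perfect ground truth (label masks, per-nucleus
planted invagination metrics, planted transport defect), so each pipeline
stage can be validated without any real imaging data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import GeometryError, InputError, ParameterError
from .masks import LabelMask
from .tracks import Track, TrackSet

__all__ = [
    "NoiseParams",
    "InvaginationSpec",
    "NucleusSpec",
    "FieldSpec",
    "SyntheticField",
    "sample_population",
    "make_field_spec",
    "render_field",
    "add_noise",
    "simulate_tracks",
    "simulate_field_tracks",
    "write_field",
]

# -- rendering defaults (photons / pixel before noise) ---------------------
DEFAULT_PIXEL_SIZE_UM = 0.1     # oversampled confocal plane
LAMIN_LINE_UM = 0.22            # rendered thickness of the lamina line
DAPI_INTENSITY = 100.0
LAMIN_RIM_INTENSITY = 200.0
LAMIN_INTERIOR_BACKGROUND = 5.0
REPORTER_INTENSITY = 150.0
TUBULIN_INTENSITY = 120.0
MIXING_FLOOR = 0.08             # residual signal in the depleted compartment at delta=0
CHANNEL_NAMES = ("dapi", "lamin", "nes_gfp", "nls_rfp", "tubulin")


@dataclass
class NoiseParams:
    """Shot + read noise model: ``Poisson(g*I)/g + N(0, sd) + offset``.

    ``poisson_gain`` is the number of detected photons per intensity unit;
    ``poisson_gain = inf`` disables shot noise (the noiseless limit).
    """

    poisson_gain: float = 1.0
    gaussian_sd: float = 2.0
    background_level: float = 10.0

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.gaussian_sd < 0 or self.background_level < 0:
            raise ParameterError("noise parameters must be non-negative")

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(poisson_gain=np.inf, gaussian_sd=0.0, background_level=0.0)


@dataclass
class InvaginationSpec:
    """One lamina fold: where it enters the rim, how deep and wide it is.

    ``depth_um`` is penetration depth — the Euclidean distance from the
    nuclear boundary reached by the fold tip — not arc length. ``curvature``
    bends the fold sideways (dimensionless; 0 = straight radial fold).
    """

    entry_angle: float
    depth_um: float
    width_um: float
    curvature: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_um < 0:
            raise ParameterError("depth_um must be >= 0")
        if self.width_um <= 0:
            raise ParameterError("width_um must be > 0")


@dataclass
class NucleusSpec:
    center: tuple[float, float]            # (row, col) in px
    semi_axes_um: tuple[float, float]      # (a, b), a >= b > 0
    orientation: float = 0.0               # major-axis angle, radians
    invaginations: list[InvaginationSpec] = field(default_factory=list)
    lamin_rim_intensity: float = LAMIN_RIM_INTENSITY
    interior_background: float = LAMIN_INTERIOR_BACKGROUND
    #: low-order radial harmonics (mode, amplitude_um, phase) perturbing the
    #: boundary; models the mild irregularity of real nuclear outlines
    boundary_harmonics: tuple[tuple[int, float, float], ...] = ()
    soma_margin_um: float = 3.5

    def __post_init__(self) -> None:
        a, b = self.semi_axes_um
        if not (a >= b > 0):
            raise ParameterError("semi axes must satisfy a >= b > 0")
        for inv in self.invaginations:
            if inv.depth_um >= b:
                raise ParameterError(
                    f"invagination depth {inv.depth_um} um must be smaller than "
                    f"the minor semi-axis {b} um"
                )


@dataclass
class FieldSpec:
    image_shape: tuple[int, int]
    pixel_size_um: float
    nuclei: list[NucleusSpec]
    transport_defect_delta: float = 0.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if not 0.0 <= self.transport_defect_delta <= 1.0:
            raise ParameterError("transport_defect_delta must be in [0, 1]")


@dataclass
class SyntheticField:
    channels: dict[str, np.ndarray]
    truth_nuclei: LabelMask
    truth_cells: LabelMask
    truth_table: pd.DataFrame
    spec: FieldSpec

    @property
    def truth_invaginated_fraction(self) -> pd.Series:
        return self.truth_table.set_index("nucleus_id")["planted_fraction"]

    @property
    def truth_positive(self) -> pd.DataFrame:
        return self.truth_table.set_index("nucleus_id")[
            ["positive_fraction_rule", "positive_depth_rule"]
        ]


# -- population sampling ---------------------------------------------------

DEFAULT_DEPTH_DIST = {"name": "uniform", "low": 3.3, "high": 4.3}


def _sample_depth(rng: np.random.Generator, depth_dist) -> float:
    if callable(depth_dist):
        return float(depth_dist(rng))
    name = depth_dist.get("name", "uniform")
    if name == "uniform":
        return float(rng.uniform(depth_dist["low"], depth_dist["high"]))
    if name == "constant":
        return float(depth_dist["value"])
    raise ParameterError(f"unknown depth distribution {name!r}")


def sample_population(
    n_nuclei: int,
    prevalence: float,
    depth_dist=None,
    rng_seed: int = 0,
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    spacing_um: float = 16.0,
    n_invaginations: tuple[int, int] = (3, 5),
    width_um_range: tuple[float, float] = (0.8, 1.2),
    boundary_irregularity_um: float = 0.15,
) -> list[NucleusSpec]:
    """Sample a population of nuclei, a ``prevalence`` fraction of which
    carries planted invaginations.

    Each nucleus independently receives invaginations with probability
    ``prevalence`` (a Bernoulli draw, so the planted-positive count is
    Binomial(n, prevalence)). Affected nuclei get 3-5 folds with depths
    drawn from ``depth_dist`` (default uniform 3.3-4.3 um, clamped below
    the minor semi-axis), mimicking the deeply folded phenotype; healthy
    nuclei have a smooth (mildly irregular) boundary. Centers are laid out
    on a jittered grid so nuclei and somata never overlap.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ParameterError("prevalence must be in [0, 1]")
    if n_nuclei < 1:
        raise ParameterError("n_nuclei must be >= 1")
    if depth_dist is None:
        depth_dist = DEFAULT_DEPTH_DIST
    rng = np.random.default_rng(rng_seed)
    spacing_px = spacing_um / pixel_size_um
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    specs: list[NucleusSpec] = []
    for k in range(n_nuclei):
        gi, gj = divmod(k, n_cols)
        jitter = rng.uniform(-1.5, 1.5, size=2) / pixel_size_um
        center = (
            (gi + 1.0) * spacing_px + jitter[0],
            (gj + 1.0) * spacing_px + jitter[1],
        )
        a = float(np.clip(rng.normal(6.0, 0.5), 5.0, 7.5))
        b = float(np.clip(rng.normal(5.0, 0.4), 4.0, 6.5))
        if b > a:
            a, b = b, a
        harmonics = tuple(
            (mode, float(rng.uniform(0.3, 1.0)) * boundary_irregularity_um,
             float(rng.uniform(0, 2 * np.pi)))
            for mode in (2, 3, 5)
        )
        invs: list[InvaginationSpec] = []
        if rng.uniform() < prevalence:
            n_inv = int(rng.integers(n_invaginations[0], n_invaginations[1] + 1))
            angles = rng.uniform(0, 2 * np.pi) + np.arange(n_inv) * (2 * np.pi / n_inv)
            angles = angles + rng.uniform(-0.3, 0.3, size=n_inv)
            for ang in angles:
                depth = min(_sample_depth(rng, depth_dist), b - 0.8)
                invs.append(
                    InvaginationSpec(
                        entry_angle=float(ang % (2 * np.pi)),
                        depth_um=max(depth, 0.0),
                        width_um=float(rng.uniform(*width_um_range)),
                        curvature=float(rng.normal(0.0, 0.25)),
                    )
                )
        specs.append(
            NucleusSpec(
                center=center,
                semi_axes_um=(a, b),
                orientation=float(rng.uniform(0, np.pi)),
                invaginations=invs,
                boundary_harmonics=harmonics,
            )
        )
    return specs


def make_field_spec(
    nuclei: list[NucleusSpec],
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    transport_defect_delta: float = 0.0,
    noise: NoiseParams | None = None,
    rng_seed: int = 0,
    image_shape: tuple[int, int] | None = None,
) -> FieldSpec:
    """Wrap a nucleus population into a FieldSpec, sizing the image to hold
    every soma with a margin when ``image_shape`` is not given."""
    if noise is None:
        noise = NoiseParams()
    if image_shape is None:
        margin = max(
            (n.semi_axes_um[0] + n.soma_margin_um + 1.0) / pixel_size_um for n in nuclei
        )
        rows = max(n.center[0] for n in nuclei) + margin
        cols = max(n.center[1] for n in nuclei) + margin
        image_shape = (int(np.ceil(rows)) + 2, int(np.ceil(cols)) + 2)
    return FieldSpec(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        nuclei=nuclei,
        transport_defect_delta=transport_defect_delta,
        noise=noise,
        rng_seed=rng_seed,
    )


# -- geometry helpers ------------------------------------------------------

def _nucleus_radius_um(spec: NucleusSpec, theta: np.ndarray) -> np.ndarray:
    """Radial boundary distance r(theta) in the nucleus frame (um)."""
    a, b = spec.semi_axes_um
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    for mode, amp, phase in spec.boundary_harmonics:
        r = r + amp * np.cos(mode * theta + phase)
    return r


def _nucleus_local_frame(spec: NucleusSpec, shape: tuple[int, int], px: float, extra_um: float):
    """Bounding-box slices plus local polar coordinates (um) of each pixel."""
    a, _ = spec.semi_axes_um
    max_amp = sum(abs(h[1]) for h in spec.boundary_harmonics)
    extent_px = (a + max_amp + extra_um) / px + 2
    r0 = int(max(np.floor(spec.center[0] - extent_px), 0))
    r1 = int(min(np.ceil(spec.center[0] + extent_px) + 1, shape[0]))
    c0 = int(max(np.floor(spec.center[1] - extent_px), 0))
    c1 = int(min(np.ceil(spec.center[1] + extent_px) + 1, shape[1]))
    rows = np.arange(r0, r1)[:, None] - spec.center[0]
    cols = np.arange(c0, c1)[None, :] - spec.center[1]
    # rotate into the nucleus frame: x along the major axis
    co, si = np.cos(spec.orientation), np.sin(spec.orientation)
    x = (cols * co + rows * si) * px
    y = (-cols * si + rows * co) * px
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    return (slice(r0, r1), slice(c0, c1)), rho, theta


def _boundary_point(spec: NucleusSpec, angle: float, px: float) -> np.ndarray:
    """Boundary point at nucleus-frame angle, returned in (row, col) px."""
    r = float(_nucleus_radius_um(spec, np.asarray([angle]))[0])
    x, y = r * np.cos(angle), r * np.sin(angle)
    co, si = np.cos(spec.orientation), np.sin(spec.orientation)
    dcol = (x * co - y * si) / px
    drow = (x * si + y * co) / px
    return np.array([spec.center[0] + drow, spec.center[1] + dcol])


def _fold_path(
    spec: NucleusSpec,
    inv: InvaginationSpec,
    edt_um: np.ndarray,
    bbox: tuple[slice, slice],
    px: float,
) -> np.ndarray:
    """Sampled points (local bbox px coords) of one curved fold.

    A quadratic Bezier arc from the rim entry point to an interior anchor
    chosen so the stamped fold tip penetrates to ``depth_um``; the control
    point is displaced sideways in proportion to ``curvature``.
    """
    p0 = _boundary_point(spec, inv.entry_angle, px)
    p0_local = p0 - np.array([bbox[0].start, bbox[1].start])
    center_local = np.array(
        [spec.center[0] - bbox[0].start, spec.center[1] - bbox[1].start]
    )
    direction = center_local - p0_local
    direction = direction / max(np.linalg.norm(direction), 1e-9)
    # march inward until the centerline anchor reaches the target depth;
    # the fold is stamped width/2 around the centerline, so the anchor
    # stops short by that radius for the fold tip to land at depth_um
    target_um = max(inv.depth_um - inv.width_um / 2, 0.05)
    step = 0.25
    p = p0_local.copy()
    best_p, best_d = p.copy(), 0.0
    max_steps = int(np.linalg.norm(center_local - p0_local) / step) + 2
    for _ in range(max_steps):
        p = p + direction * step
        i, j = int(round(p[0])), int(round(p[1]))
        if not (0 <= i < edt_um.shape[0] and 0 <= j < edt_um.shape[1]):
            break
        d = edt_um[i, j]
        if d > best_d:
            best_d, best_p = d, p.copy()
        if d >= target_um:
            break
    p2 = best_p
    chord = p2 - p0_local
    perp = np.array([-chord[1], chord[0]])
    perp = perp / max(np.linalg.norm(perp), 1e-9)
    p1 = (p0_local + p2) / 2 + perp * inv.curvature * (inv.depth_um / px) * 0.5
    t = np.linspace(0.0, 1.0, max(int(np.linalg.norm(chord) / 0.5) * 2, 8))[:, None]
    return ((1 - t) ** 2) * p0_local + 2 * (1 - t) * t * p1 + (t**2) * p2


# -- field rendering -------------------------------------------------------

def render_field(
    spec: FieldSpec,
    *,
    truth_rim_width_um: float = 0.5,
    truth_fraction_threshold: float = 0.3,
    truth_min_depth_um: float = 3.0,
) -> SyntheticField:
    """Render a FieldSpec into channels plus exact ground truth.

    The lamin channel is the rim line plus invagination folds at the rim
    intensity over a dim interior background; DAPI fills nucleus interiors;
    the NES/NLS reporters partition between soma cytoplasm and nucleus
    according to ``transport_defect_delta``. Per-nucleus planted metrics
    (invaginated fraction within/beyond a ``truth_rim_width_um`` band,
    maximum planted penetration depth, and positivity under the fraction
    and depth criteria) are computed from the noiseless geometry.
    """
    shape = tuple(spec.image_shape)
    px = spec.pixel_size_um
    channels = {name: np.zeros(shape, dtype=np.float32) for name in CHANNEL_NAMES}
    nuc_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    # soma pixels contested by several cells go to the nearest boundary
    claim_q = np.full(shape, np.inf, dtype=np.float32)

    rows = []
    for idx, nucleus in enumerate(spec.nuclei, start=1):
        extra = nucleus.soma_margin_um + 1.0
        bbox, rho, theta = _nucleus_local_frame(nucleus, shape, px, extra)
        r_nuc = _nucleus_radius_um(nucleus, theta)
        nuc_mask = rho <= r_nuc
        if not nuc_mask.any():
            raise GeometryError(f"nucleus {idx} renders to zero pixels")
        if (nuc_labels[bbox][nuc_mask] != 0).any():
            raise GeometryError(f"nucleus {idx} overlaps a previously placed nucleus")
        nuc_labels[bbox][nuc_mask] = idx

        edt_um = ndi.distance_transform_edt(nuc_mask) * px
        rim = nuc_mask & (edt_um <= LAMIN_LINE_UM)

        fold_mask = np.zeros_like(nuc_mask)
        for inv in nucleus.invaginations:
            if inv.depth_um <= 0:
                continue
            path = _fold_path(nucleus, inv, edt_um, bbox, px)
            ii = np.clip(np.round(path[:, 0]).astype(int), 0, nuc_mask.shape[0] - 1)
            jj = np.clip(np.round(path[:, 1]).astype(int), 0, nuc_mask.shape[1] - 1)
            line = np.zeros_like(nuc_mask)
            line[ii, jj] = True
            radius = max(int(round(inv.width_um / 2 / px)), 1)
            fold_mask |= ndi.binary_dilation(line, structure=disk(radius))
        fold_mask &= nuc_mask

        structure = rim | fold_mask
        lam = channels["lamin"][bbox]
        lam[nuc_mask] = np.maximum(lam[nuc_mask], nucleus.interior_background)
        lam[structure] = np.maximum(lam[structure], nucleus.lamin_rim_intensity)
        channels["dapi"][bbox][nuc_mask] = DAPI_INTENSITY

        # planted truth under the default boundary-band convention
        interior = structure & (edt_um > truth_rim_width_um)
        n_struct = int(structure.sum())
        frac = float(interior.sum()) / n_struct if n_struct else 0.0
        depth = float(edt_um[interior].max()) if interior.any() else 0.0
        rows.append(
            {
                "nucleus_id": idx,
                "n_invaginations": len(nucleus.invaginations),
                "planted_fraction": frac,
                "planted_depth_um": depth,
                "positive_fraction_rule": frac > truth_fraction_threshold,
                "positive_depth_rule": depth >= truth_min_depth_um,
                "area_um2": float(nuc_mask.sum()) * px**2,
            }
        )

        # soma claim: signed distance beyond the nuclear boundary (um)
        r_soma = r_nuc + nucleus.soma_margin_um
        for mode, amp, phase in nucleus.boundary_harmonics:
            r_soma = r_soma + amp * np.cos(mode * theta + phase + 1.0)
        soma = rho <= r_soma
        q = (rho - r_nuc).astype(np.float32)
        take = soma & (q < claim_q[bbox])
        claim_q[bbox][take] = q[take]
        cell_labels[bbox][take] = idx

    cell_labels[nuc_labels > 0] = nuc_labels[nuc_labels > 0]

    nuc_bool = nuc_labels > 0
    cyto_bool = (cell_labels > 0) & ~nuc_bool
    mix = spec.transport_defect_delta + (1 - spec.transport_defect_delta) * MIXING_FLOOR
    channels["nes_gfp"][cyto_bool] = REPORTER_INTENSITY
    channels["nes_gfp"][nuc_bool] = REPORTER_INTENSITY * mix
    channels["nls_rfp"][nuc_bool] = REPORTER_INTENSITY
    channels["nls_rfp"][cyto_bool] = REPORTER_INTENSITY * mix
    channels["tubulin"][cyto_bool] = TUBULIN_INTENSITY
    channels["tubulin"][nuc_bool] = 0.6 * TUBULIN_INTENSITY

    seeds = np.random.SeedSequence(spec.rng_seed).generate_state(len(CHANNEL_NAMES))
    for name, sub in zip(CHANNEL_NAMES, seeds):
        channels[name] = add_noise(channels[name], spec.noise, int(sub))

    truth = pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "n_invaginations",
            "planted_fraction",
            "planted_depth_um",
            "positive_fraction_rule",
            "positive_depth_rule",
            "area_um2",
        ],
    )
    return SyntheticField(
        channels=channels,
        truth_nuclei=LabelMask(nuc_labels, px),
        truth_cells=LabelMask(cell_labels, px),
        truth_table=truth,
        spec=spec,
    )


def add_noise(image: np.ndarray, noise: NoiseParams, rng_seed: int) -> np.ndarray:
    """Apply the shot + read noise model to a non-negative photon image."""
    image = np.asarray(image)
    if np.any(image < 0):
        raise InputError("photon image must be non-negative")
    rng = np.random.default_rng(rng_seed)
    out = image.astype(np.float32, copy=True)
    if np.isfinite(noise.poisson_gain) and noise.poisson_gain > 0:
        out = (
            rng.poisson(noise.poisson_gain * out.astype(np.float64)) / noise.poisson_gain
        ).astype(np.float32)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape).astype(np.float32)
    if noise.background_level > 0:
        out = out + np.float32(noise.background_level)
    return out


# -- comet track simulation ------------------------------------------------

def simulate_tracks(
    cell_mask: LabelMask,
    nucleus_mask: LabelMask,
    p_enter: float,
    n_tracks: int,
    speed_um_s: float = 0.2,
    frame_interval_s: float = 1.0,
    rng_seed: int = 0,
    cell_id: int | None = None,
    turn_sd: float = 0.3,
) -> TrackSet:
    """Persistent-random-walk comet tracks inside one cell.

    Each track independently enters the nucleus with probability
    ``p_enter``. Entering tracks steer toward an interior nucleus pixel
    until they cross the boundary; non-entering tracks are rejected away
    from a nucleus neighbourhood wide enough that no inter-frame segment
    can cross it. Step lengths jitter uniformly within +-5% of
    ``speed_um_s * frame_interval_s``.
    """
    if not 0.0 <= p_enter <= 1.0:
        raise ParameterError("p_enter must be in [0, 1]")
    if cell_id is None:
        ids = cell_mask.ids
        if ids.size != 1:
            raise GeometryError("cell_id required when the mask holds several cells")
        cell_id = int(ids[0])
    cell = cell_mask.labels == cell_id
    if not cell.any():
        raise GeometryError("cell mask is empty")
    nuc = nucleus_mask.labels == cell_id
    if not nuc.any():
        nuc = nucleus_mask.labels > 0
        if not nuc.any():
            raise GeometryError("nucleus mask is empty")
    px = cell_mask.pixel_size_um
    rng = np.random.default_rng(rng_seed)
    step_px = speed_um_s * frame_interval_s / px
    # distance (px) from each pixel to the nucleus, for the keep-out zone
    dist_to_nuc = ndi.distance_transform_edt(~nuc)
    cyto_idx = np.argwhere(cell & ~nuc & (dist_to_nuc > step_px + 2))
    if cyto_idx.size == 0:
        raise GeometryError("no cytoplasm far enough from the nucleus to seed tracks")
    nuc_edt = ndi.distance_transform_edt(nuc)
    nuc_interior = np.argwhere(nuc_edt >= min(3, nuc_edt.max()))
    h, w = cell.shape

    def inside(arr, p):
        i, j = int(round(p[1])), int(round(p[0]))
        return 0 <= i < h and 0 <= j < w and arr[i, j]

    tracks = []
    for tid in range(n_tracks):
        enters = rng.uniform() < p_enter
        start = cyto_idx[rng.integers(len(cyto_idx))]
        pos = np.array([start[1], start[0]], dtype=float)  # (x, y)
        pts = [pos.copy()]
        n_steps = int(rng.integers(15, 41))
        if enters:
            target_rc = nuc_interior[rng.integers(len(nuc_interior))]
            target = np.array([target_rc[1], target_rc[0]], dtype=float)
            while not inside(nuc, pos):
                d = target - pos
                heading = np.arctan2(d[1], d[0]) + rng.normal(0.0, 0.15)
                ds = step_px * rng.uniform(0.95, 1.05)
                pos = pos + ds * np.array([np.cos(heading), np.sin(heading)])
                pts.append(pos.copy())
            for _ in range(3):  # a few persistent steps past entry
                ds = step_px * rng.uniform(0.95, 1.05)
                cand = pos + ds * np.array([np.cos(heading), np.sin(heading)])
                if not inside(cell | nuc, cand):
                    break
                pos = cand
                pts.append(pos.copy())
        else:
            heading = rng.uniform(0, 2 * np.pi)
            for _ in range(n_steps):
                placed = False
                for _try in range(60):
                    h_try = heading + rng.normal(0.0, turn_sd)
                    ds = step_px * rng.uniform(0.95, 1.05)
                    cand = pos + ds * np.array([np.cos(h_try), np.sin(h_try)])
                    ci, cj = int(round(cand[1])), int(round(cand[0]))
                    if (
                        0 <= ci < h
                        and 0 <= cj < w
                        and cell[ci, cj]
                        and dist_to_nuc[ci, cj] > step_px + 2
                    ):
                        heading = h_try
                        pos = cand
                        pts.append(pos.copy())
                        placed = True
                        break
                    heading = heading + rng.uniform(-1.0, 1.0)
                if not placed:
                    break
        if len(pts) < 2:
            pts.append(pts[0] + np.array([step_px, 0.0]))
        xy = np.asarray(pts)
        tracks.append(Track(tid, np.arange(len(xy)), xy))
    return TrackSet(
        tracks,
        frame_interval_s=frame_interval_s,
        pixel_size_um=px,
        cell_id=cell_id,
        meta={"p_enter": p_enter, "speed_um_s": speed_um_s},
    )


def simulate_field_tracks(
    cells: LabelMask,
    nuclei: LabelMask,
    p_enter: float,
    n_tracks_per_cell: int,
    speed_um_s: float = 0.2,
    frame_interval_s: float = 1.0,
    rng_seed: int = 0,
) -> list[TrackSet]:
    """One TrackSet per cell label; seeds derived per cell for determinism."""
    seeds = np.random.SeedSequence(rng_seed).generate_state(cells.n_objects)
    return [
        simulate_tracks(
            cells,
            nuclei,
            p_enter,
            n_tracks_per_cell,
            speed_um_s,
            frame_interval_s,
            rng_seed=int(s),
            cell_id=int(cid),
        )
        for cid, s in zip(cells.ids, seeds)
    ]


# -- on-disk form ----------------------------------------------------------

def write_field(field_out: SyntheticField, out_dir: str | Path) -> Path:
    """Write a field as multi-page TIFF + JSON sidecar + truth CSVs."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(out / "channels.tif") as tw:
        for name in CHANNEL_NAMES:
            tw.write(field_out.channels[name], description=name)
    tifffile.imwrite(
        out / "truth_nuclei.tif", field_out.truth_nuclei.labels.astype(np.uint16)
    )
    tifffile.imwrite(
        out / "truth_cells.tif", field_out.truth_cells.labels.astype(np.uint16)
    )
    field_out.truth_table.to_csv(out / "truth_nuclei.csv", index=False)
    spec_dict = asdict(field_out.spec)
    spec_dict["noise"]["poisson_gain"] = (
        None if np.isinf(field_out.spec.noise.poisson_gain)
        else field_out.spec.noise.poisson_gain
    )
    with open(out / "field_spec.json", "w") as fh:
        json.dump(spec_dict, fh, indent=2, default=lambda o: list(o))
    return out
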