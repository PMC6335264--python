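"""End-to-end synthetic pipeline: simulate, segment, score, assay.

``run_pipeline`` turns a validated configuration into a run directory
containing every intermediate (channel TIFF, label masks, per-nucleus and
per-cell CSVs, field summaries) plus a JSON manifest echoing every
threshold, mode and seed, so a run is fully determined by its config.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .errors import InputError
from .invagination import ScoringConfig, measurements_table, score_field, summarize_field
from .io import write_channels, write_label_mask, write_manifest
from .segmentation import SegmentationConfig, segment_cell_body, segment_nuclei
from .synthetic import (
    NoiseParams,
    make_field_spec,
    render_field,
    sample_population,
    simulate_field_tracks,
)
from .tracks import summarize_cells, write_tracks_csv
from .transport import assay_field, transport_table

__all__ = ["validate_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "pixel_size_um": 0.1,
    "simulate": {
        "n_nuclei": 25,
        "prevalence": 0.25,
        "transport_defect_delta": 0.0,
        "depth_dist": None,
        "noise": {"poisson_gain": 1.0, "gaussian_sd": 2.0, "background_level": 10.0},
    },
    "segmentation": {
        "threshold": "otsu",
        "min_area_um2": 20.0,
        "split_min_distance_um": 6.0,
    },
    "scoring": {
        "rim_width_um": 0.5,
        "fraction_threshold": 0.3,
        "min_depth_um": 3.0,
        "fraction_mode": "intensity",
        "rule": "fraction",
    },
    "transport": {"enabled": True},
    "tracks": {
        "enabled": False,
        "p_enter": 0.3,
        "n_tracks_per_cell": 10,
        "speed_um_s": 0.2,
        "frame_interval_s": 1.0,
    },
}

_SCHEMA = {
    "seed": int,
    "pixel_size_um": (int, float),
    "simulate.n_nuclei": int,
    "simulate.prevalence": (int, float),
    "simulate.transport_defect_delta": (int, float),
    "segmentation.min_area_um2": (int, float),
    "scoring.rim_width_um": (int, float),
    "scoring.fraction_threshold": (int, float),
    "scoring.min_depth_um": (int, float),
    "scoring.fraction_mode": str,
    "scoring.rule": str,
}


def _merged(user: dict) -> dict:
    out = {}
    for key, val in DEFAULT_CONFIG.items():
        if isinstance(val, dict):
            out[key] = {**val, **user.get(key, {})}
        else:
            out[key] = user.get(key, val)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise InputError(f"unknown config section(s): {sorted(unknown)}")
    return out


def validate_config(config: dict) -> dict:
    """Merge with defaults and type-check; errors name the field path."""
    cfg = _merged(config)
    for path, typ in _SCHEMA.items():
        node = cfg
        for part in path.split("."):
            node = node[part]
        if isinstance(node, bool) or not isinstance(node, typ):
            raise InputError(f"config field {path}: expected {typ}, got {node!r}")
    if not 0 <= cfg["simulate"]["prevalence"] <= 1:
        raise InputError("config field simulate.prevalence: must be in [0, 1]")
    if cfg["simulate"]["n_nuclei"] < 1:
        raise InputError("config field simulate.n_nuclei: must be >= 1")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run simulate -> segment -> score (-> transport -> tracks).

    Returns a summary dict with the field-level results; all artifacts are
    written under ``out_dir``.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    px = float(cfg["pixel_size_um"])
    seed = int(cfg["seed"])

    sim = cfg["simulate"]
    nuclei_specs = sample_population(
        sim["n_nuclei"],
        sim["prevalence"],
        depth_dist=sim.get("depth_dist"),
        rng_seed=seed,
        pixel_size_um=px,
    )
    noise = NoiseParams(**sim["noise"])
    spec = make_field_spec(
        nuclei_specs,
        pixel_size_um=px,
        transport_defect_delta=float(sim["transport_defect_delta"]),
        noise=noise,
        rng_seed=seed,
    )
    field = render_field(
        spec,
        truth_rim_width_um=float(cfg["scoring"]["rim_width_um"]),
        truth_fraction_threshold=float(cfg["scoring"]["fraction_threshold"]),
        truth_min_depth_um=float(cfg["scoring"]["min_depth_um"]),
    )
    write_channels(field.channels, out / "channels.tif")
    field.truth_table.to_csv(out / "truth_nuclei.csv", index=False)

    seg_cfg = SegmentationConfig(
        threshold=cfg["segmentation"]["threshold"],
        min_area_um2=float(cfg["segmentation"]["min_area_um2"]),
        split_min_distance_um=float(cfg["segmentation"]["split_min_distance_um"]),
    )
    nuclei = segment_nuclei(field.channels["dapi"], px, seg_cfg)
    cells = segment_cell_body(field.channels["tubulin"], nuclei, seg_cfg)
    write_label_mask(nuclei, out / "nuclei_mask.tif")
    write_label_mask(cells, out / "cells_mask.tif")
    nuclei.object_table().to_csv(out / "nuclei.csv", index=False)

    score_cfg = ScoringConfig(
        rim_width_um=float(cfg["scoring"]["rim_width_um"]),
        fraction_threshold=float(cfg["scoring"]["fraction_threshold"]),
        min_depth_um=float(cfg["scoring"]["min_depth_um"]),
        fraction_mode=cfg["scoring"]["fraction_mode"],
    )
    measurements, excluded = score_field(nuclei, field.channels["lamin"], score_cfg)
    measurements_table(measurements).to_csv(out / "measurements.csv", index=False)
    summary = summarize_field(measurements, cfg["scoring"]["rule"])
    pd.DataFrame([summary.__dict__]).to_csv(out / "field_summary.csv", index=False)

    result = {
        "n_nuclei": summary.n_nuclei,
        "n_positive": summary.n_positive,
        "percent_positive": summary.percent_positive,
        "n_excluded_no_lamin": len(excluded),
    }

    if cfg["transport"]["enabled"]:
        cell_results, t_excluded = assay_field(
            field.channels["nes_gfp"], field.channels["nls_rfp"], cells, nuclei
        )
        tdf = transport_table(cell_results)
        tdf.to_csv(out / "transport.csv", index=False)
        result["median_nc_ratio_nes"] = float(tdf["nc_ratio_nes"].median())
        result["median_nc_ratio_nls"] = float(tdf["nc_ratio_nls"].median())
        result["n_cells_excluded_transport"] = len(t_excluded)

    if cfg["tracks"]["enabled"]:
        tr = cfg["tracks"]
        tracksets = simulate_field_tracks(
            field.truth_cells,
            field.truth_nuclei,
            p_enter=float(tr["p_enter"]),
            n_tracks_per_cell=int(tr["n_tracks_per_cell"]),
            speed_um_s=float(tr["speed_um_s"]),
            frame_interval_s=float(tr["frame_interval_s"]),
            rng_seed=seed + 1,
        )
        write_tracks_csv(tracksets, out / "tracks.csv")
        table, overall = summarize_cells(tracksets, field.truth_nuclei)
        table.to_csv(out / "tracks_per_cell.csv", index=False)
        result.update({f"tracks_{k}": v for k, v in overall.items()})

    write_manifest(
        {"version": __version__, "config": cfg, "result": result}, out / "manifest.json"
    )
    return result
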