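"""File formats: multi-page channel TIFFs, 16-bit label masks, CSV tables,
JSON/YAML configuration and run manifests.

Channels travel as one multi-page TIFF with the channel name stored in
each page's description tag; label masks are 16-bit single-page TIFFs.
All um-valued parameters are specified in um and converted once at ingest
using ``pixel_size_um``; internal computation is in pixels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import InputError
from .masks import LabelMask

__all__ = [
    "read_channels",
    "write_channels",
    "require_channels",
    "read_label_mask",
    "write_label_mask",
    "load_config",
    "write_manifest",
]


def write_channels(channels: dict[str, np.ndarray], path: str | Path) -> None:
    with tifffile.TiffWriter(path) as tw:
        for name, img in channels.items():
            tw.write(np.asarray(img), description=name)


def read_channels(path: str | Path) -> dict[str, np.ndarray]:
    """Read a multi-page TIFF into a {channel_name: image} dict.

    Pages without a description are named ``channel_<index>``.
    """
    out: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            name = (page.description or "").strip() or f"channel_{i}"
            out[name] = page.asarray()
    return out


def require_channels(channels: dict[str, np.ndarray], names: list[str]) -> None:
    missing = [n for n in names if n not in channels]
    if missing:
        raise InputError(
            f"missing channel(s) {missing} in input (found: {sorted(channels)})"
        )


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise InputError("too many labels for a 16-bit mask")
    tifffile.imwrite(
        path,
        mask.labels.astype(np.uint16),
        description=json.dumps({"pixel_size_um": mask.pixel_size_um}),
    )


def read_label_mask(path: str | Path, pixel_size_um: float | None = None) -> LabelMask:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        labels = page.asarray().astype(np.int32)
        if pixel_size_um is None:
            try:
                pixel_size_um = json.loads(page.description or "{}").get("pixel_size_um")
            except json.JSONDecodeError:
                pixel_size_um = None
    if pixel_size_um is None:
        raise InputError("pixel_size_um not stored in mask; pass it explicitly")
    return LabelMask(labels, float(pixel_size_um))


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InputError("config file must contain a mapping")
    return cfg


def write_manifest(manifest: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    Path(path).write_text(json.dumps(manifest, indent=2, default=default) + "\n")
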