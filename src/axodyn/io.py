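"""Readers and writers for the pipeline's on-disk formats.

Track and protrusion tables are plain CSV; image stacks and masks are
multi-page TIFF (via :mod:`tifffile`); ground truth is JSON; simulation
configuration is YAML. The same track/protrusion schemas are accepted from
real tracking exports.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile
import yaml

from .groundtruth import GroundTruth
from .presets import BranchEventPreset, FrapPreset, GranuleKineticsPreset

__all__ = [
    "write_tracks",
    "read_tracks",
    "write_protrusions",
    "read_protrusions",
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "load_config",
]

TRACK_SCHEMA = ["granule_id", "frame", "t_s", "x_px", "y_px", "s_um"]
PROTRUSION_SCHEMA = ["protrusion_id", "birth_s", "death_s", "origin_s_um"]


def write_tracks(tracks: pd.DataFrame, path) -> None:
    missing = [c for c in TRACK_SCHEMA if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    tracks.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("granule_id", "t_s", "s_um") if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    return df


def write_protrusions(events: pd.DataFrame, events_path, lengths=None, lengths_path=None):
    missing = [c for c in PROTRUSION_SCHEMA if c not in events.columns]
    if missing:
        raise ValueError(f"protrusion table missing columns: {missing}")
    events.to_csv(events_path, index=False)
    if lengths is not None and lengths_path is not None:
        lengths.to_csv(lengths_path, index=False)


def read_protrusions(events_path, lengths_path=None):
    events = pd.read_csv(events_path)
    lengths = pd.read_csv(lengths_path) if lengths_path else None
    return events, lengths


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8),
                     photometric="minisblack")


def read_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


def write_ground_truth(gt: GroundTruth, path) -> None:
    gt.to_json(path)


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(path)


def load_config(path):
    """Load presets from a YAML config with optional sections
    ``kinetics``, ``branching`` and ``frap`` (field overrides)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "kinetics" in raw:
        out["kinetics"] = GranuleKineticsPreset(**raw["kinetics"])
    if "branching" in raw:
        out["branching"] = BranchEventPreset(**raw["branching"])
    if "frap" in raw:
        out["frap"] = FrapPreset(**raw["frap"])
    return out
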