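"""Render granule tracks into multi-page image stacks.

Granules are drawn as Gaussian spots (FWHM equal to the granule diameter)
on an axon-shaped ridge over a flat background, one page per frame. The
rendering is linear, so a noiseless render is exactly invertible by local
maxima detection: spot centers land within one pixel of the input track
positions.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .geometry import AxonGeometry

__all__ = ["render_stack", "detect_spot_maxima"]


def render_stack(
    tracks: pd.DataFrame,
    geometry: AxonGeometry,
    shape=None,
    granule_diameter_um: float = 1.0,
    background_level: float = 10.0,
    axon_level: float = 20.0,
    axon_halfwidth_um: float = 1.0,
    spot_amplitude: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a track table into a ``(n_frames, H, W)`` float stack.

    The frame count is taken from the table's ``frame`` column (an empty
    table renders one background-only frame). Spot positions outside the
    field of view are clipped to it with a warning.
    """
    px = geometry.pixel_size_um
    if shape is None:
        pts = geometry.shaft_polyline / px
        w = int(math.ceil(pts[:, 0].max() + 10))
        h = int(math.ceil(pts[:, 1].max() + 10))
        shape = (max(h, 24), max(w, 24))
    h, w = shape
    rng = np.random.default_rng(seed)

    # axon ridge: distance to the shaft polyline, evaluated once
    rr, cc = np.mgrid[0:h, 0:w]
    ridge = np.zeros(shape)
    halfwidth_px = axon_halfwidth_um / px
    poly = geometry.shaft_polyline / px
    dmin = np.full(shape, np.inf)
    for p0, p1 in zip(poly[:-1], poly[1:]):
        d = _dist_to_segment(cc, rr, p0, p1)
        np.minimum(dmin, d, out=dmin)
    ridge[dmin <= halfwidth_px] = axon_level

    sigma_px = granule_diameter_um / 2.355 / px
    n_frames = int(tracks["frame"].max()) + 1 if len(tracks) else 1
    stack = np.empty((n_frames, h, w))
    clipped = 0
    for f in range(n_frames):
        frame = background_level + ridge.copy()
        rows = tracks[tracks["frame"] == f] if len(tracks) else tracks
        for row in rows.itertuples():
            x, y = float(row.x_px), float(row.y_px)
            if not (0 <= x < w and 0 <= y < h):
                clipped += 1
                x, y = min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0)
            frame += spot_amplitude * np.exp(
                -((cc - x) ** 2 + (rr - y) ** 2) / (2 * sigma_px**2)
            )
        if noise_sd > 0:
            frame = np.clip(frame * (1 + noise_sd * rng.standard_normal(shape)), 0, None)
        stack[f] = frame
    if clipped:
        warnings.warn(f"{clipped} spot positions outside the field of view were clipped")
    return stack


def _dist_to_segment(x, y, p0, p1):
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    norm2 = vx * vx + vy * vy
    if norm2 == 0:
        return np.hypot(x - p0[0], y - p0[1])
    t = np.clip(((x - p0[0]) * vx + (y - p0[1]) * vy) / norm2, 0.0, 1.0)
    return np.hypot(x - (p0[0] + t * vx), y - (p0[1] + t * vy))


def detect_spot_maxima(frame, min_distance=3, threshold_abs=None):
    """Local maxima spot detection (renderer round-trip checks only)."""
    from skimage.feature import peak_local_max

    frame = np.asarray(frame, dtype=float)
    if threshold_abs is None:
        threshold_abs = frame.min() + 0.5 * np.ptp(frame)
    return peak_local_max(
        frame, min_distance=min_distance, threshold_abs=threshold_abs
    )
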