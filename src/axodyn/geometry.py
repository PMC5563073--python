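"""Axon terminal geometry.

The analyses operate mostly in a one-dimensional arc-length coordinate ``s``
along the terminal axon shaft: ``s = 0`` at the proximal end of the analyzed
segment and increasing distally, so anterograde motion is increasing ``s``.
The geometry object also carries the imaging metadata (pixel size, frame
interval) needed to render tracks into images and to convert between pixel
and micrometre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AxonGeometry"]


@dataclass(frozen=True)
class AxonGeometry:
    """Geometry and imaging metadata of one axon terminal.

    Parameters
    ----------
    shaft_polyline:
        Ordered ``(n, 2)`` array of 2-D points in micrometres tracing the
        shaft from proximal to distal. Defaults to a straight horizontal
        segment of ``terminal_length_um``.
    terminal_length_um:
        Length of the analyzed terminal segment (default 100 um, the distal
        portion of the shaft that live-imaging studies of retinal ganglion
        cell arbors quantify).
    pixel_size_um:
        Effective pixel size on the sample (default 0.118 um, an EM-CCD at
        high magnification).
    frame_interval_s:
        Seconds between acquired frames.
    """

    shaft_polyline: np.ndarray = None  # type: ignore[assignment]
    terminal_length_um: float = 100.0
    pixel_size_um: float = 0.118
    frame_interval_s: float = 3.0
    origin_um: tuple = (5.0, 5.0)  # image-space offset of s = 0

    def __post_init__(self) -> None:
        if self.shaft_polyline is None:
            poly = np.array(
                [[0.0, 0.0], [float(self.terminal_length_um), 0.0]]
            ) + np.asarray(self.origin_um, dtype=float)
            object.__setattr__(self, "shaft_polyline", poly)
        poly = np.asarray(self.shaft_polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
            raise ValueError("shaft_polyline must be an (n>=2, 2) point array")
        object.__setattr__(self, "shaft_polyline", poly)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.terminal_length_um <= 0:
            raise ValueError("terminal_length_um must be positive")
        if self.arc_length_um < self.terminal_length_um - 1e-9:
            raise ValueError(
                "shaft polyline arc length is shorter than terminal_length_um"
            )

    @property
    def arc_length_um(self) -> float:
        seg = np.diff(self.shaft_polyline, axis=0)
        return float(np.sqrt((seg**2).sum(axis=1)).sum())

    def point_at(self, s_um):
        """Interpolate image-space point(s) (um) at arc length ``s_um``.

        Values outside the polyline are linearly extrapolated along the
        first/last segment so that slightly out-of-segment tracks remain
        renderable (the renderer clips to the field of view).
        """
        s = np.atleast_1d(np.asarray(s_um, dtype=float))
        seg = np.diff(self.shaft_polyline, axis=0)
        seg_len = np.sqrt((seg**2).sum(axis=1))
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        pts = self.shaft_polyline[idx] + frac[:, None] * seg[idx]
        return pts if np.ndim(s_um) else pts[0]

    def to_pixels(self, xy_um):
        return np.asarray(xy_um, dtype=float) / self.pixel_size_um
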