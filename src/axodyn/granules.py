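"""Granule motility classification, docking detection and association stats.

Motility is scored over a 60 s window: granules whose position range stays
below 1 um are stationary; granules with at least one reversal between runs
of at least 1 um each are bidirectional; the remainder are anterograde or
retrograde by the sign of their net displacement along the shaft. Docking is
a dwell within one granule diameter (total excursion) lasting at least 10 s
for RNA granules or 1 min for mitochondria.

The three association statistics mirror the live-imaging analysis: the
fraction of protrusions preceded by a dock at their base within a 10 s
window, the fraction of random (position, time) sites covered by a dock,
and the random-follow control (nearest granule to a random site, tracked
forward to its first dock, scored for protrusion emergence within 10 s of
dock onset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GranuleTrack",
    "DockEvent",
    "MotilitySummary",
    "SpeedEstimate",
    "tracks_from_table",
    "classify_motility",
    "motility_fractions",
    "estimate_speeds",
    "granule_density",
    "detect_docks",
    "detect_docks_all",
    "protrusion_dock_association",
    "random_site_dock_fraction",
    "random_follow_control",
]

MITO_DOCK_MIN_DURATION_S = 60.0  # slower organelle criterion: 1 min


@dataclass
class GranuleTrack:
    """Time-stamped positions of one granule along the shaft."""

    granule_id: int
    t_s: np.ndarray
    s_um: np.ndarray
    x_px: Optional[np.ndarray] = None
    y_px: Optional[np.ndarray] = None
    channel: str = "rna"
    on_shaft: Optional[np.ndarray] = None  # per-sample flag; None = all shaft

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.s_um = np.asarray(self.s_um, dtype=float)
        if len(self.t_s) != len(self.s_um):
            raise ValueError("t_s and s_um must have equal length")
        if len(self.t_s) >= 2 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def span_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self.t_s) else 0.0

    def position_at(self, t: float) -> float:
        return float(np.interp(t, self.t_s, self.s_um))


@dataclass
class DockEvent:
    """One docking event: a dwell within a diameter-wide window."""

    granule_id: int
    position_um: float  # mean s during the dock
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SpeedEstimate:
    v_antero_um_min: Optional[float]
    v_retro_um_min: Optional[float]
    n_antero: int
    n_retro: int


@dataclass
class MotilitySummary:
    fractions: dict  # class -> fraction, summing to 1 over classified tracks
    speeds: SpeedEstimate
    density_per_10um: Optional[float]
    n_tracks: int


def tracks_from_table(table: pd.DataFrame) -> List[GranuleTrack]:
    """Build :class:`GranuleTrack` objects from a tidy track table.

    Requires columns ``granule_id, t_s, s_um``; ``x_px``/``y_px`` and an
    ``on_shaft`` flag (or a ``branch_id`` column, where a finite branch id
    marks off-shaft samples) are used when present.
    """
    tracks = []
    for gid, grp in table.groupby("granule_id", sort=True):
        grp = grp.sort_values("t_s")
        on_shaft = None
        if "on_shaft" in grp.columns:
            on_shaft = grp["on_shaft"].to_numpy(dtype=bool)
        elif "branch_id" in grp.columns:
            on_shaft = ~np.isfinite(grp["branch_id"].to_numpy(dtype=float))
        tracks.append(
            GranuleTrack(
                granule_id=int(gid),
                t_s=grp["t_s"].to_numpy(dtype=float),
                s_um=grp["s_um"].to_numpy(dtype=float),
                x_px=grp["x_px"].to_numpy(dtype=float) if "x_px" in grp else None,
                y_px=grp["y_px"].to_numpy(dtype=float) if "y_px" in grp else None,
                on_shaft=on_shaft,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# motility
# ---------------------------------------------------------------------------


def _monotone_runs(t, s, min_step_um=0.1):
    """Split a trajectory into monotone runs, ignoring sub-threshold jitter.

    Returns a list of ``(sign, displacement_um, duration_s)`` tuples where
    displacement is the unsigned run length.
    """
    runs = []
    sign = 0
    start_idx = 0
    anchor = s[0]
    for i in range(1, len(s)):
        step = s[i] - anchor
        if abs(step) < min_step_um:
            continue
        step_sign = 1 if step > 0 else -1
        if sign == 0:
            sign = step_sign
        elif step_sign != sign:
            runs.append((sign, abs(s[i - 1] - s[start_idx]), t[i - 1] - t[start_idx]))
            start_idx = i - 1
            sign = step_sign
        anchor = s[i]
    if sign != 0:
        runs.append((sign, abs(s[-1] - s[start_idx]), t[-1] - t[start_idx]))
    return runs


def classify_motility(
    track: GranuleTrack,
    window_s: float = 60.0,
    stationary_thresh_um: float = 1.0,
    run_min_um: float = 1.0,
):
    """Classify one track over its first ``window_s`` seconds.

    Returns one of ``stationary``, ``anterograde``, ``retrograde``,
    ``bidirectional``, or ``None`` when the track does not span the window.
    """
    if track.span_s < window_s - 1e-9:
        return None
    sel = track.t_s <= track.t_s[0] + window_s + 1e-9
    t, s = track.t_s[sel], track.s_um[sel]
    if np.ptp(s) < stationary_thresh_um:
        return "stationary"
    runs = [r for r in _monotone_runs(t, s) if r[1] >= run_min_um]
    for a, b in zip(runs, runs[1:]):
        if a[0] != b[0]:
            return "bidirectional"
    net = s[-1] - s[0]
    return "anterograde" if net >= 0 else "retrograde"


def motility_fractions(tracks: Sequence[GranuleTrack], window_s: float = 60.0) -> dict:
    """Fractions of each motility class among classifiable tracks."""
    counts = {"stationary": 0, "anterograde": 0, "retrograde": 0, "bidirectional": 0}
    n = 0
    for tr in tracks:
        cls = classify_motility(tr, window_s=window_s)
        if cls is not None:
            counts[cls] += 1
            n += 1
    if n == 0:
        return {k: float("nan") for k in counts}
    return {k: v / n for k, v in counts.items()}


def estimate_speeds(
    tracks: Sequence[GranuleTrack],
    shaft_only: bool = True,
    min_run_speed_um_min: float = 2.0,
    min_run_um: float = 1.0,
) -> SpeedEstimate:
    """Mean anterograde and retrograde run speed (um/min) across granules.

    A run is a maximal block of consecutive frames whose instantaneous speed
    exceeds ``min_run_speed_um_min`` with a consistent direction; runs
    shorter than ``min_run_um`` are discarded as jitter. Run speed is run
    displacement over run duration; speeds are averaged per granule first,
    then across granules. Branch-resident samples are excluded when
    ``shaft_only``.
    """
    per_granule = {"antero": [], "retro": []}
    for tr in tracks:
        t, s = tr.t_s, tr.s_um
        if shaft_only and tr.on_shaft is not None:
            keep = tr.on_shaft
            t, s = t[keep], s[keep]
        if len(t) < 2:
            continue
        v = np.diff(s) / np.diff(t) * 60.0
        moving = np.abs(v) >= min_run_speed_um_min
        sign = np.sign(v)
        speeds = {"antero": [], "retro": []}
        i = 0
        while i < len(v):
            if not moving[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(v) and moving[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            disp = abs(s[j + 1] - s[i])
            dur = t[j + 1] - t[i]
            if disp >= min_run_um and dur > 0:
                speeds["antero" if sign[i] > 0 else "retro"].append(disp / dur * 60.0)
            i = j + 1
        for key in speeds:
            if speeds[key]:
                per_granule[key].append(float(np.mean(speeds[key])))
    return SpeedEstimate(
        v_antero_um_min=float(np.mean(per_granule["antero"]))
        if per_granule["antero"]
        else None,
        v_retro_um_min=float(np.mean(per_granule["retro"]))
        if per_granule["retro"]
        else None,
        n_antero=len(per_granule["antero"]),
        n_retro=len(per_granule["retro"]),
    )


def granule_density(
    tracks: Sequence[GranuleTrack],
    terminal_length_um: float = 70.0,
    shaft_length_um: Optional[float] = None,
) -> float:
    """Granules per 10 um on the terminal segment, averaged over frames.

    The terminal segment is ``[shaft_length - terminal_length, shaft_length]``
    (``shaft_length`` defaults to the maximum observed position). The count
    of distinct granules inside the segment is averaged over the common
    frame grid and scaled to 10 um.
    """
    if terminal_length_um <= 0:
        raise ValueError("terminal_length_um must be positive")
    if not tracks:
        return 0.0
    if shaft_length_um is None:
        shaft_length_um = max(float(tr.s_um.max()) for tr in tracks)
    lo = shaft_length_um - terminal_length_um
    frame_counts: dict = {}
    for tr in tracks:
        inside = (tr.s_um >= lo) & (tr.s_um <= shaft_length_um)
        for tt in np.round(tr.t_s[inside], 6):
            frame_counts[tt] = frame_counts.get(tt, 0) + 1
    all_times = set()
    for tr in tracks:
        all_times.update(np.round(tr.t_s, 6))
    if not all_times:
        return 0.0
    mean_count = sum(frame_counts.values()) / len(all_times)
    return mean_count * 10.0 / terminal_length_um


# ---------------------------------------------------------------------------
# docking
# ---------------------------------------------------------------------------


def detect_docks(
    track: GranuleTrack,
    granule_diameter_um: float = 1.0,
    min_duration_s: float = 10.0,
) -> List[DockEvent]:
    """Detect docking events: maximal dwells within one diameter.

    A dock is a maximal time interval in which every position stays within
    ``granule_diameter_um / 2`` of the interval's running centroid (total
    excursion window of one diameter) for at least ``min_duration_s``.
    Intervals are selected greedily left to right and do not overlap.

    The track must be sampled at intervals no longer than a third of the
    duration criterion so that a minimal dock spans at least 3 frames.
    """
    t, s = track.t_s, track.s_um
    if len(t) < 2:
        return []
    dt_max = float(np.max(np.diff(t)))
    if dt_max > min_duration_s / 3.0 + 1e-9:
        raise ValueError(
            f"track sampled every {dt_max:.2f} s; the {min_duration_s:.0f} s "
            "criterion requires at least 3 frames per dock "
            f"(interval <= {min_duration_s / 3.0:.2f} s)"
        )
    tol = granule_diameter_um / 2.0
    docks = []
    i = 0
    n = len(t)
    while i < n:
        best_j = None
        cum = 0.0
        mn = mx = s[i]
        for j in range(i, n):
            cum += s[j]
            mn, mx = min(mn, s[j]), max(mx, s[j])
            if mx - mn > 2.0 * tol + 1e-12:
                break  # the range only grows; no larger window can be valid
            centroid = cum / (j - i + 1)
            if max(mx - centroid, centroid - mn) <= tol + 1e-12:
                best_j = j
        # best_j is the farthest extent of a valid window starting at i
        if best_j is not None and t[best_j] - t[i] >= min_duration_s - 1e-6:
            docks.append(
                DockEvent(
                    granule_id=track.granule_id,
                    position_um=float(np.mean(s[i : best_j + 1])),
                    start_s=float(t[i]),
                    end_s=float(t[best_j]),
                )
            )
            i = best_j + 1
        else:
            i += 1
    return docks


def detect_docks_all(
    tracks: Sequence[GranuleTrack],
    granule_diameter_um: float = 1.0,
    min_duration_s: float = 10.0,
) -> List[DockEvent]:
    out: List[DockEvent] = []
    for tr in tracks:
        out.extend(detect_docks(tr, granule_diameter_um, min_duration_s))
    return out


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------


def protrusion_dock_association(
    docks: Sequence[DockEvent],
    protrusions: pd.DataFrame,
    window_s: float = 10.0,
    base_radius_um: float = 1.0,
):
    """Fraction of protrusions with a dock at their base before emergence.

    A protrusion counts as dock-positive when some dock overlaps the time
    window ``[birth - window_s, birth]`` with its position within
    ``base_radius_um`` of the protrusion origin. Returns ``(fraction,
    flags)``; the fraction is NaN when there are no protrusions.
    """
    births = protrusions["birth_s"].to_numpy(dtype=float)
    origins = protrusions["origin_s_um"].to_numpy(dtype=float)
    if len(births) == 0:
        return float("nan"), np.zeros(0, dtype=bool)
    flags = np.zeros(len(births), dtype=bool)
    for d in docks:
        hit = (
            (np.abs(origins - d.position_um) <= base_radius_um)
            & (d.start_s <= births + 1e-9)
            & (d.end_s >= births - window_s - 1e-9)
        )
        flags |= hit
    return float(flags.mean()), flags


def random_site_dock_fraction(
    docks: Sequence[DockEvent],
    s_range: tuple,
    t_range: tuple,
    n_sites: int = 500,
    seed: int = 0,
    base_radius_um: float = 1.0,
):
    """Fraction of random (position, time) sites covered by a dock.

    Sites are drawn uniformly over ``s_range x t_range``; a site is positive
    when some dock covers its time point with position within
    ``base_radius_um``. Deterministic given the seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    rng = np.random.default_rng(seed)
    s_sites = rng.uniform(s_range[0], s_range[1], n_sites)
    t_sites = rng.uniform(t_range[0], t_range[1], n_sites)
    flags = np.zeros(n_sites, dtype=bool)
    for d in docks:
        flags |= (
            (np.abs(s_sites - d.position_um) <= base_radius_um)
            & (t_sites >= d.start_s - 1e-9)
            & (t_sites <= d.end_s + 1e-9)
        )
    return float(flags.mean()), flags


def random_follow_control(
    tracks: Sequence[GranuleTrack],
    protrusions: pd.DataFrame,
    s_range: tuple,
    t_range: tuple,
    n_sets: int = 20,
    seed: int = 0,
    granule_diameter_um: float = 1.0,
    min_duration_s: float = 10.0,
    window_s: float = 10.0,
    base_radius_um: float = 1.0,
    docks: Optional[Sequence[DockEvent]] = None,
):
    """Random-position follow control for the dock-to-protrusion rate.

    For each of ``n_sets`` random (time, position) queries, the granule
    nearest to the position at that time is followed forward to its first
    dock of at least ``min_duration_s``; the query scores positive when a
    protrusion is born within ``window_s`` after dock onset and within
    ``base_radius_um`` of the dock position. Queries whose nearest granule
    never docks from the query time onward are skipped. Returns
    ``(fraction_positive, n_resolved, n_skipped)``; the fraction is over
    resolved queries only.
    """
    rng = np.random.default_rng(seed)
    if docks is None:
        docks = detect_docks_all(tracks, granule_diameter_um, min_duration_s)
    docks_by_granule: dict = {}
    for d in docks:
        docks_by_granule.setdefault(d.granule_id, []).append(d)
    for lst in docks_by_granule.values():
        lst.sort(key=lambda d: d.start_s)

    births = protrusions["birth_s"].to_numpy(dtype=float)
    origins = protrusions["origin_s_um"].to_numpy(dtype=float)

    n_pos = n_resolved = n_skipped = 0
    for _ in range(n_sets):
        t_q = rng.uniform(t_range[0], t_range[1])
        s_q = rng.uniform(s_range[0], s_range[1])
        best = None
        best_dist = np.inf
        for tr in tracks:
            if tr.t_s[0] - 1e-9 <= t_q <= tr.t_s[-1] + 1e-9:
                dist = abs(tr.position_at(t_q) - s_q)
                if dist < best_dist:
                    best, best_dist = tr, dist
        if best is None:
            n_skipped += 1
            continue
        # first dock that is ongoing at, or starts after, the query time
        dock = next(
            (d for d in docks_by_granule.get(best.granule_id, []) if d.end_s >= t_q),
            None,
        )
        if dock is None:
            n_skipped += 1
            continue
        n_resolved += 1
        hit = (
            (np.abs(origins - dock.position_um) <= base_radius_um)
            & (births >= dock.start_s - 1e-9)
            & (births <= dock.start_s + window_s + 1e-9)
        )
        if hit.any():
            n_pos += 1
    frac = n_pos / n_resolved if n_resolved else float("nan")
    return frac, n_resolved, n_skipped


def summarize_motility(
    tracks: Sequence[GranuleTrack],
    window_s: float = 60.0,
    terminal_length_um: float = 70.0,
    shaft_length_um: Optional[float] = None,
) -> MotilitySummary:
    """One-stop motility summary: class fractions, speeds, density."""
    return MotilitySummary(
        fractions=motility_fractions(tracks, window_s=window_s),
        speeds=estimate_speeds(tracks),
        density_per_10um=granule_density(tracks, terminal_length_um, shaft_length_um)
        if tracks
        else None,
        n_tracks=len(tracks),
    )
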