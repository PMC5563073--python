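"""Protrusion dynamics scoring and RNA presence within branches.

Protrusions are filopodia below 5 um maximal length and branches at or above
it. Addition/removal counts are taken on the terminal 50 um over a 10 min
window at 30 s sampling; lifetimes split into short-lived (up to 30 min) and
persistent (beyond 30 min within the 60 min observation); branch lengths
split at 15 um. RNA presence inside a branch is scored per frame in three
regions — base, mid and tip — and correlated with branch lifetime and
maximal length. Axon navigation is summarized by tip velocity with a
stalling flag below 5 um/hr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ProtrusionEvent",
    "PresenceDurations",
    "events_from_table",
    "classify_protrusion",
    "count_dynamics",
    "lifetime_class",
    "length_class",
    "rna_presence",
    "presence_correlations",
    "navigation_metrics",
]

FILOPODIUM_MAX_UM = 5.0
SHORT_LIVED_MAX_MIN = 30.0
LONG_BRANCH_MIN_UM = 15.0
STALL_THRESH_UM_PER_HR = 5.0


@dataclass
class ProtrusionEvent:
    """Birth/death and per-frame length of one filopodium or branch."""

    protrusion_id: int
    birth_s: float
    origin_s_um: float
    death_s: Optional[float] = None  # None while censored
    length_t_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    length_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.length_t_s = np.asarray(self.length_t_s, dtype=float)
        self.length_um = np.asarray(self.length_um, dtype=float)
        if (self.length_um < 0).any():
            raise ValueError("protrusion lengths must be non-negative")

    @property
    def max_length_um(self) -> float:
        return float(self.length_um.max()) if len(self.length_um) else 0.0

    @property
    def lifetime_s(self) -> Optional[float]:
        if self.death_s is None:
            return None
        return self.death_s - self.birth_s

    def length_at(self, t: float) -> float:
        if len(self.length_t_s) == 0:
            return 0.0
        return float(np.interp(t, self.length_t_s, self.length_um))


@dataclass
class PresenceDurations:
    """Cumulative seconds an RNA granule occupies each branch region."""

    protrusion_id: int
    base_s: float = 0.0
    mid_s: float = 0.0
    tip_s: float = 0.0

    @property
    def total_s(self) -> float:
        return self.base_s + self.mid_s + self.tip_s


def events_from_table(
    events: pd.DataFrame, lengths: Optional[pd.DataFrame] = None
) -> list:
    """Build :class:`ProtrusionEvent` objects from tidy event/length tables."""
    by_id = {}
    if lengths is not None:
        for pid, grp in lengths.groupby("protrusion_id"):
            grp = grp.sort_values("t_s")
            by_id[pid] = (grp["t_s"].to_numpy(float), grp["length_um"].to_numpy(float))
    out = []
    for row in events.itertuples():
        t_l, l = by_id.get(row.protrusion_id, (np.empty(0), np.empty(0)))
        if len(l) == 0 and hasattr(row, "max_length_um"):
            t_l, l = np.array([row.birth_s]), np.array([row.max_length_um])
        death = None if pd.isna(row.death_s) else float(row.death_s)
        out.append(
            ProtrusionEvent(
                protrusion_id=int(row.protrusion_id),
                birth_s=float(row.birth_s),
                death_s=death,
                origin_s_um=float(row.origin_s_um),
                length_t_s=t_l,
                length_um=l,
            )
        )
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_protrusion(max_length_um: float) -> str:
    """``filopodium`` below 5 um maximal length, ``branch`` at or above.

    The printed definitions ("< 5 um" and "> 5 um") leave exactly 5 um
    unassigned; the boundary goes to ``branch`` here.
    """
    if max_length_um < 0:
        raise ValueError("length cannot be negative")
    return "filopodium" if max_length_um < FILOPODIUM_MAX_UM else "branch"


def lifetime_class(lifetime_s: float) -> str:
    """``short_lived`` up to 30 min, ``persistent`` beyond (0-30 / 31-60 bins)."""
    if lifetime_s < 0:
        raise ValueError("lifetime cannot be negative")
    return "short_lived" if lifetime_s <= SHORT_LIVED_MAX_MIN * 60.0 else "persistent"


def length_class(max_length_um: float) -> str:
    """``short`` for 5-15 um branches, ``long`` above 15 um."""
    if max_length_um < 0:
        raise ValueError("length cannot be negative")
    return "short" if max_length_um <= LONG_BRANCH_MIN_UM else "long"


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def count_dynamics(
    events: Sequence[ProtrusionEvent],
    window_s: float = 600.0,
    terminal_um: float = 50.0,
    shaft_length_um: Optional[float] = None,
    observation_s: Optional[float] = None,
) -> dict:
    """Added/removed counts by protrusion type on the terminal segment.

    ``added`` counts births and ``removed`` counts deaths inside
    ``[0, window_s]`` whose origin lies on the terminal ``terminal_um`` of
    the shaft. A protrusion seen in a single frame counts as both added and
    removed. Raises when the requested window exceeds the observation span.
    """
    if observation_s is not None and window_s > observation_s + 1e-9:
        raise ValueError("counting window exceeds the observation span")
    if shaft_length_um is None:
        shaft_length_um = max((e.origin_s_um for e in events), default=0.0)
    lo = shaft_length_um - terminal_um
    counts = {
        "filopodia_added": 0,
        "filopodia_removed": 0,
        "branches_added": 0,
        "branches_removed": 0,
    }
    for e in events:
        if not (lo - 1e-9 <= e.origin_s_um <= shaft_length_um + 1e-9):
            continue
        kind = "filopodia" if classify_protrusion(e.max_length_um) == "filopodium" else "branches"
        if 0.0 <= e.birth_s <= window_s:
            counts[f"{kind}_added"] += 1
        if e.death_s is not None and 0.0 <= e.death_s <= window_s:
            counts[f"{kind}_removed"] += 1
    return counts


# ---------------------------------------------------------------------------
# RNA presence within branches
# ---------------------------------------------------------------------------


def rna_presence(
    protrusion: ProtrusionEvent,
    tracks_table: pd.DataFrame,
    frame_interval_s: float,
    base_radius_um: float = 1.0,
    tip_fraction: float = 0.2,
    tip_min_um: float = 1.0,
    observation_s: Optional[float] = None,
) -> PresenceDurations:
    """Score cumulative granule presence at the base, mid and tip regions.

    The track table uses a branch coordinate: rows with ``branch_id`` equal
    to the protrusion id carry ``d_um``, the distance from the branch origin
    along the branch; rows without a branch id are shaft-resident and count
    as base presence when within ``base_radius_um`` of the origin. Per
    frame, the tip region is the distal ``tip_fraction`` of the current
    branch length (at least ``tip_min_um``); the base region is within
    ``base_radius_um`` of the origin; the remainder of the branch is mid.
    Each occupied frame contributes ``frame_interval_s`` seconds.
    """
    out = PresenceDurations(protrusion_id=protrusion.protrusion_id)
    if tracks_table.empty:
        return out
    t_end = protrusion.death_s if protrusion.death_s is not None else np.inf
    if observation_s is not None:
        t_end = min(t_end, observation_s)
    has_branch = "branch_id" in tracks_table.columns
    for t_frame, grp in tracks_table.groupby("t_s"):
        if not (protrusion.birth_s - 1e-9 <= t_frame <= t_end + 1e-9):
            continue
        length = protrusion.length_at(t_frame)
        tip_span = max(tip_fraction * length, tip_min_um)
        base_hit = mid_hit = tip_hit = False
        for row in grp.itertuples():
            bid = getattr(row, "branch_id", np.nan) if has_branch else np.nan
            if has_branch and np.isfinite(bid) and int(bid) == protrusion.protrusion_id:
                d = float(row.d_um)
                if d < 0 or d > length + 1e-9:
                    continue
                if d <= base_radius_um:
                    base_hit = True
                elif d >= length - tip_span:
                    tip_hit = True
                else:
                    mid_hit = True
            else:
                if abs(float(row.s_um) - protrusion.origin_s_um) <= base_radius_um:
                    base_hit = True
        out.base_s += frame_interval_s * base_hit
        out.mid_s += frame_interval_s * mid_hit
        out.tip_s += frame_interval_s * tip_hit
    return out


def presence_correlations(
    durations: Sequence[PresenceDurations],
    lifetimes_s: Sequence[float],
    max_lengths_um: Sequence[float],
) -> pd.DataFrame:
    """Pearson r of per-region presence time against lifetime and length.

    Returns a tidy frame with columns ``region, against, r, p, n``.
    """
    rows = []
    regions = {
        "base": [d.base_s for d in durations],
        "mid": [d.mid_s for d in durations],
        "tip": [d.tip_s for d in durations],
    }
    targets = {"lifetime": np.asarray(lifetimes_s, float),
               "max_length": np.asarray(max_lengths_um, float)}
    for region, vals in regions.items():
        vals = np.asarray(vals, float)
        for name, target in targets.items():
            r, p = scipy.stats.pearsonr(vals, target)
            rows.append(
                {"region": region, "against": name, "r": float(r), "p": float(p),
                 "n": len(vals)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# navigation
# ---------------------------------------------------------------------------


def navigation_metrics(t_s, tip_xy_um) -> dict:
    """Axon tip velocity (um/hr) over up to 1 hr, with a stalling flag.

    Velocity is the net tip displacement scaled to one hour; the axon is
    stalled when it moves strictly less than 5 um over the hour.
    """
    t = np.asarray(t_s, dtype=float)
    xy = np.atleast_2d(np.asarray(tip_xy_um, dtype=float))
    if len(t) < 2:
        raise ValueError("need at least two tip positions")
    span_hr = (t[-1] - t[0]) / 3600.0
    if span_hr <= 0:
        raise ValueError("time span must be positive")
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    velocity = net / span_hr
    return {"velocity_um_per_hr": velocity, "stalled": bool(velocity < STALL_THRESH_UM_PER_HR)}
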