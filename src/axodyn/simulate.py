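"""Synthetic axon time-lapse generator with known ground truth.

Three generators cover the data the analysis modules consume:

``simulate_tracks``
    A population of granule tracks with run-and-pause kinetics whose 60 s
    window statistics (motility-class fractions, run speeds, density) equal
    the preset values in expectation.

``simulate_branching_axon``
    Protrusion birth/death events plus the granule tracks that realize
    docking events, constructed so that the three dock/protrusion
    association probabilities (dock before protrusion, protrusion after
    dock, random-site coverage) hold in expectation and are independently
    tunable.

``generate_frap_series``
    Masked FRAP image series whose noiseless normalized recovery follows
    ``A (1 - exp(-t/tau))`` exactly, with spatially uniform or focal
    (hotspot) recovery patterns.

The granule population of a combined dataset is partitioned spatially: the
trafficking cohort lives on the proximal shaft and the docking cohort on the
protrusion-bearing terminal segment, so that each printed statistic is
recovered on the cohort that defines it (see docs/methods.md for why a
single homogeneous population cannot satisfy all of them at once).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .frap import FrapSeries
from .geometry import AxonGeometry
from .groundtruth import GroundTruth, TrueDock, TrueProtrusion
from .presets import BranchEventPreset, FrapPreset, GranuleKineticsPreset, PresetError

__all__ = [
    "SimulatedDataset",
    "simulate_tracks",
    "simulate_branching_axon",
    "generate_dataset",
    "generate_frap_series",
    "default_frap_scene",
]

#: Frame interval of the docking/branching time-lapse: 18 frames/min, inside
#: the 3-6 s/frame acquisition range, and the largest interval for which a
#: 10 s dock still spans >= 4 frames on the grid.
BRANCHING_DT_S = 10.0 / 3.0

TRACK_COLUMNS = ["granule_id", "frame", "t_s", "x_px", "y_px", "s_um", "cohort"]


@dataclass
class SimulatedDataset:
    """Track/event tables plus the ground truth that generated them."""

    tracks: pd.DataFrame
    protrusions: pd.DataFrame
    protrusion_lengths: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# granule kinetics
# ---------------------------------------------------------------------------


def _run_pause_steps(rng, n_steps, dt_s, kin):
    """Boolean run/pause flag per frame step for one mobile granule."""
    flags = np.empty(n_steps, dtype=bool)
    i = 0
    running = True  # start in a run so mobile granules always clear 1 um
    pause_cap = max(1, int(kin.pause_max_s // dt_s))
    while i < n_steps:
        if running:
            k = max(1, int(round(rng.exponential(kin.run_mean_s) / dt_s)))
        else:
            k = min(pause_cap, max(1, int(round(rng.exponential(kin.pause_mean_s) / dt_s))))
        k = min(k, n_steps - i)
        flags[i : i + k] = running
        running = not running
        i += k
    return flags


def _directional_path(rng, s0, sign, v_um_min, n_frames, dt_s, kin):
    steps = _run_pause_steps(rng, n_frames - 1, dt_s, kin)
    ds = np.where(steps, sign * v_um_min * dt_s / 60.0, 0.0)
    return s0 + np.concatenate([[0.0], np.cumsum(ds)])


def _bidirectional_path(rng, s0, n_frames, dt_s, kin):
    # alternating runs of 1.2-3 um with 1-frame pauses; every run clears the
    # 1 um reversal criterion so the window classifier sees a reversal
    ds = np.zeros(n_frames - 1)
    sign = rng.choice([-1.0, 1.0])
    i = 0
    while i < n_frames - 1:
        v = kin.v_antero_um_min if sign > 0 else kin.v_retro_um_min
        step = v * dt_s / 60.0
        k = max(int(math.ceil(1.2 / step)), int(round(rng.uniform(1.2, 3.0) / step)))
        k = min(k, n_frames - 1 - i)
        ds[i : i + k] = sign * step
        i += k + 1  # one pause frame between runs
        sign = -sign
    return s0 + np.concatenate([[0.0], np.cumsum(ds)])


def simulate_tracks(
    geometry: Optional[AxonGeometry] = None,
    kinetics: Optional[GranuleKineticsPreset] = None,
    *,
    duration_s: float = 60.0,
    dt_s: float = 3.0,
    seed: int = 0,
    n_granules: Optional[int] = None,
    s_range: Optional[tuple] = None,
    cohort: str = "kinetics",
    granule_id_offset: int = 0,
):
    """Simulate a population of granule tracks along the shaft.

    Granules are assigned a motility class by the preset fractions and move
    with run-and-pause kinetics at the preset speeds. When ``n_granules`` is
    omitted the count is Poisson with mean ``density * length / 10``; the
    initialization region is padded by the maximum 1-window excursion so the
    per-frame count inside ``s_range`` is stationary (no net boundary flux).

    Returns ``(tracks, ground_truth)`` where ``tracks`` is a tidy frame with
    columns ``granule_id, frame, t_s, x_px, y_px, s_um, cohort``.
    """
    geometry = geometry if geometry is not None else AxonGeometry()
    kinetics = kinetics if kinetics is not None else GranuleKineticsPreset()
    rng = np.random.default_rng(seed)
    s0, s1 = s_range if s_range is not None else (0.0, geometry.terminal_length_um)
    if s1 <= s0:
        raise PresetError("s_range must have positive length")

    vmax = max(kinetics.v_antero_um_min, kinetics.v_retro_um_min)
    if n_granules is None:
        pad = vmax * duration_s / 60.0 + 2.0
        lo, hi = s0 - pad, s1 + pad
        n = int(rng.poisson(kinetics.density_per_10um * (hi - lo) / 10.0))
    else:
        lo, hi = s0, s1
        n = int(n_granules)

    times = np.arange(0.0, duration_s + dt_s / 2.0, dt_s)
    n_frames = len(times)
    classes = rng.choice(
        ["anterograde", "retrograde", "bidirectional", "stationary"],
        size=n,
        p=[
            kinetics.frac_antero,
            kinetics.frac_retro,
            kinetics.frac_bidir,
            kinetics.frac_stationary,
        ],
    )
    starts = rng.uniform(lo, hi, size=n)

    frames_idx = np.arange(n_frames)
    records = []
    gclasses = {}
    for j in range(n):
        gid = granule_id_offset + j
        cls = classes[j]
        gclasses[gid] = str(cls)
        if cls == "stationary":
            s = starts[j] + rng.normal(0.0, kinetics.jitter_stationary_um, n_frames)
        elif cls == "bidirectional":
            s = _bidirectional_path(rng, starts[j], n_frames, dt_s, kinetics)
            s = s + rng.normal(0.0, kinetics.jitter_mobile_um, n_frames)
        else:
            sign = 1.0 if cls == "anterograde" else -1.0
            v = kinetics.v_antero_um_min if sign > 0 else kinetics.v_retro_um_min
            s = _directional_path(rng, starts[j], sign, v, n_frames, dt_s, kinetics)
            s = s + rng.normal(0.0, kinetics.jitter_mobile_um, n_frames)
        xy = geometry.point_at(s) / geometry.pixel_size_um
        records.append(
            pd.DataFrame(
                {
                    "granule_id": gid,
                    "frame": frames_idx,
                    "t_s": times,
                    "x_px": xy[:, 0],
                    "y_px": xy[:, 1],
                    "s_um": s,
                    "cohort": cohort,
                }
            )
        )
    tracks = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    gt = GroundTruth(
        rng_seed=int(seed),
        true_rates=asdict(kinetics),
        granule_classes=gclasses,
    )
    return tracks, gt


# ---------------------------------------------------------------------------
# dock-coupled protrusion events
# ---------------------------------------------------------------------------


def _dock_durations(rng, n, dt_s, min_duration_s, target_mean_s):
    """Grid-aligned dock durations >= the criterion, tuned to a target mean."""
    min_span = dt_s * math.ceil(min_duration_s / dt_s - 1e-9)
    lam = max(0.0, (target_mean_s - min_span) / dt_s)
    return min_span + dt_s * rng.poisson(lam, size=n)


def simulate_branching_axon(
    geometry: Optional[AxonGeometry] = None,
    branching: Optional[BranchEventPreset] = None,
    kinetics: Optional[GranuleKineticsPreset] = None,
    *,
    duration_s: float = 600.0,
    dt_s: float = BRANCHING_DT_S,
    seed: int = 0,
    n_transport: Optional[int] = None,
    granule_id_offset: int = 0,
) -> SimulatedDataset:
    """Simulate one axon's protrusion events and dock-realizing tracks.

    Protrusions are scheduled first (Poisson in time, uniform on the terminal
    protrusion segment). A fraction ``p_dock_given_protrusion`` of them get a
    coupled dock ending within the 10 s window before birth; uncoupled docks
    are added so that the coupled fraction of all docks equals
    ``p_protrusion_given_dock``, with durations tuned so the overlap-corrected
    (position, time) coverage matches ``background_site_dock_coverage``.
    Uncoupled docks are rejection-sampled away from protrusion scoring
    windows so they cannot create accidental positives. Every dock is
    realized as a granule track (dwell with sub-diameter jitter, then a
    departure run); a few non-docking transport granules are added as
    distractors for the nearest-granule follow control.
    """
    geometry = geometry if geometry is not None else AxonGeometry()
    branching = branching if branching is not None else BranchEventPreset()
    kinetics = kinetics if kinetics is not None else GranuleKineticsPreset()
    rng = np.random.default_rng(seed)

    L = geometry.terminal_length_um
    seg_len = min(branching.protrusion_segment_um, L)
    seg = (L - seg_len, L)
    T = float(duration_s)
    r = branching.base_radius_um
    window_s = 10.0

    # --- protrusion schedule -------------------------------------------------
    rate = (
        (branching.filopodia_add_rate_per_10min + branching.branch_add_rate_per_10min)
        * T
        / 600.0
    )
    n_prot = int(rng.poisson(rate))
    total_rate = (
        branching.filopodia_add_rate_per_10min + branching.branch_add_rate_per_10min
    )
    p_branch = (
        branching.branch_add_rate_per_10min / total_rate if total_rate > 0 else 0.0
    )
    births = np.sort(rng.uniform(window_s + 2.0, T, size=n_prot))
    origins = rng.uniform(seg[0], seg[1], size=n_prot)
    kinds = np.where(rng.random(n_prot) < p_branch, "branch", "filopodium")
    max_len = np.where(
        kinds == "branch", rng.uniform(6.0, 25.0, n_prot), rng.uniform(1.5, 4.5, n_prot)
    )
    life_mean = np.where(
        kinds == "branch",
        branching.branch_lifetime_mean_s,
        branching.filopodium_lifetime_mean_s,
    )
    deaths = births + rng.exponential(life_mean)
    censored = deaths >= T

    protrusions = pd.DataFrame(
        {
            "protrusion_id": np.arange(n_prot),
            "birth_s": births,
            "death_s": np.where(censored, np.nan, deaths),
            "origin_s_um": origins,
            "max_length_um": max_len,
            "kind": kinds,
        }
    )

    # --- dock budget ----------------------------------------------------------
    coupled = rng.random(n_prot) < branching.p_dock_given_protrusion
    n_c = int(coupled.sum())
    if branching.p_protrusion_given_dock > 0:
        n_u = int(round(n_c * (1.0 / branching.p_protrusion_given_dock - 1.0)))
    else:
        n_u = 0
    n_docks = n_c + n_u

    cov = branching.background_site_dock_coverage
    if n_docks > 0 and cov > 0 and cov < 1:
        area_req = -math.log(1.0 - cov) * seg_len * T
        target_mean = area_req / (2.0 * r * n_docks)
    else:
        target_mean = branching.dock_min_duration_s
    durations = _dock_durations(
        rng, n_docks, dt_s, branching.dock_min_duration_s, target_mean
    )

    docks = []
    # coupled docks: onset 4-8 s (snapped up to the grid) before birth
    ci = 0
    for pid in np.flatnonzero(coupled):
        dur = durations[ci]
        u = rng.uniform(4.0, 8.0)
        start = dt_s * math.ceil((births[pid] - u) / dt_s)
        docks.append((origins[pid], start, start + dur, int(pid)))
        ci += 1

    # uncoupled docks: rejection-sampled clear of protrusion scoring windows
    margin_s, margin_um = dt_s, 0.5
    for k in range(n_u):
        dur = durations[n_c + k]
        placed = False
        for _ in range(200):
            pos = rng.uniform(seg[0], seg[1])
            max_start = int((T - dur) // dt_s)
            start = dt_s * rng.integers(0, max(1, max_start) + 1)
            end = start + dur
            near = np.abs(origins - pos) <= r + margin_um
            if near.any():
                b = births[near]
                overlaps = (start <= b + margin_s) & (end >= b - window_s - margin_s)
                follows = (b - start >= -margin_s) & (b - start <= window_s + margin_s)
                if (overlaps | follows).any():
                    continue
            docks.append((pos, start, end, None))
            placed = True
            break
        if not placed:  # crowded axon: place anyway rather than under-count
            docks.append((pos, start, end, None))

    # --- realize docks as granule tracks -------------------------------------
    # departure step: large enough that the first post-dwell frame falls
    # outside the diameter window even after the running centroid is pulled
    # toward it, so the detected dock ends exactly at the dwell end
    dep_step_um = 0.9
    n_dep = 2
    jit = 0.08
    records = []
    true_docks = []
    gid = granule_id_offset
    for pos, start, end, pid in docks:
        n_dwell = int(round((end - start) / dt_s)) + 1
        t_frames = start + dt_s * np.arange(n_dwell + n_dep)
        s = np.empty(len(t_frames))
        s[:n_dwell] = pos + rng.normal(0.0, jit, n_dwell)
        sign = rng.choice([-1.0, 1.0])
        s[n_dwell:] = pos + sign * dep_step_um * np.arange(1, n_dep + 1)
        keep = t_frames <= T + 1e-9
        t_frames, s = t_frames[keep], s[keep]
        xy = geometry.point_at(s) / geometry.pixel_size_um
        records.append(
            pd.DataFrame(
                {
                    "granule_id": gid,
                    "frame": np.round(t_frames / dt_s).astype(int),
                    "t_s": t_frames,
                    "x_px": xy[:, 0],
                    "y_px": xy[:, 1],
                    "s_um": s,
                    "cohort": "docking",
                }
            )
        )
        true_docks.append(
            TrueDock(
                granule_id=gid,
                position_um=float(pos),
                start_s=float(start),
                end_s=float(end),
                coupled_protrusion_id=pid,
            )
        )
        gid += 1

    # --- transport distractors (mobile, never docking) ------------------------
    nt = int(rng.poisson(3)) if n_transport is None else int(n_transport)
    times = np.arange(0.0, T + dt_s / 2.0, dt_s)
    for _ in range(nt):
        sgn = rng.choice([-1.0, 1.0])
        v = kinetics.v_antero_um_min if sgn > 0 else kinetics.v_retro_um_min
        s = np.empty(len(times))
        s[0] = rng.uniform(seg[0], seg[1])
        for i in range(1, len(times)):
            nxt = s[i - 1] + sgn * v * dt_s / 60.0
            if nxt < seg[0] or nxt > seg[1]:  # reflect at segment ends
                sgn = -sgn
                v = kinetics.v_antero_um_min if sgn > 0 else kinetics.v_retro_um_min
                nxt = s[i - 1] + sgn * v * dt_s / 60.0
            s[i] = nxt
        xy = geometry.point_at(s) / geometry.pixel_size_um
        records.append(
            pd.DataFrame(
                {
                    "granule_id": gid,
                    "frame": np.arange(len(times)),
                    "t_s": times,
                    "x_px": xy[:, 0],
                    "y_px": xy[:, 1],
                    "s_um": s,
                    "cohort": "transport",
                }
            )
        )
        gid += 1

    tracks = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )

    # --- per-frame protrusion lengths (30 s sampling) -------------------------
    growth_um_s = 5.0 / 60.0
    length_rows = []
    for p in protrusions.itertuples():
        t_end = T if np.isnan(p.death_s) else min(p.death_s, T)
        ts = np.arange(math.ceil(p.birth_s / 30.0) * 30.0, t_end + 1e-9, 30.0)
        lengths = np.minimum(p.max_length_um, growth_um_s * (ts - p.birth_s))
        length_rows.append(
            pd.DataFrame(
                {"protrusion_id": p.protrusion_id, "t_s": ts, "length_um": lengths}
            )
        )
    lengths = (
        pd.concat(length_rows, ignore_index=True)
        if length_rows
        else pd.DataFrame(columns=["protrusion_id", "t_s", "length_um"])
    )

    gt = GroundTruth(
        rng_seed=int(seed),
        true_rates={**asdict(branching), "duration_s": T, "dt_s": dt_s,
                    "n_coupled": n_c, "n_uncoupled": n_u},
        true_docks=true_docks,
        true_protrusions=[
            TrueProtrusion(
                protrusion_id=int(p.protrusion_id),
                birth_s=float(p.birth_s),
                death_s=None if np.isnan(p.death_s) else float(p.death_s),
                origin_s_um=float(p.origin_s_um),
                max_length_um=float(p.max_length_um),
                kind=str(p.kind),
            )
            for p in protrusions.itertuples()
        ],
    )
    return SimulatedDataset(tracks, protrusions, lengths, gt)


def generate_dataset(
    geometry: Optional[AxonGeometry] = None,
    kinetics: Optional[GranuleKineticsPreset] = None,
    branching: Optional[BranchEventPreset] = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Full synthetic dataset: trafficking cohort plus docking cohort.

    The docking cohort (dock-realizing tracks, protrusion events) occupies
    the terminal protrusion segment; the trafficking cohort (run-and-pause
    population carrying the motility statistics) occupies the proximal
    remainder of the shaft. Identical seed and configuration give identical
    output.
    """
    geometry = geometry if geometry is not None else AxonGeometry()
    kinetics = kinetics if kinetics is not None else GranuleKineticsPreset()
    branching = branching if branching is not None else BranchEventPreset()

    branch_ds = simulate_branching_axon(
        geometry, branching, kinetics, seed=seed, granule_id_offset=100_000
    )
    prox_end = max(
        geometry.terminal_length_um - branching.protrusion_segment_um, 0.0
    )
    if prox_end > 0:
        kin_tracks, kin_gt = simulate_tracks(
            geometry, kinetics, seed=seed + 1, s_range=(0.0, prox_end)
        )
    else:
        kin_tracks = pd.DataFrame(columns=TRACK_COLUMNS)
        kin_gt = GroundTruth(rng_seed=int(seed + 1))

    tracks = pd.concat([kin_tracks, branch_ds.tracks], ignore_index=True)
    gt = GroundTruth(
        rng_seed=int(seed),
        true_rates={"kinetics": asdict(kinetics), **branch_ds.ground_truth.true_rates},
        true_docks=branch_ds.ground_truth.true_docks,
        true_protrusions=branch_ds.ground_truth.true_protrusions,
        granule_classes=kin_gt.granule_classes,
    )
    return SimulatedDataset(
        tracks, branch_ds.protrusions, branch_ds.protrusion_lengths, gt
    )


# ---------------------------------------------------------------------------
# FRAP series
# ---------------------------------------------------------------------------


def default_frap_scene(shape=(120, 120), pixel_size_um=0.25):
    """A small axon-terminal scene: shaft band, two branches, masks, sites.

    Returns a dict with ``shaft_mask``, ``branch_mask``, ``roi_mask``,
    ``background_region`` (all boolean images) and ``dock_sites_px`` — six
    (row, col) sites at branch bases, mid-branches and tips where focal
    recovery hotspots are placed.
    """
    h, w = shape
    shaft = np.zeros(shape, dtype=bool)
    branch = np.zeros(shape, dtype=bool)
    row = int(h * 0.5)
    shaft[row - 2 : row + 3, int(w * 0.07) : int(w * 0.93)] = True
    b1c, b2c = int(w * 0.33), int(w * 0.66)
    branch[int(h * 0.17) : row - 2, b1c - 1 : b1c + 2] = True
    branch[row + 3 : int(h * 0.83), b2c - 1 : b2c + 2] = True
    roi = shaft | branch
    background = np.zeros(shape, dtype=bool)
    background[3 : int(h * 0.1), 3 : w - 3] = True
    background &= ~roi
    sites = [
        (row - 4, b1c), (int(h * 0.3), b1c), (int(h * 0.19), b1c),
        (row + 4, b2c), (int(h * 0.7), b2c), (int(h * 0.81), b2c),
    ]
    return {
        "shaft_mask": shaft,
        "branch_mask": branch,
        "roi_mask": roi,
        "background_region": background,
        "dock_sites_px": sites,
        "pixel_size_um": pixel_size_um,
    }


def generate_frap_series(
    preset: FrapPreset,
    dock_sites_px=None,
    *,
    seed: int = 0,
    scene=None,
    background_level: float = 10.0,
    prebleach_level: float = 100.0,
    postbleach_floor: float = 5.0,
):
    """Generate a FRAP image series from a recovery preset.

    Pre-bleach frames sit at the plateau intensity; post-bleach frames
    recover as ``A (1 - exp(-t/tau))`` of the pre-bleach signal, spatially
    uniform or concentrated in Gaussian hotspots at ``dock_sites_px`` whose
    spatial mean over the axon mask is 1 (so the mask-averaged recovery is
    identical in both modes). Relative Gaussian intensity noise and an
    optional per-frame multiplicative bleach decay are applied last. Time 0
    is the first post-bleach frame.

    Returns ``(series, ground_truth_dict)``.
    """
    scene = scene if scene is not None else default_frap_scene()
    if preset.hotspot_mode == "focal_at_docks":
        sites = dock_sites_px if dock_sites_px is not None else scene["dock_sites_px"]
        if sites is None or len(sites) == 0:
            raise PresetError("focal_at_docks mode requires non-empty dock sites")
    rng = np.random.default_rng(seed)
    roi = scene["roi_mask"]
    shape = roi.shape
    A = preset.plateau_amplitude

    if preset.hotspot_mode == "focal_at_docks":
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        weight = np.zeros(shape)
        s2 = preset.hotspot_sigma_px**2
        for r0, c0 in sites:
            weight += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s2))
        mean_w = weight[roi].mean()
        if mean_w <= 0:
            raise PresetError("hotspot sites do not overlap the axon mask")
        # amplitude scales the spatial contrast around the mask mean of 1,
        # so the mask-averaged recovery is amplitude-independent
        weight = 1.0 + preset.hotspot_amplitude * (weight / mean_w - 1.0)
        weight = np.clip(weight, 0.0, None)
    else:
        weight = np.ones(shape)

    t_s = np.arange(0.0, preset.total_s + preset.frame_interval_s / 2.0,
                    preset.frame_interval_s)

    def _noisy(frame, k):
        out = frame
        if preset.noise_sd > 0:
            out = out * (1.0 + preset.noise_sd * rng.standard_normal(shape))
        if preset.bleach_rate > 0:
            out = out * math.exp(-preset.bleach_rate * k)
        return np.clip(out, 0.0, None)

    pre = np.empty((preset.n_pre_frames, *shape))
    base = np.full(shape, background_level)
    for i in range(preset.n_pre_frames):
        frame = base.copy()
        frame[roi] += prebleach_level
        pre[i] = _noisy(frame, 0)

    post = np.empty((len(t_s), *shape))
    for i, t in enumerate(t_s):
        rec = A * (1.0 - math.exp(-t / preset.tau_s))
        frame = base.copy()
        frame[roi] += postbleach_floor + prebleach_level * rec * weight[roi]
        post[i] = _noisy(frame, i)

    series = FrapSeries(
        pre_bleach=pre,
        post_bleach=post,
        t_s=t_s,
        roi_mask=roi,
        shaft_mask=scene["shaft_mask"],
        branch_mask=scene["branch_mask"],
        background_region=scene["background_region"],
        frame_interval_s=preset.frame_interval_s,
        pixel_size_um=scene.get("pixel_size_um", 0.25),
    )
    gt = {
        "plateau_amplitude": A,
        "tau_s": preset.tau_s,
        "anchor": tuple(preset.recovery_at_t),
        "hotspot_mode": preset.hotspot_mode,
        "rng_seed": int(seed),
    }
    return series, gt
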