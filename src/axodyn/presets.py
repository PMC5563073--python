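"""Parameter presets for the synthetic axon time-lapse generator.

The presets encode the population statistics that the estimators in the
analysis modules are expected to recover: granule density and run speeds,
motility-class fractions over a 60 s window, the dock/protrusion coupling
probabilities, protrusion addition rates, and FRAP recovery anchors for the
translation-reporter constructs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GranuleKineticsPreset",
    "BranchEventPreset",
    "FrapPreset",
    "FRAP_PRESETS",
    "frap_preset",
]


class PresetError(ValueError):
    """Raised when a preset violates its invariants."""


@dataclass(frozen=True)
class GranuleKineticsPreset:
    """Run-and-pause transport statistics of axonal RNA granules.

    Defaults are the population statistics reported for endogenous RNA
    granules in retinal axon terminals in vivo: density 2.6 granules/10 um,
    anterograde runs at 10.0 um/min and retrograde runs at 11.4 um/min, and
    per-minute motility-class fractions of 25.6% anterograde, 27.7%
    retrograde, 5.9% bidirectional and 40.8% stationary.
    """

    density_per_10um: float = 2.6
    v_antero_um_min: float = 10.0
    v_retro_um_min: float = 11.4
    frac_antero: float = 0.256
    frac_retro: float = 0.277
    frac_bidir: float = 0.059
    frac_stationary: float = 0.408
    granule_diameter_um: float = 1.0
    # kinetic nuisance parameters (not printed statistics): exponential
    # run/pause waiting times, chosen so 60 s window classification is exact
    run_mean_s: float = 15.0
    pause_mean_s: float = 6.0
    pause_max_s: float = 9.0  # pauses stay below the 10 s dock criterion
    jitter_stationary_um: float = 0.08
    jitter_mobile_um: float = 0.02

    def __post_init__(self) -> None:
        fr = (self.frac_antero, self.frac_retro, self.frac_bidir, self.frac_stationary)
        if any(f < 0 for f in fr):
            raise PresetError("motility fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise PresetError(f"motility fractions must sum to 1, got {sum(fr)!r}")
        if self.v_antero_um_min <= 0 or self.v_retro_um_min <= 0:
            raise PresetError("run speeds must be positive")
        if self.density_per_10um < 0:
            raise PresetError("density must be non-negative")
        if self.granule_diameter_um <= 0:
            raise PresetError("granule diameter must be positive")

    @property
    def fractions(self) -> dict:
        return {
            "anterograde": self.frac_antero,
            "retrograde": self.frac_retro,
            "bidirectional": self.frac_bidir,
            "stationary": self.frac_stationary,
        }


@dataclass(frozen=True)
class BranchEventPreset:
    """Dock-coupled protrusion birth/death statistics.

    The three association probabilities are independently tunable:
    ``p_dock_given_protrusion`` (84% of protrusions are preceded by a dock),
    ``p_protrusion_given_dock`` (22% of docks are followed by a protrusion),
    and ``background_site_dock_coverage`` (16% of random (position, time)
    sites fall on a dock). Addition rates default to 50 filopodia and 8
    branches per 10 min on the terminal 50 um.
    """

    p_dock_given_protrusion: float = 0.84
    p_protrusion_given_dock: float = 0.22
    background_site_dock_coverage: float = 0.16
    dock_min_duration_s: float = 10.0
    filopodia_add_rate_per_10min: float = 50.0
    branch_add_rate_per_10min: float = 8.0
    protrusion_segment_um: float = 50.0
    base_radius_um: float = 1.0
    filopodium_lifetime_mean_s: float = 90.0
    branch_lifetime_mean_s: float = 400.0

    def __post_init__(self) -> None:
        for name in (
            "p_dock_given_protrusion",
            "p_protrusion_given_dock",
            "background_site_dock_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PresetError(f"{name} must be in [0, 1], got {v!r}")
        if self.dock_min_duration_s <= 0:
            raise PresetError("dock_min_duration_s must be positive")
        if self.filopodia_add_rate_per_10min < 0 or self.branch_add_rate_per_10min < 0:
            raise PresetError("addition rates must be non-negative")


@dataclass(frozen=True)
class FrapPreset:
    """FRAP recovery model for one reporter construct.

    Recovery follows ``R(t) = A (1 - exp(-t / tau_s))`` with the plateau
    ``A`` derived from a (time, fraction) anchor pair so that the noiseless
    normalized recovery at the anchor time equals the anchor fraction
    exactly. ``hotspot_mode`` selects spatially uniform recovery or focal
    Gaussian hotspots at supplied dock sites.
    """

    name: str = "venus_bactin"
    tau_s: float = 100.0
    recovery_at_t: tuple = (300.0, 0.186)
    hotspot_mode: str = "uniform"  # "uniform" | "focal_at_docks"
    hotspot_sigma_px: float = 3.0
    hotspot_amplitude: float = 1.0  # 0 reduces focal mode to uniform recovery
    noise_sd: float = 0.05
    bleach_rate: float = 0.0
    total_s: float = 300.0
    frame_interval_s: float = 1.0
    n_pre_frames: int = 5

    def __post_init__(self) -> None:
        t, frac = self.recovery_at_t
        if frac >= 1.0:
            raise PresetError("anchor recovery fraction must be < 1")
        if frac < 0 or t <= 0 or self.tau_s <= 0:
            raise PresetError("invalid recovery anchor or time constant")
        if not 0.0 < self.plateau_amplitude < 1.0 and frac > 0:
            raise PresetError("derived plateau amplitude must lie in (0, 1)")
        if self.hotspot_mode not in ("uniform", "focal_at_docks"):
            raise PresetError(f"unknown hotspot_mode {self.hotspot_mode!r}")

    @property
    def plateau_amplitude(self) -> float:
        """Plateau ``A = fraction / (1 - exp(-t_anchor / tau))``."""
        t, frac = self.recovery_at_t
        return frac / (1.0 - math.exp(-t / self.tau_s))


#: Library of reporter presets. venus_bactin reaches 18.6% recovery at 5 min
#: (1 Hz acquisition, 300 s); venus_control reaches 4.8% at 10 min (30 s
#: interval, 600 s, the spinning-disk protocol); venus_bactin_chx represents
#: translation-inhibited recovery with a chosen 3% plateau.
FRAP_PRESETS = {
    "venus_bactin": FrapPreset(
        name="venus_bactin",
        tau_s=100.0,
        recovery_at_t=(300.0, 0.186),
        total_s=300.0,
        frame_interval_s=1.0,
    ),
    "venus_control": FrapPreset(
        name="venus_control",
        tau_s=200.0,
        recovery_at_t=(600.0, 0.048),
        total_s=600.0,
        frame_interval_s=30.0,
    ),
    "venus_bactin_chx": FrapPreset(
        name="venus_bactin_chx",
        tau_s=100.0,
        recovery_at_t=(300.0, 0.03 * (1.0 - math.exp(-3.0))),
        total_s=300.0,
        frame_interval_s=1.0,
    ),
}


def frap_preset(name: str, **overrides) -> FrapPreset:
    """Look up a named FRAP preset, optionally overriding fields."""
    try:
        base = FRAP_PRESETS[name]
    except KeyError:
        raise PresetError(
            f"unknown FRAP preset {name!r}; available: {sorted(FRAP_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
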