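"""Dock detection and the three dock/protrusion association statistics.

Simulates branching axons (protrusion births coupled to granule docking),
detects docks from the raw tracks with the 10 s / one-diameter criterion,
and computes: the fraction of protrusions preceded by a dock at their base,
the dock coverage of random control sites, and the random-position
follow control (nearest granule tracked forward to its first dock).
"""

import numpy as np

import axodyn as ax

geometry = ax.AxonGeometry()
branching = ax.BranchEventPreset()
segment = (geometry.terminal_length_um - branching.protrusion_segment_um,
           geometry.terminal_length_um)

assoc_flags, site_flags, follow = [], [], [0, 0]
for seed in range(8):
    ds = ax.simulate_branching_axon(geometry, branching, seed=seed)
    tracks = ax.tracks_from_table(ds.tracks)
    docks = ax.detect_docks_all(tracks, granule_diameter_um=1.0, min_duration_s=10.0)
    _, flags = ax.protrusion_dock_association(docks, ds.protrusions, window_s=10.0)
    assoc_flags.extend(flags)
    _, sflags = ax.random_site_dock_fraction(docks, segment, (0, 600), 200, seed=seed)
    site_flags.extend(sflags)
    frac, n_res, _ = ax.random_follow_control(
        tracks, ds.protrusions, segment, (0, 600), n_sets=20, seed=seed, docks=docks
    )
    follow[0] += round(frac * n_res)
    follow[1] += n_res

print(f"protrusions with a dock in the 10 s before emergence: "
      f"{100 * np.mean(assoc_flags):.1f} % (n={len(assoc_flags)})")
print(f"random sites covered by a dock:                       "
      f"{100 * np.mean(site_flags):.1f} % (n={len(site_flags)})")
print(f"followed docks leading to a protrusion within 10 s:   "
      f"{100 * follow[0] / follow[1]:.1f} % (n={follow[1]})")

# Expected near 84%, 16% and 22%: a strong spatial/temporal association of
# docking with branch emergence against a low random background.
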