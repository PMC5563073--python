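"""RNA dwell map vs cumulative FRAP map with a Costes-style scramble null.

Renders an RNA-granule time-lapse, projects it to a per-pixel temporal
median (dwell map), builds a recovery map correlated with it by
construction (noise variance = 0.731 x dwell variance, expected R = 0.76),
and tests the observed masked Pearson correlation against a null obtained
by permuting PSF-sized blocks within the axon mask.
"""

import numpy as np

import axodyn as ax

geometry = ax.AxonGeometry(terminal_length_um=30.0, pixel_size_um=0.25,
                           origin_um=(25.0, 7.0))
shape = (56, 340)
mask = np.zeros(shape, bool)
mask[16:40, 100:220] = True

table, _ = ax.simulate_tracks(geometry, seed=5, s_range=(0.0, 30.0))
stack = ax.render_stack(table, geometry, shape=shape, noise_sd=0.05, seed=6)
dwell = ax.dwell_map(stack, mask, background=0.0)

rng = np.random.default_rng(7)
recovery_map = dwell.copy()
recovery_map[mask] += rng.normal(0, np.sqrt(0.731 * dwell[mask].var()), mask.sum())

r_obs = ax.masked_pearson(dwell, recovery_map, mask)
null = ax.costes_scramble_null(dwell, recovery_map, mask, n=500,
                               block_size_px=4, seed=8)
print(f"R(observed) = {r_obs:.3f}")
print(f"R(random):    mean {null.mean:.3f}, SD {null.sd:.3f} "
      f"({null.n_scrambles} scrambles)")
print(f"observed percentile within null: {null.percentile_of(r_obs):.1f}")

# R(observed) ~ 0.76 sits far above the scramble null: the association
# between where granules dwell and where signal recovers is not explained
# by the images' marginal intensity structure.
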