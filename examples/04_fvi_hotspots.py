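"""Fluorescence variation index: uniform recovery vs focal hotspots.

FVI = SD(branch pixels) / SD(shaft pixels). Spatially uniform recovery
keeps FVI near 1; recovery concentrated in hotspots at dock sites pushes it
above 1 with a rising time course, summarized by a quadratic fit.
"""

import numpy as np

import axodyn as ax

for mode in ("uniform", "focal_at_docks"):
    preset = ax.frap_preset("venus_bactin", frame_interval_s=30.0, hotspot_mode=mode)
    series, _ = ax.generate_frap_series(preset, seed=4)
    fvi = ax.fvi_series(series.post_bleach, series.branch_mask,
                        series.shaft_mask, t_s=series.t_s)
    fit = ax.fit_quadratic(fvi)
    print(f"{mode:>15}: FVI(start) = {fvi.fvi[1]:.2f}  "
          f"FVI(300 s) = {fvi.fvi[-1]:.2f}  "
          f"quadratic c2 = {fit.params['c2']:.2e}")

# Uniform recovery stays at FVI ~ 1 throughout; hotspot recovery climbs
# well above 1 as the focal signal accumulates (positive curvature).
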