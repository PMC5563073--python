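# axodyn

Quantitative image-analysis pipeline for studying how RNA-granule dynamics
and local protein synthesis relate to axon branch remodeling in live-imaged
axon terminals (developing retinal ganglion cell arbors are the motivating
system). The package is aimed at researchers who track fluorescent RNA
granules, score filopodial/branch dynamics, run in vivo FRAP on translation
reporters, and need the associated statistics to be testable: every
estimator ships with a synthetic time-lapse generator whose ground truth is
the published population statistics, so parameter recovery can be verified
end to end.

## What it computes

**Granule dynamics** — motility classification over a 60 s window
(stationary if the position range stays under 1 μm; bidirectional if there
is a reversal between ≥1 μm runs; otherwise anterograde/retrograde by net
direction), run speeds (run displacement / run duration, averaged per
granule then across granules), density per 10 μm, and docking detection:
a dock is a maximal dwell whose positions stay within one granule diameter
(±d/2 of the running centroid) for ≥10 s (RNA) or ≥1 min (mitochondria).
Three association statistics follow: the fraction of protrusions with a
dock at their base in the 10 s before emergence, dock coverage of random
(position, time) control sites, and a random-position follow control
(nearest granule tracked forward to its first dock, scored for protrusion
emergence within 10 s of dock onset).

**Branch dynamics** — filopodium (< 5 μm) vs branch (≥ 5 μm)
classification, addition/removal counts on the terminal 50 μm per 10 min,
lifetime (short-lived ≤ 30 min vs persistent) and length (≤ 15 μm vs
longer) classes, RNA presence time at branch base/mid/tip, Pearson
correlations of presence with lifetime and length, and axon navigation
metrics (velocity, stalling below 5 μm/hr).

**Arbor complexity** — branch orders from SWC-like traces (primary off the
shaft, order + 1 below), per-order counts and lengths, and the axon
complexity index

    ACI = (Σ branch orders) / (number of branches),

with arbors classed simple (ACI < 1.4) or complex (ACI ≥ 1.4).

**FRAP analysis** — drift correction (phase correlation), photobleaching
correction (histogram matching), recovery normalization

    R(t) = (F(t) − F₀) / F_p,

single-exponential fits R(t) = A(1 − e^(−t/τ)), quadratic fits for the
fluorescence variation index FVI = SD(F_branch)/SD(F_shaft) (≈1 for uniform
recovery, >1 for focal hotspots), and the extra sum-of-squares F test for
nested curve comparisons.

**Colocalization** — RNA dwell maps (per-pixel temporal median), cumulative
FRAP maps (per-pixel temporal maximum), masked Pearson correlation in 2-D
and 3-D, and Costes-style scramble nulls (mask-interior blocks permuted,
1000 scrambles by default) with paired observed-vs-null summaries.

**Synthetic data** — `simulate_tracks`, `simulate_branching_axon`,
`generate_dataset`, `generate_frap_series` and `render_stack` produce track
tables, protrusion tables, FRAP series and TIFF stacks with full ground
truth, parameterized by presets that default to the published statistics
(2.6 granules/10 μm; 10.0/11.4 μm/min; 25.6/27.7/5.9/40.8 % motility split;
84 %/22 %/16 % docking association; 50 filopodia + 8 branches per 10 min;
18.6 % recovery at 5 min for the β-actin reporter vs 4.8 % at 10 min for
the control).

## Worked example

```bash
python examples/02_docking_association.py
```

```
protrusions with a dock in the 10 s before emergence: 83.4 % (n=475)
random sites covered by a dock:                       17.1 % (n=1600)
followed docks leading to a protrusion within 10 s:   25.6 % (n=78)
```

Eight synthetic axons are simulated at the default coupling preset, docks
are detected from the raw tracks, and the three association statistics are
recovered: ~84 % of protrusions are preceded by a dock at their base while
random sites show only ~16 % coverage — the spatial/temporal association of
docking with branch emergence far exceeds its random background — and
roughly a fifth of followed docking events are followed by a protrusion.
The other examples (`examples/01`–`06`) cover motility statistics, FRAP
fitting, FVI hotspot scoring, dwell-map colocalization with scramble nulls,
and arbor complexity.

A thin CLI mirrors the library for shell use:
`axodyn simulate|granules|branches|arbor|frap|coloc --help`.

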