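# Methods

This note documents the models behind `axodyn`: what the synthetic
generator simulates and why, the exact reading of each scoring rule, the
numerical choices, and what passing tests do and do not establish about
real imaging data.

## Coordinate and time conventions

Analyses run in the arc-length coordinate `s` along the terminal axon
shaft: `s = 0` at the proximal end of the analyzed segment, increasing
distally, so anterograde motion is increasing `s`. Time origin is the first
post-bleach frame for FRAP series and the first acquisition frame
otherwise. Default imaging metadata: 0.118 μm pixels; 3 s frame interval
for trafficking movies; 10/3 s (18 frames/min) for the branching/docking
movies — within the 3–6 s/frame acquisition range and the largest interval
at which a 10.0 s dock still spans enough frames on the grid (the dock
criterion requires sampling at ≤ min_duration/3, i.e. at least 3 frames per
minimal dock).

## Granule kinetics generator

Mobile granules follow run-and-pause kinetics: constant-velocity runs
(anterograde 10.0 μm/min, retrograde 11.4 μm/min) alternating with pauses,
with exponential waiting times (run mean 15 s; pause mean 6 s, capped at
9 s so a pause can never satisfy the 10 s dock criterion). State durations
are quantized to the frame grid, which makes run-speed recovery exact up to
tracking jitter (0.02 μm SD on mobile positions, 0.08 μm on stationary
ones). Bidirectional granules alternate direction with run lengths of
1.2–3 μm so each run clears the 1 μm reversal criterion. These kinetic
nuisance parameters are not published quantities; they are chosen so that
the 60 s window classifier reproduces the preset class fractions
essentially without misclassification, because the window statistics —
not the microscopic kinetics — are what the estimators must recover.

Granule counts are Poisson with mean `density × length/10`. The
initialization region is padded by one window's maximum excursion
(~12 μm) on both sides and granules move freely (no reflection), so the
per-frame count inside the analyzed segment is stationary in expectation;
reflecting boundaries were rejected because a reflection mid-window would
masquerade as a direction reversal and contaminate the bidirectional
fraction.

## Docking generator and the three association probabilities

The generator is designed so that the three association probabilities are
independently tunable. Protrusions are scheduled first: Poisson in number
(50 filopodia + 8 branches per 10 min), births uniform in time, origins
uniform on the terminal 50 μm. With probability 0.84 a coupled dock is
inserted at the origin with onset 4–8 s before birth (snapped up to the
frame grid, so onset-to-birth stays within the 10 s scoring window after
detection). Uncoupled docks are added so that coupled docks are 22 % of all
docks. All dock durations come from one shared distribution — grid-aligned,
10 s minimum, plus a Poisson number of extra frames tuned per dataset so
that the overlap-corrected space-time coverage `1 − exp(−Σ 2r·dur / (L·T))`
matches the 16 % random-site target. Sharing the distribution between
coupled and uncoupled docks keeps the nearest-granule follow control
unbiased at the group level: the probability that a resolved query lands on
a coupled dock is exactly the coupled count share.

Each dock is realized as a granule track: dwell frames with 0.08 μm jitter
followed by a two-frame departure at 0.9 μm/frame. The departure step is
deliberately larger than half a granule diameter so the first post-dwell
frame falls outside the detection window even after the running centroid is
pulled toward it — otherwise the detected dock would systematically
overrun its true end by a frame or two and inflate the random-site
coverage (observed and fixed during development). Uncoupled docks are
rejection-sampled away from every protrusion's scoring windows (with one
frame/0.5 μm margins) so they cannot create accidental positives.

Two intrinsic, unfixed artifacts of the published procedures are worth
knowing. First, the follow control converges to ~23 % rather than 22 %:
queries landing near a birth event preferentially resolve the coupled dock
there, because no uncoupled dock can occupy that window (and the
alternative — unconstrained placement — produces the same shift through
accidental positives instead). Second, the protrusion association runs
1–2 % below its preset near the end of the observation, where a coupled
dock truncated by the recording falls under the 10 s criterion and goes
undetected. Both effects are small against the reported uncertainties of
the corresponding in vivo quantities and both would occur with real data.

### Combined datasets

A single homogeneous granule population cannot satisfy the trafficking and
docking statistics simultaneously: 40.8 % stationary granules at
2.6/10 μm density are themselves permanent docks and alone would push
random-site dock coverage far above 16 %. `generate_dataset` therefore
partitions the shaft: the trafficking cohort (motility/speed/density)
occupies the proximal segment and the docking cohort the terminal 50 μm
where protrusions are scheduled, with a `cohort` column identifying each
track. Each statistic is measured on the cohort that defines it; random
control sites are drawn over the protrusion-bearing segment.

## Dock detection

The dwell criterion is read as: all positions within half a granule
diameter of the interval's running centroid, i.e. a total excursion window
of one diameter. The wider reading (±one full diameter) was rejected
because at the measured speeds and frame rates a steady 10 μm/min run
spans exactly two diameters in the minimal dock time and would sit on the
inclusive boundary, turning every run into a chain of spurious docks.
Intervals are selected greedily left-to-right, each extended to the
farthest end for which the window is valid (the position range is monotone
in the window, which bounds the search); duration uses a 1 μs tolerance so
grid-aligned 10.0 s docks are not lost to floating-point rounding.
Mitochondria reuse the same operations with `min_duration_s = 60`.

## Boundary conventions

Printed definitions leave several boundaries open; the package fixes them
as: exactly 5 μm → branch; lifetime exactly 30 min → short-lived; length
exactly 15 μm → short; exactly 5 μm/hr → not stalled ("less than" read
strictly); ACI exactly 1.4 → complex. All are single-point conventions
with measure zero under the generator and are exposed as constants.

## FRAP model

Recovery follows `R(t) = A(1 − e^(−t/τ))` with the plateau derived from a
(time, fraction) anchor: `A = fraction / (1 − e^(−t/τ))`, so the noiseless
normalized recovery at the anchor equals the anchor exactly by
construction (β-actin reporter: 18.6 % at 300 s, τ = 100 s chosen;
control: 4.8 % at 600 s, τ = 200 s chosen; translation-inhibited preset:
3 % plateau, chosen). Image series put the recovery on an axon scene
(shaft band plus two branches) over a flat background, with pre-bleach
plateau frames, a post-bleach floor at 5 % of the pre-bleach signal,
multiplicative Gaussian intensity noise (5 % default), and an optional
per-frame bleach decay (default zero: recovery acquisition uses low
irradiance precisely to avoid acquisition bleaching; the bleach-corrected
path is exercised on the RNA channel, where histogram matching is the
published correction). In focal mode the recovery weight is a Gaussian
mixture at dock sites normalized to unit mask mean, so the mask-averaged
R(t) — and hence the anchor — is identical to uniform mode while the
spatial contrast drives FVI above 1; a `hotspot_amplitude` of zero reduces
focal mode to uniform.

FVI uses population (n-denominator) SDs, branch pixels pooled per axon;
the choice is irrelevant asymptotically and documented for exactness. FVI
is computed on corrected frames by default, with the raw path available.
The single-exponential fit constrains A ∈ (0, 1], τ > 0, tries four
starting points, and flags the degenerate flat-curve case (where A → 0 and
A·t/τ → 0 fit equally well) by the fitted curve's maximum rather than the
raw parameter. The extra sum-of-squares F test is
`F = ((SSE_sh − SSE_sep)/(df_sh − df_sep)) / (SSE_sep/df_sep)` with p from
the F distribution; misuse with non-nested fits raises.

## Colocalization

Dwell maps are per-pixel temporal medians, cumulative FRAP maps per-pixel
temporal maxima, both restricted to the axon mask. The scramble null
permutes origin-aligned blocks lying fully inside the mask (partial blocks
frozen — the simplest rule that preserves mask support); the default block
size of 4 px matches the rendered PSF FWHM (1 μm spots at 0.25 μm test
pixels) and is exposed because the null width depends on it. Only the
second channel is scrambled since Pearson is symmetric. With structured
backgrounds the null mean need not be zero; significance statements use
the observed value's percentile within its own null and the paired
observed-vs-null t test. Correlated map pairs for validation are built by
adding zero-mean Gaussian noise with variance `r` times the within-mask
variance, giving expected correlation `1/√(1+r)` (0.760 at r = 0.731).
Scrambling is implemented for 2-D maps; the 3-D masked correlation is
available for volumes, where a single-plane volume reduces exactly to the
2-D result.

## Arbor traces

A branch's order is 1 if it emanates from the shaft and parent order + 1
otherwise; ACI is the mean branch order, which is 1 for purely primary
arbors, consistent with the 1.4 simple/complex threshold. The alternative
readings of the graphical ACI definition are isolated behind the single
`aci()` function. In SWC-like text, shaft nodes carry structure type 2 and
branch nodes type 3; a branch starts at a node whose parent is a shaft
node, and among non-shaft children the first (in file order) continues its
parent's branch while later children start child branches. The writer
never attaches a child at a parent chain's terminal node, which would merge
the two on re-reading. Branch length covers the branch's own polyline
only.

## Problem sizes and what the tests show

The recovery experiments use 600–2000 tracks for kinetics, ~15 axons
(≥800 protrusions, ~3000 docks) for the association statistics, 50 FRAP
series per anchor, 50 dwell-map replicates, and 100 axons for density and
the follow control; all complete in about a minute on one CPU, and the
test suite asserts recovery within three Monte-Carlo standard errors.
Passing these tests shows that the estimators are unbiased and correctly
scaled for data with the generator's structure: piecewise-constant
kinetics, Gaussian spots, rigid drift, multiplicative noise, and exactly
enforced coupling probabilities. Real axon data add tracking errors and
identity switches, non-rigid deformation, heterogeneous granule brightness
and size, signal-dependent (Poisson) noise, and biological variation
between axons — none of which the generator emulates. Recovery here
validates the analysis code, not the robustness of the experimental
pipeline to those effects.

## Known limitations

- Tracks are inputs; spot detection/linking from raw pixels is out of
  scope (the renderer round-trip uses a plain local-maxima detector).
- The navigation analysis computes velocity and stalling only;
  misprojection/death labels require anatomical context and pass through
  from ground truth.
- The transient-dock subclass (<10 s dwells) is not scored; no detection
  rule is defined for it.
- Costes scrambling operates on 2-D maps; volumes are correlated but not
  scrambled.
- Whether the follow control's "within 10 s of docking" counts from dock
  onset is an interpretive choice (onset is implemented); the alternative
  readings differ only for docks longer than the window.
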