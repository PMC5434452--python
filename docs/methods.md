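# Methods

## The measurement model

The package analyses flow-chamber time-lapse stacks by temporal
projection rather than by tracking.  Its assumptions are those of the
assay itself:

* in-focus cells are bright, approximately circular, and either
  stationary (firmly adherent) or translating along the flow axis at a
  roughly constant speed (rolling);
* free-stream cells are strongly defocused and low-contrast, so a
  global intensity threshold separates substrate-interacting cells from
  passers-by;
* firm adhesion is operationalized as "stationary for the whole
  acquisition window" (4 s at defaults).  A cell that detaches at 3.9 s
  is counted as rolling — the minimum projection is exact about this;
* rolling velocity is an *average* over the window.  Projection-based
  velocimetry cannot resolve instantaneous speed fluctuations,
  stop-and-go behaviour, or two cells sharing a lane.

## Geometry and acquisition defaults

| parameter | default | notes |
|---|---|---|
| frame rate | 30 frames/s | frame count must be integral (120 at defaults) |
| duration | 4 s | also the firm-adhesion window |
| field | 594 × 446 μm | flow axis = the 446 μm axis |
| pixel size | 1.0 μm/px | a free calibration parameter, never hard-coded |
| shear stress | 0.6 dyn/cm² | echoed as 0.06 Pa (divide by 10, exact in floats) |
| fields/chamber | 6 | densities aggregate as the mean over fields |

The flow axis is taken to be the shorter field axis because the
measurable-velocity cap it implies (446 μm / 4 s = 111.5 ≈ 112 μm/s)
matches the assay's stated cap; the acquisition does not otherwise
reveal the orientation.  Both field dimensions, the pixel size and the
bit depth are configurable because real camera calibrations vary.

## The synthetic generator

`flowquant.synth` renders what the detector is designed to see: a
uniform background at gray level 30, in-focus cells as flat-topped
discs (radius 5 μm — a typical monocyte is ~10 μm across) with a 1 μm
Gaussian shoulder and peak +120, free-stream cells as Gaussian blobs
(blur σ 8 μm, peak +15) translating fast, and additive Gaussian camera
noise (default σ 2 on the 8-bit scale, i.e. a generous SNR typical of
phase-contrast imaging of bright cells).  Intensities were chosen so
that a parameter-free Otsu threshold separates the three classes; all
are configurable.

Ground truth is defined at frame 0: cells whose centre is inside the
field at t=0 count, cells that enter later do not — mirroring the
snapshot convention of the assay.  Adherent cells closer than one
diameter set a warning flag rather than failing, because a segmenter
cannot be expected to resolve them.

Cohort presets parameterize donors from group-level summary statistics
(mean ± SEM of adherent density, rolling density and rolling velocity
for young/old × control/LPS, with 16 young and 14 old donors).  The
donor-to-donor SD is reconstructed as SEM × √n_group; per-field counts
are Poisson around donor expectation × field area; rolling velocities
are Normal around the group mean with SD = SEM × √178 (velocity
summaries pool ~150–207 individual cells, not donors), truncated to
(0.5 μm/s, cap).  The uncoated preset uses an adherent mean of
0.5/mm² ("hardly any" adhesion without the collagen substrate); the
anti-CD11c presets assume integrin blocking removes ~60% of adhesion,
and the Mg²⁺ presets equalize adhesion between age groups at 19/mm² —
these three are package design choices for scenario labels whose group
means are not published as numbers.

What the generator does **not** emulate: uneven illumination,
flat-field artefacts, cell deformation and shape variability,
stop-and-go rolling, detachment/attachment during the window, and
donor-level correlation between the control and LPS measurements of
the same donor.  Tests passing on this generator therefore validate
the *algorithmic* chain (projection arithmetic, segmentation gates,
subtraction logic, velocimetry geometry, statistical routing), not
robustness to real-microscopy artefacts.

Randomness is hierarchical: `SeedSequence([seed, donor_index])` per
donor, with each field's render seed derived from that stream and the
field index, so any single field is reproducible in isolation.

## Detection and classification

Segmentation threshold = max(Otsu, background + 3·noise σ); the floor
prevents Otsu from splitting the background of an empty image, the
background defaulting to the image median.  Components are gated by
area (25–400 μm², discs of ~6–22 μm diameter) and circularity
(4πA/P² ≥ 0.6).  Components larger than 2× the maximum single-cell
area get one round of watershed on the distance transform — counts,
not shapes, are the output.  Centroid convention: 0-based pixel
indices, origin top-left, x = column; physical positions in μm from
the same origin.

Rolling = snapshot count − minimum-image count, clamped at zero with a
quality flag (segmentation noise can, rarely, invert the counts).  The
minimum projection is taken over exactly the 4 s firm-adhesion window
even if a longer stack is supplied.

## Streak velocimetry

Blur components must have elongation ≥ 2, where elongation = longest
chord (Feret diameter) / mean width (area ÷ Feret — exact for the
stadium shape an ideal blur makes, and ≈1.27 for a disc, safely below
the gate).  Blurs touching the image border are discarded: their true
length is unknown ("visible start and end points").  Components with a
sustained bulge in their width-along-axis profile (> 1.6× the median
width for ≥ 3 rows) are flagged ambiguous — the signature of two blurs
merging or a blur crossing an adherent cell — and excluded from
summaries, as a human analyst would discard them by eye.  Orientation
is not gated by default (flow alignment is assumed); an optional
±15° gate is available.

Velocity = (blur length − one cell diameter) / painted time span, with
two deliberate numerical choices:

1. **The subtracted diameter is the streak's own measured width** by
   default.  Thresholding inflates the blur's length and width by the
   same margin, so subtracting the measured width cancels that margin
   exactly; subtracting a fixed configured diameter (available via
   `use_measured_width=False`) leaves a threshold-dependent bias of
   ~+0.3 μm/s at defaults.  Raw mode (`corrected_length=False`) divides
   the full blur length by time for strict fidelity to the simplest
   length/time convention.
2. **The divisor is (N−1)/frame rate**, the interval actually spanned
   between the first and last frame, not the nominal N/frame rate
   window — otherwise every velocity is biased low by one part in N
   (−0.8% at 120 frames).  The nominal 4 s window still defines firm
   adhesion and the ≈112 μm/s cap.

With both choices, recovery on noiseless synthetic rollers is within
2 px/duration (0.5 μm/s at defaults) for every streak, with residual
bias below 0.1 μm/s.  Measurements above the geometric cap are flagged
as segmentation artefacts and excluded from summaries.  Summaries are
mean ± SEM (SD/√n); an empty input yields a distinguished empty
summary rather than an exception.

## Statistics

* Normality gate: Shapiro–Wilk at α = 0.05; n < 3 or zero variance
  routes to the rank test with a warning.
* Two-group test: classic equal-variance unpaired two-sided t-test
  when both groups pass the gate (Welch via config), else Mann–Whitney
  U — exact enumeration when both n ≤ 8 and the data are tie-free, the
  tie-corrected normal approximation otherwise.  Empirical type-I
  error of the routed procedure is calibrated to [0.03, 0.07] at
  nominal 0.05 (checked over 2000 null replicates in the test suite).
* Two-way ANOVA on the age × LPS design uses Type II sums of squares
  (the 16/14 cohorts are unbalanced); an all-equal response returns
  F = 0, p = 1 rather than NaN.  Null-simulation p-values are uniform
  (KS-checked).
* LPS response = stimulated/control density ratio per donor; the
  printed group means give +26.7% (young 15→19) and +36.8% (old
  19→26), averaging ≈31.8%.
* 2^−ΔΔCt: the calibrator is the mean ΔCt of the young group (the
  natural reference when comparing age groups); the fold change is
  strictly decreasing and multiplicative in ΔΔCt.

Power caveat: reconstructing donor spread as SEM × √n_group makes the
old-vs-young control adhesion contrast (19±2 vs 15±2) a modest effect
(t ≈ 1.4 on the printed summaries, replication power ≈ 25%) and gives
the ANOVA main effects ~70–80% power each.  The test suite asserts
these attainable detection rates, not certainty.

## Problem sizes used in the test suite

Pixel-level oracle checks run on 5-frame 20×24 px stacks (100 random
stacks); count-exactness on 50 full-size noiseless scenes; velocity
recovery on 100 full-size rollers; type-I calibration on 2000 null
replicates of n = 15 per group; ANOVA null uniformity on 1000
replicates of a 2×2×8 design; preset convergence on 200 donors per
group (scene statistics only — convergence of drawn counts needs no
rendering).  End-to-end rendering runs use small cohorts (1–3 donors,
1–2 fields); the full 16 + 14 × 2 × 6 experiment is available through
`flowquant run-all` or `RunConfig` defaults.

## Known limitations

* No tracking: cells that pause part-way, reverse, or change speed are
  mis-measured by design; the projection method reports averages.
* Two cells rolling in the same lane merge into one blur; the
  ambiguity flag removes most such cases but cannot recover either
  velocity.
* The subtraction rule inherits snapshot segmentation errors into the
  rolling count; the clamp flag marks the visible failure mode.
* Preset cohorts draw control and LPS donors independently, so
  per-donor response ratios from rendered preset runs carry more
  variance than truly paired measurements would.
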