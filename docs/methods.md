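# Methods

## The measurement problem

A mother machine traps one bacterium per dead-end side channel; imaging
the channel once per minute yields a kymograph-like stack in which the
mother cell sits at the closed end and her descendants queue toward the
open end. The quantities of interest per mother are the per-minute cell
length and fluorescence, the division times, and the per-cycle pairs
(L_b, L_d) of birth and division length that characterise cell-size
homeostasis. This note records the models, conventions and numerical
choices the toolkit uses, and what the simulator does and does not
emulate.

## Growth and division model (simulator)

Each cell elongates exponentially, L(t) = L_b·e^{λt}. Division follows
the noisy linear map: at birth a target division length

  L_d = a·L_b + b + η,  η ~ N(0, σ_η²)

is drawn, and the cell divides at the first frame at which its length
has reached the target (measurements are per-minute snapshots, so
division is resolved on the frame grid; the achieved division length
therefore overshoots the target by up to one frame of growth, about
2.8% at the default rate). The mother keeps a fraction
r ~ N(ratio_mean, ratio_sd) of the divided length. The map has a stable
fixed point for |a·r| < 1 (enforced); the mean birth length is
r·b/(1 − a·r).

Defaults (the reference condition for all tests): λ = ln2/25 min⁻¹
(25 min doubling, fast-growth-like), a = 0.5, b = 37.5 px and
r = 0.5 ± 0.02, putting the fixed-point birth length at 25 px and the
mean division length at 50 px on a ~0.1 µm/px scale; σ_η = 2.5 px (5% of
the mean division length). No published parameter values exist for the
deposited datasets this pipeline is designed around, so these are
plausibility choices, stated once and used consistently.

**Filamentation.** With per-cycle probability `filament_prob`
(default 0.6%) a cell fails to divide at its target and elongates to
`filament_factor` (default 2.5) times the target before recovering. A
factor of 2 would correspond to exactly one skipped division, but the
resulting division length then sits on top of the 2(L̄+2σ_L) exclusion
bound rather than beyond it; real filaments exceed two cell-equivalents,
and the default 2.5 makes the filamentous population unambiguous. On
recovery the filament divides at two septa (the mother keeps r/2), so
the next birth length is ordinary — one filamentation event produces one
aberrant cycle.

**Fluorescence.** Constitutive expression is modelled as a
concentration following a discrete Ornstein–Uhlenbeck process with mean
100, s.d. 10 and correlation time 100 min — deliberately slower than
the ~25 min cell cycle, matching the observation that mean fluorescence
fluctuates over several cycles. The slow innovation is drawn once per
frame and shared by all cells in the channel: neighbours are recent kin
in a common microenvironment, so their expression states rise and fall
together, while each daughter additionally inherits a partition offset
(s.d. fluor_sd/3) at birth. Fully independent per-cell fluctuation
would let the brightest cell in the channel drift far from the mother,
which distorts any threshold taken relative to the frame maximum far
more than real sibling variability does.

## Rendering model

Cells are drawn as filled rods: an axial top-hat (sub-pixel edges are
area-weighted) times a transverse top-hat of width `cell_width_px`
centred in the channel — mother-machine cells are slightly compressed
by the channel walls, so their projection is near-uniform across the
width. Each cell-cell interface is dimmed over a 2 px band by
`septum_dip` (default 0.4). The frame is blurred with a Gaussian PSF
(default σ = 1 px), background (200 counts) is added, optional Poisson
shot noise and Gaussian read noise (s.d. 50) are applied, and the image
is quantised to 8 or 16 bits (gain: 30 counts per concentration unit,
so a typical interior is ~3000 counts above background).

Two geometric defaults matter more than they look:

- `channel_width_px = 15` with `cell_width_px = 7.5` leaves permanent
  background columns, so the 2nd-percentile anchor of the intensity
  rescale always samples true background even when the channel is full
  of cells;
- the half-integer cell width places the blurred transverse edge
  mid-pixel, so the column-value plateaus land near 0.12 and 0.40 of the
  interior — safely away from the 0.2/0.3 mask thresholds. An aligned
  edge produces a column plateau sitting exactly at a threshold, and
  whole columns then flicker in and out of the mask with pixel noise.
  This is a real property of threshold segmentation at few-pixel cell
  widths, not an artefact of the simulator.

## Segmentation conventions

Processing order per frame: 3×3 median filter (reflect padding) →
percentile rescale (linear-interpolation percentiles; values at or
below p2 → 0, at or above p98 → 1) → transverse-mean axial profile →
boundary minima → threshold masks → measurements.

- **Degenerate frames.** A frame whose p98−p2 contrast does not exceed
  8× the robust pixel-noise scale (1.4826·median |image − median-filtered
  image|) is treated as blank: rescaled to all zeros with a warning.
  Without this guard an empty-channel frame would have its noise
  stretched to full range and segmented into phantom cells.
- **Boundaries.** Minima of the axial profile with prominence ≥ 10% of
  the profile maximum and spacing ≥ 5 px; minima below the mask
  threshold (relative to the profile maximum) are background, not
  septa. Prominence is anchored to the profile maximum rather than the
  profile range because the range collapses when the channel is
  completely full. Each accepted minimum is refined to sub-pixel
  precision with a three-point parabola and reported as a split index —
  the first row of the next cell. Skipping the refinement biases every
  interface by half a pixel.
- **Masks.** Foreground = rescaled intensity ≥ `threshold_rel` (default
  0.30) of the frame maximum; the largest connected foreground component
  within each inter-boundary axial interval is one cell; cells are
  indexed from the closed end, index 0 the mother.
- **Length.** Two moment-based conventions are available.
  `length_method="rod"` (default) returns √12 × the axial s.d. of the
  mask pixels (each pixel contributing 1/12 unit variance) — exact for
  a filled rod, hence unbiased against the simulator's ground truth.
  `"ellipse"` returns the classical major-axis length of the
  equal-second-moments ellipse (4√λ_max), the convention of standard
  region-properties implementations; on a rod-shaped mask it reads
  ≈ 15% (√(4/3)) high by construction. Analyses that compare lengths
  within one convention are unaffected by the choice.
- **Fluorescence.** Total and mean fluorescence are measured on the raw
  (pre-rescale) intensities; the rescaled image is used only for
  geometry. Per-frame rescaling would otherwise erase the slow temporal
  fluorescence dynamics.
- **Gaps.** Frames without a measurable mother are flagged, never
  interpolated; a stack with > 50% gap frames is rejected. Converting a
  gapped series to a trace carries the last valid measurement forward
  (the original workflow corrected such frames by hand; this toolkit
  only reports them).

## Division detection and cycles

A division is flagged at frame t when length(t)/length(t−1) ≤ 0.75
(a symmetric division halves the length; 25% tolerates noise and
asymmetric division while rejecting jitter) and no flag occurred within
the preceding 10 min. Cycles run flag-to-flag: L_b is the length at the
flagged (post-drop) frame, L_d the length at the frame immediately
before the next flag; the partial stretches before the first and after
the last division are discarded, and cycles containing a run of more
than 2 gap frames are dropped. Note L_d is a last-snapshot value: it
sits up to one frame of growth (≈ 2.8%) below the instantaneous
pre-division length, a feature of per-minute sampling shared by the
real data.

## Quality filters

A cycle is filamentous when L_b > L̄ + 2σ_L or L_d > 2(L̄ + 2σ_L), and
undersized when L_b < L̄ − 2σ_L (all strict). L̄ and σ_L are computed
once, over the unfiltered cycle set, and frozen — filtering is a single
pass and re-filtering the kept set with the same statistics removes
nothing.

The basis of the "cell size distribution" is selectable and defaults to
**all instantaneous (per-frame) sizes**, reconstructed within each cycle
by geometric interpolation from L_b to L_d (exact under exponential
growth). This choice is load-bearing: the per-frame size distribution
spans the full birth-to-division range, so its ±2σ_L band lies far
outside the birth- and division-length distributions and only genuine
filaments trip the rules (~0.6% of cycles at the default filamentation
rate). Had the basis been birth lengths alone, the L̄ + 2σ_L rule would
cut ~2.3% of perfectly normal cycles on purely statistical grounds —
the tail mass of a near-normal distribution beyond two of its own
standard deviations — regardless of how tight the distribution is.
Birth-length and cycle-endpoint bases remain available for sensitivity
checks.

## Homeostasis and robustness analyses

The noisy linear map is fitted by ordinary least squares of L_d on L_b
(scipy's linear regression); the residual s.d. (n−2 denominator)
estimates σ_η, and R² is the squared Pearson correlation. Fits require
variation in L_b; a two-point fit is reported as saturated with
undefined residual s.d. On the default conditions, OLS on 500 filtered
cycles recovers a and b within ~2 standard errors, with ±2 SE coverage
at its nominal level across replicate lineages.

The two-threshold robustness check segments one stack at two mask
thresholds (default 0.2 vs 0.3), pairs the frames, and regresses the
low-threshold series on the high-threshold series for mother length and
mean fluorescence. Lowering the threshold admits dimmer edge pixels, so
lengths grow and mean fluorescence falls; both series remain linear
images of the same underlying signal, with R² ≥ 0.99 on default
simulations. The R² is computed pooled across frames (a per-lineage
mode is a one-line loop over stacks).

## Problem sizes and runtime

The test suite and the acceptance script use: 10-generation stacks
(~280 frames of 150×15 px) for imaging-level checks; 20 lineages × 20
generations for division metrics; 10 × 1000 cycles for the filtered
fraction; 20 × 500 cycles for map-parameter coverage. The whole suite
runs in well under a minute on one CPU; the acceptance script in a few
seconds. All randomness flows through seeded NumPy generators;
simulations are bit-reproducible per seed.

## What the simulator does not emulate

Real mother-machine data differ in ways the generator deliberately
ignores: phase-contrast or out-of-focus halos, photobleaching, stage
drift and channel-to-channel variation, cell-width changes with growth
rate, partial divisions and paused growth, and segmentation errors that
required manual correction in the original workflow. Passing tests
therefore demonstrate that the algorithms are correct and calibrated on
an idealised rod-in-channel imaging model — not that the pipeline's
accuracy numbers transfer unchanged to any particular microscope. The
deposited per-mother analysis files use an unspecified whitespace
dialect; the writer here emits a documented tab-separated format and
the reader tolerates any whitespace.
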