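# Methods

This note documents the models and numerical choices behind pulsekit: what
the simulator generates, how the analysis reconstructs expression pulses,
where the open design decisions were, and what the recovery benchmarks do
and do not demonstrate.

## The generative microcolony model

`synthetic.simulate_colony` grows a single microcolony in continuous time
from one founder cell.

* **Growth and division.** Each cell draws an elongation rate once at
  birth from a lognormal with mean `elong_rate_mean` (default ln2/180
  min⁻¹, a 3 h doubling time typical for slow-growing rhizobia in minimal
  medium) and CV `elong_rate_cv` (0.15). It elongates exponentially and
  divides on reaching a trigger length (`division_length`, default 40 px,
  with 7% relative trigger noise), splitting its length between two
  daughters as a fraction ~ Normal(0.5, `division_fraction_sd`=0.03).
  The founder starts mid-cycle (length uniform in 0.55–0.95 of the
  trigger) so colonies are desynchronized. The movie is `n_frames` = 46
  frames at `dt` = 20 min (~15 h); if the single-layer cap `max_cells`
  (256) would be exceeded the movie is cropped in time at the last
  compliant frame, keeping every retained frame a complete snapshot.

* **Pulses.** Pulse initiations are a per-cell Poisson process with rate
  `pulse_rate` (per hour; the preset values are the field-measured
  frequencies). A pulse sets the production rate P̃ to `pulse_activity`
  (default 50 intensity/min) for `pulse_duration` (default 40 min, two
  frames); because observed pulses can span divisions, a pulse in progress
  at division continues in *both* daughters, counted once in the ground
  truth. Initiations that overlap an
  ongoing pulse in the same cell extend it and are *not* recorded as
  separate ground-truth events — the merged event is what any
  rate-reconstruction method can possibly see. Consequence: at high rates
  the ground-truth *event* rate is below the initiation rate (~25% below
  at 0.28/h with 40-min pulses; negligible at 0.028/h). Recovery claims
  are therefore exact statements about observable events, not initiations.

* **Fluorescence.** Mean intensity M (per unit length) obeys
  dM/dt = P̃ − (r+γ)M — production minus dilution by growth and
  degradation/bleaching (γ default 0.0015 min⁻¹). Being linear with
  piecewise-constant coefficients, it is solved exactly between events (no
  stepper error); M is continuous across division (a concentration).
  Observed M = true M × lognormal(CV 5%) + Normal(0, 0.5). Lengths are
  reported noise-free; the division and trigger noise already dominate
  their variability, and the analysis tolerances do not hinge on length
  noise.

* **What the generator does not emulate:** fluorophore maturation,
  phototoxicity, cell motion/mechanics (rendered layouts are static
  non-overlapping placements), segmentation/tracking errors, and 3D
  colony growth. Passing recovery tests therefore demonstrates
  correctness of the analysis chain under its stated model, not robustness
  to tracking mistakes or maturation delays.

Auxiliary generators produce non-dividing "dark" cells for γ calibration
(division suppressed deliberately — the estimator γ = −r − d[log M]/dt is
insensitive to it, and uninterrupted series keep the fixture transparent),
replicate protein-decay curves, per-cell photon-count fields for
single-molecule spot statistics, and rendered image stacks (square-ended
rods filled with the cell's M, convolved with a PSF, multiplied by a
shading field, offset by background; masks and blurred probability maps
alongside).

## Rate reconstruction

All slopes (r from log length, dM/dt, d[log M]/dt) share one windowed
least-squares routine with an 11-point window (200 min at 20-min frames).
Series are first extended across divisions: lengths after division as the
daughter sum, before birth as the mother's length times L₀/(L₀+L₀,sister);
intensities after division as the daughter mean, before birth as the
mother's value. With noiseless exponential growth the extended log-length
is globally linear through divisions, which the tests assert exactly.

**End-of-series handling.** At series ends the full 11-point window is
*shifted* to stay inside the series (the standard Savitzky–Golay edge
treatment) rather than truncated. A truncated window weights its trailing
points ever more strongly, so whenever M is still rising at the movie's
end the reconstructed P̃ increases monotonically into the final frame and
every late pulse is pushed onto the series endpoint, where a peak finder
cannot call it; with shifted windows the last frames share one slope and
the apex is decided by M itself, which does turn over. Positions with
fewer than 6 finite points (only very short series) are undefined (NaN)
and skipped downstream.

## Pulse detection

Per backward lineage, candidates are all strict local maxima of P̃
(plateaus count once at their first frame; endpoints are never peaks; NaN
frames cannot host a peak and comparisons use nearest defined
neighbours). Candidates are accepted left to right when their backward
prominence — apex minus the minimum since the last *accepted* pulse, or
since the movie start — exceeds the threshold (default 6 intensity/min, a
single value used across all strains; the simulator's default pulse
amplitude puts real pulses far above it). Sub-threshold wiggles do not
reset the baseline. Detections are deduplicated on the (cell, frame)
apex; an optional conservative rule (`merge_sibling_apexes`, off by
default) additionally collapses the two sister-cell apexes a
division-spanning pulse can produce.

**Known detection biases, quantified on ground truth.** Interior,
well-separated pulses are recovered essentially completely (≥90% matched
within ±1–2 frames in the 9-colony benchmark, with <15% surplus). Two
structural losses remain: (i) pulses not completed roughly one frame
before the movie end cannot form an interior maximum — with exponential
colony growth a sizeable share of all cell-hours lies in that terminal
window; (ii) at high rates the generative merging described above removes
events before detection even starts. At 0.028 pulses/h/cell the pipeline
recovers the generative rate within its 95% Poisson interval; at 0.28 the
recovered frequency is ~0.17–0.19, i.e. biased low by the product of both
effects. Between-strain frequency *ratios* cancel the edge loss but not
the merge loss, so the wild-type/expr-minus fold reads ~6.5–8 rather than
10 while expr-minus/psinr-star (both low-rate) reads ~7 correctly. These
biases are properties of sliding-window reconstruction plus
endpoint-excluding peak detection at a fixed movie length, not
implementation defects.

`pulse_frequency` divides the deduplicated pulse count by the total
observation time dt·Σnᵢ (converted to cell-hours). For rare-event presets
the benchmark fold ratios use exposure-pooled frequencies (total events /
total cell-hours) because per-colony frequencies with ~3 events each are
highly skewed; longer (70-frame) movies and more colonies keep the event
counts usable.

## Imaging measurements

* **Probability-map post-processing:** Gaussian smoothing (σ = 1 px),
  fixed 0.6 threshold, closing + hole filling, opening by 1 px; objects
  whose moment-based across-axis width exceeds the expected cell width get
  a second 2-px opening to split cell clusters. Re-running on its own
  binarized output only nibbles convex corner pixels (the smoothing +
  threshold are not exactly idempotent on corners); object count and
  interiors are stable.
* **Cell length:** a cubic centerline polynomial fitted in the region's
  principal-axis frame (pose-invariant; reduces to an image-x fit for
  horizontal cells), extrapolated 10 px past the mask; poles where the
  silhouette proximity (sum of squared distances to the 25 nearest mask
  pixels, sampled at 1-px steps along the centerline) reaches 110% of its
  average over the central half of the cell; length is the arc-length
  integral of √(1+f′²) between the poles (adaptive quadrature — the
  integrand is analytic). The raw 110% crossing sits about one kernel
  radius (√(25/π) ≈ 2.8 px) inside the physical pole; a per-width offset
  calibrated once on an ideal straight rod corrects this, making the
  estimator exact in the straight-cell limit and ~rotation-invariant to
  1%. Nearly round or tiny regions fall back (flagged) to the
  moment-based estimate. The "ellipse" method reports the rod-equivalent
  length √12·σ_major (exact for rectangles) by default; the classical
  equivalent-ellipse major axis 4σ — which over-reads a rectangle by 15% —
  is available as `ellipse_scale="moment"`.
* **Photometry:** shading division, Lucy–Richardson deconvolution with
  the supplied PSF (25 iterations by default, configurable), median
  background subtraction over non-cell pixels, then the mean intensity
  over the mask eroded by a disk of radius round(5% of the cell width),
  minimum 1 px (falling back, flagged, to the un-eroded mean if erosion
  would empty the mask).

## Population statistics

Positive gating downsamples sample and control without replacement to
15,000 events (seeded) and gates at the 99.9th percentile of the control —
a quantile rather than the maximum for robustness to single outlier
events, exposed as a parameter. Spot fractions count cells with ≥1
detection above a photon threshold (default 20). Correlations report the
least-squares line, Pearson r², and Spearman ρ with two-tailed p values;
fold-change tables report max/min ratios per metric with flagged zero
denominators. Hypothesis tests beyond these (Welch/ANOVA/Kruskal–Wallis)
are deliberately left to general statistics libraries.

## Response-onset model

The link from single-cell pulse frequency to the population-level
quorum-sensing response is made explicit as the minimal pool model
dA/dt = a·f·N(t) − δA with onset at A ≥ A_thr, in a deterministic
(rate-equation; exact closed forms for constant N, including onset =
A_thr/(a f N) at δ = 0) and a stochastic (thinned Poisson events) mode.
Per-pulse yield a and threshold A_thr are not identifiable from data, so
only orderings are meaningful and only orderings are tested: onset is
decreasing in f, increasing in A_thr and δ, and faster-pulsing strains
respond earlier and at smaller colony sizes under a shared growth curve.

## Benchmark problem sizes

The recovery benchmarks use 9 colonies × 46 frames per preset for the
frequency targets (~1,400 cell-hours per preset), 24 + 12 colonies × 70
frames for the rare-preset fold, 51 cells × 30 frames for γ, 3 replicates
× 9 timepoints for the half-life, and 2,000 cells for the spot fraction —
sizes at which the Poisson/binomial sampling error of the target quantity
is comfortably inside the stated tolerance.
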