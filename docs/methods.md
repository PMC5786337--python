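# Methods

## Kinetic model and presets

Furrow depth within one nuclear cycle is modeled as continuous piecewise
linear: Ingression I (duration τ₁, rate r₁), Stabilization (τs, slope 0),
optionally Ingression II (τ₂, rate r₂, present with probability p₂), then
Retraction at rate r_r with depth clamped at 0. When Ingression II is skipped
(e.g. the cycle-12 mixture, or transcription-blocked genotypes), the plateau
extends by τ₂ so retraction still initiates at the same clock time — matching
the observation that blocking the second ingression phase does not move the
onset of retraction. Cycle 14 (cellularization) has no stabilization or
retraction; its slow and fast phases are the same two ingression segments
with a 2.4× maximal-rate ratio.

Preset values are the published per-cycle numbers where printed (Ingression I
2.5 min at cycle 10, 3.6 min at cycle 11; Ingression II 2.0 min at cycle 12
with 58 % penetrance and 6.2 min at cycle 13 contributing 4.3 µm;
stabilization 3.5 → 5.1 min; total cycle-13 times 18.8 / 22.2 / 19.0 min for
WT / α-amanitin / zelda-deficient; defect rates 47.1 / 16.2 / 7.6 / 4.5 % for
α-amanitin / zelda / compound-X / nullo-deficient; interphase nuclear
densities 2.3 → 15.4 → 29.8 per 1000 µm² at cycles 10/13/14). Values the
source does not print (per-cycle interphase/prophase/metaphase splits,
cycle-11/12 densities, checkpoint-mutant kinetics, WT and compound-autosome
defect rates) are filled with documented defaults and flagged in each
config's `inferred` set. One derived choice: the cycle-13 Ingression I
duration is set to 2.4 min because the printed peak time (13.7 min) minus the
printed stabilization (5.1) and Ingression II (6.2) durations leaves exactly
that; no cycle-13 Ingression I duration is printed. Retraction rates are
chosen so retraction completes exactly at cycle end.

## Synthetic data: what it emulates and what it does not

The trace simulator samples the model at the acquisition interval (20 s for
cycles 10–13, 30 s for cycle 14) and adds i.i.d. Gaussian observation noise,
default sd 0.3 µm — the noise level is a free parameter (chosen to resemble
the visible scatter of published traces) since no imaging-noise figure is
reported. Embryo-to-embryo parameter variability is off by default: cohort
scatter comes from observation noise and the Ingression II Bernoulli draw
only. Randomness is split into sub-streams (kinetics, defects, layout,
camera) keyed off one seed, so toggling camera noise never changes the
kinetic realization.

The renderer draws, per nucleus of a jittered hexagonal layout, circular
membrane rings at every z from the apical reference (slice 4 by default,
0.5 µm z-step, ~30 slices) down to the current model depth; below a preset
`fragmentation_depth` only a partial arc (default half the perimeter) is
drawn, reproducing the broken-furrow phenotype. Ring radii are capped by each
nucleus' nearest-neighbor distance so rings in one plane never touch. The
histone channel renders the chromatin cycle per nucleus: diffuse interphase
disc → disc plus bright condensation puncta (prophase) → compact bright
metaphase plate → two separating anaphase masses (starting ~2.8 µm apart so
segregation is resolvable at its scheduled frame; separation scales with the
realized nuclear spacing) → daughter nuclei. Scheduled adjacent fusions move
one daughter from each partner to the pair midpoint; collapses re-merge a
figure's own masses. Camera noise is a Poisson–Gaussian normal approximation
(shot noise on the signal plus read noise, sd 2 counts on a background of
10), applied frame-by-frame from its own stream.

Deliberately not emulated: optics (no PSF convolution; membranes are
sharp-edged rings, not diffraction-limited walls shared between cells),
photobleaching, mitotic waves across the field, nuclear-cycle asynchrony,
z-drift of the apical surface, and inter-embryo kinetic variability.
Passing recovery tests therefore demonstrates correctness of the measurement
logic under realistic geometry, sampling and noise — not robustness to every
artifact of real microscopy.

## Measurement rules and calibrations

**Ring detection.** Membrane planes are Otsu-thresholded, skeletonized, and
connected skeleton components become ring candidates. Each gets an algebraic
(Kåsa) least-squares circle fit; *completeness* is the fraction of angular
bins (bin width ≈1.5 px of arc, 24–90 bins) around the fitted center covered
by skeleton pixels. This returns the rendered arc fraction directly (a half
ring scores 0.5); a perimeter/convex-hull ratio would not, because the hull
closes the chord. All outputs are invariant to uniform intensity rescaling.

**Apical reference.** The shallowest z whose complete-ring coverage (summed
enclosed area over field area) exceeds 0.25 — the plane where apical
membranes meet and tile the field. Re-estimated every frame and logged.

**Intact depth / deepest extent.** A plane counts as intact when a connected
group of ≥ 4 complete rings (completeness ≥ 0.9) exists; adjacency means
contour gaps ≤ 2 µm. The 4-ring *connected group* implements the "4–5 cell
region" rule: a literal 4-clique is geometrically impossible for disjoint
rings on a hexagonal lattice, and the criterion passes if any such group
exists. Deepest extent takes any ring with completeness ≥ 0.2. Both
thresholds are configurable; the source describes these calls qualitatively,
so the numeric values are this package's operationalization. Depth is
(z − apical) × z-step, so measurements floor-quantize to one z-step.

**Phase segmentation.** Free-knot continuous piecewise-linear least squares:
candidate breakpoints on the sampling grid are searched exhaustively (suffix
-sum Gram matrices make each candidate O(k²); a coarse-to-fine pass bounds
the combinatorics above ~80 000 candidate sets), the best grid solution per
breakpoint count is polished by Nelder–Mead over continuous knot positions
(true breakpoints rarely sit on the grid), and the count (1–4) is selected by
BIC with 2k+2 effective parameters. An RSS floor of n·10⁻¹⁶ keeps noiseless
fits from selecting spurious extra knots. Labeling: slopes ≥ 0.3 µm/min are
ingression, |slope| ≤ 0.15 µm/min is plateau, slopes in between count as
plateau (ambiguous band), and falls steeper than the plateau bound are
retraction. Retraction is terminal within a cycle, so a shallow fall fitted
before a substantial later rise is reinterpreted as plateau; a trailing flat
at zero depth (post-retraction clamp) merges into Retraction. A rise
directly after Ingression I splits into Ingression II only when the first
rise is ≥ 3 min long and the second is ≥ 1.8× faster (the cellularization
slow→fast transition); with an intervening plateau no ratio test is needed.
Segment slope is reported as depth-change/duration of the fitted curve, so
`depth_change = slope × duration` holds exactly.

**Rates and peak.** Maximal rates use a 2-min rolling window
(depth(t+w) − depth(t))/w, unrestricted by default; phase-restricted windows
must lie inside the segment. `max_depth_and_time` locates the peak on a 1-min
centered rolling mean but reports the raw maximum within half a window of
that location: smoothing alone would shift and erode an asymmetric
noiseless tent peak (rise 0.69 vs fall 1.57 µm/min displaces a 2-min-window
peak by ~0.4 min), while the locate-then-read-raw rule is exact on noiseless
traces and noise-robust otherwise. Ties break to the earliest time.

**Cell-cycle annotation.** Field-level features per frame from the
max-projected histone channel, thresholded at the first-frame (interphase)
Otsu level so blob footprints stay comparable as figures brighten: blob
count, median blob area, foreground mean intensity, and the 99th-percentile/
median brightness ratio. Boundaries are first crossings against the
interphase baseline: condensation at ratio ≥ 1.25×, nuclear disassembly at
median area ≤ 0.55×, segregation at count ≥ 1.5×, and daughter-nucleus
appearance (cycle end) at mean intensity back within 1.25× of baseline.
These factors are calibrated once against the renderer's contrast settings
(the published calls were made by eye) and recorded in the annotation
metadata. Asynchrony across the field is collapsed by field-median features.
Boundary estimates carry a one-frame ceiling bias (~+0.2 min on total cycle
time at 20 s sampling). Ensemble alignment shifts each trace so anaphase
onsets coincide and interpolates onto the reference grid.

**Defect tracking.** Metaphase figures are segmented just before anaphase
onset; two daughter cursors per figure follow mass centroids with a linking
gate of 3 µm capped at 0.45× the mean figure spacing, assigned jointly so two
resolvable masses are never claimed by one cursor. Outcomes follow terminal
nuclei: shared with another figure → adjacent fusion, own daughters
re-merged → collapse, otherwise normal; unresolvable tracks are
indeterminate and excluded from denominators (never counted defective),
figures within 1 µm of the border are excluded and logged. Fusion events are
scheduled as spatial neighbor pairs — Binomial(⌊N/2⌋, p_fusion) pairs, both
partners defective — so the nucleus-level defective fraction equals
p_fusion + p_collapse; collapse is drawn on the remaining nuclei at
p_collapse/(1−p_fusion).

**Statistics.** Cohort summaries are mean ± SD over embryos with n < 3
flagged; comparisons use the two-sample equal-variance t-test (Welch behind a
flag) with star codes ns/*/**/*** at p thresholds 0.05/0.005/0.0005; no
multiple-testing correction is applied. The furrow-length–versus-defect
relation is summarized by Spearman rank correlation (the relation is reported
as an inverse association without a named statistic), omitted for < 3
genotypes or constant columns.

## Problem sizes and determinism

Validation cohorts: 200 simulated traces for the cycle-13 and cycle-11 phase
recoveries, 100 for the cycle-12 mixture penetrance, 20 rendered 60×60 µm
movies for cycle-time annotation, and 10 rendered fields (~560 figures) for
the defect pipeline; unit tests use 30×30 µm fields. With a fixed seed every
stage — trace simulation, rendering, segmentation, tracking — is bit-stable
across runs. Quantities estimated from n = 100 binary draws (the cycle-12
penetrance) carry a binomial sd of ~5 percentage points by design.

## Known limitations

* Depth extraction floor-quantizes to the 0.5 µm z-step; sub-z-step kinetics
  are invisible.
* The cycle-14 slow/fast boundary uses the same slope thresholds as the
  syncytial phases; no separate criterion is defined for cellularization.
* The slow post-peak regression reported for zelda-deficient embryos falls
  within the plateau band (|slope| ≤ 0.15 µm/min) and is labeled
  Stabilization; steeper regressions would be labeled Retraction.
* Annotation is field-level; per-nucleus cell-cycle heterogeneity and
  mitotic-wave geometry are out of scope.
* Carry-over of unretracted furrow depth between consecutive cycles is
  modeled only via the optional `carry_over_depth` parameter (default 0);
  multi-cycle traces are not simulated end-to-end.
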