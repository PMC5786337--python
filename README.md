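# furrowdyn

Quantification of plasma-membrane **furrow ingression dynamics** in the early
*Drosophila* syncytial embryo (nuclear cycles 10–14), paired with a synthetic
4D embryo generator so that every stage of the pipeline can be validated by
parameter recovery — no deposited imaging data required.

## The biology and who this is for

During cycles 10–13 the fly embryo is a syncytium: thousands of cortical
nuclei divide in a shared cytoplasm, transiently separated by plasma-membrane
furrows that ingress basally each cycle and retract at anaphase. Furrow depth
grows ~5-fold across these cycles (≈1.5 µm at cycle 10 to ≈8 µm at cycle 13,
then ≈28 µm at cellularization), driven by a biphasic kinetic program:

* **Ingression I** — an initial, maternally driven deepening phase;
* **Stabilization** — a plateau of constant depth;
* **Ingression II** — a second, zygotic-transcription–dependent deepening
  phase that appears at cycle 12 (in ~58 % of embryos) and is robust by
  cycle 13;
* **Retraction** — withdrawal back to the apical surface at anaphase.

The package is for quantitative cell/developmental biologists who need to
turn two-channel (membrane + histone) time-lapse z-stacks into calibrated
depth-versus-time traces, phase segmentations, ingression rates, cell-cycle
annotations and mitotic-defect scores — and for methodologists who want a
ground-truth generator to benchmark such pipelines.

## The model

Within one cycle, furrow depth follows a continuous piecewise-linear model

```
d(t) =  r₁·t                                    0 ≤ t < τ₁          (Ingression I, rate r₁)
        r₁·τ₁                                   τ₁ ≤ t < τ₁+τs       (Stabilization)
        r₁·τ₁ + r₂·(t−τ₁−τs)                    … for τ₂ min         (Ingression II, rate r₂)
        max(0, d_peak − r_r·(t−t_peak))         afterwards           (Retraction)
```

Analysis fits this model to a measured trace by exhaustive free-knot
least squares (1–4 breakpoints, selected by BIC, knots polished by continuous
optimization) and labels the fitted segments in canonical order. Rates are
also reported as **maximal rates** from a 2-minute rolling window. Depth
itself is measured per time point from the membrane channel as

* **intact depth** — the deepest z-plane (below the apical reference, where
  apical membranes first tile the field into closed rings) still carrying a
  connected patch of ≥ 4 complete furrow rings, and
* **deepest extent** — the deepest plane with any partial furrow signal
  (the "broken furrow" measurement).

The histone channel yields interphase/prophase/metaphase/anaphase–telophase
intervals from chromatin morphology features; traces are aligned across
embryos at **anaphase onset**. Mitotic figures are tracked through division
and classified as `normal`, `adjacent_fusion` (chromatin merged with a
neighboring figure) or `mitotic_collapse` (a figure's own daughters
re-merged), giving per-field defect percentages.

The synthetic generator inverts all of this: genotype presets (`WT`,
`alpha_amanitin`, `zelda`, `mei41`, aneuploid chromosome arms, `nullo_Df`,
`smg`) carry the per-cycle phase durations, rates, cell-cycle splits, nuclear
densities and defect probabilities; from a preset it simulates noisy depth
traces or renders calibrated two-channel OME-TIFF movies with full ground
truth.

## Worked example

Simulate eight wild-type cycle-13 embryos (0.3 µm depth noise), segment their
traces, and aggregate the cohort:

```bash
furrowdyn simulate --genotype WT --cycle 13 --n 8 --seed 1 --out demo
furrowdyn segment  --in demo/traces.csv --out demo/phases.csv
furrowdyn report   --traces demo/traces.csv --out demo/summary.csv --genotype WT
```

The report prints (seed 1):

```
genotype  cycle  n  max_depth_um_mean  IngressionI_duration_min_mean  Stabilization_duration_min_mean  IngressionII_duration_min_mean
      WT     13  8           8.10                           2.38                             5.06                            6.28
```

i.e. from noisy traces alone the pipeline recovers the preset kinetics:
maximum furrow depth ≈ 8 µm reached at ≈ 13.7 min, a ≈ 5.1 min stabilization
plateau, and a ≈ 6.2 min Ingression II contributing ≈ 4.3 µm — the per-phase
breakdown for each embryo is in `demo/phases.csv`, e.g.

```
embryo_00,13,IngressionII,7.78,13.66,0.73,4.30
```

(phase, start min, end min, slope µm/min, depth change µm). `furrowdyn
quantify` runs the ring-detection depth measurement on a rendered (or real)
OME-TIFF movie, and `furrowdyn defects` scores chromosome-segregation defects
from the histone channel.

## Layout

```
src/furrowdyn/
  config.py          genotype/cycle presets (KineticConfig)
  simulate.py        depth-trace simulation, nuclear layouts, mitosis schedules
  render.py          two-channel 4D movie rendering with ground truth
  furrow_depth.py    ring detection, apical reference, intact/deepest depth
  phase_kinetics.py  piecewise-linear phase segmentation, rates, peak depth
  cell_cycle.py      histone-channel annotation, anaphase alignment
  mitotic_defects.py figure tracking, outcome classification, defect rates
  reporting.py       cohort aggregation, t-tests, length–defect relation
  cli.py             simulate / quantify / segment / defects / report
docs/methods.md      model, parameters, calibrations, limitations
```
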