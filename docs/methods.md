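# Methods

`ionopt` reimplements, as a testable library, the design-of-experiments
workflow a lipidomics lab uses to tune the electrospray source and
collision cell of a triple-quadrupole LC-MS/MS method for oxylipin
quantification: screening → response-surface optimization → Monte-Carlo
design space → collision-energy refinement → sensitivity evaluation. All
inputs are produced by a seeded synthetic instrument, so every stage runs
and is validated without hardware.

## Factors and coding

A `Factor` maps natural instrument units onto the coded frame of a design
(−1 at `low`, +1 at `high`). Settable values are quantised to the
instrument's granularity — 5 kPa for the CID gas during design
construction (1 kPa when reporting optima), 1 °C for temperatures, 0.1 kV
for the interface voltage — with round-half-to-even, and clipped to hard
feasibility bounds first. The interface heater cannot exceed 400 °C, so
the +α star point of the central composite design clips to 400 °C; the run
is kept (preserving the 17-run count) and flagged `clipped` rather than
dropped. Two coded frames are used and always stored with their designs:
the wide screening frame (e.g. IntT 200–400 °C) and the narrower
optimization frame (IntT 300–400 °C, CID 140–250 kPa, IntV 2–3 kV);
models are always fitted in the frame of the design that produced the
data.

## Designs

* **Screening**: regular 2^(7−3) fractional factorial over IntV, IntT,
  HG, DG, HB, DL, CID with the standard minimum-aberration generators
  E=ABC, F=BCD, G=ACD, three center points, duplicate runs (19 runs). The
  defining relation (seven words, shortest of length four → resolution
  IV) and the alias map are computed by mod-2 set algebra; main effects
  are clear of two-factor interactions, while two-factor interactions
  confound in triples. Which interactions share a triple depends on the
  generator convention, so alias partners from other software may differ.
* **Optimization**: central composite design in CID/IntT/IntV — 8 cube,
  6 axial at α = 1.35, 3 center points (17 runs, duplicated).
* **CE × CID**: 14-run multilevel D-optimal subset of the CE 12–28 eV
  (step 2) × CID 190–250 kPa (step 10) candidate grid for a full
  quadratic model, selected by greedy Fedorov-style coordinate exchange
  with 20 seeded restarts. The exchange objective det(XᵀX) is
  non-decreasing by construction; on grids small enough to enumerate it
  matches the exhaustive optimum (tested).

## Response-surface models

Per analyte, ordinary least squares on replicate-level data. The default
response transform for synthetic data is the natural log, because the
generator's effects are multiplicative (gains are reported as
percentages); identity is available for raw peak heights. Diagnostics
follow response-surface conventions: corrected R²; Q² from PRESS
(leave-one-out via hat-matrix leverages, equal to explicit refitting —
tested); reproducibility = 1 − MS_pure_error/MS_total (mean-square
convention, formula exposed); and a lack-of-fit F test with pure error
pooled from duplicate injections and repeated settings (center points).
Models are fitted to replicates, not run means — averaging first would
destroy the pure-error estimate the lack-of-fit test needs.

**Refinement** is backward elimination: repeatedly drop the least
significant removable term (confidence interval covering zero), where the
intercept is never removed and a main effect is protected while any
retained quadratic or interaction term contains its factor. Significance
during refinement is tested at a Bonferroni-adjusted level α/m over the m
candidate terms currently in the model. With per-term 5% testing, a
model with ~9 inert candidate terms retains at least one noise term in
roughly a quarter of runs (a selection effect, measured at 44/200 runs on
synthetic data); family-wise control brings exact structure recovery to
187/200 while the strongly expressed true terms (|t| ≳ 15) are untouched.
Reported confidence intervals on the final model are conventional 95%
intervals; per-term testing remains available (`family_adjust=False`).
Refinement is idempotent.

**Screening analysis**: two-level main effects are estimated on the
factorial points only; the center points measure curvature, which on the
wide screening ranges is strong enough to otherwise inflate the residual
of a purely linear model and mask real effects. A factor advances to
optimization when its main effect is significant at the
Bonferroni-adjusted level (family α = 0.05 over the seven factors) for at
least two of the five analytes. The majority rule plus family-wise
control keeps the chance of advancing an inert factor low across the
4-factors × 5-analytes family of tests; with per-analyte, per-factor 5%
tests the probability of at least one false selection would exceed 60%.

## Monte-Carlo design space

Failure at a setpoint is the event that any analyte's simulated response
falls below its acceptance target. Targets default to 70% of that
analyte's own model-predicted maximum over the evaluation grid (the
fraction is configurable). Disturbances: Gaussian setpoint jitter with SD
= 2% of each factor's [low, high] range (clipped at hard bounds), and
model residual noise resampled from each model's residual SD. Draws are
common across grid points (one jitter/residual sample set per map), which
keeps each point's estimate unbiased and the map smooth. The default
grid is CID 120–270 kPa and IntT 282–400 °C at 2 kPa/2 °C steps, with
IntV slices {1.8, 2.0, 2.5, 3.0} kV; default 20 000 samples per point
for final maps and 1000–2000 during search (convergence checked: the
reduced counts move pfail by < 0.02).

The operating point maximizes the weighted log-margin score
Σ_a w_a log(pred_a / target_a) over grid points with pfail ≤ 1%, with
ties broken toward lower IntV then lower IntT (gentler settings), and is
reported at 1 kPa / 1 °C / 0.1 kV resolution. Weights default to
PGE2-d4 = LXA4-d5 = 2.0, LTB4-d4 = 1.5, 9-HODE-d4 = 5-HETE-d8 = 1.0:
prostaglandins and lipoxins are the low-abundance mediators whose
ionization matters most. If no grid point meets the threshold the map is
flagged `no_design_space` and the unconstrained score argmax is reported.

## Collision-energy stage

Quadratic CE × CID models are fitted to the D-optimal responses and
refined as above; whether any CID term survives is the stage's headline
answer. The model-predicted "optimal CE region" is the interval where
predicted response is ≥ 95% of the model maximum (the cutoff is our
convention for reading contour plots). The one-factor scan at fixed
222 kPa averages duplicates per 2 eV step and normalizes to max = 100%;
its argmax (ties → lower CE, flagged) is compared against the region and
the point optimum.

## Calibration and LOQ

Calibration series are ten 2-fold levels from 31.25 pg down to 0.061 pg
on column (a 3.125 ng/mL top standard injected at 10 µL), duplicate
injections, fitted by 1/x-weighted linear least squares via the weighted
normal equations. Back-calculated accuracy per level uses the replicate
mean; S/N divides peak height by the baseline-noise SD (the simple SD
convention; vendor peak-to-peak definitions differ by a constant factor,
configurable upstream of this package's inputs). The LOQ is the lowest
level with S/N ≥ 5 (boundary passing) whose back-calculated accuracy and
that of every level above it is within 80–120% — the contiguity clause
prevents a broken quantifiable range. One global fit is used; levels
below a candidate LOQ are not excluded and refit. The LOQ is monotone in
baseline noise and in the accuracy band width.

## Synthetic instrument

Ground truth per analyte is a log-quadratic surface H(x) = H0·exp(f(x))
over coded CID/IntT/IntV, plus near-zero linear terms for the inert
factors (HG, DG, HB, DL; |coefficient| < half the noise CV). Replicate
noise is multiplicative lognormal with 4% CV — consistent with
"duplicate injections, tight center points" instrument behavior. AUC is
height times a fixed per-analyte peak-width factor (no chromatographic
peak model is simulated).

The committed coefficient table (`src/ionopt/data/ground_truth.csv`) was
solved by bounded least squares (`scripts/calibrate_ground_truth.py`) so
that, simultaneously: the analyte-average gain is 51% for CID
140→250 kPa (at 400 °C, 2.5 kV) and 32% for IntT 300→400 °C (at
250 kPa); the weighted joint optimum sits exactly at 222 kPa / 380 °C
with voltage optimal at its 2 kV lower bound; PGE2-d4's marginal optimum
falls at 210–270 kPa and 360–390 °C while 5-HETE-d8 prefers 180–210 kPa
with a temperature plateau above 390 °C; the CID × IntT interaction is
positive only for LTB4-d4/9-HODE-d4 and IntT × IntV only for LXA4-d5.
Each anchor is re-verified by direct evaluation in the test suite. A
deliberate consequence of the boundary voltage optimum: the response
difference between the 1.8 and 2.0 kV grid slices is under 1%, below
what fitted models resolve at 4% noise, so recovered optima legitimately
land on either low-voltage slice; recovery tests therefore assert "at
the low boundary" for IntV while CID and IntT are recovered within
±10 kPa / ±10 °C.

The calibration generator inverts the shipped 14-analyte reference
comparison table: per analyte and method, the slope/baseline-noise pair
is chosen to reproduce the printed S/N at the pre-optimization LOQ, and
post/pre height gains are spread over 1.70–2.10 (inside the reported
65–117% band, leaving room for triplicate noise). Where the printed LOQ
is not S/N-limited (S/N at the next lower level would still be ≥ 5), a
sharp low-end recovery loss x_eff = x⁵/(x⁴ + ℓ⁴) with ℓ = 1.127 × the
level below the LOQ makes that LOQ accuracy-limited; a merely affine
loss would be absorbed exactly by the calibration intercept and could
not gate accuracy. Baseline noise (the S/N denominator) is held
amount-independent and separate from replicate repeatability — if
replicate scatter equalled baseline noise, accuracy at an S/N≈5 level
would have ~15–30% SD and no stable LOQ pattern could exist.

### What the generator does and does not emulate

It reproduces the effect structure, noise magnitude, replicate layout and
calibration behavior the workflow is designed to detect. It does not
simulate chromatography (retention, peak shape, coelution), in-source
fragmentation kinetics (encoded only as PGE2-d4's strong negative
high-temperature curvature), matrix effects, drift, or vendor S/N
algorithms. Passing tests therefore demonstrate that the statistical
machinery recovers known structure under realistic noise — not that any
particular instrument will show these exact gains.

## Problem sizes and runtime choices

Stochastic validation uses 20-seed campaigns for optimum/effect recovery,
5 seeds for diagnostic summaries, 100–300 seeds for rate checks, and
1000–2000 Monte-Carlo samples per grid point during search (20 000 for
final maps); these sizes give comfortably sub-percent Monte-Carlo error
on the quantities asserted while keeping the whole suite fast on a single
CPU.

## Known limitations

* Regular two-level fractions only, from a small generator table;
  Plackett-Burman and Box-Behnken are out of scope.
* The D-optimal exchange selects distinct candidate points (no repeated
  runs); with n_runs well above the term count this is the practical
  regime here.
* Q²/PRESS treats replicate observations as independent leave-one-out
  units.
* The design-space disturbance model (jitter SD, residual resampling) is
  a package convention; commercial tools do not publish theirs.
* `reproducibility` uses the mean-square convention; software using
  sum-of-squares ratios will differ slightly.
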