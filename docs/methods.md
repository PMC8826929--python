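# Methods

## Model

The package implements a three-state ODE model of glucose–insulin
homeostasis with β-cell mass dynamics (a Topp-type GIβ system) extended
by an autocrine negative feedback of insulin on its own secretion:

    dG/dt = R0 − (EG0 + S_P·I)·G
    dI/dt = β·σ0/(1 + Sβ·I) · G²/(α + G²) − k·I
    dβ/dt = (−d0 + r1·G − r2·G²)·β

G is plasma glucose (mM), I plasma insulin (nM), β β-cell mass
(arbitrary units), and time is in minutes.  The factor 1/(1 + Sβ·I)
models insulin-receptor-mediated inhibition of secretion within the
β-cell; Sβ (nM⁻¹) is the β-cell insulin sensitivity, and Sβ = 0
recovers the classical Topp model exactly (the implementation arranges
the arithmetic so this reduction is bitwise).  S_P (nM⁻¹·min⁻¹) is the
peripheral insulin sensitivity (the classical model's S_I).

Because β-cell mass relaxes over days while G and I relax in minutes,
glucose-tolerance-test (GTT) simulations use the two-equation *fast GI*
reduction with β frozen; over a 30-minute horizon the full and reduced
models differ by < 10⁻³ mM in glucose at the default parameters.

### Units

All quantities use mM (glucose), nM (insulin) and minutes.  The
classical human Topp parametrization (mg/dl, μU/ml, days) is shipped as
`topp_human_params()` via the conversions 18.016 mg/dl per mM,
0.006 nM per μU/ml, and 1440 min per day.  Peripheral sensitivities
quoted as round numbers like "S_P = 70" follow the per-day convention
(the converted human value is 120 nM⁻¹·day⁻¹); internally the package
stores per-minute rates, so the reference value is 70/1440 ≈ 0.0486
nM⁻¹·min⁻¹.

### Default parameters

No measured rodent parameter set is bundled; the defaults
(`data/default_params.json`) are the package's own calibration, obtained
by converting the human Topp values and adjusting them so that

- the full-model steady state sits at a typical 6-h-fasted mouse
  glycemia, G* = 8 mM, with I* ≈ 0.15 nM and reference β mass ≈ 1;
- a +20 mM GTT clears over roughly an hour, as in wildtype female mice
  on a low-fat diet;
- Sβ defaults to 3.4 nM⁻¹ (the wildtype-female clamp estimate) and
  S_P to 70 nM⁻¹·day⁻¹ expressed per minute.

Values: R0 = 0.07 mM·min⁻¹, EG0 = 0.0015 min⁻¹, S_P = 0.04861
nM⁻¹·min⁻¹, σ0 = 0.136 nM·min⁻¹·mass⁻¹, α = 64 mM², k = 0.3 min⁻¹
(insulin half-life ≈ 2.3 min), d0 = 10⁻⁴ min⁻¹, r1 = 1.65×10⁻⁵
mM⁻¹·min⁻¹, r2 = 5×10⁻⁷ mM⁻²·min⁻¹ (β-equation roots at 8 and 25 mM).

## Steady states and the clamp estimator

`steady_state_full` solves the β-equation quadratic
−d0 + r1·G − r2·G² = 0 in closed form (lower root by default — the
stable branch), then I* from the glucose equation and β* from the
insulin equation; G* is therefore independent of S_P and Sβ.
`steady_state_fast` finds the unique root of the glucose equation on
(0, R0/EG0] by bracketed Brent iteration, using the closed-form clamp
insulin I*(G).  `clamp_steady_insulin` solves
k·Sβ·I² + k·I − β·σ0·G²/(α+G²) = 0 exactly (positive root).

During a hyperglycemic clamp (glucose held at ~19 mM), insulin sits at
this secretion–clearance balance.  Writing the balance for a control
group (sensitivity Sβ) and a β-cell insulin-receptor-knockout group
(Sβ = 0) sharing all other parameters and eliminating them yields a
parameter-free estimator from the two steady insulin levels:

- *derivation* variant: Sβ = (I_m − I_wt)/I_wt², the form the paired
  steady-state algebra yields (I_m = I_wt·(1 + Sβ·I_wt) exactly);
- *printed* variant: Sβ = (I_m − I_wt)/I_m², the form usually quoted.

On noiseless data the two are related exactly by
printed = derivation/(1 + Sβ·I_wt)²; the derivation variant inverts the
generator exactly and is used for recovery tests, while the printed
variant is the reporting default.  Estimates are formed per retained
timepoint (the first clamp sample is discarded as pre-steady-state) on
group-mean insulins; mean, SEM across timepoints and a one-sample
two-sided t-test against zero are reported.  A per-animal bootstrap SEM
is available as an alternative.  Negative estimates are reported as-is.

## In-silico GTTs and S_P inversion

A GTT starts the fast model at its steady state and adds the bolus to
glucose instantaneously at t = 0 (G0 = G* + 20 mM; I0 = I*).  The
default protocol is 0–60 min sampled every minute; areas under the
glucose/insulin curves (AUGC/AUIC) are total trapezoids with no baseline
subtraction (a baseline-subtracted variant exists behind a flag).  The
β mass used for every GTT is the full-model steady-state β of the
reference (wildtype-female) parameter set, reused across all (Sβ, S_P)
cells rather than recomputed per cell.

`build_augc_surface` tabulates AUGC/AUIC over an (Sβ, S_P) grid; AUGC is
strictly decreasing in S_P and increasing in Sβ (checked cell-by-cell),
so bands invert cleanly.  `invert_sp` works on the continuous forward
map (simulate-then-integrate per evaluation) rather than on the grid:
with AUGC target band [a−s, a+s] and Sβ band [b−w, b+w], the extreme
compatible S_P values sit at opposite rectangle corners, giving the
interval [solve(b−w, a+s), solve(b+w, a−s)] via bracketed Brent root
finds (the tabulated surface is kept for visualization).  Monotonicity
over the bracket is verified before solving.

## Synthetic data

Generators are deterministic in (seed, config) and embed ground truth.

- **Clamps**: 14 animals per group, glucose 19 mM, samples every 10 min
  over 2 h (13 timepoints; the first is excluded from estimation).
  Each measurement is the closed-form group steady state plus Gaussian
  noise with SD = 10% of the group mean (the upper end of typical
  insulin-assay plus sampling variability), floored at 1% of the mean.
  The knockout group is forced to Sβ = 0; both groups share β mass,
  matching the unchanged-β-cell-mass phenotype.
- **GTTs**: 14 animals; the noiseless model curve plus 10% Gaussian
  noise per sample; per-animal AUGC and the cohort mean ± SEM feed the
  inversion.
- **Calcium traces**: a 300 s baseline phase (3 mM glucose) at constant
  ratio 1.0 and a 600 s stimulation phase (15 mM) carrying k
  Gaussian-shaped transients of amplitude +40% over baseline
  (σ = 6 s, centres evenly spaced with 4σ margins), sampled every 5 s
  with additive noise of SD 2% of baseline.  The Gaussian bump shape is
  arbitrary; only the counting rule matters.

What the generators deliberately do *not* emulate: animal-level
covariates (body mass, diet, age), within-animal autocorrelation of
clamp samples, glucose-infusion-rate dynamics, drift or bleaching in
imaging traces, and irregular sampling.  Passing tests therefore show
the estimators invert the model they assume, not that real data meet
those assumptions.

## Calcium peak counting

Peaks in a phase are interior local maxima of the raw trace whose
percent difference above the *baseline-phase median* exceeds 20%.  A
local maximum is a sample strictly greater than the nearest differing
neighbours on both sides; plateau runs count once at their leftmost
sample (the minimal deterministic plateau rule).  No smoothing and no
refractory period are applied by default, matching the bare rule;
optional moving-median and minimum-spacing flags exist for noisy data.
The per-trace feature record (version `v1`: peak count, baseline median,
mean peak amplitude, time to first peak, AUC above baseline, mean
peak-to-peak interval, max ratio, end-plateau level) is a package
definition.

## Numerical choices

- Integrator: LSODA (stiff-capable), rtol 10⁻⁸ / atol 10⁻¹⁰, dense
  output on the sampling grid; blow-up guard at |state| > 10⁶.
- Root finds: Brent with xtol 10⁻¹⁴ (steady states) and 10⁻¹²
  (S_P inversion).
- Degenerate inputs: β = 0 is allowed (insulin decays to zero);
  α ≤ 0 and negative rates are rejected at construction; a clamp series
  with nonpositive insulin is rejected at the schema layer.
- Reported numbers print with 9 significant digits so repeated runs are
  byte-comparable.

## Statistical design notes and limitations

- The Sβ SEM is computed across the 12 retained timepoints.  With so
  few points, a ±2·SEM interval is narrower than a 95% t-interval
  (t₀.₉₇₅,₁₁ ≈ 2.20), so per-run "within 2 SEM of truth" events occur
  at ≈ 92% rate, not 95%; simulation at the default noise gives
  0.919 ± 0.005.  Users wanting nominal 95% coverage should use the
  t-quantile or the bootstrap SEM.
- The derivation-variant estimator is a nonlinear function of the
  group-mean insulins (1/Ī²), so it carries a small positive
  O(CV²) bias (≈ +0.4% at the default noise) and a right-skewed null,
  which inflates the nominal 5% test slightly (≈ 6% measured).
- S_P intervals from band intersection are *compatibility* intervals,
  not confidence intervals; their coverage depends on the width of the
  Sβ band carried forward.  With the clamp-stage band (±1.5 nM⁻¹) the
  generating S_P is covered in ≈ 100% of simulated cohorts because the
  Sβ-band term dominates the AUGC SEM.
- Problem sizes used in the shipped studies (500-seed recovery,
  1000-seed null calibration, 200-cohort coverage, 20×20 surface) were
  chosen to give binomial standard errors of ~1 percentage point on
  every reported rate.
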