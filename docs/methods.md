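# Methods

## Energy-partition model

A constant-load session is split into three contiguous phases — seated
rest, exercise, recovery — on a strictly increasing breath-by-breath time
base. The partition assumes:

* **Aerobic**: whole-body V̇O2 above the resting baseline during exercise
  reflects oxidative ATP turnover. The baseline is the arithmetic mean of
  the breaths in the final 120 s of rest (the early rest period is
  discarded as un-steady; the window is configurable). Exercise V̇O2 is
  linearly interpolated to a 1 s grid anchored at the first exercise
  breath and integrated by the trapezoidal rule over exactly the declared
  exercise duration (default 30 min), regardless of any extra exercise
  data beyond it. A session whose exercise V̇O2 sits below baseline
  yields a negative aerobic volume, returned with a warning flag rather
  than silently clamped.
* **Anaerobic alactic**: the fast component of EPOC estimates the
  phosphocreatine resynthesis O2 cost. Recovery V̇O2 follows
  `baseline + A1` for `t < td` and `baseline + A1·exp(−(t−td)/τ1)` for
  `t ≥ td`. The pre-delay plateau keeps the curve continuous at `td`.
  The decay-form exponent is the standard off-kinetics reading; an
  alternative `exp(1 − (t−td)/τ1)` form (which would make the value at
  `td` equal `baseline + e·A1`, contradicting A1 being an amplitude) is
  available behind `form="printed"` for sensitivity analysis only.
  A single fast component is modelled; no slow-component term. The
  recovery baseline is fitted independently of the pre-exercise baseline.
* **Anaerobic lactic**: net lactate accumulation is the **peak** of the
  immediately-post/3/5/7-min samples minus the pre-exercise sample; the
  15-min-exercise sample is kept for time-course reporting only.
  Conversion uses 3 mL O2·kg⁻¹ body mass per mmol·L⁻¹. Negative net
  accumulation is clamped to 0 with a warning by default
  (`clamp_negative=False` propagates it), on physical non-negativity
  grounds.

Total O2 volume is the exact sum of the three components — conservation
holds to the last bit on every partition — and converts to energy at a
configurable caloric equivalent, default 20.92 kJ·L⁻¹ O2 (≈5 kcal·L⁻¹),
reported in every output because no universal constant exists.

## Off-kinetics fitting

Nonlinear least squares (scipy `least_squares`, trust-region reflective,
analytic Jacobian, ftol/xtol/gtol 1e-12) on the raw breaths of the first
10 min of recovery (≥20 breaths required), unsmoothed and unweighted.
Bounds: baseline ∈ [0, 2] L·min⁻¹, A1 ∈ [0, 10] L·min⁻¹,
τ1 ∈ (0.05, 10] min, td ∈ [0, 2] min. The fit is multistarted over a
fixed 3×3×3 grid — A1 at {0.25×, 1×, 2×} of (first-30 s mean − last-2 min
mean), τ1 ∈ {0.3, 0.75, 1.5} min, td ∈ {0, 0.25, 0.5} min, baseline
started at the last-2 min mean — and the lowest-RSS converged solution is
kept (ties broken toward the smaller amplitude). Seeded jittered restarts
run only if every grid start fails. On noiseless forward-generated data
the generating parameters are recovered to ~1e-10 relative error; with
0.03 L·min⁻¹ breath noise the median amplitude and time-constant errors
are a few percent.

## Phase averaging

5-min HR/V̇E summaries use half-open windows `[start, start+w)` anchored
at each phase's first breath; only complete windows are produced, and a
window containing no breaths is an error. Bin means and the rest baseline
are arithmetic means of the covered breaths (breath spacing is
near-uniform, so time weighting would change values negligibly); the 1 s
interpolation grid is reserved for integrals, where spacing matters.

## Incremental-test utilities

The graded protocol starts at 50 W for 1 min, +15 W·min⁻¹ until 200 W,
+10 W·min⁻¹ after. Maximality requires ≥2 of: V̇O2 plateau (operationally
ΔV̇O2 < 150 mL·min⁻¹ between final stages, configurable — no standard
number exists), RER > 1.1, HR > 90% of (220 − age), RPE > 17 (all strict
inequalities). VT/RCP detection replaces by-eye placement by independent
raters with a reproducible surrogate: a continuous two-segment
piecewise-linear least-squares fit, breakpoint searched on a 101-point
interior grid, gated by an F-test (2 extra parameters, α = 0.05) against
the single line; perfectly linear input returns "not found". Cuff
pressure is `round(fraction × AOP)` in integer mmHg (cuff hardware
resolution).

## Crossover statistics

Paired t-tests (two-sided, df = n−1) compare conditions on each energy
component. The condition × time ANOVA is the classical fully-within-
subject decomposition; each effect is tested against its own
subject-interaction stratum, whose sums of squares are checked to
partition the total exactly. Sphericity is assumed (no Greenhouse–
Geisser correction), flagged in the result object. Post hocs are
per-time between-condition paired t-tests Bonferroni-adjusted over the
number of time points. Normality/variance pre-tests are not re-derived
here; users can apply scipy's Shapiro–Wilk/Levene to the same arrays.
α = 0.05 throughout.

## Synthetic trial generator

The generator emulates the study conditions the analysis expects: ~5 min
rest, 30 min cycling, 15 min recovery; breaths every 3 ± 0.5 s (uniform
jitter) shared across channels; mono-exponential on-kinetics (τ_on
~0.55 min) to a steady state set by a 10.8 mL·min⁻¹·W⁻¹ cycling economy
at ~70 W; recovery per the off-kinetics model; Gaussian breath noise
(V̇O2 SD 0.03 L·min⁻¹). Lactate samples at pre/15 min/0/3/5/7 min
post/15 min recovery follow a fixed rise-decay shape peaking immediately
post-exercise, with sample noise SD 0.12 mmol·L⁻¹ (consistent with a
0.07 mmol·L⁻¹ typical error). Population moments: mass 82.8 ± 12.6 kg,
V̇O2max 33.4 ± 4.6 mL·kg⁻¹·min⁻¹, age 24.5 ± 4.0 y, resting V̇O2
3.5 mL·kg⁻¹·min⁻¹-scaled; all truncated normals, drawn independently
(per-subject covariance between fitness, mass and lactate response is
unconstrained by group summaries, so independence is assumed).

BFR shifts are additive and apply only to the LIE-BFR arm: +1.0 mmol·L⁻¹
net lactate (LIE rise 0.65, so group peaks land near 1.97/2.89 over pre
~1.25), +0.05 L·min⁻¹ steady-state V̇O2, +8 bpm HR, +5 L·min⁻¹ V̇E. The
recovery amplitude A1 is deliberately **not** shifted — phosphocreatine
stores are condition-independent — so the alactic component differs only
by session noise. Day-to-day session offsets (SD 0.02 L·min⁻¹ on steady
state, 0.02 L·min⁻¹ on A1, 0.03 min on τ1, 0.15 mmol·L⁻¹ on the lactate
rise) give the within-subject variability a paired design needs; without
them paired tests would be degenerate.

What the generator does **not** emulate: drifting baselines, the V̇O2
slow component, coughs/swallows and other breath artefacts, lactate
assay calibration error, subject dropout, or any mechanistic muscle
metabolism (PCr kinetics, pH) and hemodynamics. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
structure, not robustness to every artefact of real metabolic-cart data.

Seeding: a trial seed deterministically expands to per-session seeds
(`trial_seed·100003 + subject_index·211 + condition·7 + 1 mod 2³¹`),
recorded in the manifest; identical seeds give byte-identical datasets.
The same session seed drives the breath and lactate streams so the
session's lactate rise is shared between them.

## Problem sizes and numerical choices

Property suites that need many sessions (the 1000-session conservation/
monotonicity sweep, the null-effect false-positive check) run on
shortened sessions (3 min rest, 6 min exercise, 5 min recovery): every
property checked is duration-invariant, and this keeps the full test
suite around two minutes. The acceptance script and the direction-
pattern checks use the full 12-subject design. Windows are half-open and
0-based; O2 volumes are reported to 3 decimals and energies to 1 decimal
in serialized outputs while full precision is kept internally.

## Known limitations

* Absolute energy anchors for a real trial depend on the caloric
  equivalent chosen; only O2 volumes are assumption-free.
* The breakpoint detector assumes a single slope change; curvilinear
  ventilatory drift can produce spurious breakpoints that human raters
  would discount.
* The ANOVA offers no sphericity correction; with only two conditions
  the condition effect is exact, but time effects at k > 2 rely on the
  assumption.
* `td` identifiability is weak when breath spacing is coarse relative to
  the delay; bounds keep estimates finite but near-boundary values
  deserve scepticism.
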