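# Methods

## Scope

`metpower` implements two estimators of the energy expenditure and its
aerobic/anaerobic partition during intermittent running, a synthetic-data
harness that makes both testable against a known ground truth, and the
repeated-measures/agreement statistics used to compare them. It does not
parse GNSS device exports, does not model jumps/collisions/ball handling,
does not distinguish alactic from lactic supply inside the metabolic power
model (the model cannot), and does not implement the modified
"intermittent" variant of the three-component model.

## Metabolic power model

The model maps a uniform 20 Hz speed trace to metabolic load under two
assumptions: accelerating on flat ground is energetically equivalent to
running uphill at constant speed, and the constant-speed cost of running is
speed-independent at 3.6 J/kg/m.

- **Acceleration.** Central finite differences of speed, one-sided at the
  ends, then a moving average over a configurable window (default 0.25 s).
  The filtering applied by commercial devices is proprietary and
  undisclosed; results at high sample rates depend on this choice, which is
  why it is exposed as a parameter.
- **Equivalent slope and mass.** ES = a/g with g = 9.81 m/s², from the
  forward acceleration only (flat-terrain assumption, no vertical
  component); EM = √(ES² + 1).
- **Energy cost.** The fifth-order polynomial in ES times EM. The
  polynomial was fitted up to |ES| = 0.45 (≈ 4.5 m/s²); beyond that the
  implementation extrapolates as the field software does, but counts and
  warns about the out-of-range samples so the extrapolation is observable.
  Negative ES is evaluated by the same polynomial; no braking-specific
  cost model is applied.
- **Simulated oxygen uptake.** The oxygen-equivalent demand
  Ė = P · 60/20.9 ml/kg/min relaxes through a first-order filter with time
  constant τ (default 20 s, the oxidative muscle-to-airway delay). The
  "metabolic power intervals" of the recursion are the individual 0.05 s
  samples — the finest consistent reading, making the response a standard
  discrete first-order filter. The measured V̇O2max caps the response;
  after a capped step, the next step starts from the capped value (the
  onset-value convention when the cutoff engages is otherwise undefined).
  The response starts at 0 because net uptake is modelled.
- **Partition.** Per sample, aerobic rate = min(P, P_vo2sim) and anaerobic
  rate = the non-negative remainder, so W_AER + W_ANA = ∫P dt·m holds to
  machine precision by construction. Integrals are trapezoidal with each
  inter-sample strip assigned to the phase of its left sample (half-open
  [t, t+Δ) intervals); this makes effort/break window integrals add up
  exactly to the total. Break exclusion subtracts the aerobic integral
  over break-labelled strips; the anaerobic supply has no per-break
  attribution and is left unchanged.

Canonical units: s, m/s, m/s², W/kg, ml/kg/min, kJ; the only
power↔uptake conversion constant is 60/20.9, derived from the fixed
energy equivalent of 20.9 kJ/L O2.

## Three-component (PCr-LA-O2) model

- **Net aerobic supply.** Net accumulated uptake is computed first
  (accumulated V̇O2 minus resting uptake × duration) and then multiplied by
  the energy equivalent — the dimensionally consistent reading. Negative
  net uptake is clipped to zero with a warning.
- **Windowed integration.** Breath data are irregular (~1.5–3 s). Window
  edges rarely coincide with breaths and the uptake curve has sharp
  on-/off-kinetic kinks at effort boundaries. Integrals therefore use a
  shape-preserving monotone cubic (PCHIP) interpolant of the breaths
  rather than plain trapezoids: a linear chord straddling a kink
  systematically overshoots it, which for few-second effort windows
  produced double-digit percentage errors; the monotone interpolant stays
  within the data. (Plain trapezoid remains what `numpy.trapezoid` would
  give and is used internally for uniform 20 Hz series.)
- **Smoothing.** A centered 10-breath moving average is provided and used
  for peak RER and peak/mean uptake reporting. It is deliberately *not*
  applied before the windowed integrals or the EPOC fit: the average has a
  transition width of roughly 20 s, which redistributes flux across
  effort-window boundaries, and pre-averaging an exponential decay inflates
  the fitted fast amplitude by sinh(w/2τa)/(w/2τa) (~2–4% at typical
  breathing rates). Least squares and quadrature already average
  breath-level noise without that bias.
- **EPOC fit.** vo2(t) = a·e^(−t/τa) + b·e^(−t/τb) + c on ≥ 6 min of
  post-exercise breaths, trust-region nonlinear least squares with
  non-negative amplitudes, multi-start over a 3×3 grid of time-constant
  pairs, components reordered afterwards so τa < τb. The offset c is
  initialized at the measured resting uptake and bounded to ±50% of it,
  which stabilizes the fit against slow-component/offset trade-off over a
  7 min window. Non-convergence from every start raises with the best
  residual attached.
- **Alactic supply.** The fast component integrated to the 2τa cut-off,
  a·τa·(1 − e⁻²), closed form; numerical quadrature is retained only as a
  test oracle. The slow component is not subtracted inside [0, 2τa] — the
  fast term alone is the phosphocreatine-resynthesis proxy.
- **Lactic supply.** max(ΔLa, 0) · 0.003 L/kg · m · EE, with ΔLa the
  highest post-exercise minus the pre-exercise concentration. Negative
  ΔLa is reported as-is but contributes zero energy (energy cannot be
  negative), with a warning.
- **Energy equivalent.** Fixed 20.9 kJ/L, or individual by linear
  interpolation of the bundled nonprotein caloric-equivalent table
  (Lusk's classical respiratory-quotient table, kcal/L × 4.184; RER
  0.70 → 19.61 up to 1.00 → 21.12 kJ/L), with the peak exercise RER
  clamped to [0.70, 1.00] under a warning.

## Synthetic sessions

The generator emulates the three protocols with a known energy truth:

- **Speed profile.** Every shuttle leg is a symmetric
  accelerate–cruise–decelerate trapezoid with a full stop at each 180°
  turn. Peak accelerations default to 4.25 m/s² (decelerations 4.5 m/s²),
  keeping the trace essentially inside the equivalent-slope validity
  range; the continuous shuttles use gentle 1.5 m/s² ramps with the cruise
  speed solved so each 20 m leg averages exactly 8 km/h. The true
  within-effort speed profiles of field athletes are unknown; this profile
  is a modelling choice, not a reconstruction.
- **Ground truth.** The noiseless trace defines the metabolic power demand
  through the energy-cost model. The true uptake response is the same
  first-order filter (τ_on = 20 s, capped at V̇O2max); the aerobic truth is
  its integral over the effort windows, and the anaerobic truth is the
  effort-window demand integral minus the aerobic truth — so the three
  components sum to the effort-window demand by construction. The deficit
  is split into lactic/alactic by `lactic_fraction` (defaults 0.15 / 0.4 /
  0.9 for continuous / accelerations / sprints, chosen once to mirror the
  energy system each protocol is designed to stress).
- **Breath series.** Gross uptake = response + resting offset during
  exercise; after the last effort it decays biexponentially with the fast
  amplitude *derived from the alactic truth* (inverse of the 2τa integral)
  and a default slow component. Breath intervals shorten with uptake
  (3 s at rest to 1.5 s at V̇O2max) with log-normal jitter; uptake carries
  4% multiplicative noise (typical metabolic-cart error). Speed noise is
  2.3% relative, lactate noise 0.1 mmol/L additive on a 1.6 mmol/L
  baseline — the typical device errors of the instruments emulated.
- **Lactate.** The peak rise above baseline inverts the 3 ml O2/kg per
  mmol/L mapping of the lactic truth; the 1/3/5/7 min samples follow an
  appearance/clearance shape peaking in minute 3.
- **Randomness.** One seed feeds a `SeedSequence` with named sub-streams
  for speed, breaths and lactate; identical inputs reproduce a session
  bit-for-bit.

What the harness does *not* emulate: GPS positional error structure
(speed-level noise only), slow-component V̇O2 drift during exercise,
cadence/stride mechanics, bicarbonate buffering, and — importantly — any
*disagreement mechanism* between the two models: the synthetic truth is
derived from the metabolic-power demand itself, so on synthetic cohorts
the two models agree far more closely than on real athletes. Passing
recovery tests therefore validates the estimator implementations, not the
field validity of either model. A related artefact: for maximal protocols
the conserved demand forces large anaerobic truths, so synthetic lactate
peaks can exceed physiological values.

## Statistics

Per variable, a gate (Shapiro–Wilk per condition, Levene across
conditions, α = 0.05, constant conditions fail by convention) chooses
RM-ANOVA or Friedman. The one-way within-subject ANOVA is computed from
its sums of squares with generalized η² = SS_effect/(SS_effect + SS_subj +
SS_error); Friedman's W = χ²/(n(k−1)). Post-hocs are paired t or Wilcoxon
signed-rank (exact p for n ≤ 25, zeros dropped), Bonferroni-multiplied and
capped at 1. Cohen's d uses the paired-difference SD (the pooled-SD
alternative is not implemented). Relative bias is the mean of per-subject
percentage differences against the reference (not the percentage of
means), matching a "bias ± SD" report; zero-reference subjects are
excluded from it with a flag. Bland-Altman limits are bias ± 1.96 SD of
the differences. Note that a four-test gate at α = 0.05 routes ~19% of
perfectly normal datasets to the nonparametric branch; the type-I error of
the full gated procedure stays at the nominal 5% (tested at n = 12,
k = 3).

## Problem sizes in the test suite

The acceptance tests use one noiseless session per protocol for
ground-truth recovery, 100 random traces for partition conservation, 50
noise seeds for EPOC recovery, 1000 parameter sets for the
analytic-vs-quadrature check, 2000 null replicates (n = 12, k = 3) for the
type-I error and n = 1000 for Bland-Altman coverage; the full suite runs
in well under a minute on one CPU.

## Known limitations

- Acceleration smoothing is a free parameter with real influence at 20 Hz;
  there is no ground truth for the proprietary device filtering.
- The equivalent-slope polynomial is extrapolated beyond |ES| = 0.45
  during maximal decelerations (flagged, as the field software does).
- The EPOC fast/slow decomposition is weakly identified when τa and τb are
  close; the multi-start fit reports the best residual but the 2τa
  cut-off inherits that ambiguity.
- Break exclusion corrects only the aerobic side in both models; anaerobic
  supplies are identical including/excluding breaks by construction.
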