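# Methods

This note documents the models behind `fgrtools`, the defaults and why they
were chosen, what the synthetic cohort does and does not emulate, and the
numerical conventions used throughout.

## Study design being modelled

A 2×2 mouse study at embryonic day 18.5: genotype (wild-type WT vs
placental-specific *Igf2* knockout P0, coexisting within each litter) ×
maternal treatment (plain drinking water vs drug-medicated water from
E12.5).  Endpoints are fetal and placental weight, fetal anthropometrics,
umbilical-artery velocimetry, and placental transfer of a radiolabelled
System A substrate.

## Maternofetal clearance

Maternal plasma tracer concentration is modelled as a one-phase exponential
decay `C(t) = C₀·e^(−kt)`, fitted by nonlinear least squares
(`scipy.optimize.curve_fit`, non-negative bounds) with a deterministic
log-linear regression start.  r² is computed against the fitted curve; fits
with r² ≤ 0.6 are *flagged* rather than discarded, and the flag propagates
to every clearance result (`qc_pass`) so downstream summaries can exclude
them.  The default fit pools all dams' samples, since a disappearance curve
is typically built from many dams each contributing a terminal sample; a
per-dam mode exists for rich per-dam time courses.  A two-parameter model
(no plateau) is the default; `plateau=True` adds a non-negative offset for
conventions that include one.

The time integral uses the closed form `∫₀ˣ C dt = C₀(1 − e^(−kx))/k`
(implemented with `expm1` for small `k`; the `k = 0` limit is `C₀·x`) and is
property-tested against adaptive quadrature at 10⁻⁸ relative tolerance.
Clearance is then

    Kmf per g placenta = Nx / (W_placenta · ∫),   total = Nx / ∫,
    per g fetus        = Nx / (W_fetus · ∫),

with units dpm / (g · dpm·min/µl) = µl/min/g.  `Nx` is the measured carcass
count re-inflated for the tail tip removed for genotyping,
`Nx = raw/(1 − f)`, assuming the label distributes uniformly with fetal
mass; the original protocol states that a correction was applied but not
its formula, so the proportional-to-mass model is this package's documented
choice.  Each dam's actual exsanguination time `x ∈ [1, 5]` min is carried
per fetus; no standardised `x` is assumed.

## Fetal-weight centiles

The reference distribution (untreated WT) is modelled as Gaussian.  Two
estimators are provided: `histogram_nls` (default 0.05 g bins, least-squares
Gaussian through bin counts — mirroring frequency-distribution-curve
practice; note binning inflates the fitted SD by ≈ w²/12, ~1% at these
scales) and `direct_moments` (sample mean/SD).  The 5th-centile threshold is
`mean − 1.645·SD`; 1.645 is the conventional rounding of Φ⁻¹(0.95) = 1.6449
(`z_for_centile` returns the exact value).  "Below the centile" means
strictly below, matching clinical usage; the boundary rule is configurable.
Empty cells are omitted from reports rather than shown as zero.

Calibration note: pup-level SDs are rarely published.  The WT-control SD
default (0.1034 g) is back-derived by inverting the threshold formula
against a published mean of 1.20 g and threshold of 1.03 g; the P0-control
SD (0.1334 g) is back-derived from a published 25% above-threshold fraction
via the normal tail, `(1.03 − 0.94)/Φ⁻¹(0.75)`.  These are calibrations,
not measurements.

## Doppler velocimetry

Cycles are delimited peak-to-peak by prominence-filtered maxima
(`scipy.signal.find_peaks`, prominence defaulting to 20% of trace
amplitude — robust at the synthetic noise levels; configurable).  A trace
with fewer than 3 full segments raises an explicit error rather than
returning an unreliable value.  Per segment, PSV = max, MDV = min, MV =
trapezoidal time-average.  The published PI formula operates on single
summary values, so the default aggregation averages PSV/MDV/MV across
cycles first and forms PI from the averages; the mean of per-cycle PIs is
reported alongside (`pi_per_cycle_mean`), and the two agree to < 1% on
low-noise traces.  No operational motion-artefact criterion is imposed;
EDV and MDV both denote the waveform minimum.

## Litter-aware inference

Litters, not pups, are independent.  The primary inference collapses pups
to per-(litter, genotype) means and permutes at the exchangeable level:
treatment labels across whole litters, genotype labels within litters
(litters carrying a single genotype keep their label), with the two-sided
p-value `(1 + #{|T*| ≥ |T|})/(1 + n_perm)` and T the difference of level
means.  This replaces a generalized-linear-mixed-model analysis whose
family/link is typically unreported; the permutation test is exact under
exchangeability and assumes no distributional form.  Interaction is tested
by permuting residuals of the additive litter-summary model — an
approximation, documented as such.  A delegated mixed-model mode
(statsmodels `MixedLM`, random litter intercept, Wald p-values) is included
for comparison only.

"Sequential Šidák" is implemented as the step-down variant: order raw
p-values ascending, set `p̃₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(m−i+1)`, enforce monotone
non-decrease along the ordered sequence, return in original order.  Cell
summaries report mean ± SEM with the litter as the unit of n.  Default
`n_perm = 9999` for analyses (999 in the pipeline default for speed); the
permutation seed is mandatory in configs and echoed to the log.

## Synthetic cohort

The generator emulates: litters of ~8 pups (Poisson-dispersed, floor 1;
8.0/8.6 mean by arm), 52% WT per pup, and pup weights from a two-level
model `weight = cell_mean + litter_intercept + pup_deviation` with shared
per-litter intercepts (marginal variance = litter_sd² + pup_sd²).
Published studies report litter-level SEMs only, so the implied WT variance
(marginal SD 0.1034 g) is split 50/50 between levels by default
(litter_sd = pup_sd = 0.0731 g); the split is configurable.  Fetal and
placental pup deviations are independent by default with an optional
correlation parameter.  Negative weight draws are resampled (truncation
mass is negligible at these calibrations); negative plasma concentrations
are clamped to zero with a logged warning.  Plasma defaults (C₀ = 100
dpm/µl, k = 0.1 /min), ground-truth Kmf (25 µl/min/g) and waveform defaults
(PSV 60, EDV 10 mm/s at 3.5 Hz) are realistic round numbers for this assay
class, chosen once; they are not published values.

The waveform is a half-rectified raised-cosine systolic pulse occupying 40%
of the cycle atop a flat diastolic baseline, giving the closed-form cycle
mean `edv + (psv − edv)·0.2` used as the analytic oracle.  Any shape with
controllable max/min/mean would do; no physiological claim is attached.

What the generator does *not* emulate: gestational time courses (E18.5
snapshot only), embryo loss/resorption, maternal physiology, within-litter
weight trends (e.g. uterine position), non-Gaussian weight tails, or
measurement error structure beyond multiplicative/additive noise.  Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to real-data pathologies.

## Numerical conventions and problem sizes

- Degenerate inputs: constant plasma samples fit `k = 0` with r² defined as
  1 (zero total variance); all-identical weights fall back from histogram
  to moment fitting; all-equal litter summaries yield permutation p = 1.
- Determinism: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); the pipeline derives stage streams from one
  config seed and reruns are byte-identical.
- Validation suites use: 10⁵-draw samples for distribution-recovery and
  tail checks; 200 replicates for noisy decay-rate recovery (median
  relative error < 5% at 5% noise); 1000 null datasets × 199 permutations
  for type-I-error calibration (rejection rate within [0.03, 0.07] at
  α = 0.05); 10 replicate 19-litter arms for the treated-P0 recovery check.
  These sizes keep Monte-Carlo error well inside the asserted bands.

## Known limitations

- The permutation interaction test relies on residual exchangeability and
  is approximate in small designs.
- The histogram Gaussian fit inherits binning bias; use `direct_moments`
  when an unbiased SD matters more than mirroring histogram practice.
- The tail-tip correction model and the variance split are calibrated
  choices that cannot be verified against published per-pup data.
- `Kmf` assumes unidirectional transfer over the 1–5 min window; no
  two-phase kinetics, backflux, or transporter saturation (Km/Vmax) is
  modelled.
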