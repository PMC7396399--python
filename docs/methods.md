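# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind petquant, in the spirit of the methods documentation of
packages like statsmodels or msprime: what is computed, under which
assumptions, and what the tests do and do not demonstrate.

## Data model and units

Time is minutes internally (hours in the dosimetry layer, where the field's
conventions differ); readers convert from header-declared units.
Concentrations are kBq·cm⁻³ and are stored decay-corrected to injection
time, as dynamic-PET TACs conventionally are.  Dosimetry explicitly
re-applies physical decay (¹⁸F half-life 109.77 min) where the physics
requires the un-corrected activity.  A TAC's model value is attributed to
the frame *interval*, not the mid-time: simulated and fitted model curves
are averaged over each frame, because with 20-s early frames the
distinction is material.  Observed values are plotted and integrated at
frame mid-times.

## Arterial input function

The metabolite-corrected input is plasma(t)·pf(t).  The parent fraction
pf(t) = 1 − a·t^b/(t^b + c) is a Hill-type model with pf(0) = 1 enforced,
a ∈ [0,1], b, c > 0, fitted by bounded least squares from three starts.
With nine radiometabolite samples this form is robust and monotone; any
monotone form consistent with the measured fractions would serve.  The
continuous input interpolates the corrected knots piecewise-linearly, rises
from an implicit (0, 0) knot, and continues beyond the last sample with a
mono-exponential fitted to the last three knots — kinetic integrals extend
past the last blood sample at late frame mid-times, so the tail rule is
part of the definition.  A non-decaying fitted tail is clamped to a slow
decay (1e-4 min⁻¹) to keep integrals finite.  A constant delay parameter
exists (default 0); dispersion correction is deliberately out of scope.

The plasma free fraction is f_P = mean(sample free/total) / mean(control
free/total): per-replicate ratios first, then the membrane-binding
correction by the control recovery; values above 1 are clipped.

## Compartment simulation and fitting

The 1TCM/2TCM tissue response is the convolution of the input with
K1·Σ cᵢ·e^(−θᵢt), where θ₁, θ₂ are the eigenvalue magnitudes of the rate
matrix and the cᵢ come from the partial fractions of
K1(s + k3 + k4)/((s + θ₁)(s + θ₂)).  On a uniform 1-s grid the convolution
of a piecewise-linear input with an exponential kernel has an exact
one-step recursion, evaluated with `scipy.signal.lfilter`; frame averages
use the identity ∫y dt = (∫Cp dt − Δy)/θ per component, with ∫Cp exact by
trapezoid (Cp is piecewise linear on the grid).  The simulator agrees with
an independent Runge–Kutta oracle to ~1e-5 relative per frame; degenerate
repeated eigenvalues are split by an epsilon.

Fits minimise Σ wᵢ(obsᵢ − modᵢ)² with frame-duration weights wᵢ ∝ Δtᵢ by
default (uniform optional).  For the synthetic noise model — additive
Gaussian with SD ∝ 1/√Δt — duration weighting is exactly inverse-variance.
Rates are bounded to [1e-6, 5]; the blood-volume fraction vB is fixed at 0
by default (the model supports it).  The 2TCM is seeded from a 1TCM pre-fit
with two standard starts, (K1, k2, 0.05, 0.05) and a near-1TCM start
(k3 = 1e-4), which guarantees WRSS(2TCM) ≤ WRSS(1TCM) in practice; three
seeded log-normal restarts run only if the standard starts fail.  AIC uses
the least-squares form N·ln(WRSS/N) + 2k.  A 2TCM fit whose k4 lands on
the lower bound with k3 > 0 is reported non-converged: that corner is
irreversible trapping, where V_T is unidentifiable, and such fits are
excluded from downstream tables the way non-convergent fits are excluded
in practice.

Logan graphical analysis regresses ∫₀ᵗC_T/C_T on ∫₀ᵗCp/C_T over frames
with mid-time ≥ t* (default t* = 30 min, configurable); ∫Cp uses the exact
piecewise-linear integral of the input, ∫C_T the trapezoid over mid-time
samples anchored at (0, 0).  The F-test compares nested fits with
df = N − 2 and N − 4; time stability refits truncated data at
63…123 min in 12-min steps, using the full-data solution as an additional
start for short scans.

SUV follows the standard definition conc[kBq·cm⁻³] / (dose[kBq] / body
mass[g]), i.e. conc·weight[kg]/dose[MBq] numerically.

## Reliability statistics

TRV and ICC implement the printed formulas exactly; s_b² and s_w² are the
one-way ANOVA mean squares.  Negative ICC estimates are reported, not
clipped.  Regional TRV is the across-subject mean of per-subject TRVs.
Subjects missing a session, or with a non-converged fit in a region, are
excluded pairwise for that region only; a region left with fewer than three
complete pairs gets an undefined (NaN) row rather than failing the run.
Note that the ANOVA ICC estimator is biased low in small cohorts (about
−0.07 at true ICC 0.6 with 8 subjects and 2 sessions); the recovery tests
therefore check unbiasedness on 30-subject cohorts and separately assert
the direction of the small-cohort bias.

## Dosimetry

%ID = conc[Bq·cm⁻³]·volume[cm³]/injected[Bq]·100.  Urine voids are added
back to the bladder VOI cumulatively — a measurement-driven approach, no
dynamic voiding model.  Organ retention (decay-corrected %ID) is fitted
with Σ aᵢ·e^(−λᵢt), aᵢ, λᵢ ≥ 0, order 1–3 selected by AIC (with the RSS
floored at numerical precision so an exact fit does not buy extra terms);
λ = 0 is an allowed plateau, and rates below 1e-6 h⁻¹ are reported as 0.
Because the coefficients are non-negative, organs with *rising* uptake
(gall bladder, small intestine) resolve to a plateau at roughly their late
level — conservative for the dose integral, since the physical-decay
window is short.  A trapezoid-plus-physical-tail integration is the
fallback when fitting fails.  Residence times use the closed form
τ = Σ aᵢ/(λᵢ + λ_phys)/100 (hours); a whole body with no biological
clearance gives exactly T½/ln2 = 2.6394 h.

Absorbed doses are D_target = Σ_source τ·S(target←source) with S in
mGy/(MBq·h), reported as μSv/MBq (radiation weighting factor 1).  Source
organs absent from the S-matrix fold into rest-of-body.  The effective dose
uses ICRP-60 tissue weighting factors, stored in a YAML scheme file so
ICRP-103 can be swapped in: gonads 0.20; red marrow, colon, lung, stomach
0.12; bladder, breast, liver, oesophagus, thyroid 0.05; skin, bone surface
0.01; remainder 0.05 over {adrenals, brain, small intestine, kidneys,
muscle, pancreas, spleen, thymus, uterus}.  Conventions of the
adult-male-phantom era are encoded as data: thymus dose stands in for the
oesophagus, testes for the gonads, colon = 0.57·ULI + 0.43·LLI (mass
split).  The ICRP-60 splitting rule applies when one remainder tissue
exceeds every named organ (here typically the pancreas): half the remainder
weight to that tissue, half to the arithmetic mean of the rest.  The exact
remainder handling of the legacy phantom software is unpublished, which is
why effective-dose comparisons against published values carry a ±5%
tolerance; under this implementation the published per-organ doses give
25.6 μSv/MBq.  The repository ships only a clearly-labelled synthetic toy
S-matrix; real phantom S-values are an input file.

## Synthetic data generator

The generator emulates the study conditions; every generator is a pure
function of (spec, seed).

*Input*: plasma rises linearly to 15.0 kBq·cm⁻³ at 1 min, then decays
tri-exponentially with fractions (0.85, 0.10, 0.05) and rates (3.0, 0.15,
0.002) min⁻¹.  The shape and scale were set so the default whole-brain
curve peaks near SUV 1.8 at ~36 min for the default 122 MBq / 70 kg
subject; the late washout (SUV ratio ~0.7 of peak at 120 min) is somewhat
faster than the flattest real curves.  Parent-fraction defaults
(a, b, c) = (0.6, 2.0, 3600) give exactly 70% parent at 60 min.  Whole
blood is plasma divided by a constant ratio 1.2.

*Brain cohorts*: population kinetic parameters for the 12 gray-matter
regions take the published mean K1, k2, k3 with k4 derived as
k4 = k3/(V_T·k2/K1 − 1), so the population macro-parameter equals the
published regional mean V_T (per-subject ratio means do not compose, so
the printed parameter means and printed mean V_T cannot both be honoured;
V_T is the primary outcome and wins, and k4 — the least identifiable rate —
absorbs the adjustment).  Between-/within-subject variation is log-normal
with unit median; the CV labelled k4 applies to the exchange ratio k3/k4
(k4 derived), because perturbing 1/k4 directly produces V_T tails far
outside the emulated magnitudes.  Defaults: between-subject CV 0.15,
within-subject (session-to-session) CV 0.07 — the latter calibrated so the
simulated-cohort mean TRV of V_T lands near the published ~16.5%.  Frame
noise is additive, zero-mean Gaussian with SD = tac_noise_cv × TAC peak at
the 1-min reference frames, scaled by 1/√Δt across frames (default CV
0.05); anchoring at the reference frame keeps the V_T uncertainty in the
range implied by the study's across-subject variability.  Each session gets
its own input amplitude (between CV 0.15, within CV 0.06) so the AUC-based
reliability diagnostics have realistic structure; V_T, a ratio, is
unaffected by input scale.  f_P is drawn log-normally around 0.095.

*Whole body*: organ %ID curves use uptake-washout shapes
A(1 − e^(−t/τ_up))e^(−βt) at the 8 session mid-times of the 4-session
protocol (0.15–5.8 h), with liver peaking ≈25 %ID at 0.5 h, rising
hepatobiliary organs, total urinary excretion 12·(1 − e^(−t/3.5)) %ID
(≈9.7 %ID by 5.8 h), 2%-CV multiplicative noise, and a remainder term that
enforces a fixed 98 %ID recovery, so activity is conserved by construction.

What passing tests on these data do *not* show: robustness to real-world
input-function artefacts (dispersion, delay, metabolite-model error),
non-Gaussian or correlated PET noise, VOI delineation and partial-volume
effects, or inter-scanner resolution differences.  The generator's variance
components are knobs, not estimates of the study's true components — only
the printed TRV/ICC summaries constrain them.

## Problem sizes

The test suite and the acceptance script use 3–8-subject simulated cohorts,
100-replicate noise studies, 60–100-curve model-selection and concordance
samples, and 500-replicate variance-component simulations (fit-free); these
sizes give Monte-Carlo error comfortably below each assertion's tolerance
while keeping a full run to a few minutes on one CPU.

## Known limitations

- No dispersion correction and no fitted delay by default.
- vB is not fitted by default; whole-blood curves are used only if supplied.
- Logan t* is fixed (default 30 min), not selected by an error criterion.
- The non-negative retention family cannot represent rising organ uptake
  exactly (see above).
- Published per-subject tables are not reproducible from this package:
  subject-level raw data are unpublished, and parameter means do not
  compose to mean V_T; all subject-level behaviour is validated through
  simulation instead.
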