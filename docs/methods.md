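# Methods

`cortdbs` implements a population pharmacokinetic (PK) model of oral
hydrocortisone (HC, pharmaceutical cortisol) that links total cortisol
concentrations measured in plasma and in dried blood spots (DBS, whole
blood including red blood cells), for therapy monitoring in pediatric
adrenal insufficiency. This note documents the model, the numerical
choices, the synthetic-study generator, and the known limitations.

## Whole-blood binding model

At every instant total cortisol in whole blood is assumed to be at
equilibrium between four species, parameterized by the unbound plasma
concentration `Cu` (nmol/L):

    A_u   = Cu · V_c                          unbound
    A_CBG = V_c · Bmax · Cu / (Kd + Cu)       corticosteroid-binding globulin
    A_Alb = V_c · NS_Alb · Cu                 albumin (linear)
    A_RBC = V_c · KR · Cu                     red-blood-cell association (linear)

with `V_c` the central (plasma) volume. CBG binding is saturable
(`Kd = 9.71 nmol/L` fixed; `Bmax` calibrated, see below); albumin binding
is linear (`NS_Alb = 4.15` fixed). The plasma observation pools every
species except the RBC pool over `V_c`; the DBS observation pools all four
species over the whole-blood volume `V_c + V_delta`, where `V_delta` is an
apparent RBC volume estimated per age group (11.1 L children/infants,
1.05 L neonates; not allometrically scaled). Two identities follow
directly and are enforced by tests:

* `f_Alb / f_u = NS_Alb` and `f_RBC / f_u = KR` at every concentration;
* `C_pla / C_DBS = (1 + V_delta/V_c) · (1 − f_RBC)`, which decreases with
  concentration because CBG saturation raises `f_RBC`.

Inverting total amount to `Cu` is a quadratic with exactly one
non-negative root; the cancellation-safe branch of the quadratic formula
is used and checked against bisection on random parameter sets at 1e-8.

### Why KR instead of the published association constant

The source estimate for the RBC association constant is 6.62, but its
published form couples to `V_delta` through equations not reproducible
from the printed material. The printed saturated-end fractions fix the
effective RBC:unbound amount ratio at ≈0.92 in *both* age groups
(8.3/9.0 and 12/13), so the module parameterizes the association as
`A_RBC = KR·Cu·V_c` with `KR` calibrated, and stores the published 6.62
separately for documentation. This reproduces every printed Cmax-side
fraction and the ratio behaviour.

### Calibration of Bmax and KR

`Bmax` does not appear in the published parameter table, so both free
binding constants are calibrated deterministically against the published
fraction-curve anchors: `KR` equals the mean saturated-end RBC:unbound
ratio, and `Bmax` then minimizes the squared error of the predicted
fractions at the anchors (coarse log grid plus Nelder–Mead polish), the
dominant anchor being the ≈90% CBG fraction at the DBS quantification
limit of 1.8 nmol/L. The calibrated values are `Bmax ≈ 552 nmol/L`,
`KR ≈ 0.9226`. With them, fourteen of the sixteen published endpoint
fractions are reproduced within 5% relative. The two exceptions are the
low-concentration RBC fractions: the published endpoints imply
`f_RBC/f_u ≈ 1.12` at 1.8 nmol/L but ≈0.92 at Cmax, which no single
linear coupling can satisfy; the model predicts ≈1.5% there instead of
the printed 1.9% (a ~20% relative gap on a sub-2% fraction). A baseline
RBC amount could in principle lift the low end, but the reported pediatric
baselines imply a baseline RBC amount larger than the entire whole-blood
amount at 1.8 nmol/L, so the curves are reported without baseline and the
discrepancy is documented rather than absorbed.

## Structural model

Absorption from an oral depot is Michaelis–Menten
(`Vmax = 21,388 nmol/h`, `Km = 4,810 nmol` at half-saturation,
bioavailability F = 1), feeding a two-compartment disposition model in
which clearance (`CL = 400 L/h`) and intercompartmental exchange
(`Q = 160 L/h`) act on the *unbound* concentration; `CL` of this
magnitude is physiologic only as unbound clearance. The ODE state is the
total central amount including the RBC pool (rapid-equilibrium
assumption); the binding inversion runs inside every right-hand-side
evaluation. Clearances scale with body weight to the 0.75 power and
volumes linearly, referenced to 70 kg. Doses convert to nmol with the
cortisol molar mass 362.46 g/mol. Baselines are additive constants on
each observation scale (15.2 nmol/L adult plasma; 9.41/4.22 nmol/L
pediatric plasma/DBS). Adults carry no RBC pool at all (`V_delta = 0`,
`KR = 0`): the adult arm of the source data contained no DBS samples and
its published plasma parameters were essentially unchanged by the DBS
extension.

Typical pediatric individuals use the weights implied by the published
per-kg RBC volumes: 13.5 kg (children/infants) and 3.6 kg (neonates).
Deterministic 6-h simulations of 7 mg reproduce the published whole-blood
Cmax values (180 and 820 nmol/L) within 0.5%; 4 mg gives 153 vs 141 and
679 vs 767.5 nmol/L (within the ±20% band expected when absorption and
weight assumptions are partially reconstructed).

### Integrators

The reference path (`structural.simulate_profile`) uses LSODA with
rtol 1e-8 / atol 1e-10 and integration restarts at dose events; outputs
at a dose instant report the pre-dose state. The estimation path uses a
Dormand–Prince 5(4) integrator compiled with numba (default rtol 1e-6),
because the Laplace/SIR/VPC machinery needs on the order of 1e5 profile
evaluations on one CPU. The two paths agree to better than 1e-5 relative
and are cross-checked in the test suite; the compiled kernel flags
pathological parameter vectors with NaN instead of looping.

## Population model

Interindividual variability is log-normal on CL, Km, Vmax, F, V_delta and
the baselines, with the published %CV values converted by
`CV = sqrt(exp(ω²) − 1)` (under this convention the fixed 131.1% CV of
the shared pediatric baseline corresponds to ω = 1.000, which is why the
convention was chosen). The pediatric plasma and DBS baselines share one
random effect. Residual error is additive on the log scale
(σ at 14.4% CV), shared across observation types and populations.
Observations below the LLOQ (14.1 nmol/L plasma, 1.8 nmol/L DBS) are
discarded (M1). A pediatric baseline is fixed to the subject's pre-dose
observation when that observation is quantifiable — in which case the
pre-dose record leaves the likelihood, since its residual would be
identically zero — and is otherwise estimated under the fixed shared
variability.

### Likelihood

The marginal likelihood uses the Laplace approximation around per-subject
empirical-Bayes modes. The inner problem is solved as a least-squares
problem on the stacked residual vector `[(log y − log f)/σ ; η/ω]` with
Levenberg–Marquardt; the Hessian of the joint density is approximated by
the Gauss–Newton form `JᵀJ` from the inner Jacobian. Two numerical
details matter in practice:

* the finite-difference step of the inner Jacobian (1e-4 relative) must
  sit well above the integrator's relative tolerance, otherwise the
  Jacobian is dominated by solver jitter and the inner optimizer stalls
  on spurious modes;
* the joint η-density can be multimodal, so final evaluations and
  curvature computations restart each inner optimization from the prior
  mode as well as the warm start (`dual_start`).

Subjects with non-finite predictions contribute a large penalty rather
than NaN, and are reported by warning. The outer optimization (Powell,
then a short Nelder–Mead polish that descends the shallow ridge Powell
tends to stall on) runs on log-transformed parameters. The asymptotic
covariance comes from a central-difference Hessian with step 0.1 on the
log scale — deliberately wide, because the Laplace surface carries
small-scale roughness from the inner optimizations — with non-positive
information directions floored at unit log-scale variance.

On sparse designs (three samples per subject) the Laplace approximation
is visibly anticonservative: a χ²(1) calibration experiment (freeing an
unnecessary parameter on null data) holds at the nominal rate on the rich
adult design but inflates on the sparse pediatric one. The calibration
test therefore runs in the data-rich regime and the limitation is stated
here rather than hidden.

### SIR and VPC

Parameter uncertainty uses sampling importance resampling: a
multivariate-normal proposal on the log parameters centered at the
estimate with the fit covariance, proper importance weights (likelihood
ratio divided by proposal density — the proposal correction is required
for the conjugate-Gaussian oracle test to hold), and resampling without
replacement. The resample fraction should stay well below one, since
without-replacement resampling flattens the represented posterior as the
fraction grows; defaults are 1000 samples / 500 resamples, and an
effective-sample-size warning fires below 5%. Visual predictive checks
simulate replicate datasets under the observed design (same covariates,
doses and sampling times; fresh random effects and residuals; the same
BLQ discard rule) and report 5th/50th/95th percentile bands with 95% CIs
per time bin, stratified by observation type and age group.

## Synthetic studies

The generator emulates the two source designs:

* **Adult study** — 30 dexamethasone-suppressed adults, weights
  N(75, 10²) kg truncated to [55, 100], single doses cycling the ladder
  0.5/1/2/5/10/15/20 mg, 12 plasma samples over 12 h, suppressed baseline
  15.2 nmol/L with its own variability. No DBS, no LLOQ censoring in
  practice (all concentrations stay quantifiable without residual noise).
* **Pediatric study** — 12 young children (2–6 y), 6 infants (28 d–2 y),
  6 term neonates (0–28 d) on their regular morning dose; paired
  plasma+DBS samples pre-dose and at 1 and 4 h; children additionally get
  two samples at 0.5–1.5 h and a 6 h trough-side sample (the stated
  "30–90 h" extra-sample window is treated as a typo for minutes, since
  cortisol's 1–2 h half-life makes extra samples beyond 30 h vacuous).
  This yields 108 paired observations (the source had 106). Weight-for-age
  uses coarse bands (neonates 2.5–4.5 kg, infants 4–11 kg, children
  10–22 kg) with log-normal noise — statistical structure for testing,
  not growth charts. Dose is deterministic given the weight band, with
  neonates receiving the highest dose per kg (3–4 mg, ≈1 mg/kg), which is
  what produces the high neonatal concentrations; BLQ flags are applied
  at the two LLOQs.

At the published parameters the generated pediatric study reproduces the
qualitative censoring structure of the source data: plasma BLQ ≈ 17%
(source 17.9%), DBS BLQ far lower (≈6% vs 0.94%), DBS concentrations
above 200 nmol/L only in neonates. The generator writes a truth record
(population parameters plus every realized individual parameter) so that
estimation can be scored against known truth.

* **Recovery design** — the parameter-recovery experiment uses a pooled
  design (20 adults with the full dose ladder plus 15 children/infants
  and 15 neonates with 12 paired samples over 12 h), mirroring the pooled
  estimation dataset of the source model. The adult arm is load-bearing:
  with only single-dose-level pediatric data, a finite-sample shift in
  the bioavailability random effects is nearly indistinguishable from a
  shift in the volumes, and conditional CIs on the volume terms become
  overconfident against the super-population truth. The wide adult dose
  range spans the Michaelis–Menten nonlinearity and pins that scale.

The default fit model places random effects on CL, Vmax, F and V_delta
and estimates θ{CL, V_c, Vmax, V_delta×2}, ω{CL, Vmax, F, V_delta} and σ
(10 parameters). Km variability is present in the generator but omitted
from the fit model — a deliberate, realistic misspecification. Its
signature is stable: the fitted ω_Vmax absorbs part of the Km spread and
σ inflates by ~10%, so the SIR CIs for those two parameters sit high;
the remaining eight parameters are recovered with CI coverage. CL is
recovered within ~7% and the children:neonate V_delta ratio within ~15%
at the default seed.

## What passing tests do and do not show

The synthetic generator shares its structural and stochastic model with
the estimator, so parameter recovery demonstrates the correctness and
calibration of the machinery, not the adequacy of the model for real
children — the source analysis's clinical datasets are not deposited, and
observed-data quantities (ratio medians 5.17/2.41, the exact BLQ rates,
covariate dOFV) are reproduced only at the level of direction and
structure. Real data would additionally carry capillary-vs-venous
differences, hematocrit variation, assay error structure and circadian
endogenous secretion, none of which are modeled.

## Known limitations

* The RBC association mechanism is a phenomenological linear coupling;
  the published constant 6.62 is stored but not operative.
* The low-concentration RBC fractions of the published curves cannot be
  matched by any single linear coupling (see above).
* Laplace inference degrades on very sparse designs; expect
  anticonservative model-comparison statistics there.
* BLQ handling is discard-only (M1); censored likelihood (M3) is out of
  scope.
* Estimation assumes one dose at t = 0 per subject (the designs used
  here); the simulator itself supports multiple doses.
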