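# Methods

## Model

The package models the cascade by which a single intraperitoneal bolus of
bacterial endotoxin (LPS, 0.8 mg/kg) drives depressive-like behavior in
mice, and how a single intragastric dose of azithromycin (AZI, 100 mg/kg,
given 20 minutes before the challenge) blunts it.

**Pharmacokinetics.** Both compounds follow one-compartment kinetics with
first-order absorption, parameterized by the absorption rate `ka` (1/h),
the elimination rate `ke` (1/h) and an apparent volume `V/F` (L/kg).  The
closed-form plasma concentration after an extravascular bolus `D` (mg/kg)
is

    C(t) = D / (V/F) * ka / (ka - ke) * (exp(-ke t) - exp(-ka t)).

LPS mass is translated into endotoxin activity at 3.4 Eu per ng.  The
`ka = ke` degeneracy is rejected with an explicit error rather than
switched silently to the `t exp(-kt)` limiting form: fitting bounds keep
the rates apart, and a silent branch change inside an optimizer loop is a
debugging hazard.  `ka <= ke` triggers a flip-flop warning because the
terminal slope then measures absorption, not elimination.

**Pharmacodynamics.** Four turnover (indirect-response) variables — total
proinflammatory cytokines PCs (pg/ml), kynurenine KYN (ng/ml), and the
immobility times of the forced-swimming and tail-suspension tests FST/TST
(s) — each obey zero-order production `kin = kout * R0` and first-order
loss `kout`, with one transit compartment on the production side per
transduction step:

    dT/dt = kin * driver(t) - ktr * T
    dR/dt = ktr * T        - kout * R

Cytokine production is driven by a Hill-1 stimulation of LPS
(`1 + Smax C/(SC50 + C)`) and a Hill-1 inhibition by AZI
(`1 - Imax C/(IC50 + C)`); KYN production by a linear function of the
cytokine excursion (`1 + slope (PCs - PCs0)`, floored at 0), and each
behavioral score by a linear function of the KYN excursion.  Anchoring the
linear drivers at the upstream *baseline* (rather than at zero) makes
`kin = kout * R0` exact, so the drug-free system is stationary by
construction — no rescaling of production rates is needed.

**Combining stimulation and inhibition.** Two scopes are implemented.  The
default, `stimulated_only`, multiplies only the LPS-stimulated production
increment by the AZI inhibition, `1 + (S - 1) * I`: an AZI-only arm then
sits exactly at baseline, matching the observation that AZI alone is
indistinguishable from vehicle control.  The `classical` scope multiplies
total production (`S * I`), under which AZI alone would depress cytokines
below baseline; it is kept as a configuration option because the
literature uses both forms.

**State vector.** Twelve states: absorption/central amounts for AZI and
LPS (mg/kg), and a transit/response pair for each of PCs, KYN, FST, TST.
A transit compartment is attached to the behavioral endpoints as well as
to the biomarkers: without it the behavioral peak cannot lag the KYN peak
by the observed ~12 h, because a bare indirect response tracks its driver
with a lag of order `1/kout` (~4 h here).

## Simulation

Dose events are bolus additions to the absorption compartments; the
integrator (LSODA, relative tolerance 1e-8, absolute 1e-10) is restarted at
each event.  Integration begins at the earliest dose (-1/3 h when AZI is
present, t = 0 at the LPS injection).  States are clipped at zero only
when evaluating drivers, never in the state vector, and a state below
-1e-6 aborts with a simulation error.  Reported peaks are refined by a
three-point quadratic through the grid maximum so they do not depend on
grid resolution (halving the step moves the cytokine peak by < 0.1%).
During likelihood evaluation the tolerances are relaxed to 1e-6/1e-9
(1e-8/1e-11 for noise-free recovery work, where finite-difference
gradients must resolve sub-percent effects).

## Calibration of the unpublished constants

The published tables fix the baselines, loss rates, and the four sigmoid
constants, but not the transit rates `ktr` nor the three linear slopes.
These are recovered against the printed disease-progression landmarks of
the LPS arm — cytokines peaking at 3 h (1055 pg/ml), KYN at 12 h
(649 ng/ml), behavior at 24 h — by nested one-dimensional searches that
exploit the cascade's triangular structure: downstream peak *times* are
invariant to the linear slopes (excursions scale exactly linearly), so
each `ktr` is tuned to its peak-time target at unit slope, after which
each slope is solved in closed form from the unit-slope excursion.

Two landmarks are structurally out of reach of the published parameter
set, and the calibrator reports this rather than hiding it.  The LPS
terminal half-life (8.45 h) keeps the stimulation high for over a day,
and a production-side envelope bounds the cytokine response by
`PCs0 * (1 + Smax * Cmax/(SC50 + Cmax)) ~ 840 pg/ml`; transit compartments
can only delay a peak, never advance it.  The best attainable cytokine
peak is therefore ~650 pg/ml at ~9.5 h (not 1055 pg/ml at 3 h), and the
KYN peak lands at ~17 h (not 12 h).  In strict mode the calibration raises
an error naming the binding constraint; in best-effort mode it returns the
nearest attainable system, which preserves every qualitative landmark:
the peak ordering PCs < KYN < FST/TST and the attenuation of the cytokine
peak under AZI (here ~22%, direction matching the printed 1055 → 762
pg/ml).  The best-effort set is the generator's ground truth.

Behavioral peak magnitudes are not tabulated; the calibration targets are
set once at FST 170 s (baseline 51.3 s) and TST 230 s (baseline 108.2 s) —
a roughly three-fold/two-fold rise consistent with a strong sickness
response while staying below the 300-s scoring window of either test.

## Synthetic studies

`StudyDesign` encodes the study structure: four arms (control, LPS,
AZI+LPS, AZI alone), destructive sampling with 8 animals per time point,
and per-analyte schedules (PK/biomarkers at 0, 0.5, 1, 2, 3, 4, 6, 8, 12,
24, 36, 48 h; behavior at 0, 2, 6, 12, 24, 36, 48 h — the published
sampling times are not enumerated, so this schedule is a documented
assumption).  Arms use condition-matched PK (the AZI+LPS arm uses the
LPS-challenged AZI kinetics and the AZI-treated LPS kinetics).  Noise is
mean-preserving lognormal at a 10% coefficient of variation by default
(assay CVs are stated as < 10%); a zero-truncated normal law is available
for additive-floor assays.  Each animal is an independent draw around the
typical trajectory.

What the generator does *not* emulate: between-animal biological
variability (every animal shares the typical parameters), assay
quantification limits, circadian structure, or correlations between
analytes within an animal.  Passing recovery tests therefore demonstrate
estimator correctness under the assumed error model, not robustness to
real-data pathologies; in particular the bootstrap CVs obtained here
(roughly 3-15%) are smaller than the published parameter CVs (31-43%),
which fold in biological heterogeneity the generator deliberately omits.

## Estimation

Fitting is staged: each PK submodel is fitted from its arm's data using
the closed form, then frozen; the cascade parameters are estimated from
the fully coupled ODE model.  All animals are pooled naively — every
observation is an independent Gaussian draw around the typical-trajectory
prediction.  The default error model is proportional per analyte
(`sd = sigma * prediction`, profiled analytically), which weights small
concentrations more heavily, with an additive option.  A residual-SD
floor of 0.1% keeps the profiled likelihood smooth on noise-free data.
Rows where both observation and prediction are exactly zero (pre-dose
samples of the dosed compound) carry no information and are dropped.

Optimization is bounded L-BFGS-B in log10-parameter space with
multi-start (default 8 starts: the initial values, then log-uniform draws
within bounds).  PK initial values come from NCA: the terminal slope
seeds `ke`, AUC(0-inf) seeds `V/F`, and Tmax is inverted for `ka`.  The
finite-difference step (1e-5 in log10 space) is held well above the ODE
integration noise.  A failed simulation returns a large penalty so the
search continues.  The objective is reported as -2 log L and
`AIC = -2 log L + 2k` with `k` the number of free structural parameters
(profiled error SDs are not counted; the convention is stated so AIC
comparisons are made within this package only).

Bootstrap uncertainty resamples animals with replacement within each
(arm, analyte, time) cell — the destructive-sampling analogue of
resampling subjects — and refits each replicate warm-started from the
point estimate with a capped function-evaluation budget (200 evaluations;
warm-started replicates converge well within it).  CV% is
`100 * sd / mean` over converged replicates; replicates that fail are
dropped and counted, with a warning above 20%.

## Non-compartmental analysis

Linear trapezoidal AUC (a log-linear-down variant was considered and left
out: on these dense simulated grids the difference is far below the 0.5%
checks the suite applies).  The terminal window defaults to the last four
positive post-peak points and expands up to eight, keeping the window
with the best log-linear R²; R² < 0.8 flags the fit.  AUC(0-inf) adds
`C_last / lambda_z`.

## Problem sizes used by the checks

The shipped acceptance checks run the full pipeline at the study's own
dimensions: 8 animals per time point, 12/7-point schedules, 20 replicate
studies for the noisy-recovery experiment, and 50 bootstrap replicates.
Noise-free recovery uses a single study and tight ODE tolerances.

## Known limitations

- The published equations themselves are not recoverable from the source
  (typeset as images); the structure implemented here is the standard
  reconstruction the text describes, and the calibration section above
  quantifies where that reconstruction cannot reproduce the printed
  landmarks with the printed parameters.
- Naive pooling only; no mixed-effects machinery, no profile-likelihood
  intervals beyond the bootstrap.
- Single-dose regimens only.
- No brain compartment: behavior is linked to plasma kynurenine.
- The published AIC (22.31) and observed AUC/Cmax summaries depend on the
  raw animal data and the legacy estimation software's objective
  convention, and are not reproduction targets.
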