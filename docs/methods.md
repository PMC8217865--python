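# Methods

## The kinetic model

Glucose disappearance after an intravenous bolus is described by the
single-compartment minimal model with a remote insulin-action compartment,
driven by measured insulin as a forcing function:

    dG/dt = −(p1 + X(t))·G(t) + p1·G_b        G(0) = G0
    dX/dt = −p2·X(t) + p3·(I(t) − I_b)        X(0) = 0

G is blood glucose (mmol/l), X insulin action (min⁻¹), I(t) plasma insulin
(pmol/l). Glucose effectiveness S_G ≡ p1 is the fractional disposal rate at
basal insulin; the insulin sensitivity index S_I ≡ p3/p2 measures how much
circulating insulin accelerates disposal. G0 is the modelled glucose at t =
0⁺ after instantaneous distribution of the bolus; the measured t = 0 sample
is the pre-injection baseline (G_b, I_b) and never enters the residual.

The model assumes a single well-mixed glucose pool, linear insulin action
through a remote compartment, and instantaneous bolus distribution. These
are the standard assumptions under which S_G and S_I are defined for bolus
tests; they are approximations at early times (mixing) and at high insulin
(receptor saturation).

### Insulin forcing

I(t) is the piecewise-linear interpolant of the sampled insulin values,
held constant past the last sample. At six samples this is the only
representation the data support; any estimate of S_I inherits its
interpolation error.

### Simulation

`simulate_minimal_model` integrates the two ODEs with an adaptive solver
(LSODA, rtol 1e-8, atol 1e-10), restarting at every forcing knot so the
solver never steps across a derivative discontinuity. Inside the optimiser
a fast fixed-grid kernel is used instead: X(t) has an exact closed-form
update on every sub-step of a piecewise-linear forcing segment, and the
scalar glucose equation is advanced with classical RK4 at Δt = 0.05 min.
The kernel agrees with the adaptive reference to better than 1e-6 relative
(tested) and falls back to the reference whenever sample times are not
commensurate with the grid.

## Fitting

The fit minimises the relative residual Σ_{t ≥ 1 min} [(G_model −
G_obs)/G_obs]² — constant-CV weighting, matching a proportional assay error
model — over the box

    p1 ∈ [1e-4, 0.3] min⁻¹,  p2 ∈ [1e-3, 1] min⁻¹,
    p3 ∈ [0, 1e-3] min⁻² per pmol/l,  G0 ∈ [G_b, 40] mmol/l,

from a deterministic 16-point multi-start grid (no randomness anywhere: the
same curve always yields bit-identical estimates). The lowest weighted SSR
wins; ties break toward smaller p3. Any estimate within 1e-6 of a bound is
reported in `at_bound`.

### Identifiability at six samples, and why p2 is fixed by default

Five post-injection residuals cannot support four free parameters. With p2
free, 2 % glucose noise collapses the global minimum to p1 ≈ 0 (insulin
action absorbing the whole decay) in roughly one fit in five — verified by
restarting the optimiser at the true parameters, which converges to the
same degenerate minimum — and the p3 ≥ 0 constraint makes the remaining
errors one-sided, biasing mean S_G low by ~20 %. The default therefore
holds the remote-insulin decay rate at a population value, p2 = 0.05 min⁻¹,
the standard sparse-sampling practice, and estimates (p1, p3, G0);
`fix_p2=None` restores the free 4-parameter fit. On noise-free data both
modes recover (S_G, S_I, G0) to better than 1 % across the S_G span
0.003–0.065 min⁻¹ (tested); p2 recovery is never asserted.

Two further safeguards:

* a fit whose p1 is pinned at a bound (or p3 at its upper bound) is
  reported but **rejected** as an estimate — the per-animal summary records
  the reason instead of a number (≈3 % of noisy fits);
* when the suprabasal insulin AUC is below 50 pmol/l·min (flat insulin, as
  after complete secretion blockade) the fit succeeds but S_I is flagged
  low-identifiability — there is no dynamic signal to identify it from.

## Model-free metrics

* **K_G** = −100 × OLS slope of ln(G) vs t over the closed window [5, 20]
  min (%/min). The window deliberately excludes the 1-min mixing peak. Unit
  changes of glucose shift ln(G) by a constant and cancel in the slope.
* **Suprabasal AUC**: trapezoid integral of (value − value at t = 0) up to
  the last sample ≤ 50 min. The single pre-injection sample is the
  baseline; negative values (insulin under diazoxide) are meaningful.
* **Beta-cell glucose sensitivity** = suprabasal AUC_insulin (nmol/l·min) /
  suprabasal AUC_glucose (mmol/l·min), computed per animal and averaged —
  group SEMs presuppose per-animal values, so the ratio of group means is
  never used.

## Group statistics

Mean ± SEM (SD with n−1 denominator over √n) per group; classical
equal-variance unpaired Student's *t*-test, two-sided (a Welch switch
exists, default off). Insulin-level metrics are compared after natural-log
transformation, but only when every value in both groups is positive;
otherwise the untransformed test is used and the row flagged — suprabasal
insulin AUCs under diazoxide are negative and cannot be logged. The log
base only rescales both groups and cancels in t. No multiple-testing
correction is applied; each row carries its own P.

## The synthetic cohort generator

The generator emulates the study design: 6-point schedule (0, 1, 5, 10, 20,
50 min), four groups per profile. Per animal it draws G_b, I_b, S_G, S_I,
ΔG0 = G0 − G_b, p2 and an insulin-response parameter from mean-preserving
log-normals, builds the insulin curve, simulates glucose with the minimal
model, and observes both with multiplicative log-normal assay noise
(glucose CV 2 % — typical strip-glucometer precision, not reported with the
assays — insulin CV 4 %, optional censoring at the 6 pmol/l LLOQ).

* **Vehicle insulin**: first-phase pulse I(t) = I_b + A·(t/t_p)·e^(1−t/t_p),
  peaking at I_b + A at t_p = 1 min. A is calibrated so the continuous
  suprabasal AUC over 0–50 min equals the group's target AUC (closed form
  A·e·t_p, verified against quadrature).
* **Diazoxide insulin**: monotone decline I(t) = I_b·[1 − d·(1 −
  e^(−t/τ))], τ = 10 min, d calibrated to the (negative) target AUC.
  Diazoxide's raised glucose baseline is a distinct G_b mean per profile,
  not a pharmacokinetic model.
* **Observation model**: glucose is driven by the piecewise-linear
  interpolant of the *sampled* insulin values — the same forcing
  representation the fitting stage reconstructs — so noise-free cohorts are
  exactly fittable and parameter recovery isolates estimator error from
  interpolation bias. Real continuous secretion would add a forcing
  mismatch of order 5–10 % in S_G at this schedule; passing recovery tests
  therefore bound estimator error, not that mismatch.

Group means come from the published tables; between-animal CVs are
back-solved from the published SEMs at the published n (CV = SEM·√n/mean),
giving dispersions of the reported magnitude without claiming to split
biological from assay variance. Two published cells are unusable as
calibration targets and were replaced by the package's own defaults: the
GIP-KO vehicle suprabasal insulin AUC (magnitude inconsistent with its SEM
and neighbours; set to 1.00 ± 0.20 nmol/l·min) and the GLP-1R-KO vehicle
value (negative, unreachable by a non-negative pulse; set to +0.30 ± 0.05
nmol/l·min, preserving the blunted-response ordering). One diazoxide
wildtype S_G SEM printed larger than its mean was replaced by 0.003 for CV
back-solving. ΔG0 defaults to 12 mmol/l (CV 15 %), giving physiological
~20 mmol/l 1-min peaks; peak glucose is not published.

The emergent K_G of vehicle cohorts (~2.8 %/min wildtype) runs somewhat
above the published ~1.7 %/min: K_G is not a generator input, and its value
follows from the chosen ΔG0 and pulse shape.

## Problem sizes and numerical choices

Stochastic recovery checks use 200 animals per group (4 groups), comparing
mean fitted S_G with the mean of the S_G values that actually generated the
cohort — at CVs up to 0.67 the drawn mean itself wanders ~5 % from the
nominal mean at n = 200, so comparing to nominal would measure sampling
noise, not the estimator. Measured worst-group error is ~2 %. Noise
robustness of a single configuration uses 200 replicates (median within
15 %). Optimiser tolerances are 1e-12 (ftol/xtol/gtol) with x-scales
matched to parameter magnitudes; the type-I-error check uses 1000 null
pairs at n = 10–11 per group.

## Known limitations

* S_I from six samples is noisy and, in diazoxide-style data, unidentified;
  it is flagged rather than suppressed. Group S_I tables should be read
  with the flags.
* The generator's insulin curves are shape inventions constrained only by
  peak time and AUC; per-animal insulin kinetics are not modelled.
* The equal-variance t-test is used even where group variances differ
  (matching the analysis being reproduced); the Welch option exists.
* No mixed-effects or Bayesian population fitting; every animal is fitted
  independently.
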