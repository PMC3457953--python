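# Methods

## The model

`mtxhcy` implements a population pharmacokinetic/pharmacodynamic model of
high-dose methotrexate (HDMTX) and plasma homocysteine (HCY) in paediatric
acute lymphoblastic leukaemia, together with the trial-simulation and
estimation machinery needed to study it.

### Methotrexate disposition

MTX plasma concentration follows a linear two-compartment model with
central volume `V1`, peripheral volume `V2`, total clearance `CL` and
intercompartmental clearance `Q`. Because the model is linear, any dosing
history (boluses and constant-rate infusions) is evaluated by analytic
superposition of the closed-form single-event responses
(`mtxhcy.pk.mtx_concentration`); an LSODA-based integrator of the same
system (`mtx_concentration_ode`) is kept as an independent cross-check and
agrees with the analytic path to solver tolerance. Doses in mg convert to
µM through the MTX molar mass, fixed at 454.44 g/mol.

All four structural parameters scale linearly with body surface area
(BSA). Clearance additionally carries a renal-function covariate: a power
model on serum creatinine normalised by an age/sex reference value,

    CL = theta_cl * BSA * (SCR / C_CR,adj)^(-theta_cr) * exp(eta_CL + kappa_CL),

so above-reference creatinine lowers clearance. The reference table
`C_CR,adj(age, sex)` is a piecewise-constant maturation profile (shared by
both sexes below 13 years, sex-specific above); it is a configurable
plumbing default whose absolute level only anchors the covariate ratio.

### Homocysteine turnover

HCY follows an indirect-response (turnover) model

    dC_HCY/dt = k_in - k_out * I(C_MTX(t)) * C_HCY,
    I(c) = 1 - Emax * c / (EC50 + c),

in which MTX inhibits the elimination rate constant. At the protocol
steady-state targets the inhibition is nearly complete: `I` evaluates to
1.93% of baseline at 33 µM and 0.99% at 65 µM (Emax = 1,
EC50 = 0.648 µM). The baseline is the pre-treatment steady state, so
`k_in = k_out * BL` identically; `BL` increases linearly with age
(`theta_bl_age`, µM/year), centred at the cohort median age of 5.42 years
so that `theta_bl` is the typical value for the median patient. Emax is
fixed at 1 by default (it is not identifiable from sparse samples taken
while HCY is still rising; freeing it drives the estimate to 1) but can be
unfixed via `estimate_emax`.

Folinate rescue is modelled as a complete, immediate reversal of the MTX
effect: inside each rescue window the turnover runs with the uninhibited
`k_out`. Folinate has no kinetics of its own; dose rows are bookkeeping.

Two integrators serve different purposes. `simulate_hcy` wraps LSODA with
tight tolerances (rtol 1e-9) and restarts at rescue-window edges; it is the
reference path. `hcy_trajectory_grid` advances the linear ODE exactly on
each grid step with the inhibition factor frozen at the interval midpoint —
second-order accurate, exact at steady state, and vectorised across
patients. On the 0.1-h grids used for simulation studies the two agree to
well under 0.5%; the estimation layer uses the stepper on a locally
refined grid — 0.05-h steps around the infusion kinks, 0.25 h elsewhere —
which is more accurate than a uniform 0.1-h grid at ~60% of the points
(relative error ~1e-4 at the sparse sampling times).

### Stochastic model

Interindividual variability (IIV) acts as independent log-normal factors
`exp(eta)` on CL, V1, Q (PK) and BL, k_out, EC50 (PD); interoccasion
variability (IOV) adds an independent log-normal factor per treatment
course on CL and BL. Occasion 1 is the window administration, occasions
2–5 the biweekly consolidation courses. Reported variability percentages
are %CV of the log-normal factor, `CV% = 100*sqrt(exp(omega^2)-1)`.

Residual error is exponential for MTX (`y = f*exp(eps)`) and combined
exponential + additive for HCY (`y = f*exp(eps1) + eps2`); the additive
term (0.911 µM at the reference configuration) dominates near baseline.
Simulated HCY observations are not truncated at zero.

The shipped reference parameter set (`PKParameters()` / `PDParameters()`
defaults) is the configuration every simulation and recovery experiment in
this package is run against.

## Synthetic trials

`sample_population` draws virtual patients with the demography of a large
paediatric ALL front-line study: log-normal ages truncated to
[1.03, 18.85] years with median ≈ 5.4; 55% boys; 53% low-risk; height and
weight from median growth-curve tables with log-normal noise; BSA by
Mosteller; serum creatinine scattered log-normally (20% CV) around the
age/sex reference and clipped to [0.1, 1.2] mg/dL. Risk group is drawn
independently of age — the real risk classification partly depends on age,
which is one reason the simulated standard/high-risk stratum runs slightly
younger (hence lower-baseline) than its clinical counterpart.

`generate_trial` then applies the protocol: a randomised window course
(4-h 1 g/m², or 200 mg/m² bolus + 800 mg/m²/24 h), followed by four
consolidation courses individualised to a target steady-state
concentration of 33 µM (low-risk) or 65 µM (standard/high-risk). The
individualised total dose is `Cpss * CL_est * 24 h` (µmol → mg), given as
10% over 1 h plus 90% over the following 23 h; `CL_est` is the clearance
the subject actually realised on the previous occasion — the protocol's
Bayesian dose-estimation step is approximated as error-free, which
preserves the targeting behaviour while keeping the generator free of an
estimation dependency. Because the maintenance infusion carries 90% of the
24-h total over 23 h, its plateau sits at 93.9% of the nominal target;
the 23-h sample therefore reads a few percent below the target even
without variability.

Sampling is sparse per protocol: MTX at 4/24/42 h (window) and 6/23/42 h
(consolidation); HCY pre-dose/23/42 h in the first two consolidation
courses only. Folinate starts at 44 h in the window phase (50 mg/m² + 7 ×
15 mg/m² q6h) and 42 h in consolidation (5 doses q6h; 10 mg/m² LR,
15 mg/m² SHR). The rescue window closes one dosing interval (6 h) after
the last dose. Datasets are emitted in a NONMEM-style rectangular CSV
(`mtxhcy.dataset`), with missing DV written as ".".

What the generator does **not** emulate: assay quantification limits and
censoring, dropout and missed samples, deviations from nominal sampling
times, dose-estimation error in the individualisation step, non-MTX
chemotherapy, and any genetic covariates. Tests passing on these synthetic
trials therefore demonstrate internal consistency of model, simulator and
estimator under the stated design — not robustness to those real-data
features.

## Estimation

The nonlinear mixed-effects estimator (`mtxhcy.estimation`) approximates
each subject's marginal likelihood by a Laplace expansion at the empirical
Bayes mode of the subject's random effects, with the Hessian in
Gauss-Newton form — the FOCE-style linearisation of the residual model at
the individual prediction. The normative contract is oracle equivalence:
for any linear-Gaussian mixed model the OFV equals the exact
-2 log-likelihood (2π constants included), which the test suite asserts to
1e-6; on a one-dimensional nonlinear problem it matches adaptive
quadrature to 0.1 OFV units.

The inner problem is solved by a damped Gauss-Newton iteration, batched
across all subjects simultaneously (finite-difference Jacobians are pushed
through a single stacked vectorised prediction call). The PK exponential
residual is handled exactly by estimating on the log scale; the PD
combined error enters through the first-order variance
`f^2 sigma_exp^2 + sigma_add^2`. Because that variance follows the
prediction, the inner gradient carries the corresponding log-variance and
weighting terms — stopping instead at the naive reweighted-least-squares
fixed point displaces the modes and was observed to bias EC50 upward by
tens of percent. Random effects with zero prior variance are pinned at 0
and excluded from the expansion.

The outer problem maximises the Laplace likelihood over fixed effects,
variances and residual parameters with positivity enforced by log
transforms (logit for Emax). The optimiser is Nelder-Mead with an explicit
initial simplex (absolute coordinate steps, so parameters starting at
0 on the transformed scale still move), followed by a restart from the
incumbent with a tightened simplex — in ≥10 dimensions the restart
recovers from degenerate simplex geometry far more cheaply than one long
run. Starting values are method-of-moments where the data offer one
(clearance from infusion rate over the 23-h concentration; baseline HCY
from the pre-dose median), generic round numbers otherwise. The
sequential PD fit runs in stages: structural + residual parameters with
variances held, then the full fit multi-started on a log-spaced EC50 grid
around the stage-1 value (lowest OFV wins), then a polish — EC50's curved,
nearly flat likelihood valley couples with k_out and the variance terms
and defeats a single simplex run. EC50 is the weakest-identified parameter (its
information comes almost entirely from the 42-h samples where MTX is near
EC50); finite-sample maximum-likelihood estimates of EC50 scatter by tens
of percent at these designs, which is why the recovery checks give it a
35% band.

The PD model is fitted sequentially: individual PK parameters are fixed at
their empirical Bayes estimates and each subject's MTX forcing profile is
computed from them. Covariate selection on clearance follows
forward-inclusion (ΔOFV ≥ 3.84, χ²₁ at p<0.05) and backward-deletion
(retention requires a ≥ 7.88 increase, p ≤ 0.005). The age effect on the
HCY baseline is part of the structural PD model (`theta_bl_age`) rather
than the stepwise search, which covers the clearance covariates
(creatinine, age, sex).

## Evaluation

The bootstrap resamples subjects with replacement, refits, and reports
percentile 90% confidence intervals; failed replicates are counted and
excluded (a warning fires above 20%). The VPC simulates every observation
under the model (new IIV/IOV draws and residual error at the observed
design), then tabulates the simulated median and 5th/95th percentiles per
stratum and nominal sampling time — the sparse design makes time-binning
unnecessary. PK VPCs stratify by dose stratum (window arm / consolidation
target via risk group); HCY VPCs are computed on the change from the
course pre-dose value (a ratio transform is available via
`transform="ratio"`) and stratified by risk group. Pooled-bin bands are
mixture bands: they cover ~90% of observations on average, which is the
calibration property the tests check.

## The rescue simulation study

`run_rescue_study` simulates 1000 virtual patients per risk group (both
arms of each patient share the same random effects): a consolidation
course individualised on a clearance realised on a separate prior
occasion, HCY integrated on a 0.1-h grid over 0–168 h twice — once with
the inhibition model throughout, once switching to uninhibited turnover
inside the rescue window (42–72 h, extended while MTX ≥ 0.1 µM for
patients above 1.0 µM at 42 h, mirroring the protocol's escalation rule).
Per-patient metrics are computed on the noiseless trajectories: peak HCY
(C_max) and its time relative to the end of the 24-h infusion (t_max), the
trapezoidal AUC of HCY above the individual baseline over the full window,
and the HCY level at the close of rescue (72 h). Arms are compared by the
two-sided Wilcoxon rank-sum test (exact enumeration for min(n,m) ≤ 12
without ties, otherwise the tie- and continuity-corrected normal
approximation).

The 168-h horizon is effectively infinite for this metric: the excess AUC
of a typical low-risk course saturates near 314 µM·h (the excess remaining
at 168 h is < 0.25 µM), so lengthening the window changes nothing.
Absolute AUC levels are reported as computed; the percent reduction under
folinate and the peak statistics are the quantities this study is designed
to reproduce.

## Numerical choices and scaled-down defaults

- HCY grids: 0.1 h (simulation studies); locally refined (0.05 h near
  kinks, 0.25 h elsewhere) for estimation; midpoint exponential stepping,
  validated against LSODA.
- Inner Gauss-Newton: forward-difference Jacobians (step 1e-5), per-subject
  backtracking, convergence on objective decrease < 1e-10·(1+|obj|).
- Outer Nelder-Mead: `maxfev` 1200 by default plus a half-budget restart;
  ties between restarts break by lowest OFV. Library-scale fits in the
  test suite use 35–150 subjects with reduced `maxfev`; the acceptance
  script uses the protocol-sized 150-subject trial.
- Default evaluation sizes are scaled down (bootstrap 200 replicates, VPC
  1000 PK / 200 PD simulations) and configurable upward.
- Bootstrap/VPC/rescue all take explicit seeds; equal seeds reproduce
  results bit for bit.

## Known limitations

- EC50 (and with it k_out) is weakly identified by the sparse design; its
  estimate can sit tens of percent from the simulating value on a single
  trial even at the full-likelihood optimum.
- The Laplace/Gauss-Newton OFV is an approximation for the nonlinear
  model; its exactness is guaranteed (and tested) only in the
  linear-Gaussian limit.
- Pooled VPC bands mix subjects within a stratum; they are calibrated on
  average, not per patient.
- The rescue study samples new patients from the population model rather
  than re-using empirical Bayes estimates of real patients, and computes
  metrics on noiseless trajectories; prediction intervals therefore
  reflect population variability only, without parameter or assay
  uncertainty.
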