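# Methods

## Model and targets

For subject *i* let `T_i1 < T_i2 < ...` be recurrent-event times, `T_i^D`
the terminal-event time (∞ when death is not considered) and `C_i` an
independent censoring time. A subject is *at risk* at a landmark time *s*
when `min(T_i^D, C_i) > s` (strict). For an at-risk subject the recurrent
clock restarts: `T*_k` is the k-th event strictly after *s*, and the
prediction targets over the window `(s, s+w]` are the mutually exclusive
category probabilities

* `F_k(s+w|s)` — exactly k events in the window and survival past `s+w`,
  for `k = 0, ..., k_max` with the top category pooling counts `>= k_max`;
* `F_D(s+w|s)` — death by `s+w`.

Assumptions: subjects are i.i.d.; censoring is independent of event and
death times and of covariates (non-informative); the censoring survival
function remains positive beyond `s+w`. A diagnostic for the last
assumption is the fraction of the landmark risk set still under observation
at `s+w`; the heavy-censoring simulation scenarios (censoring hazard 2 with
a one-year window) approach its practical limit.

## Estimators

**Ordered-event KM.** `F_k = S*_{k+1}(s+w) − S*_k(s+w)` where `S*_k` is the
Kaplan–Meier curve of `T*_k − s`; a subject with fewer than k post-landmark
events is censored at `min(T^D, C) − s` (death counts as censoring on this
route). Crossing KM curves can make an interior `F_k` slightly negative
under heavy censoring; values are *not* clipped — pseudo-observations
tolerate out-of-range values and clipping would bias the regression — but a
warning is emitted.

**Multi-state AJ.** The forward chain `0 → 1 → ... → k_max`, with an
absorbing state D reachable from every transient state when the terminal
event is modelled. Occupation probabilities are the row-0 entries of the
product-integral `P(s, s+w) = Π (I + dA(u))` over jump times, with
Nelson–Aalen increments `dA_qr(u) = N_qr(u) / Y_q(u−)`. All transitions at
a tied time enter one factor, with risk sets taken just before the time;
a subject reaching the pooled top state stays at risk only for the
transition to D. By the Datta–Satten result the product-integral estimates
state occupation without a Markov assumption (asserted exactly on
uncensored semi-Markov data in the tests; the implementation is also
validated against R `survival::survfit`'s multi-state estimator).

## Pseudo-observations

`theta_ik(s) = n_s·F_hat_k − (n_s−1)·F_hat_k^(−i)`. Leave-one-out estimates
are honest re-estimations — every deletion replica uses its own transition
and risk-set counts — evaluated for all replicas in one vectorised pass;
equality with a literal delete-and-refit loop is asserted in the tests.
Useful identities, all tested: without censoring every theta is the
subject's 0/1 category indicator; rows sum to one (the zero-event column is
computed explicitly, making the row-sum check a genuine estimator
diagnostic); for the KM route the column means equal the full-sample
estimates exactly. For the multi-state AJ route that mean identity holds
only to O(1/n_s) — the mean of leave-one-out AJ estimates is not exactly
the full-sample estimate once the chain has more than one transition type.
The *dynamic predicted value* used throughout the evaluation harness is the
DPO column mean, which is the expectation the method reports.

## Regression

The DPO vector (reference category: zero events, excluded from the
parameters) enters a multinomial GEE with generalized-logit link. The
quasi-score `U(beta) = Σ D_iᵀ V_i⁻¹ (theta_i − mu_i(beta))` is solved by
Fisher scoring from `beta = 0` with step-halving; with the multinomial
working covariance `V = diag(mu) − mu muᵀ` the weight cancels against
`D = V Z*` and the iteration is IRLS for a multinomial logit with
continuous responses — the objective is concave, so non-convergence means
the maximum is at infinity (an empty category × covariate cell); this is
detected and raised as a named error rather than returning a boundary fit.
Convergence: max |U| < 1e-8 or relative parameter change < 1e-10, at most
100 iterations. Working probabilities are floored at 1e-10 before forming
`V`. A `working="binary"` option replaces `V⁻¹` by its diagonal (the
per-category binary workaround; identical fits for two categories and for
intercept-only models, similar point estimates otherwise).

* **Fixed-landmark model**: one landmark; covariance is the model-based
  inverse information.
* **Supermodel**: DPOs stacked over the landmark grid; coefficients vary as
  `beta(s) = f(s)·beta` with polynomial basis `1, s, ..., s^h` interacted
  with every covariate column of every category block; independence working
  structure across a subject's landmark blocks; covariance is the sandwich
  `A⁻¹BA⁻¹` clustered by subject. Landmark times are centered at the grid
  midpoint before powers are taken (cubic bases on raw multi-year grids are
  badly conditioned); `coef_table(scale="raw")` re-expands coefficients to
  raw powers of *s*.

Probabilities come from the inverse generalized logit with an overflow
max-shift; standard errors by the delta method; 95% Wald intervals on the
probability scale, truncated to [0, 1]. Prediction refuses to extrapolate
outside the fitted landmark range — polynomials are untrustworthy there.

Design conventions: an event at exactly *s* counts as a prior event, not a
window event; an endpoint at exactly *s* removes the subject from the risk
set; the prior event count is carried as a covariate (not a stratifier);
times are continuous and never binned.

## Simulator

Per subject a frailty `u` (1, or Gamma(shape 0.5, rate 0.5): mean 1,
variance 2) multiplies all hazards: first event `Exp(u·lambda01)`,
subsequent gaps `Exp(u·lambda02)`, latent death `Exp(u·lambda0D)`, censoring
`Exp(lambda_c)` independent of everything. The shared frailty makes any
pair of latent times equally dependent, with Kendall's tau
`Var(u)/(Var(u)+2) = 0.5` under the Gamma(0.5, 0.5) choice; the marginal
first-event time is then Lomax with survival `(1+2·lambda01·t)^(−1/2)`
(both asserted in tests). Events are capped at two by default — the design
whose published operating characteristics the evaluation reproduces — and
the cap is extensible so that higher-count code paths are exercised.
Note the structural consequence of a cap: under a cap of 2, a subject with
a prior event can never contribute to the "2+ further events" category at a
later landmark, which makes that regression cell empty (see above); the
application-shaped demo therefore simulates with a cap of 4.

Reproducibility: one `SeedSequence` child per replication, vectorised draws
in a fixed order within a replication; a scenario plus seed reproduces the
cohort exactly.

**True values** are paired per replication: the empirical category
proportions computed from the same cohort's latent (uncensored) times.
Closed-form limits (e.g. `e^{-1}`, `e^{-1}`, `1−2e^{-1}` for the
homogeneous rate-1 case, `e^{-1.3}` and `1−e^{-0.3}` with a rate-0.3
terminal hazard) serve as independent oracles in the tests.

## Evaluation harness

Per replication: simulate n = 100 subjects, compute the DPO matrix at
s = 0 with w = 1, take column means as the dynamic predicted values, and
difference against the paired truth. Reported per category: bias (mean of
predicted − true), RMSE, and Monte Carlo standard errors (for RMSE via the
delta method from the spread of squared errors), so scaled-down runs remain
interpretable. AJ and KM always share cohorts (paired seeds), which the
published study does not state but which strictly reduces the noise of the
efficiency comparison; RMSE ratios carry a delta-method MC standard error
from the paired squared-error covariance. The "censored proportion" of a
scenario has several plausible definitions (censored before the first
event, before the horizon, censoring as the observed endpoint before the
horizon, ...); the scenario summary reports the candidates side by side and
asserts none.

Simulation sizes used by the shipped checks: the test suite runs the two
headline accuracy scenarios at 1000 replications and the eight-scenario
efficiency comparison at 300 replications with the ratio's own MC standard
error as allowance; `scripts/acceptance.py` runs all eight scenarios at
1000 paired replications.

## What the synthetic data do and do not show

The generator reproduces the dependence structure, censoring levels and
sample sizes of the published simulation design, so passing tests show the
estimators and the regression machinery behave as claimed under those
conditions: exponential hazards, frailty-induced dependence, independent
censoring, covariate-free event processes. Real data differ in ways the
generator does not emulate: covariate-dependent hazards, non-exponential
baselines, informative censoring, measurement error in covariates. The
application-shaped demo (three binary covariates, categories
{0, 1, 2+ recurrences, death}, yearly landmarks, window 3, cubic smoothers)
exercises the full model *structure* on synthetic data; its covariate
effects are arbitrary, so its coefficient values are illustrative only.

## Known limitations

* Only the generalized-logit link is implemented (the architecture admits
  others); smoothers are polynomial only.
* Leave-one-out is O(n_s) re-estimation per landmark — intended for the
  hundreds-of-subjects scale, not biobank scale.
* Joint frailty modelling, Fine–Gray-type landmarking and predictive
  performance measures (Brier score, calibration) are out of scope.
* Interval-censored event times and time-varying covariate trajectories are
  not supported; a recurrent event recorded at exactly the same time as the
  terminal event is rejected as invalid input (the multi-state chain has no
  simultaneous two-step transition).
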