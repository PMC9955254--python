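# Methods

This note documents the models, numerical procedures and design choices
behind `warfadapt`, in the order the pipeline runs: signals and priors,
semi-blind identification, realization and order reduction, model
(in)validation, the adaptive loop, the recursive baselines, the virtual
cohort, and evaluation. It closes with known limitations.

## Signals, baseline, grid

All modeling operates on INR *deviation* `y = INR - inr_baseline` (default
baseline 1.0, the drug-free INR of a healthy subject) against raw daily dose
`u` in mg/day, on a uniform one-day grid. A linear time-invariant model
cannot represent a nonzero drug-free output level, so the baseline must be
removed before fitting and re-added to predictions; both happen inside the
library. File ingestion forward-fills the prescribed dose across missed
visits (the prescription continues between measurements), carries the last
INR forward, and rejects duplicate or non-monotone days.

## A-priori model class

The candidate set is parameterized by five positive scalars:

- `K` — gain bound, enforced as `||R^-1 T_g R||_2 <= K` with
  `R = diag(r^0, ..., r^{N_t-1})`, the Schur-complement form of the
  positive-semidefiniteness of the block matrix `[[K R^-2, T_g'], [T_g, K R^2]]`.
  This simultaneously bounds the model gain and forces the impulse response
  to decay at least like `r^k` (the entrywise consequence `|g_k| <= K r^k` is
  added as explicit variable bounds).
- `r in (0, 1]` — stability margin of the class.
- `epsilon` — elementwise (l-infinity) bound on INR measurement noise. The
  noise set is a box, not a variance: clinic INR errors are bounded,
  not Gaussian.
- `gamma * K_u` — budget for the *initial-condition response* `w`, the output
  contribution of unobserved pre-study dosing. `w` is a free vector bounded
  elementwise by the decaying envelope `gamma * K_u * r^i`: the free response
  of any member of the class decays at least that fast, and a constant box
  would let `w` absorb persistent dose response and destroy identifiability.
  The bi-affine product of the Hankel operator with the unknown past input
  sequence is never formed; bounding its effect is the standard convex
  relaxation, and the past inputs themselves are never estimated.

Defaults used throughout the package's experiments: `K = 10`, `r = 0.95`
(grid 0.90/0.95/0.99 in the adaptive loop), `epsilon = 0.1` (matching the
cohort's noise amplitude), `gamma * K_u = 0.5`.

## Semi-blind identification

The model is `G(z) = p * z/(z-1) + G_np(z)`: the integrator (impulse
response all ones, scaled by the scalar `p`) is the parametric part carrying
accumulated past-dose effects; `G_np` is a nonparametric impulse response
`g_0..g_{N_t-1}`. By default `g_0` is pinned to zero (`input_delay = 1`): an
oral anticoagulant cannot change the INR measured the same morning, and
because protocol dosing computes today's dose from past INR, a free
instantaneous coefficient soaks up closed-loop feedback correlation rather
than plant response.

The fit is a two-stage sequence of linear programs (HiGHS via
scipy.optimize.linprog, feasibility tolerances 1e-10), with the spectral-norm
constraint enforced by cutting planes: after each solve, if the top singular
value sigma of `R^-1 T_g R` exceeds `K`, the valid inequality
`u' (R^-1 T_g R) v <= K` (u, v the singular vectors; linear in g) is added
and the LP re-solved. At convergence the constraint holds exactly.

- **Stage 1** minimizes the l-infinity residual bound `t`. The optimum `t*`
  is the *certified noise level* of the window: the model class can explain
  the data with residual `t*` and no less. Feasibility versus the prior is
  `t* <= epsilon` (slack 1e-6).
- **Stage 2** fixes the residual bound at `max(t*, epsilon)` and minimizes a
  weighted l-1 norm of `(g, p, w)`. Every feasible point of stage 2 is
  consistent with the data up to admissible noise; minimizing `t` alone
  would interpolate the noise (the window has more unknowns than samples)
  and produce erratic coefficients. Weights make the channels
  unit-comparable: `g` and `p` are weighted by the mean dose (one unit of
  `g_k` contributes ~dose-scale INR units), `p` additionally by the window
  length (the integrator feeds every sample), and `w` carries a mild
  preference (0.5) so decaying early-window transients route to the
  initial-condition channel that exists for them.

The reported `achieved_noise` is the l-infinity residual of the returned
solution; with slack available it sits at `epsilon`, otherwise at `t*`.

## Realization and order reduction

The nonparametric part is realized by Ho-Kalman/eigensystem realization: the
Markov parameters `g_1..` fill the largest non-padded Hankel/shifted-Hankel
pair (realizable order is therefore at most `floor((N_t-1)/2)`), and the
numerical rank decision uses both a relative cutoff (1e-8 of the top singular
value) and an absolute one at the uncertainty scale of `g`
(`max(2 * achieved_noise, 1e-6) / dose-scale`), so measurement and solver
noise do not fabricate state dimensions. Ho-Kalman extrapolates the impulse
response beyond the identification window, which is what makes short-window
models usable for prediction. When the factorization still produces poles
outside the a-priori class — noisy windows with no shift-consistent
structure — the exact FIR (shift-register) realization of order `N_t - 1` is
used instead: always stable, reproducing `g` exactly, response truncated
after the horizon. With seven identification points the full-order model is
thus sixth order (plus one marginal state when `p != 0`).

Order reduction splits the state space by a sorted real Schur form into
marginal modes (pole magnitude >= 1 - 1e-6; the integrator, retained exactly,
and an error is raised if they alone exceed the order budget) and an
asymptotically stable part, which is balanced-truncated (gramians from
discrete Lyapunov equations, square-root balancing) to fill the budget.

## Model (in)validation

Given a model and a fresh window, the question is whether admissible noise,
an admissible initial-condition effect, and a causal uncertainty operator
`Delta` of induced norm < 1 can reproduce the window via
`y = (I + Delta)(s0 + w + eta)`. The nominal response `s0` is computed by
simulating the model over the *full* dose history, so everything observed
since the start of the record contributes the correct internal state; `w`
(box `gamma*K_u`) covers only pre-record dosing, and `eta` the noise box.
Both certificates are closed-form clips of the residual onto their boxes —
the box-constrained least-squares minimizer. The uncertainty class is causal,
linear time-varying, l2-induced-norm-bounded; for that class an operator of
norm `delta` mapping `s = s0 + w + eta` to `rho = y - s` exists if and only
if every causal cumulative-norm ratio `||rho_1:k|| / ||s_1:k||` is at most
`delta`. The certified bound `delta_hat` is the largest ratio (denominators
floored at 1e-9; a window with zero explained energy but nonzero residual is
reported as degenerate and invalid). `delta_hat < 1` certifies consistency.

Two structural properties of this test are worth knowing. It is
*asymmetric*: a model whose response overshoots the data can never be
invalidated (the ratio tends to 1 from below), while undershooting models
can. And a pure multiplicative gain change by factor `m` admits
`Delta = (m-1) I`, so its minimal uncertainty norm is `|m-1|`: gain changes
below x2 are in principle *not* invalidatable at threshold 1, and exactly x2
sits on the boundary, pushed below it by any admissible noise or
initial-condition slack. Detection of moderate regime changes therefore
relies on accumulated model mismatch, not on the gain shift itself; the
operating characteristics measured in the test suite reflect this (stationary
false-alarm control is comfortably above 95%, while a x2 gain step is
usually certified consistent).

## Adaptive loop

Initial fit: identify on the first `N_t = 7` samples, reduce to
`O_default = 3`, validate on the next `M_t` samples, where `M_t` equals the
reduced model order (a "coefficients" rule, `M_t = 2O + 1`, is available).
Each new sample slides the validation window forward and re-runs the test.
On invalidation the model is re-identified from all past samples outside the
current window (identification data grow monotonically over the record), and
escalation walks a fixed order: reduced order up to `O_max = 5` at the
current stability margin (re-reduction only — identification is cached per
margin), then the margin grid with the order reset, then (during
initialization, while unused data exist) growth of the identification
window, and finally a clinician alert, after which the loop keeps predicting
with the lowest-`delta_hat` candidate. A freshly identified model is always
validated on the same window that invalidated its predecessor before use.
Predictions are one-step-ahead from *measured* history (ARX-style difference
equation of the reduced model), never open-loop simulation; each prediction
is emitted only after a validate/re-identify decision for the preceding day,
which the event log records auditable per day.

## Recursive baselines

ARX(6,6) and ARMAX(6,6,6) with Kalman-filter parameter tracking: parameters
follow a random walk with process noise `q = 1e-4` (default), measurement
noise `r_v = 0.01`, diffuse prior `P0 = 1e6 I`, Joseph-stabilized covariance
updates (with `q = 0` and a diffuse prior the recursion is numerically equal
to batch least squares, which the tests assert to 1e-6). ARMAX feeds
posterior residuals back into the regressor (pseudolinear recursion; a
prior-residual variant is a flag). Order 6 matches the full-order semi-blind
model from seven identification points, the usual convention for a fair
comparison.

## Virtual cohort

Each virtual patient is a stable second-order dose-to-INR-deviation system
`G(z) = c z / ((z - p1)(z - p2))` with one-day latency, poles drawn uniformly
in [0.5, 0.9] and DC gain in [0.2, 0.8] INR per mg/day — so a typical 5
mg/day maintenance dose sustains an INR of 2-3 over baseline 1.0. Dosing is
closed-loop: start at 5 mg/day, step 1 mg/day up (down) when measured INR
falls below 2 (rises above 3), clamp to [0, 10]. Measurement noise is
uniform on [-0.1, 0.1] — bounded, matching the l-infinity noise set the
identification assumes; a Gaussian option exists as a deliberate
out-of-class stressor. Ten warm-up days at the starting dose are simulated
and discarded, so released records begin with a genuinely nonzero internal
state. Regime changes (0-2 per patient, days ~15-45) multiply the *input*
matrix by a factor in [0.6, 1.6] and shift both poles by up to ±0.1: an
interaction alters the effect of newly administered drug while the existing
anticoagulation state decays physiologically; scaling the output instead
would jump the measured INR overnight, which is clinically impossible.
Per-patient seeds are spawned from the master seed, and the manifest
regenerates a cohort bit-identically.

What the generator does *not* emulate: pharmacokinetic mechanism (vitamin K
intake, clotting-factor turnover, CYP2C9/VKORC1 genotype effects),
dose-response saturation (a linear-plant world, with a nonlinearity flag only
as a stressor), irregular visit spacing, and gross measurement artifacts.
Passing tests on this cohort therefore demonstrate the estimation and
certification machinery under the framework's own assumptions — bounded
noise, linear dynamics, abrupt parameter shifts — not clinical performance.

## Evaluation

MMSE is the mean squared difference between predicted and measured INR on
the raw INR scale, computed from the first day *every* compared method has a
prediction (a common-span contract; with `N_t = 7` and `M_t = 3` the
adaptive method is the binding constraint, so cohort comparisons start at
day index 10). The static reference identifies once on the first seven
points and freezes the reduced order chosen by AIC, in the Gaussian-residual
form `AIC = 2k + n ln(RSS/n)` with `k = 2O + 1` coefficients, over the grid
{3, 4, 5, 6}. The comparison report aggregates per-patient MMSE into
mean ± standard deviation per method.

Experiment sizes used by the acceptance checks (chosen to characterize the
statistics cleanly at desk scale): 50-seed identification-recovery and
detection experiments, 200 stationary windows for false-alarm control, and
ten 20-patient, 60-day cohorts for the method comparison.

## Numerical choices

- LP feasibility/duality tolerances 1e-10; spectral-cut violation tolerance
  1e-9, at most 60 cuts per stage.
- Stage-1 tie-break weight 1e-6 (determinism on degenerate faces).
- Marginal-pole classification at 1 - 1e-6; realization rank cut at
  1e-8 relative plus the noise-scale absolute cut described above.
- Integrator weights `|p| < 1e-9` are snapped to zero so numerical dust does
  not create marginal states.
- Invalidation denominators floored at 1e-9.
- Kalman covariance kept symmetric positive definite by the Joseph form.

## Known limitations

- The invalidation threshold (`delta_hat < 1` with multiplicative
  uncertainty) cannot flag gain drifts below a factor of 2, as derived above;
  on cohorts whose regime changes live in [0.6, 1.6] the adaptive loop
  re-identifies rarely, and its advantage over the static reference is
  correspondingly modest.
- Seven noisy samples under protocol dosing are weakly informative
  (near-collinear regressors); no estimator — including an oracle-structure
  least-squares fit — recovers parameters to noise-floor precision from
  them. The identification is honest about this: the certified residual
  states what the data pin down, and the adaptive machinery exists precisely
  because early models are provisional.
- The one-step predictor uses measured outputs; multi-day dose planning
  (open-loop simulation with a controller) is out of scope, as is dose
  recommendation itself.
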