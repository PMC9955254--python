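# warfadapt

Adaptive, personalized dose-response modeling for warfarin anticoagulation
management.

Warfarin is dosed against the International Normalized Ratio (INR), which must
be held inside a narrow therapeutic band (2.0-3.0). Each patient's
dose-to-INR dynamics are different, drift with diet and co-medication, and
must be learned from very few clinic visits — typically starting from a
handful of noisy samples taken while the patient already carries the effect of
unrecorded earlier dosing. `warfadapt` is a toolkit for clinicians'
quantitative support staff and for control/pharmacometrics researchers who
need individualized, certifiable INR prediction models under exactly those
constraints.

## What it implements

**Semi-blind robust identification.** The patient model is
`G(z) = p * z/(z-1) + G_np(z)`: a scalar-weighted discrete integrator (the
parametric part, carrying the accumulated effect of past dosing) in parallel
with a nonparametric impulse response `g = (g_0, ..., g_{N_t-1})`. Given
a-priori bounds — gain `K`, stability margin `r`, noise level `eps`, and an
initial-condition budget `gamma * K_u` — the identification finds members of
the consistency set

    |y - T_u (p*P + g) - w| <= t        (data, elementwise)
    M(g) = [[K R^-2, T_g'], [T_g, K R^2]] >= 0    (gain/stability prior)
    |w_i| <= gamma * K_u * r^i          (initial-condition response)

where `T_u` is the input Toeplitz operator, `R = diag(r^0..r^{N_t-1})`, and
`w` absorbs the free response of unobserved pre-study dosing. The
semidefinite constraint is equivalent to the spectral-norm bound
`||R^-1 T_g R||_2 <= K` and is enforced exactly by cutting planes on a linear
program, so the whole fit is a deterministic LP sequence. The certified
minimal residual `t*` decides consistency with the noise prior; the returned
model is the most parsimonious consistency-set member at residual level
`max(t*, eps)`.

**Model (in)validation.** A fresh data window is explained as
`y = (I + Delta)(s0 + w + eta)` with admissible noise `|eta_i| <= eps`,
a bounded initial-condition term, and a causal norm-bounded uncertainty
`Delta`. The certified bound `delta_hat` is the largest causal
cumulative-norm ratio `||rho_1:k|| / ||s_1:k||` after the noise and IC
certificates absorb what the priors allow; the model remains suitable for
prediction while `delta_hat < 1`.

**Recursive adaptation.** Identify on the first `N_t = 7` visits, certify on
the next `M_t` (equal to the reduced model order, default 3), then slide the
validation window with every new sample. On invalidation, re-identify from
all past data outside the window, escalating the reduced order (3 to 5), then
the stability-margin grid (0.90, 0.95, 0.99), then the amount of
identification data, and raising a clinician alert if nothing certifies.

**Baselines and evaluation.** Recursive ARX/ARMAX estimators with
Kalman-filter parameter tracking (order 6, the comparison convention for
7-point identification), one-step-ahead MMSE scoring, AIC order selection for
the static (never-adapted) reference, and a cohort comparison report.

**Virtual cohort.** The clinical dataset this framework was developed against
(44 anticoagulation-clinic patients, ~60-day records) is not publicly
deposited, so the package ships a generator of virtual patients with the same
statistical structure: stable second-order dose-to-INR dynamics with one-day
latency, protocol dosing in 0-10 mg/day reacting to measured INR, bounded
uniform noise, a discarded warm-up period that induces nonzero initial
conditions, and scheduled regime changes (gain and pole shifts) standing in
for diet and drug interactions.

## Worked example

```python
import numpy as np
from warfadapt import PrioriSet, reduce_order
from warfadapt.cohort import CohortConfig, TruePatient, simulate_patient
from warfadapt.semiblind import identify
from warfadapt.invalidation import invalidate
from warfadapt.adaptive import AdaptiveConfig, run_adaptive

patient = TruePatient(patient_id="demo", poles=(0.6, 0.8), dc_gain=0.4,
                      inr_baseline=1.0, noise_eps=0.1, regime_schedule=(),
                      warmup_doses=(5.0,) * 10)
series, truth = simulate_patient(patient, days=20, seed=1)

priors = PrioriSet(K=10.0, r=0.95, epsilon=0.1, gamma=0.5, K_u=1.0)
result = identify(series, priors, slice(0, 7))
print(f"certified residual: {result.achieved_noise:.3f}  "
      f"feasible vs eps: {result.feasible}")

result.model.reduced = reduce_order(result.model.realization, 3)
outcome = invalidate(result.model, series, slice(7, 10), priors)
print(f"delta_hat: {outcome.delta_hat:.3f}  validated: {outcome.validated}")

timeline = run_adaptive(series, AdaptiveConfig(priors=priors))
print(f"one-step MMSE: {timeline.mmse:.3f}  updates: {timeline.update_days}")
```

Output:

```
certified residual: 0.100  feasible vs eps: True
delta_hat: 0.193  validated: True
one-step MMSE: 0.015  updates: []
```

The identification certifies that the seven noisy samples are explainable
within the assumed noise level (residual 0.100 = eps); the third-order
reduced model is certified on the next three held-out days with an
uncertainty bound far below the invalidation threshold of 1; and the adaptive
loop, finding the model valid at every subsequent visit, predicts the
measured INR with a mean squared one-step error of 0.015 INR^2 — at the scale
of the measurement noise — without ever re-identifying.

The same flows are available from a shell:

```
warfadapt simulate-cohort --n 44 --seed 1 --out cohort/
warfadapt adaptive-run --in cohort/patient1.csv --out log.csv
warfadapt compare --in cohort/ --out table.txt
```

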