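"""Synthetic virtual-patient cohort for warfarin-INR experiments.

The study dataset this emulates (daily warfarin dose and INR for 44 patients
over roughly two months, collected under clinician dose adjustment) is not
publicly deposited, so every experiment in this package runs against virtual
patients that reproduce its statistical structure: short records, doses in a
clinician-adjusted 0-10 mg/day range, INR held near the 2-3 therapeutic band
by a protocol dosing policy, bounded (ell-infinity) measurement noise,
nonzero initial conditions induced by an unobserved pre-study dosing period,
and occasional mid-treatment regime changes standing in for diet or drug
interactions.

Each patient is a stable second-order linear dose-to-INR-deviation system
with a one-day input delay.  Regime changes switch the output gain and/or
shift the poles while the internal state carries over, exactly the kind of
abrupt dose-response shift the adaptive identification loop is meant to
catch.  Measurement noise is uniform (bounded), matching the noise set the
identification assumes; a Gaussian option exists as an out-of-class stressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model_core import DoseResponseSeries, StateSpaceModel, TransferFunctionModel

__all__ = [
    "CohortConfig",
    "TruePatient",
    "GroundTruth",
    "CohortManifest",
    "sample_patient",
    "dosing_policy",
    "simulate_patient",
    "generate_cohort",
    "plant_from_params",
]


@dataclass(frozen=True)
class CohortConfig:
    """Sampling ranges and simulation settings for the virtual cohort."""

    pole_range: tuple[float, float] = (0.5, 0.9)
    dc_gain_range: tuple[float, float] = (0.2, 0.8)  # INR per mg/day
    inr_baseline: float = 1.0
    noise_eps: float = 0.1
    noise_kind: str = "uniform"          # "uniform" (in-class) or "gaussian"
    regime_count_max: int = 2
    regime_prob: float = 0.5             # per allowed change
    min_regimes: int = 0
    gain_mult_range: tuple[float, float] = (0.6, 1.6)
    pole_shift_range: tuple[float, float] = (-0.1, 0.1)
    regime_day_range: tuple[float, float] = (15, 45)
    warmup_days: int = 10
    start_dose: float = 5.0
    step_up: float = 1.0
    step_down: float = 1.0
    dose_max: float = 10.0
    inr_low: float = 2.0
    inr_high: float = 3.0

    def __post_init__(self):
        for lo, hi in (self.pole_range, self.dc_gain_range,
                       self.gain_mult_range, self.regime_day_range):
            if not lo <= hi:
                raise ValueError("empty sampling range")
        if self.noise_kind not in ("uniform", "gaussian"):
            raise ValueError("noise_kind must be 'uniform' or 'gaussian'")


@dataclass(frozen=True)
class TruePatient:
    """Ground-truth generating system of one virtual patient."""

    patient_id: str
    poles: tuple[float, float]
    dc_gain: float                       # INR per mg/day at the first regime
    inr_baseline: float
    noise_eps: float
    regime_schedule: tuple               # of (day, gain multiplier, pole shift)
    warmup_doses: tuple

    def tf_at(self, regime: int) -> TransferFunctionModel:
        """True transfer function in the given regime (0 = initial)."""
        p1, p2 = self.poles
        gain = self.dc_gain
        for day, mult, shift in self.regime_schedule[:regime]:
            gain *= mult
            p1 = min(max(p1 + shift, 0.05), 0.98)
            p2 = min(max(p2 + shift, 0.05), 0.98)
        return plant_from_params((p1, p2), gain)


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless record and per-segment true models kept for scoring."""

    inr_noiseless: np.ndarray
    regime_of_day: np.ndarray
    models: tuple
    warmup_doses: tuple


@dataclass
class CohortManifest:
    """Everything needed to regenerate a cohort bit-identically."""

    master_seed: int
    n: int
    patient_seeds: list
    config: dict
    patients: list = field(default_factory=list)


def plant_from_params(poles: tuple[float, float], dc_gain: float) -> TransferFunctionModel:
    """Second-order dose-to-INR-deviation plant with a one-day delay.

    G(z) = c z / ((z - p1)(z - p2)) with c chosen so the DC gain (steady INR
    deviation per sustained mg/day) equals ``dc_gain``.
    """
    p1, p2 = poles
    c = dc_gain * (1.0 - p1) * (1.0 - p2)
    return TransferFunctionModel(num=[c, 0.0], den=[1.0, -(p1 + p2), p1 * p2])


def sample_patient(seed: int, cfg: CohortConfig | None = None,
                   patient_id: str | None = None) -> TruePatient:
    """Draw one virtual patient; identical seeds give identical patients."""
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(seed)
    poles = tuple(sorted(rng.uniform(*cfg.pole_range, size=2)))
    dc_gain = float(rng.uniform(*cfg.dc_gain_range))
    n_changes = 0
    for _ in range(cfg.regime_count_max):
        if rng.uniform() < cfg.regime_prob:
            n_changes += 1
    n_changes = max(n_changes, min(cfg.min_regimes, cfg.regime_count_max))
    days = np.sort(rng.uniform(*cfg.regime_day_range, size=n_changes)).astype(int)
    schedule = []
    for d in days:
        mult = float(rng.uniform(*cfg.gain_mult_range))
        shift = float(rng.uniform(*cfg.pole_shift_range))
        schedule.append((int(d), mult, shift))
    warmup = tuple(float(cfg.start_dose) for _ in range(cfg.warmup_days))
    return TruePatient(
        patient_id=patient_id or f"sim{seed}",
        poles=poles,
        dc_gain=dc_gain,
        inr_baseline=cfg.inr_baseline,
        noise_eps=cfg.noise_eps,
        regime_schedule=tuple(schedule),
        warmup_doses=warmup,
    )


def dosing_policy(inr_hist, dose_prev: float, cfg: CohortConfig | None = None) -> float:
    """Protocol dose adjustment: raise below the therapeutic band, lower
    above it, hold within, clamp to [0, dose_max]."""
    cfg = cfg or CohortConfig()
    if len(inr_hist) == 0:
        raise ValueError("need at least one INR measurement")
    inr = inr_hist[-1]
    dose = dose_prev
    if inr < cfg.inr_low:
        dose = dose_prev + cfg.step_up
    elif inr > cfg.inr_high:
        dose = dose_prev - cfg.step_down
    return float(min(max(dose, 0.0), cfg.dose_max))


def _ss(tf: TransferFunctionModel) -> StateSpaceModel:
    # controllable canonical form of c z / (z^2 + a1 z + a2): x1' = -a1 x1 - a2 x2 + u
    a1, a2 = tf.den[1], tf.den[2]
    c = tf.num[0]
    return StateSpaceModel(A=[[-a1, -a2], [1.0, 0.0]], B=[[1.0], [0.0]],
                           C=[[c, 0.0]], D=[[0.0]])


def simulate_patient(patient: TruePatient, days: int, seed: int,
                     cfg: CohortConfig | None = None):
    """Closed-loop simulation of one patient record.

    A warm-up period is simulated under the pre-study dosing and *discarded*,
    so the released series opens with a nonzero internal state (the scenario
    the semi-blind identification exists for).  The dosing policy reacts to
    the *measured* (noisy) INR.  Returns (DoseResponseSeries, GroundTruth).
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(seed)
    warm = len(patient.warmup_doses)
    total = warm + days

    # per-regime state-space matrices; the gain multiplier enters through B
    # (the effect of newly administered drug), so a regime change propagates
    # through the dynamics over days instead of jumping the INR instantly
    sched = patient.regime_schedule
    models = []
    for k in range(len(sched) + 1):
        tf_k = patient.tf_at(k)
        m = _ss(patient.tf_at(0))
        a1, a2 = tf_k.den[1], tf_k.den[2]
        scale = tf_k.num[0] / patient.tf_at(0).num[0]
        models.append(StateSpaceModel(
            A=[[-a1, -a2], [1.0, 0.0]],
            B=[[scale], [0.0]],
            C=m.C, D=m.D,
        ))

    x = np.zeros(2)
    doses = np.zeros(total)
    y_clean = np.zeros(total)
    inr_meas = np.zeros(total)
    regime_of_day = np.zeros(days, dtype=int)
    dose = patient.warmup_doses[0] if warm else cfg.start_dose
    for t in range(total):
        rel = t - warm
        regime = 0
        for k, (d, _, _) in enumerate(sched):
            if rel >= d:
                regime = k + 1
        m = models[regime]
        if t < warm:
            dose = patient.warmup_doses[t]
        doses[t] = dose
        y_clean[t] = float((m.C @ x).item())  # one-day delay: today's dose acts tomorrow
        if cfg.noise_kind == "uniform":
            eta = rng.uniform(-patient.noise_eps, patient.noise_eps)
        else:
            eta = rng.normal(0.0, patient.noise_eps)
        inr_meas[t] = patient.inr_baseline + y_clean[t] + eta
        if rel >= 0:
            regime_of_day[rel] = regime
        x = m.A @ x + m.B[:, 0] * dose
        if t >= warm - 1:  # policy takes over from the first released day
            dose = dosing_policy(inr_meas[: t + 1], dose, cfg)

    series = DoseResponseSeries(
        patient_id=patient.patient_id,
        day=np.arange(1, days + 1),
        dose=doses[warm:],
        inr=np.maximum(inr_meas[warm:], 1e-6),
        inr_baseline=patient.inr_baseline,
    )
    truth = GroundTruth(
        inr_noiseless=patient.inr_baseline + y_clean[warm:],
        regime_of_day=regime_of_day,
        models=tuple(patient.tf_at(k) for k in range(len(sched) + 1)),
        warmup_doses=patient.warmup_doses,
    )
    return series, truth


def generate_cohort(n: int = 44, seed: int = 0,
                    cfg: CohortConfig | None = None, days: int = 60):
    """Generate ``n`` independent virtual patients and a manifest.

    Per-patient seeds are spawned deterministically from the master seed, so
    regeneration from the manifest is bit-identical.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    cfg = cfg or CohortConfig()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    series_list = []
    truths = []
    manifest = CohortManifest(master_seed=seed, n=n, patient_seeds=child_seeds,
                              config=asdict(cfg))
    for i, ps in enumerate(child_seeds):
        patient = sample_patient(ps, cfg, patient_id=f"patient{i + 1}")
        series, truth = simulate_patient(patient, days, ps + 1, cfg)
        series_list.append(series)
        truths.append(truth)
        manifest.patients.append({
            "patient_id": patient.patient_id,
            "seed": ps,
            "poles": list(patient.poles),
            "dc_gain": patient.dc_gain,
            "regime_schedule": [list(r) for r in patient.regime_schedule],
        })
    return series_list, truths, manifest
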