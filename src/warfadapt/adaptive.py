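"""Recursive adaptive identification: identify, validate, re-identify.

The loop mirrors clinical use: an initial model is identified from the first
N_t visits and certified on the next M_t; every new sample slides the
validation window forward and re-runs the (in)validation test.  While the
model stays validated it is used for one-step-ahead INR prediction; when it
is invalidated the model is re-identified from all past data outside the
current validation window, escalating the reduced order O, then the
stability-margin prior r, then (while initializing) the amount of
identification data, until a candidate passes.  If every candidate fails the
loop raises a clinician alert and keeps predicting with the lowest-delta_hat
candidate seen.

The number of validation points M_t tracks the reduced model: by default it
equals the reduced order O ("order" rule); the "coefficients" rule uses the
parameter count 2*O + 1 instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .invalidation import invalidate, validation_window
from .model_core import (
    DoseResponseSeries,
    PrioriSet,
    SemiBlindModel,
    one_step_predict,
    reduce_order,
)
from .semiblind import IdentificationResult, identify, with_reduced

__all__ = [
    "AdaptiveConfig",
    "AdaptiveTimeline",
    "AdaptiveState",
    "EscalationSearch",
    "escalate",
    "initial_fit",
    "step",
    "run_adaptive",
]


@dataclass(frozen=True)
class AdaptiveConfig:
    """Settings of the adaptive loop.

    N_t: identification points for the first fit (default 7).
    O_default / O_max: first and largest reduced order tried (3 and 5).
    r_grid: increasing stability-margin candidates; the last entry is r_max.
    M_t_rule: "order" (M_t = O) or "coefficients" (M_t = 2*O + 1).
    priors: gain/noise/initial-condition priors; the r field is overridden
        by the r_grid candidate in use.
    """

    priors: PrioriSet
    N_t: int = 7
    O_default: int = 3
    O_max: int = 5
    r_grid: tuple[float, ...] = (0.90, 0.95, 0.99)
    M_t_rule: str = "order"

    def __post_init__(self):
        if not (3 <= self.O_default <= self.O_max):
            raise ValueError("need 3 <= O_default <= O_max")
        g = np.asarray(self.r_grid, dtype=float)
        if np.any(np.diff(g) <= 0) or np.any(g <= 0) or np.any(g > 1):
            raise ValueError("r_grid must be strictly increasing within (0, 1]")
        if self.M_t_rule not in ("order", "coefficients"):
            raise ValueError("M_t_rule must be 'order' or 'coefficients'")

    def M_t(self, O: int) -> int:
        return O if self.M_t_rule == "order" else 2 * O + 1


@dataclass(frozen=True)
class EscalationSearch:
    """Position in the ordered escalation search after a failed validation."""

    O: int
    r_index: int
    config: AdaptiveConfig
    can_grow_data: bool = False


def escalate(search: EscalationSearch):
    """Next escalation move: ("order"|"margin"|"grow", next search position)
    or ("exhausted", None) once every stage is spent.

    The order of stages is fixed: raise the reduced order O to O_max at the
    current stability margin, then reset O and advance r along the grid, then
    reset both and grow the identification data, and finally give up (the
    caller keeps a best-effort model and raises an alert).
    """
    cfg = search.config
    if search.O < cfg.O_max:
        return "order", replace(search, O=search.O + 1)
    if search.r_index + 1 < len(cfg.r_grid):
        return "margin", replace(search, O=cfg.O_default,
                                 r_index=search.r_index + 1)
    if search.can_grow_data:
        return "grow", replace(search, O=cfg.O_default, r_index=0)
    return "exhausted", None


@dataclass
class AdaptiveTimeline:
    """Outcome of a full adaptive run over one patient record."""

    segments: list  # (start_day, end_day, SemiBlindModel, O, r) half-open
    update_days: list
    alerts: list
    predictions: np.ndarray  # per-day INR prediction, NaN where undefined
    mmse: float
    events: list = field(default_factory=list)  # audit log records


@dataclass
class AdaptiveState:
    """Mutable state carried between steps of the adaptive loop."""

    config: AdaptiveConfig
    series: DoseResponseSeries          # samples observed so far
    result: IdentificationResult
    O: int
    r_index: int
    id_end: int                         # identification used series[:id_end]
    t_next: int                         # index of the next unseen sample
    seg_start: int                      # day index opening the current segment
    segments: list = field(default_factory=list)
    update_days: list = field(default_factory=list)
    alerts: list = field(default_factory=list)
    predictions: dict = field(default_factory=dict)
    events: list = field(default_factory=list)
    invalidate_fn: Callable = invalidate

    @property
    def model(self) -> SemiBlindModel:
        return self.result.model

    def log(self, day: int, event: str, delta_hat: float | None = None,
            prediction: float | None = None, O: int | None = None,
            r: float | None = None):
        self.events.append({
            "day": int(day),
            "event": event,
            "O": self.O if O is None else O,
            "r": self.config.r_grid[self.r_index] if r is None else r,
            "delta_hat": delta_hat,
            "prediction": prediction,
        })


def _sub_series(series: DoseResponseSeries, stop: int) -> DoseResponseSeries:
    return DoseResponseSeries(series.patient_id, series.day[:stop],
                              series.dose[:stop], series.inr[:stop],
                              series.inr_baseline)


def _fit_candidate(series, config, r_index, O, id_end, t_now, id_cache,
                   invalidate_fn):
    """Identify (cached per (r, id_end)), reduce to O, validate on the M_t
    window ending at t_now; returns (result-with-reduced, outcome)."""
    r = config.r_grid[r_index]
    key = (r_index, id_end)
    if key not in id_cache:
        priors = replace(config.priors, r=r)
        id_cache[key] = (identify(series, priors, slice(0, id_end)), priors)
    result, priors = id_cache[key]
    reduced = reduce_order(result.model.realization, O)
    cand = with_reduced(result, reduced)
    M_t = config.M_t(reduced.order) if config.M_t_rule == "order" else config.M_t(O)
    M_t = max(1, min(M_t, t_now))
    win = validation_window(series, t_now, M_t)
    outcome = invalidate_fn(cand.model, series, win, priors)
    return cand, outcome


def initial_fit(series: DoseResponseSeries, config: AdaptiveConfig,
                invalidate_fn: Callable = invalidate,
                _state_events: list | None = None):
    """First identification on N_t points, validated on the next M_t.

    Runs the escalation search (order, margin, data growth within the given
    series) if the first candidate fails; returns
    (IdentificationResult, InvalidationOutcome, O, r_index, id_end, events).
    """
    N_t = config.N_t
    M_t0 = config.M_t(config.O_default)
    if len(series) < N_t + M_t0:
        raise ValueError("series shorter than N_t + M_t")
    events = _state_events if _state_events is not None else []
    id_cache: dict = {}
    id_end = N_t
    t_now = N_t + M_t0
    search = EscalationSearch(O=config.O_default, r_index=0, config=config,
                              can_grow_data=True)
    best = None  # (delta_hat, cand, outcome, O, r_index, id_end)
    while True:
        cand, outcome = _fit_candidate(series, config, search.r_index,
                                       search.O, id_end, t_now, id_cache,
                                       invalidate_fn)
        events.append({"day": int(series.day[t_now - 1]),
                       "event": "validate" if outcome.validated else "invalidate",
                       "O": search.O, "r": config.r_grid[search.r_index],
                       "delta_hat": outcome.delta_hat, "prediction": None})
        if best is None or outcome.delta_hat < best[0]:
            best = (outcome.delta_hat, cand, outcome, search.O,
                    search.r_index, id_end)
        if outcome.validated:
            return cand, outcome, search.O, search.r_index, id_end, events
        move, nxt = escalate(replace(
            search, can_grow_data=id_end + 1 + M_t0 <= len(series)))
        if move == "exhausted":
            events.append({"day": int(series.day[t_now - 1]), "event": "alert",
                           "O": best[3], "r": config.r_grid[best[4]],
                           "delta_hat": best[0], "prediction": None})
            return best[1], best[2], best[3], best[4], best[5], events
        if move == "grow":
            id_end += 1
            t_now = max(t_now, id_end + M_t0)
        search = nxt


def step(state: AdaptiveState, dose: float, inr: float) -> AdaptiveState:
    """Consume one new (dose, INR) sample and update the loop state.

    Slides the validation window over the new sample, re-identifies on
    invalidation (all past data outside the window, order/margin escalation),
    then emits the one-step-ahead prediction for the next day.
    """
    s = state.series
    series = DoseResponseSeries(
        s.patient_id,
        np.append(s.day, s.day[-1] + 1 if len(s) else 0),
        np.append(s.dose, dose),
        np.append(s.inr, inr),
        s.inr_baseline,
    )
    state.series = series
    t_now = len(series)
    config = state.config
    day = int(series.day[-1])

    M_t = config.M_t(state.O)
    win = validation_window(series, t_now, M_t)
    priors = replace(config.priors, r=config.r_grid[state.r_index])
    outcome = state.invalidate_fn(state.model, series, win, priors)
    if outcome.validated:
        state.log(day, "validate", delta_hat=outcome.delta_hat)
    else:
        state.log(day, "invalidate", delta_hat=outcome.delta_hat)
        _reidentify(state, t_now, M_t)
    state.t_next = t_now
    return state


def _reidentify(state: AdaptiveState, t_now: int, M_t_invalidating: int):
    """Escalation search after an invalidation at sample index t_now - 1."""
    config = state.config
    series = state.series
    day = int(series.day[-1])
    # all past data outside the invalidating window; never shrink the window
    id_end = max(t_now - M_t_invalidating, state.id_end + 1, config.N_t)
    id_end = min(id_end, t_now - 1)
    id_cache: dict = {}
    search = EscalationSearch(O=config.O_default, r_index=0, config=config)
    best = None
    while True:
        cand, outcome = _fit_candidate(series, config, search.r_index,
                                       search.O, id_end, t_now, id_cache,
                                       state.invalidate_fn)
        state.log(day, "reidentify", delta_hat=outcome.delta_hat,
                  O=search.O, r=config.r_grid[search.r_index])
        if best is None or outcome.delta_hat < best[0]:
            best = (outcome.delta_hat, cand, search.O, search.r_index)
        if outcome.validated:
            _accept(state, cand, search.O, search.r_index, id_end, t_now)
            return
        move, nxt = escalate(search)
        if move == "exhausted":
            state.log(day, "alert", delta_hat=best[0], O=best[2],
                      r=config.r_grid[best[3]])
            state.alerts.append(day)
            _accept(state, best[1], best[2], best[3], id_end, t_now)
            return
        search = nxt


def _accept(state: AdaptiveState, cand, O, r_index, id_end, t_now):
    day = int(state.series.day[t_now - 1]) + 1  # model governs from next day
    state.segments.append((state.seg_start, day, state.model,
                           state.O, state.config.r_grid[state.r_index]))
    state.seg_start = day
    state.result = cand
    state.O = O
    state.r_index = r_index
    state.id_end = id_end
    state.update_days.append(day)


def run_adaptive(series: DoseResponseSeries, config: AdaptiveConfig,
                 invalidate_fn: Callable = invalidate) -> AdaptiveTimeline:
    """Fold the adaptive loop over a full patient record.

    Deterministic given the configuration: identification and invalidation
    contain no randomness.
    """
    N_t = config.N_t
    M_t0 = config.M_t(config.O_default)
    T0 = N_t + M_t0
    if len(series) < T0:
        raise ValueError("series shorter than N_t + M_t")

    init_series = _sub_series(series, T0)
    events: list = []
    result, outcome, O, r_index, id_end, events = initial_fit(
        init_series, config, invalidate_fn, events)
    state = AdaptiveState(config=config, series=init_series, result=result,
                          O=O, r_index=r_index, id_end=id_end, t_next=T0,
                          seg_start=int(series.day[T0 - 1]) + 1,
                          events=events, invalidate_fn=invalidate_fn)

    predictions = np.full(len(series), np.nan)
    for t in range(T0, len(series)):
        predictions[t] = _predict_next(state, series.dose[t])
        state.log(int(series.day[t]), "predict", prediction=predictions[t])
        state = step(state, series.dose[t], series.inr[t])

    # close the final segment
    state.segments.append((state.seg_start, int(series.day[-1]) + 1,
                           state.model, state.O,
                           config.r_grid[state.r_index]))

    mask = ~np.isnan(predictions)
    mmse = float(np.mean((predictions[mask] - series.inr[mask]) ** 2)) if mask.any() else float("nan")
    return AdaptiveTimeline(segments=state.segments,
                            update_days=state.update_days,
                            alerts=state.alerts,
                            predictions=predictions,
                            mmse=mmse,
                            events=state.events)


def _predict_next(state: AdaptiveState, next_dose: float) -> float:
    s = state.series
    u_hist = np.append(s.dose, next_dose)
    return one_step_predict(state.model, s.inr, u_hist, s.inr_baseline)
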