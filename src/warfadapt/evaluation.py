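"""One-step-ahead evaluation: MMSE, AIC order selection, method comparison.

``run_static`` is the no-adaptation reference: one semi-blind identification
on the first N_t points, reduced order chosen once by AIC, model frozen for
the rest of the record.  ``compare`` runs several methods over a cohort and
aggregates per-patient MMSE into a small report table (mean +/- std per
method), the shape in which the clinical study reports its results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DoseResponseSeries, PrioriSet, one_step_predict, reduce_order
from .semiblind import identify, with_reduced

__all__ = ["ComparisonReport", "mmse", "aic", "run_static", "compare"]


def mmse(actual, predicted, start: int = 0) -> float:
    """Mean squared error between two series from index ``start`` on.

    NaN predictions inside the span are excluded (days without a defined
    prediction).
    """
    a = np.asarray(actual, dtype=float)[start:]
    p = np.asarray(predicted, dtype=float)[start:]
    if len(a) != len(p):
        raise ValueError("series lengths differ over the evaluation span")
    mask = ~np.isnan(p)
    if not mask.any():
        raise ValueError("empty evaluation span")
    return float(np.mean((a[mask] - p[mask]) ** 2))


def aic(rss: float, n: int, k: int) -> float:
    """Akaike information criterion under Gaussian residuals:
    AIC = 2k + n ln(rss / n)."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= 0 or k < 1:
        raise ValueError("need n > 0 and k >= 1")
    return float(2 * k + n * np.log(rss / n))


def _one_step_series(model, series: DoseResponseSeries, start: int) -> np.ndarray:
    """One-step-ahead predictions for days >= start (NaN elsewhere)."""
    preds = np.full(len(series), np.nan)
    for t in range(start, len(series)):
        preds[t] = one_step_predict(model, series.inr[:t],
                                    series.dose[: t + 1], series.inr_baseline)
    return preds


def run_static(series: DoseResponseSeries, priors: PrioriSet, N_t: int = 7,
               order_grid: tuple[int, ...] = (3, 4, 5, 6)):
    """Semi-blind identification without (in)validation.

    One identification on the first N_t points; the reduced order is chosen
    by minimum AIC of the one-step residuals over the identification window
    (k = 2*O + 1 coefficients) and then frozen for the whole record.
    Returns (predictions, chosen order, result).
    """
    if len(series) <= N_t:
        raise ValueError("series must extend beyond the identification window")
    result = identify(series, priors, slice(0, N_t))
    if not np.isfinite(result.achieved_noise):
        raise RuntimeError(f"identification failed: {result.solver_status}")
    best = None
    for O in order_grid:
        reduced = reduce_order(result.model.realization, O)
        order = reduced.order
        fit_start = max(order, 1)
        res_sq = []
        for t in range(fit_start, N_t):
            pred = one_step_predict(reduced, series.inr[:t],
                                    series.dose[: t + 1], series.inr_baseline)
            res_sq.append((pred - series.inr[t]) ** 2)
        rss = float(np.sum(res_sq)) if res_sq else 0.0
        score = aic(max(rss, 1e-12), len(res_sq), 2 * O + 1)
        if best is None or score < best[0]:
            best = (score, O, reduced)
    _, O_star, reduced = best
    chosen = with_reduced(result, reduced)
    preds = _one_step_series(chosen.model, series, N_t)
    return preds, O_star, chosen


@dataclass
class ComparisonReport:
    """Per-patient and cohort-level MMSE by method."""

    per_patient: dict            # method -> list of per-patient MMSE
    cohort_mean: dict            # method -> mean MMSE
    cohort_std: dict             # method -> std of per-patient MMSE
    start: int                   # first day index entering the MMSE
    failures: dict               # method -> list of (patient index, error)

    def as_table(self) -> str:
        lines = ["Identification method            MMSE (mean +/- std)",
                 "-" * 52]
        for m in self.per_patient:
            lines.append(f"{m:<32} {self.cohort_mean[m]:.3g} +/- "
                         f"{self.cohort_std[m]:.3g}")
        return "\n".join(lines)


def compare(series_list, methods: dict, start: int | None = None) -> ComparisonReport:
    """Run each method on each patient and aggregate MMSE.

    ``methods`` maps a method name to a callable returning a per-day
    prediction array (NaN where undefined) for a DoseResponseSeries.  The
    evaluation span starts at the first day every method has a prediction
    for (common-span contract), unless ``start`` is given.  A method failure
    on a patient is recorded, not fatal.
    """
    if not series_list:
        raise ValueError("need at least one patient")
    preds = {m: [] for m in methods}
    failures = {m: [] for m in methods}
    for i, series in enumerate(series_list):
        for m, fn in methods.items():
            try:
                preds[m].append(np.asarray(fn(series), dtype=float))
            except Exception as exc:  # noqa: BLE001 - recorded per patient
                preds[m].append(None)
                failures[m].append((i, repr(exc)))
    if start is None:
        start = 0
        for m in methods:
            for p in preds[m]:
                if p is not None and np.any(~np.isnan(p)):
                    start = max(start, int(np.argmax(~np.isnan(p))))
    per_patient = {m: [] for m in methods}
    for i, series in enumerate(series_list):
        for m in methods:
            p = preds[m][i]
            if p is None:
                per_patient[m].append(np.nan)
            else:
                per_patient[m].append(mmse(series.inr, p, start))
    cohort_mean = {m: float(np.nanmean(per_patient[m])) for m in methods}
    cohort_std = {m: float(np.nanstd(per_patient[m])) for m in methods}
    return ComparisonReport(per_patient=per_patient, cohort_mean=cohort_mean,
                            cohort_std=cohort_std, start=start,
                            failures=failures)
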