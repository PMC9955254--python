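"""Model (in)validation against new data under norm-bounded uncertainty.

Given an identified model and a fresh window of dose-INR samples, the test
asks whether admissible measurement noise (elementwise bound epsilon), a
bounded initial-condition effect (elementwise bound gamma*K_u), and a causal
norm-bounded uncertainty operator Delta can together reproduce the window:

    y = (I + Delta)(s0 + w + eta_bar)

where s0 is the nominal model response.  The uncertainty class is taken as
causal, linear time-varying, with bounded ell-2-induced norm; for that class
a Delta of norm delta mapping s to rho = y - s exists exactly when every
causal cumulative-norm ratio ||rho_1:k|| / ||s_1:k|| is at most delta.  The
certified bound delta_hat is the largest such ratio after the noise and
initial-condition certificates have absorbed as much of the residual as the
priors allow; the model is declared validated when delta_hat < 1.

Initial conditions are realized by simulating the model over the full dose
history (so the window inherits the correct internal state for everything
observed since the start of the record) plus the bounded w refinement that
covers pre-record dosing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DoseResponseSeries, Model, PrioriSet, SemiBlindModel, simulate

__all__ = ["NUM_FLOOR", "InvalidationOutcome", "nominal_window_response",
           "invalidate", "validation_window"]

#: Guard against zero-energy denominators in the cumulative-norm ratios.
NUM_FLOOR = 1e-9


@dataclass
class InvalidationOutcome:
    """Certificate of a model-(in)validation test on one window.

    delta_hat is a certified upper bound on the minimal uncertainty norm that
    reconciles model and data; validated means delta_hat < 1.  eta_hat and
    w_hat are the admissible noise and initial-condition-effect certificates;
    ratios holds the per-step cumulative-norm ratios whose maximum is
    delta_hat.  degenerate flags a window whose explained signal has (near)
    zero energy while a residual remains.
    """

    delta_hat: float
    validated: bool
    eta_hat: np.ndarray
    w_hat: np.ndarray
    window: tuple[int, int]
    ratios: np.ndarray
    degenerate: bool = False


def nominal_window_response(model: Model | SemiBlindModel,
                            series: DoseResponseSeries,
                            window: slice) -> np.ndarray:
    """Model response over ``window``, simulated from the full dose history.

    Simulating from the start of the record realizes the initial-condition
    term of the window without estimating past inputs.
    """
    start, stop, _ = window.indices(len(series))
    if stop > len(series):
        raise ValueError("window extends beyond the series")
    if isinstance(model, SemiBlindModel):
        model = model.reduced
    full = simulate(model, series.dose[:stop])
    return full[start:stop]


def invalidate(model: Model | SemiBlindModel, series: DoseResponseSeries,
               window: slice, priors: PrioriSet) -> InvalidationOutcome:
    """Run the (in)validation test for ``model`` on ``series[window]``."""
    start, stop, _ = window.indices(len(series))
    M_t = stop - start
    if M_t < 1:
        raise ValueError("validation window must contain at least one sample")
    y = series.deviation[start:stop]
    s0 = nominal_window_response(model, series, window)

    # (i) initial-condition certificate: box-constrained least squares on the
    # residual is a clip onto the box
    box = priors.ic_bound
    w = np.clip(y - s0, -box, box)
    # (ii) admissible-noise certificate
    eta = np.clip(y - s0 - w, -priors.epsilon, priors.epsilon)
    # (iii) explained signal and unexplained residual
    s = s0 + w + eta
    rho = y - s
    # (iv) causal cumulative-norm ratios
    cum_s = np.sqrt(np.cumsum(s**2))
    cum_rho = np.sqrt(np.cumsum(rho**2))
    degenerate = bool(cum_s[-1] <= NUM_FLOOR and cum_rho[-1] > NUM_FLOOR)
    ratios = cum_rho / np.maximum(cum_s, NUM_FLOOR)
    delta_hat = float("inf") if degenerate else float(np.max(ratios))
    return InvalidationOutcome(
        delta_hat=delta_hat,
        validated=bool(delta_hat < 1.0),
        eta_hat=eta,
        w_hat=w,
        window=(start, stop),
        ratios=ratios,
        degenerate=degenerate,
    )


def validation_window(series: DoseResponseSeries, t_now: int, M_t: int) -> slice:
    """Half-open index window [t_now - M_t, t_now) of the most recent M_t
    samples; slides forward by one as each new sample arrives."""
    if M_t < 1:
        raise ValueError("M_t must be positive")
    if t_now < M_t:
        raise ValueError("insufficient data for the validation window")
    return slice(t_now - M_t, t_now)
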