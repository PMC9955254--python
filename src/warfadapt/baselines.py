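"""Recursive ARX/ARMAX identification with Kalman-filter parameter tracking.

Comparison methods for the semi-blind adaptive framework.  The model
coefficients theta = (a_1..a_na, b_1..b_nb[, c_1..c_nc]) follow a random-walk
state model with process-noise scale q; each new sample updates theta through
the standard Kalman recursion driven by the one-step prediction error.  With
q = 0 the recursion is exactly recursive least squares and converges to the
batch least-squares estimate.  ARMAX feeds past innovations back into the
regressor (pseudolinear recursion); by default the posterior residual (after
the parameter update) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import DoseResponseSeries

__all__ = ["RecursiveEstimatorState", "regressor", "kf_update", "run_recursive"]


@dataclass
class RecursiveEstimatorState:
    theta: np.ndarray
    P: np.ndarray
    q: float = 1e-4            # random-walk drift of theta
    r_v: float = 0.01          # measurement-noise variance
    residuals: list = field(default_factory=list)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.theta)
        if self.P.shape != (n, n):
            raise ValueError("P must be square with len(theta) rows")

    @classmethod
    def initial(cls, n_par: int, q: float = 1e-4, r_v: float = 0.01,
                P0: float = 1e6) -> "RecursiveEstimatorState":
        return cls(theta=np.zeros(n_par), P=P0 * np.eye(n_par), q=q, r_v=r_v)


def regressor(y_hist, u_hist, e_hist, na: int, nb: int, nc: int = 0,
              t: int | None = None) -> np.ndarray:
    """Regression vector phi(t) for predicting y(t).

    phi = [-y(t-1)..-y(t-na), u(t-1)..u(t-nb), e(t-1)..e(t-nc)]; ``t``
    defaults to len(y_hist) (predict the next sample).
    """
    y = np.asarray(y_hist, dtype=float)
    u = np.asarray(u_hist, dtype=float)
    e = np.asarray(e_hist, dtype=float)
    if t is None:
        t = len(y)
    if t < na or t < nb or (nc and t < nc):
        raise ValueError("insufficient history for the requested orders")
    phi = np.concatenate([
        -y[t - na : t][::-1],
        u[t - nb : t][::-1],
        e[t - nc : t][::-1] if nc else np.zeros(0),
    ])
    return phi


def kf_update(state: RecursiveEstimatorState, phi: np.ndarray, y_obs: float):
    """One Kalman update of the random-walk parameter model.

    Returns (state, y_pred) where y_pred = phi . theta uses the *prior*
    parameters (a genuine one-step-ahead prediction).
    """
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(phi)) and np.isfinite(y_obs)):
        raise ValueError("non-finite input to kf_update")
    if len(phi) != len(state.theta):
        raise ValueError("regressor length does not match parameter count")
    n = len(state.theta)
    P = state.P + state.q * np.eye(n)
    y_pred = float(phi @ state.theta)
    denom = float(phi @ P @ phi) + state.r_v
    K = (P @ phi) / denom
    state.theta = state.theta + K * (y_obs - y_pred)
    # Joseph-stabilized covariance update (algebraically (I - K phi^T) P);
    # keeps P symmetric positive definite even for the diffuse-prior limit
    M = np.eye(n) - np.outer(K, phi)
    P = M @ P @ M.T + state.r_v * np.outer(K, K)
    state.P = (P + P.T) / 2.0
    return state, y_pred


def run_recursive(series: DoseResponseSeries, na: int = 6, nb: int = 6,
                  nc: int = 0, q: float = 1e-4, r_v: float | None = None,
                  P0: float = 1e6, posterior_residuals: bool = True):
    """Sequential one-step-ahead prediction over a patient record.

    Signals are baseline-removed for estimation; predictions are returned on
    the raw INR scale.  ARMAX (nc > 0) feeds residuals back into the
    regressor.  Returns (predictions with NaN before the first prediction,
    mmse over the predicted span, final state).
    """
    start = max(na, nb, nc)
    if len(series) <= start:
        raise ValueError("series too short for the requested orders")
    if r_v is None:
        r_v = 0.01
    y = series.deviation
    u = series.dose
    state = RecursiveEstimatorState.initial(na + nb + nc, q=q, r_v=r_v, P0=P0)
    preds = np.full(len(series), np.nan)
    e_hist: list = [0.0] * start
    for t in range(start, len(series)):
        phi = regressor(y[:t], u[:t], e_hist, na, nb, nc, t=t)
        state, y_pred = kf_update(state, phi, float(y[t]))
        preds[t] = y_pred + series.inr_baseline
        if posterior_residuals:
            e_hist.append(float(y[t] - phi @ state.theta))
        else:
            e_hist.append(float(y[t] - y_pred))
    mask = ~np.isnan(preds)
    mmse = float(np.mean((preds[mask] - series.inr[mask]) ** 2))
    return preds, mmse, state
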