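"""Core data types and discrete-time LTI machinery for dose-response modeling.

Everything downstream (identification, invalidation, adaptation, baselines)
works with daily warfarin dose as input and INR *deviation from the drug-free
baseline* as output, on a uniform one-day grid.  This module provides the
containers for patient records, prior (a-priori) information, and models, plus
the Toeplitz/Hankel operator algebra, impulse-response extraction, simulation,
Ho-Kalman realization, modal/balanced order reduction, and the one-step-ahead
difference-equation predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence, Union

import numpy as np
import scipy.linalg as sla

__all__ = [
    "POLE_TOL",
    "RANK_TOL_REL",
    "DoseResponseSeries",
    "PrioriSet",
    "TransferFunctionModel",
    "StateSpaceModel",
    "SemiBlindModel",
    "StabilityMargin",
    "toeplitz_of",
    "hankel_of",
    "impulse_response",
    "simulate",
    "realize_ss",
    "fir_realization",
    "parallel",
    "reduce_order",
    "stability_margin",
    "one_step_predict",
]

#: Poles with magnitude >= 1 - POLE_TOL are treated as marginal: they are
#: retained exactly by order reduction and flagged by stability_margin.
POLE_TOL = 1e-6

#: Relative singular-value cutoff for the Ho-Kalman realization rank decision.
RANK_TOL_REL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseSeries:
    """Per-patient uniform-grid record of daily warfarin dose and measured INR.

    Parameters
    ----------
    patient_id
        Free-form identifier.
    day
        Strictly increasing integer day index with unit steps.
    dose
        Administered dose in mg/day, one value per day, nonnegative.
    inr
        Measured INR (dimensionless, > 0), one value per day.
    inr_baseline
        Drug-free INR level subtracted before modeling (default 1.0).
    """

    patient_id: str
    day: np.ndarray
    dose: np.ndarray
    inr: np.ndarray
    inr_baseline: float = 1.0

    def __post_init__(self):
        day = np.asarray(self.day, dtype=int)
        dose = np.asarray(self.dose, dtype=float)
        inr = np.asarray(self.inr, dtype=float)
        if not (len(day) == len(dose) == len(inr)):
            raise ValueError("day, dose and inr must have equal length")
        if len(day) and np.any(np.diff(day) != 1):
            raise ValueError("day grid must be strictly increasing with unit steps")
        if np.any(dose < 0):
            raise ValueError("dose must be nonnegative")
        if np.any(inr <= 0):
            raise ValueError("inr must be positive")
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "inr", inr)

    def __len__(self) -> int:
        return len(self.day)

    @property
    def deviation(self) -> np.ndarray:
        """INR with the drug-free baseline removed (the modeled output)."""
        return self.inr - self.inr_baseline


@dataclass(frozen=True)
class PrioriSet:
    """A-priori information defining the consistency set for identification.

    K
        Maximum model gain (bound on the scaled Toeplitz operator norm).
    r
        Stability margin in (0, 1]: candidate impulse responses decay at
        least like ``r**k``.
    epsilon
        ell-infinity bound on the INR measurement noise.
    gamma
        Gain bounding the effect of unobserved past inputs.
    K_u
        Bound on the norm of the unobserved past input sequence.
    """

    K: float
    r: float
    epsilon: float
    gamma: float
    K_u: float

    def __post_init__(self):
        for name in ("K", "r", "epsilon", "gamma", "K_u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior {name} must be positive")
        if self.r > 1:
            raise ValueError("stability margin r must lie in (0, 1]")

    @property
    def ic_bound(self) -> float:
        """Elementwise bound gamma*K_u on the initial-condition response."""
        return self.gamma * self.K_u


@dataclass(frozen=True)
class TransferFunctionModel:
    """Discrete transfer function num(z)/den(z), coefficients in descending
    powers of z, monic denominator."""

    num: np.ndarray
    den: np.ndarray

    def __post_init__(self):
        num = np.atleast_1d(np.asarray(self.num, dtype=float))
        den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if den.size == 0:
            raise ValueError("denominator must be non-empty")
        if len(num) > len(den):
            raise ValueError("improper transfer function: len(num) > len(den)")
        if abs(den[0] - 1.0) > 1e-12:
            if den[0] == 0:
                raise ValueError("denominator leading coefficient is zero")
            num = num / den[0]
            den = den / den[0]
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)

    @property
    def order(self) -> int:
        return len(self.den) - 1

    def poles(self) -> np.ndarray:
        return np.roots(self.den) if self.order else np.array([])

    def dc_gain(self) -> float:
        return float(np.polyval(self.num, 1.0) / np.polyval(self.den, 1.0))


@dataclass(frozen=True)
class StateSpaceModel:
    """Discrete state-space model (A, B, C, D), single input single output."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValueError("A must be square")
        if n:
            B = np.asarray(self.B, dtype=float).reshape(n, -1)
            C = np.asarray(self.C, dtype=float).reshape(-1, n)
        else:
            B = np.zeros((0, 1))
            C = np.zeros((1, 0))
        D = np.atleast_2d(np.asarray(self.D, dtype=float))
        if B.shape[1] != D.shape[1] or C.shape[0] != D.shape[0]:
            raise ValueError("inconsistent state-space dimensions")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "D", D)

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def poles(self) -> np.ndarray:
        return np.linalg.eigvals(self.A) if self.order else np.array([])

    def to_tf(self) -> TransferFunctionModel:
        if self.order == 0:
            return TransferFunctionModel(num=np.atleast_1d(self.D.ravel()[0]),
                                         den=np.array([1.0]))
        from scipy.signal import ss2tf

        num, den = ss2tf(self.A, self.B, self.C, self.D)
        return TransferFunctionModel(num=np.atleast_1d(num[0]), den=den)


Model = Union[TransferFunctionModel, StateSpaceModel]


@dataclass
class SemiBlindModel:
    """Result container of the semi-blind identification.

    ``g`` is the nonparametric impulse response (length ``N_t``), ``p`` the
    scalar weight on the parametric integrator whose fixed impulse response is
    ``P_basis`` (all ones), and ``w_hat`` the estimated initial-condition
    response over the identification window.  ``realization`` is the parallel
    interconnection p*integrator + realize_ss(g); ``reduced`` a reduced-order
    version of it (initially identical).
    """

    g: np.ndarray
    p: float
    P_basis: np.ndarray
    w_hat: np.ndarray
    achieved_noise: float
    realization: StateSpaceModel
    reduced: StateSpaceModel
    N_t: int

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.P_basis = np.asarray(self.P_basis, dtype=float)
        self.w_hat = np.asarray(self.w_hat, dtype=float)
        if len(self.g) != self.N_t:
            raise ValueError("len(g) must equal N_t")
        if self.achieved_noise < 0:
            raise ValueError("achieved_noise must be nonnegative")
        if self.reduced.order > self.realization.order:
            raise ValueError("reduced order exceeds full order")

    def full_impulse(self, N: int) -> np.ndarray:
        """Impulse response of the combined model: p*P + g over N steps."""
        g = np.zeros(N)
        m = min(N, len(self.g))
        g[:m] = self.g[:m]
        P = np.ones(N)
        return self.p * P + g


# ---------------------------------------------------------------------------
# operator algebra
# ---------------------------------------------------------------------------

def toeplitz_of(h: Sequence[float], N: int) -> np.ndarray:
    """Lower-triangular Toeplitz (causal convolution) operator of ``h``.

    Entry (i, j) equals ``h[i-j]`` for i >= j and 0 above the diagonal, so
    ``toeplitz_of(h, N) @ u`` is the causal convolution of ``h`` with ``u``.
    ``h`` is zero-padded or truncated to length ``N``.
    """
    if N < 1:
        raise ValueError("N must be positive")
    h = np.asarray(h, dtype=float)
    col = np.zeros(N)
    col[: min(N, len(h))] = h[:N]
    row = np.zeros(N)
    row[0] = col[0]
    return sla.toeplitz(col, row)


def hankel_of(h: Sequence[float], N: int, L: int) -> np.ndarray:
    """N x L Hankel operator mapping past inputs to the free response.

    Entry (i, j) equals ``h[i+j+1]`` (zero beyond the available length), so
    row i of ``hankel_of(h, N, L) @ u_past`` is sum_j h[i+j+1]*u_past[j],
    where ``u_past[j]`` is the input j+1 steps before time zero.
    """
    if N < 1 or L < 1:
        raise ValueError("N and L must be positive")
    h = np.asarray(h, dtype=float)
    hp = np.zeros(N + L)
    m = min(len(h), N + L)
    hp[:m] = h[:m]
    col = hp[1 : N + 1]
    row = hp[N : N + L]
    return sla.hankel(col, row)


def impulse_response(model: Model, N: int) -> np.ndarray:
    """First N impulse-response coefficients h_0..h_{N-1} of a model."""
    if N < 1:
        raise ValueError("N must be positive")
    if isinstance(model, SemiBlindModel):
        model = model.realization
    if isinstance(model, StateSpaceModel):
        h = np.zeros(N)
        h[0] = model.D.ravel()[0]
        if model.order:
            x = model.B[:, 0].copy()
            for i in range(1, N):
                h[i] = float(model.C[0] @ x)
                x = model.A @ x
        return h
    num = model.num
    den = model.den
    if den.size == 0:
        raise ValueError("empty denominator")
    na = len(den) - 1
    b = np.zeros(na + 1)
    b[na + 1 - len(num):] = num
    h = np.zeros(N)
    for t in range(N):
        acc = b[t] if t <= na else 0.0
        for j in range(1, min(t, na) + 1):
            acc -= den[j] * h[t - j]
        h[t] = acc
    return h


def simulate(model: Model, u: Sequence[float],
             w: Sequence[float] | None = None) -> np.ndarray:
    """Causal response of ``model`` to input ``u`` plus an optional additive
    free-response sequence ``w`` (e.g. an initial-condition effect)."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("input must be finite")
    N = len(u)
    if N == 0:
        return np.zeros(0)
    h = impulse_response(model, N)
    y = toeplitz_of(h, N) @ u
    if w is not None:
        w = np.asarray(w, dtype=float)
        if len(w) != N:
            raise ValueError("free-response length must match input length")
        y = y + w
    return y


# ---------------------------------------------------------------------------
# realization and order reduction
# ---------------------------------------------------------------------------

def realize_ss(g: Sequence[float], tol: float | None = None,
               tol_abs: float = 0.0) -> StateSpaceModel:
    """Ho-Kalman / ERA state-space realization from impulse coefficients.

    The Markov parameters g_1.. are arranged in the largest Hankel/shifted-
    Hankel pair the data supports (no zero padding, so the realized order is
    at most floor((len(g)-1)/2)); the numerical rank at ``tol`` (relative to
    the largest singular value), or at the absolute scale ``tol_abs`` when
    the coefficients carry known uncertainty, sets the state dimension.  For
    systems whose true order is within that bound the realization reproduces
    ``g`` exactly up to roundoff.
    """
    g = np.asarray(g, dtype=float)
    if len(g) < 2:
        raise ValueError("need at least two impulse coefficients")
    D = g[0]
    q = len(g) - 1
    markov = g[1:]
    if not np.any(markov != 0.0):
        return StateSpaceModel(A=np.zeros((0, 0)), B=np.zeros((0, 1)),
                               C=np.zeros((1, 0)), D=np.array([[D]]))
    a = (q + 1) // 2
    b = q - a
    if b < 1:
        a, b = 1, 1  # q == 1: single Markov parameter
        H = np.array([[markov[0]]])
        H2 = np.array([[0.0]])
    else:
        H = sla.hankel(markov[:a], markov[a - 1 : a + b - 1])
        H2 = sla.hankel(markov[1 : a + 1], markov[a : a + b])
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    if tol is None:
        tol = RANK_TOL_REL
    n = int(np.sum(s > max(tol * s[0], tol_abs)))
    if n == 0:
        return StateSpaceModel(A=np.zeros((0, 0)), B=np.zeros((0, 1)),
                               C=np.zeros((1, 0)), D=np.array([[D]]))
    U, s, Vt = U[:, :n], s[:n], Vt[:n]
    sq = np.sqrt(s)
    obs = U * sq          # a x n observability factor
    con = (Vt.T * sq).T   # n x b controllability factor
    A = np.diag(1.0 / sq) @ U.T @ H2 @ Vt.T @ np.diag(1.0 / sq)
    B = con[:, :1]
    C = obs[:1, :]
    return StateSpaceModel(A=A, B=B, C=C, D=np.array([[D]]))


def fir_realization(g: Sequence[float]) -> StateSpaceModel:
    """Exact shift-register realization of a finite impulse response.

    Order len(g) - 1, nilpotent (all poles at zero, hence stable), impulse
    response exactly ``g`` followed by zeros.  This is the full-order
    realization of an identified impulse-response window: with N_t
    coefficients it has order N_t - 1.
    """
    g = np.asarray(g, dtype=float)
    if len(g) < 1:
        raise ValueError("need at least one coefficient")
    n = len(g) - 1
    if n == 0:
        return StateSpaceModel(A=np.zeros((0, 0)), B=np.zeros((0, 1)),
                               C=np.zeros((1, 0)), D=np.array([[g[0]]]))
    A = np.diag(np.ones(n - 1), -1)
    B = np.zeros((n, 1))
    B[0, 0] = 1.0
    C = g[1:].reshape(1, n)
    return StateSpaceModel(A=A, B=B, C=C, D=np.array([[g[0]]]))


def parallel(m1: StateSpaceModel, m2: StateSpaceModel) -> StateSpaceModel:
    """Parallel interconnection: output is the sum of both outputs."""
    A = sla.block_diag(m1.A, m2.A)
    B = np.vstack([m1.B, m2.B])
    C = np.hstack([m1.C, m2.C])
    D = m1.D + m2.D
    return StateSpaceModel(A=A, B=B, C=C, D=D)


def _split_marginal(ss: StateSpaceModel, pole_tol: float):
    """Block-diagonalize into (marginal, stable) subsystems via a sorted real
    Schur form; returns (marginal StateSpaceModel, stable StateSpaceModel)."""
    n = ss.order
    T, Z, sdim = sla.schur(
        ss.A, output="real",
        sort=lambda re, im: np.hypot(re, im) >= 1.0 - pole_tol,
    )
    k = int(sdim)  # marginal modes lead
    Bt = Z.T @ ss.B
    Ct = ss.C @ Z
    if k in (0, n):
        sub = StateSpaceModel(A=T, B=Bt, C=Ct, D=np.zeros((1, 1)))
        empty = StateSpaceModel(A=np.zeros((0, 0)), B=np.zeros((0, 1)),
                                C=np.zeros((1, 0)), D=np.zeros((1, 1)))
        return (sub, empty) if k == n else (empty, sub)
    T11, T12, T22 = T[:k, :k], T[:k, k:], T[k:, k:]
    # decouple: X solves T11 X - X T22 = -T12, similarity kills the coupling
    X = sla.solve_sylvester(T11, -T22, -T12)
    B1 = Bt[:k] + X @ Bt[k:]
    B2 = Bt[k:]
    C1 = Ct[:, :k]
    C2 = Ct[:, k:] - C1 @ X
    marg = StateSpaceModel(A=T11, B=B1, C=C1, D=np.zeros((1, 1)))
    stab = StateSpaceModel(A=T22, B=B2, C=C2, D=np.zeros((1, 1)))
    return marg, stab


def _balanced_truncate_stable(ss: StateSpaceModel, k: int) -> StateSpaceModel:
    """Balanced truncation of an asymptotically stable system to order k."""
    n = ss.order
    if k >= n:
        return ss
    if k <= 0:
        return StateSpaceModel(A=np.zeros((0, 0)), B=np.zeros((0, 1)),
                               C=np.zeros((1, 0)), D=ss.D)
    Wc = sla.solve_discrete_lyapunov(ss.A, ss.B @ ss.B.T)
    Wo = sla.solve_discrete_lyapunov(ss.A.T, ss.C.T @ ss.C)
    # square-root balancing
    Lc = _chol_psd(Wc)
    Lo = _chol_psd(Wo)
    U, s, Vt = np.linalg.svd(Lo.T @ Lc)
    s = np.maximum(s, 1e-300)
    sq = np.sqrt(s)
    Ti = Lc @ Vt.T / sq       # balancing transform (state = Ti @ balanced)
    T = (U / sq).T @ Lo.T
    Ab = T @ ss.A @ Ti
    Bb = T @ ss.B
    Cb = ss.C @ Ti
    return StateSpaceModel(A=Ab[:k, :k], B=Bb[:k], C=Cb[:, :k], D=ss.D)


def _chol_psd(W: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a (numerically) positive semidefinite matrix."""
    W = (W + W.T) / 2.0
    try:
        return np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(W)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def reduce_order(ss: StateSpaceModel, O: int,
                 pole_tol: float = POLE_TOL) -> StateSpaceModel:
    """Reduce a state-space model to order at most ``O``.

    Modes with pole magnitude >= 1 - pole_tol (integrators and other marginal
    dynamics) are retained exactly; the remaining asymptotically stable part
    is balanced-truncated to fill the order budget.  Raises if the marginal
    modes alone already exceed ``O``.
    """
    if O < 1:
        raise ValueError("target order must be at least 1")
    if ss.order <= O:
        return ss
    marg, stab = _split_marginal(ss, pole_tol)
    if marg.order > O:
        raise ValueError(
            f"cannot reduce to order {O}: {marg.order} marginal modes "
            "(pole magnitude >= 1 - pole_tol) must be retained"
        )
    stab_red = _balanced_truncate_stable(stab, O - marg.order)
    out = parallel(marg, stab_red)
    return StateSpaceModel(A=out.A, B=out.B, C=out.C, D=ss.D)


class StabilityMargin(NamedTuple):
    margin: float
    marginal: bool


def stability_margin(model: Model, pole_tol: float = POLE_TOL) -> StabilityMargin:
    """Largest pole magnitude of a model and whether it is (near-)marginal."""
    if isinstance(model, SemiBlindModel):
        model = model.realization
    poles = model.poles()
    margin = float(np.max(np.abs(poles))) if len(poles) else 0.0
    return StabilityMargin(margin=margin, marginal=margin >= 1.0 - pole_tol)


# ---------------------------------------------------------------------------
# one-step-ahead prediction
# ---------------------------------------------------------------------------

def one_step_predict(model: Model, y_hist: Sequence[float],
                     u_hist: Sequence[float],
                     inr_baseline: float = 1.0) -> float:
    """One-step-ahead INR prediction from measured history.

    ``y_hist`` holds measured INR up to time t; ``u_hist`` holds doses up to
    and including time t+1 (the next administered dose is known).  The
    difference equation of the model is driven by *measured* past outputs
    (ARX-style), on baseline-removed signals; the baseline is re-added.
    """
    if isinstance(model, SemiBlindModel):
        model = model.reduced
    if isinstance(model, StateSpaceModel):
        model = model.to_tf()
    y = np.asarray(y_hist, dtype=float) - inr_baseline
    u = np.asarray(u_hist, dtype=float)
    den = model.den
    na = len(den) - 1
    if len(y) < na:
        raise ValueError("insufficient output history for the model order")
    if len(u) != len(y) + 1:
        raise ValueError("u_hist must extend one step past y_hist")
    b = np.zeros(na + 1)
    b[na + 1 - len(model.num):] = model.num
    t1 = len(y)  # index of the predicted sample
    acc = 0.0
    for i in range(1, na + 1):
        acc -= den[i] * y[t1 - i]
    for j in range(0, na + 1):
        if t1 - j >= 0:
            acc += b[j] * u[t1 - j]
    return float(acc + inr_baseline)
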