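"""SIR dynamics with logistic recruitment of susceptibles.

The compartments track forum authors on one topic: S(t) are users who might
start posting (susceptibles), I(t) are currently active authors
(infectives), R(t) are past authors whose posts have lost influence
(recovered).  Unlike the classical closed-population SIR model, the
susceptible pool is replenished by logistic growth of the total population
N = S + I + R toward a carrying capacity K — the largest author pool the
topic can recruit:

    dS/dt = mu * ((K - N)/K) * N - alpha * S * I
    dI/dt = alpha * S * I - beta * I
    dR/dt = beta * I

All rates are per month; the observation grid is integer months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SIRParams",
    "InitialState",
    "Trajectory",
    "sir_rhs",
    "simulate",
    "effective_reproduction_ratio",
]

#: Largest negative compartment excursion tolerated before the integration
#: is declared failed; smaller excursions are clipped to zero.
NEGATIVITY_ABORT = -1e-6


@dataclass(frozen=True)
class SIRParams:
    """Rate parameters of the model.

    alpha : infection rate per susceptible-infective contact pair per month
            (probability that reading a post leads to authoring one).
    beta  : recovery rate per infective per month (probability that an
            author's posts lose infectivity).
    mu    : logistic recruitment rate of the author pool per month; unlike
            alpha and beta it may exceed 1.
    K     : carrying capacity — the highest total number of authors the
            topic can recruit.
    """

    alpha: float
    beta: float
    mu: float
    K: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.alpha, self.beta, self.mu, self.K)):
            raise ValueError("SIR parameters must be finite")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")
        if self.mu < 0.0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")
        if self.K <= 0.0:
            raise ValueError(f"K must be positive, got {self.K}")


@dataclass(frozen=True)
class InitialState:
    """Compartment sizes at t = 0.

    N0 = S0 + I0 + R0 may exceed K in simulation (the logistic term turns
    negative and the population shrinks toward K); the fitter enforces
    N0 <= K on its candidates.
    """

    S0: float
    I0: float
    R0: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.S0, self.I0, self.R0)):
            raise ValueError("initial state must be finite")
        if min(self.S0, self.I0, self.R0) < 0.0:
            raise ValueError("initial compartments must be non-negative")

    @property
    def N0(self) -> float:
        return self.S0 + self.I0 + self.R0


@dataclass
class Trajectory:
    """Compartment sizes evaluated on a time grid (months)."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    N: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if not len(self.t) == len(self.S) == len(self.I) == len(self.R):
            raise ValueError("t, S, I, R must share one grid")
        if self.N is None:
            self.N = self.S + self.I + self.R
        else:
            self.N = np.asarray(self.N, dtype=float)


class SimulationError(RuntimeError):
    """Raised when the integrator fails or a compartment goes negative."""

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


def sir_rhs(
    state: tuple[float, float, float] | np.ndarray, params: SIRParams
) -> tuple[float, float, float]:
    """Right-hand side (dS/dt, dI/dt, dR/dt) of the model at one state.

    The susceptible inflow is the logistic recruitment mu*((K-N)/K)*N; the
    infection flow alpha*S*I moves authors from S to I; the recovery flow
    beta*I moves them from I to R.
    """
    S, I, R = (float(x) for x in state)
    if not all(math.isfinite(v) for v in (S, I, R)):
        raise ValueError(f"non-finite state {state!r}")
    N = S + I + R
    recruit = params.mu * ((params.K - N) / params.K) * N
    infect = params.alpha * S * I
    recover = params.beta * I
    return recruit - infect, infect - recover, recover


def simulate(
    params: SIRParams,
    init: InitialState,
    horizon: int,
    *,
    euler: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the model from t=0 to t=horizon, reporting integer months.

    The default integrator is scipy's adaptive explicit Runge-Kutta
    (RK45).  ``euler=True`` instead steps the discrete-time variant with
    Delta-t = 1 month, for comparison with difference-equation treatments.

    Raises
    ------
    SimulationError
        If the integrator fails, or a compartment dips below -1e-6 (the
        exact system preserves non-negativity, so a large excursion signals
        integrator failure rather than model behaviour).  Excursions in
        (-1e-6, 0) are clipped to zero.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    t_eval = np.arange(horizon + 1, dtype=float)

    if euler:
        states = np.empty((horizon + 1, 3))
        states[0] = (init.S0, init.I0, init.R0)
        for k in range(horizon):
            d = sir_rhs(states[k], params)
            states[k + 1] = states[k] + np.asarray(d)
        ys = states.T
    else:
        sol = solve_ivp(
            lambda _t, y: sir_rhs(y, params),
            (0.0, float(horizon)),
            [init.S0, init.I0, init.R0],
            t_eval=t_eval,
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={sol.t[-1]:.4f}: {sol.message}",
                failure_time=float(sol.t[-1]),
            )
        ys = sol.y

    if ys.min() < NEGATIVITY_ABORT:
        k = int(np.argwhere(ys < NEGATIVITY_ABORT)[0, 1])
        raise SimulationError(
            f"compartment fell below {NEGATIVITY_ABORT} at t={t_eval[k]:g}",
            failure_time=float(t_eval[k]),
        )
    ys = np.clip(ys, 0.0, None)
    return Trajectory(t=t_eval, S=ys[0], I=ys[1], R=ys[2])


def effective_reproduction_ratio(params: SIRParams, S0: float) -> float:
    """Average number of secondary infections per infective, alpha*S0/beta.

    By the epidemic threshold principle, a value above 1 predicts initial
    growth of I(t) (an outbreak of the topic); below 1 predicts die-out.
    """
    if params.beta == 0.0:
        raise ValueError(
            "reproduction ratio undefined for beta = 0 (I never recovers)"
        )
    return params.alpha * S0 / params.beta
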