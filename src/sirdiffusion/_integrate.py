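"""Vectorized fixed-step RK4 integration of whole candidate populations.

The genetic algorithm evaluates population_size * generations candidate
parameter vectors, each requiring a forward simulation.  Integrating every
candidate separately through the adaptive solver would dominate the run
time, so candidates are integrated simultaneously: the state is a (3, m)
array and one classical RK4 step advances all m trajectories at once.

A fixed step of h = 0.1 month keeps the per-month error orders of
magnitude below the observation noise for feasible parameters; wild
candidates that blow up numerically yield non-finite values and are
reported as failed rather than aborting the sweep.
"""

from __future__ import annotations

import math

import numpy as np

DEFAULT_STEP = 0.1


def _rhs(S, I, R, alpha, beta, mu, K):
    N = S + I + R
    recruit = mu * ((K - N) / K) * N
    infect = alpha * S * I
    recover = beta * I
    return recruit - infect, infect - recover, recover


def _integrate_single(
    alpha: float,
    beta: float,
    mu: float,
    K: float,
    S0: float,
    I0: float,
    R0: float,
    horizon: int,
    step: float,
) -> np.ndarray:
    """Scalar twin of the population integrator (same operation order).

    scipy's simplex polish evaluates one candidate at a time; running the
    array path for a single trajectory is dominated by per-operation
    overhead, so this plain-float loop exists purely for speed.  It mirrors
    the vector path operation for operation, giving bit-identical output.
    """
    S, I, R = float(S0), float(I0), float(R0)
    steps_per_month = int(round(1.0 / step))
    h = 1.0 / steps_per_month
    out = np.empty(horizon + 1)
    out[0] = I

    def rhs(S, I, R):
        N = S + I + R
        recruit = mu * ((K - N) / K) * N
        infect = alpha * S * I
        recover = beta * I
        return recruit - infect, infect - recover, recover

    h6 = h / 6.0
    for month in range(1, horizon + 1):
        for _ in range(steps_per_month):
            a1, b1, c1 = rhs(S, I, R)
            a2, b2, c2 = rhs(S + 0.5 * h * a1, I + 0.5 * h * b1, R + 0.5 * h * c1)
            a3, b3, c3 = rhs(S + 0.5 * h * a2, I + 0.5 * h * b2, R + 0.5 * h * c2)
            a4, b4, c4 = rhs(S + h * a3, I + h * b3, R + h * c3)
            S = S + h6 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            I = I + h6 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            R = R + h6 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            if not (math.isfinite(S) and math.isfinite(I) and math.isfinite(R)):
                out[month:] = np.nan
                return out
            if S < 0.0:
                S = 0.0
            if I < 0.0:
                I = 0.0
            if R < 0.0:
                R = 0.0
        out[month] = I
    return out


def integrate_population(
    alpha: np.ndarray,
    beta: np.ndarray,
    mu: np.ndarray,
    K: np.ndarray,
    S0: np.ndarray,
    I0: float | np.ndarray,
    R0: float | np.ndarray,
    horizon: int,
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Return I(t) at integer months 0..horizon for every candidate.

    Parameters are 1-D arrays of equal length m (scalars broadcast).
    Output has shape (horizon + 1, m); candidates whose trajectory became
    non-finite carry NaN from the point of failure on.  Compartments are
    clipped at zero after every step, mirroring the clipping contract of
    the scalar simulator.
    """
    alpha, beta, mu, K, S0 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in (alpha, beta, mu, K, S0))
    )
    m = alpha.shape[0]
    S = S0.astype(float).copy()
    I = np.broadcast_to(np.asarray(I0, dtype=float), (m,)).copy()
    R = np.broadcast_to(np.asarray(R0, dtype=float), (m,)).copy()

    steps_per_month = int(round(1.0 / step))
    h = 1.0 / steps_per_month
    h6 = h / 6.0
    out = np.empty((horizon + 1, m))
    out[0] = I
    zero = 0.0

    with np.errstate(all="ignore"):
        for month in range(1, horizon + 1):
            for _ in range(steps_per_month):
                a1, b1, c1 = _rhs(S, I, R, alpha, beta, mu, K)
                a2, b2, c2 = _rhs(
                    S + 0.5 * h * a1, I + 0.5 * h * b1, R + 0.5 * h * c1,
                    alpha, beta, mu, K,
                )
                a3, b3, c3 = _rhs(
                    S + 0.5 * h * a2, I + 0.5 * h * b2, R + 0.5 * h * c2,
                    alpha, beta, mu, K,
                )
                a4, b4, c4 = _rhs(
                    S + h * a3, I + h * b3, R + h * c3, alpha, beta, mu, K
                )
                S = S + h6 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
                I = I + h6 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
                R = R + h6 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
                # clip negatives; NaN passes through np.maximum untouched
                np.maximum(S, zero, out=S)
                np.maximum(I, zero, out=I)
                np.maximum(R, zero, out=R)
            # overflow -> inf/NaN; make failure sticky at month granularity
            bad = ~(np.isfinite(S) & np.isfinite(I) & np.isfinite(R))
            if bad.any():
                S[bad] = I[bad] = R[bad] = np.nan
            out[month] = I
    return out
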