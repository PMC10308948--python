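"""Lotka-Volterra model algebra and simulators.

The community model couples logistic growth through the spent-medium
interaction matrix::

    dS_i/dt = r_i S_i (1 - (S_i - sum_{j != i} c_ij S_j) / K_i)

with ``c_ij < 0`` for inhibition. Setting all ``c_ij = 0`` recovers
independent logistic growth; holding partner *j* at its monoculture capacity
``K_j`` (the spent-medium limit) gives an effective logistic with capacity
``K_ij = K_i + c_ij K_j`` and rate ``r_ij = r_i K_ij / K_i``, so the ratio
``r_ij / K_ij = r_i / K_i`` is invariant under the model — the criterion the
consistency module tests.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import CFSMRecord, LogisticParams, LVSystem, ParameterError


def logistic_solution(params: LogisticParams, t) -> np.ndarray:
    """Closed-form logistic density at time(s) ``t`` (hours).

    The lag is a hard delay: density stays at ``S0`` for ``t < lag`` and
    follows ``K / (1 + (K/S0 - 1) e^{-r (t - lag)})`` afterwards (a
    numerically stable rewriting of the textbook closed form).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.full(t.shape, params.S0, dtype=float)
    m = t >= params.lag
    if np.any(m):
        expo = np.exp(-params.r * (t[m] - params.lag))
        out[m] = params.K / (1.0 + (params.K / params.S0 - 1.0) * expo)
    return out[0] if scalar else out


def interaction_coefficient(K_ij: float, K_i: float, K_j: float) -> float:
    """Spent-medium interaction coefficient ``c_ij = (K_ij - K_i) / K_j``.

    Negative = inhibition, positive = facilitation, zero = no effect of the
    context isolate's spent medium on the focal isolate's capacity.
    """
    if K_j <= 0:
        raise ParameterError(f"context carrying capacity must be > 0, got {K_j}")
    return (K_ij - K_i) / K_j


def lv_interaction_strength(c_ij: float, r_i: float, K_i: float) -> float:
    """Classical LV rate coefficient ``a_ij = c_ij r_i / K_i`` (1/h per OD600)."""
    if K_i <= 0:
        raise ParameterError(f"focal carrying capacity must be > 0, got {K_i}")
    return c_ij * r_i / K_i


def predict_cfsm_params(params_i: LogisticParams, c_ij: float, K_j: float,
                        context: str = "") -> CFSMRecord:
    """Predict the conditioned-growth parameters of isolate *i* in the spent
    medium of a context isolate with capacity ``K_j``.

    ``K_ij = K_i + c_ij K_j`` and ``r_ij = r_i K_ij / K_i``, so the returned
    record satisfies ``r_ij / K_ij = r_i / K_i`` exactly. A non-positive
    predicted capacity yields a suppressed-growth record (r = K = 0, flagged)
    rather than an exception.
    """
    K_ij = params_i.K + c_ij * K_j
    if K_ij <= 0:
        return CFSMRecord(focal=params_i.name, context=context, r=0.0, K=0.0,
                          suppressed=True)
    r_ij = params_i.r * K_ij / params_i.K
    return CFSMRecord(focal=params_i.name, context=context, r=r_ij, K=K_ij)


def simulate_lv(system: LVSystem, initial, t_grid, rtol: float = 1e-8,
                atol: float = 1e-10) -> np.ndarray:
    """Integrate the coupled community ODEs on ``t_grid`` (hours).

    Returns an array of shape ``(len(t_grid), n)`` of densities (OD600).
    Per-isolate lags are honoured by zeroing the whole growth term of isolate
    *i* for ``t < lag_i``; integration is split at the lag breakpoints so the
    adaptive stepper never straddles a discontinuity. Densities are clipped
    at zero on output (the dynamics cannot cross zero analytically).
    """
    initial = np.asarray(initial, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    n = system.n
    if initial.shape != (n,):
        raise ParameterError(f"initial densities must have length {n}")
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ParameterError("t_grid must be an increasing vector")

    r, K, lag = system.r, system.K, system.lag
    c_off = system.c.copy()
    np.fill_diagonal(c_off, 0.0)

    def make_rhs(active: np.ndarray):
        act = active.astype(float)

        def rhs(t, S):
            Sc = np.maximum(S, 0.0)
            inter = c_off @ Sc
            return act * r * Sc * (1.0 - (Sc - inter) / K)

        return rhs

    t0, t_end = t_grid[0], t_grid[-1]
    breaks = np.unique(lag[(lag > t0) & (lag < t_end)])
    edges = np.concatenate(([t0], breaks, [t_end]))

    out = np.empty((len(t_grid), n))
    # grid points exactly at t0 take the initial state
    out[t_grid == t0] = initial
    y = initial.copy()
    for a, b in zip(edges[:-1], edges[1:]):
        active = lag <= a + 1e-12
        pts = t_grid[(t_grid > a) & (t_grid <= b)]
        t_eval = np.union1d(pts, [b])  # always land on the edge to carry state
        sol = solve_ivp(make_rhs(active), (a, b), y, t_eval=t_eval,
                        rtol=rtol, atol=atol, method="RK45")
        if not sol.success:
            raise RuntimeError(
                f"LV integration failed on [{a}, {b}] for r={r}, K={K}, "
                f"c={system.c.tolist()}: {sol.message}"
            )
        if len(pts):
            out[np.isin(t_grid, pts)] = sol.y.T[np.isin(sol.t, pts)]
        y = sol.y[:, -1].copy()
    return np.maximum(out, 0.0)
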