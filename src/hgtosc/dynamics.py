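"""Exact time-dependent dynamics of the two-population model.

The abundances obey generalised Lotka-Volterra competition with an HGT
exchange term,

    dn_A/dt = n_A (r_A - a_11 n_A - a_12 n_B) + gamma n_A n_B,
    dn_B/dt = n_B (r_B - a_21 n_A - a_22 n_B) - gamma n_A n_B,

which in the canonical variables (p_A, N) with N = n_A + n_B,
p_A = n_A / N becomes replicator dynamics with a density-dependent
payoff and a dynamic total abundance:

    dp_A/dt = p_A (f_A - fbar),      dN/dt = N fbar,

    f_A = r_A - a_11 p_A N - (a_12 - gamma)(1 - p_A) N,
    f_B = r_B - (a_21 + gamma) p_A N - a_22 (1 - p_A) N,

with mean fitness fbar = p_A f_A + p_B f_B.  Oscillating environments
replace (r_A, r_B, gamma) by their instantaneous values r_i + rt_i(omega t),
gamma + gt(omega t).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .oscillation import OscillatorySpec
from .params import ModelParams, PopulationState, Trajectory

__all__ = [
    "IntegrationError",
    "fitness",
    "rhs_full",
    "rhs_counts",
    "integrate_full",
    "integrate_counts",
    "default_divergence_ceiling",
]

#: violations of p in [0,1] / N >= 0 below this are treated as integration
#: round-off; must sit above the integrator error scale (rtol 1e-9)
CLIP_TOL = 1e-8


class IntegrationError(RuntimeError):
    """Numerical integration failed (step-size collapse or invalid state)."""


def fitness(params: ModelParams, state, rate_overrides=None):
    """Density-dependent fitness (f_A, f_B) of the two populations.

    ``state`` is a :class:`PopulationState` or a pair ``(p_A, N)``.
    ``rate_overrides``, if given, supplies instantaneous
    ``(r_A, r_B, gamma)`` for a time-dependent environment.
    """
    if isinstance(state, PopulationState):
        p, N = state.p_A, state.N
    else:
        p, N = state
    if N < 0:
        raise ValueError(f"total abundance must be non-negative, got N={N}")
    if rate_overrides is not None:
        r_A, r_B, gamma = rate_overrides
    else:
        r_A, r_B, gamma = params.r_A, params.r_B, params.gamma
    f_A = r_A - params.a_11 * p * N - (params.a_12 - gamma) * (1.0 - p) * N
    f_B = r_B - (params.a_21 + gamma) * p * N - params.a_22 * (1.0 - p) * N
    return f_A, f_B


def rhs_full(t, y, params: ModelParams, osc: OscillatorySpec | None = None):
    """Right-hand side of the (p_A, N) system, constant or oscillating rates."""
    p, N = y
    rates = osc.rates_at(t, params) if osc is not None else None
    f_A, f_B = fitness(params, (p, N), rate_overrides=rates)
    fbar = p * f_A + (1.0 - p) * f_B
    return np.array([p * (f_A - fbar), N * fbar])


def rhs_counts(t, y, params: ModelParams, osc: OscillatorySpec | None = None):
    """Right-hand side in raw abundances (n_A, n_B); used as a cross-check."""
    n_A, n_B = y
    if osc is not None:
        r_A, r_B, gamma = osc.rates_at(t, params)
    else:
        r_A, r_B, gamma = params.r_A, params.r_B, params.gamma
    dn_A = n_A * (r_A - params.a_11 * n_A - params.a_12 * n_B) + gamma * n_A * n_B
    dn_B = n_B * (r_B - params.a_21 * n_A - params.a_22 * n_B) - gamma * n_A * n_B
    return np.array([dn_A, dn_B])


def default_divergence_ceiling(params: ModelParams) -> float:
    """Abundance ceiling signalling unbounded growth (the N/A regime)."""
    a_pos = [a for a in (params.a_11, params.a_12, params.a_21, params.a_22) if a > 0]
    return 1e6 * max(params.r_A, params.r_B) / min(a_pos)


def _make_grid(t_end: float, osc: OscillatorySpec | None) -> np.ndarray:
    if osc is not None:
        per_period = 40
        n = int(min(2e5, max(2000, per_period * t_end / osc.period)))
    else:
        n = 1000
    return np.linspace(0.0, t_end, n + 1)


def _clip(name, arr, lo, hi):
    low = np.min(arr)
    high = np.max(arr)
    if low < lo - CLIP_TOL or high > hi + CLIP_TOL:
        raise IntegrationError(
            f"{name} left its admissible range by more than round-off "
            f"(min={low}, max={high})"
        )
    return np.clip(arr, lo, hi)


def integrate_full(
    params: ModelParams,
    osc: OscillatorySpec | None,
    init: PopulationState,
    t_end: float,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
    n_max: float | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the exact (p_A, N) dynamics up to ``t_end``.

    Oscillating runs cap the integrator step at one twentieth of the
    environmental period so no oscillation is skipped.  Crossing the
    divergence ceiling ``n_max`` terminates the run with
    ``Trajectory.diverged = True`` (the coarse-grained N/A regime).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_max is None:
        n_max = default_divergence_ceiling(params)
    if t_eval is None:
        t_eval = _make_grid(t_end, osc)

    def event_diverge(t, y, *args):
        return y[1] - n_max

    event_diverge.terminal = True
    event_diverge.direction = 1

    max_step = osc.period / 20 if osc is not None else np.inf
    sol = solve_ivp(
        rhs_full,
        (0.0, t_end),
        [init.p_A, init.N],
        args=(params, osc),
        method=method,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        t_eval=t_eval,
        events=[event_diverge],
    )
    if sol.status == -1:
        raise IntegrationError(f"integration failed: {sol.message}")
    diverged = sol.status == 1
    times, p, N = sol.t, sol.y[0], sol.y[1]
    if diverged and sol.t_events[0].size:
        # append the crossing point so the trajectory records the event
        te = sol.t_events[0][0]
        if times.size == 0 or te > times[-1]:
            times = np.append(times, te)
            p = np.append(p, sol.y_events[0][0][0])
            N = np.append(N, sol.y_events[0][0][1])
    if times.size < 2:
        raise IntegrationError("integration terminated before producing output")
    p = _clip("p_A", p, 0.0, 1.0)
    N = _clip("N", N, 0.0, np.inf)
    return Trajectory(
        times=times,
        p_A=p,
        N=N,
        rate_mode="oscillating" if osc is not None else "constant",
        diverged=diverged,
    )


def integrate_counts(
    params: ModelParams,
    osc: OscillatorySpec | None,
    n0: tuple[float, float],
    t_end: float,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
):
    """Integrate the raw-abundance system; returns (times, n_A, n_B).

    Kept alongside :func:`integrate_full` so the two equivalent
    representations can be checked against each other.
    """
    if t_eval is None:
        t_eval = _make_grid(t_end, osc)
    max_step = osc.period / 20 if osc is not None else np.inf
    sol = solve_ivp(
        rhs_counts,
        (0.0, t_end),
        list(n0),
        args=(params, osc),
        method=method,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]
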