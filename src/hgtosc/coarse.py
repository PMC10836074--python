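"""Coarse-grained (slow-time) dynamics of the oscillating environment.

Averaging the fast environmental oscillations leaves autonomous
replicator dynamics in which each population's fitness gains an induced
term,

    phi_A = N (1 - p_A) xi,      phi_B = -N kappa p_A,

so the slow system is algebraically identical to the fixed-environment
system with effective between-population competition rates
a_12 - xi and a_21 + kappa.  For the single-allele scenario
(a_ij = a, gamma = 0) the stable coexistence equilibrium is

    N_c* = (r_B xi - r_A kappa) / (a (xi - kappa) + xi kappa),
    p_A* = (r_A a - r_B (a - xi)) / (r_B xi - r_A kappa),

valid when kappa < a (r_B/r_A - 1), xi > a (1 - r_A/r_B) and the
denominator is positive; a non-positive denominator is the N/A regime
where the averaged description predicts unbounded growth.

The slow variables do not share initial conditions with the full system:
the observed state is slow part plus an O(1/omega) oscillation, so the
slow initial condition solves

    p(0) = pbar(0) + pi_1(pbar(0), Nbar(0), 0)/omega,
    N(0) = Nbar(0) + v_1(pbar(0), Nbar(0), 0)/omega,

with the leading-order oscillating corrections obtained by the standard
averaging recipe (zero-mean tau-primitive of the oscillatory part of the
full right-hand side at frozen slow variables):

    pi_1 = pbar (1 - pbar) [hat(rt_A) - hat(rt_B) + Nbar hat(gt)],
    v_1  = Nbar [pbar hat(rt_A) + (1 - pbar) hat(rt_B)]

(the gt contribution cancels from the mean fitness because it enters
the two fitnesses antisymmetrically).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .dynamics import IntegrationError, default_divergence_ceiling, fitness
from .fixed_env import EquilibriumResult
from .oscillation import (
    InducedPayoffs,
    OscillatorySpec,
    effective_competition,
    zero_mean_primitive,
)
from .params import ModelParams, PopulationState, Trajectory

__all__ = [
    "CoexistenceError",
    "induced_fitness",
    "slow_rhs",
    "integrate_slow",
    "coexistence_equilibrium",
    "oscillating_corrections",
    "corrected_initial_conditions",
]


class CoexistenceError(ValueError):
    """Coexistence conditions are violated or the averaged abundance diverges."""


def induced_fitness(payoffs: InducedPayoffs, state):
    """Induced fitness terms (phi_A, phi_B) of the environment game."""
    if isinstance(state, PopulationState):
        p, N = state.p_A, state.N
    else:
        p, N = state
    return N * (1.0 - p) * payoffs.xi, -N * payoffs.kappa * p


def slow_rhs(t, y, params: ModelParams, payoffs: InducedPayoffs):
    """Replicator dynamics in the total fitness f_i + phi_i."""
    p, N = y
    f_A, f_B = fitness(params, (p, N))
    phi_A, phi_B = induced_fitness(payoffs, (p, N))
    g_A, g_B = f_A + phi_A, f_B + phi_B
    gbar = p * g_A + (1.0 - p) * g_B
    return np.array([p * (g_A - gbar), N * gbar])


def integrate_slow(
    params: ModelParams,
    payoffs: InducedPayoffs,
    init: PopulationState,
    t_end: float,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
    n_max: float | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the autonomous slow system; flags divergence (N/A regime)."""
    if n_max is None:
        n_max = default_divergence_ceiling(params)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 1001)

    def event_diverge(t, y, *args):
        return y[1] - n_max

    event_diverge.terminal = True
    event_diverge.direction = 1

    sol = solve_ivp(
        slow_rhs,
        (0.0, t_end),
        [init.p_A, init.N],
        args=(params, payoffs),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=[event_diverge],
    )
    if sol.status == -1:
        raise IntegrationError(f"integration failed: {sol.message}")
    diverged = sol.status == 1
    times, p, N = sol.t, sol.y[0], sol.y[1]
    if diverged and sol.t_events[0].size:
        te = sol.t_events[0][0]
        if times.size == 0 or te > times[-1]:
            times = np.append(times, te)
            p = np.append(p, sol.y_events[0][0][0])
            N = np.append(N, sol.y_events[0][0][1])
    p = np.clip(p, 0.0, 1.0)
    N = np.clip(N, 0.0, np.inf)
    return Trajectory(
        times=times, p_A=p, N=N, rate_mode="coarse_grained", diverged=diverged
    )


def coexistence_equilibrium(
    params: ModelParams, payoffs: InducedPayoffs
) -> EquilibriumResult:
    """Stable coexistence equilibrium of the averaged single-allele model.

    Requires equal competition rates and balanced average HGT
    (gamma = 0); the general case goes through
    :func:`hgtosc.oscillation.effective_competition` plus the
    fixed-environment machinery.
    """
    if not params.equal_competition:
        raise ValueError("coexistence_equilibrium requires equal competition rates")
    if params.gamma != 0.0:
        raise ValueError(
            "coexistence_equilibrium requires balanced average HGT (gamma = 0); "
            "route unbalanced cases through effective_competition + fixed_env"
        )
    a = params.a_11
    xi, kappa = payoffs.xi, payoffs.kappa
    if not (kappa < a * (params.r_B / params.r_A - 1.0)):
        raise CoexistenceError(
            f"kappa={kappa} violates kappa < a(r_B/r_A - 1) = "
            f"{a * (params.r_B / params.r_A - 1.0)}"
        )
    if not (xi > a * (1.0 - params.r_A / params.r_B)):
        raise CoexistenceError(
            f"xi={xi} violates xi > a(1 - r_A/r_B) = "
            f"{a * (1.0 - params.r_A / params.r_B)}"
        )
    den = a * (xi - kappa) + xi * kappa
    if den <= 0.0:
        raise CoexistenceError(
            f"averaged abundance diverges (N/A regime): a(xi-kappa)+xi*kappa = {den} <= 0"
        )
    num = params.r_B * xi - params.r_A * kappa
    N_star = num / den
    p_star = (params.r_A * a - params.r_B * (a - xi)) / num
    return EquilibriumResult(p_A_star=p_star, N_star=N_star, stable=True, label="interior")


def oscillating_corrections(params: ModelParams, osc: OscillatorySpec):
    """Leading-order oscillating corrections (pi_1, v_1) as callables of (p, N, tau)."""
    hat_rA = zero_mean_primitive(osc.r_tilde_A)
    hat_rB = zero_mean_primitive(osc.r_tilde_B)
    hat_g = zero_mean_primitive(osc.gamma_tilde)

    def pi_1(p, N, tau):
        return p * (1.0 - p) * (hat_rA(tau) - hat_rB(tau) + N * hat_g(tau))

    def v_1(p, N, tau):
        return N * (p * hat_rA(tau) + (1.0 - p) * hat_rB(tau))

    return pi_1, v_1


def corrected_initial_conditions(
    p0: float,
    N0: float,
    params: ModelParams,
    osc: OscillatorySpec,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PopulationState:
    """Slow-system initial condition matching an observed full-system state.

    Solves the fixed-point system p0 = pbar + pi_1(pbar, Nbar, 0)/omega,
    N0 = Nbar + v_1(pbar, Nbar, 0)/omega by damped Picard iteration
    (damping 0.5), falling back on a derivative-free root finder if the
    iteration stalls.
    """
    if not 0.0 <= p0 <= 1.0 or N0 <= 0.0:
        raise ValueError("require p0 in [0, 1] and N0 > 0")
    pi_1, v_1 = oscillating_corrections(params, osc)
    w = osc.omega

    def residual(y):
        p, N = y
        return np.array([p + pi_1(p, N, 0.0) / w - p0, N + v_1(p, N, 0.0) / w - N0])

    p, N = float(p0), float(N0)
    damping = 0.5
    for _ in range(max_iter):
        target_p = p0 - pi_1(p, N, 0.0) / w
        target_N = N0 - v_1(p, N, 0.0) / w
        p_new = p + damping * (target_p - p)
        N_new = N + damping * (target_N - N)
        if max(abs(p_new - p), abs(N_new - N)) < tol and np.all(
            np.abs(residual([p_new, N_new])) < tol
        ):
            p, N = p_new, N_new
            break
        p, N = p_new, N_new
    else:
        res = optimize.root(residual, [p, N], method="hybr", tol=1e-12)
        if not res.success or np.any(np.abs(residual(res.x)) > tol):
            raise RuntimeError(
                f"slow initial-condition solve did not converge: residual "
                f"{residual(res.x if res.success else [p, N])}"
            )
        p, N = res.x
    p = min(1.0, max(0.0, p))
    return PopulationState(p_A=p, N=N)


def slow_equals_effective_fixed(params: ModelParams, payoffs: InducedPayoffs):
    """Effective fixed-environment parameter set equivalent to the slow system."""
    return effective_competition(params, payoffs)
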