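"""Equilibria, stability and outcome classification in a fixed environment.

Setting the right-hand sides of the (p_A, N) system to zero gives four
equilibria: the trivial one (extinction of both populations, always
unstable for positive reproduction rates), the two boundary states
(1, r_A/a_11) and (0, r_B/a_22), and — when it lies in the physical
range — an interior state with both populations present.

Stability of the boundary states is governed by the invasion conditions

    A-only stable  <=>  (a_21 + gamma)/a_11 * r_A/r_B > 1,
    B-only stable  <=>  (a_12 - gamma)/a_22 * r_B/r_A > 1,

and the sign of the community-matrix determinant
det = a_11 a_22 - (a_12 - gamma)(a_21 + gamma) separates coexistence
(both invasion conditions violated, det > 0) from bistability (both
satisfied, det < 0).  With equal competition rates a_ij = a and balanced
HGT (gamma = 0) the competitive exclusion principle holds: coexistence
is impossible for r_A != r_B.  Unbalanced HGT restores coexistence for
gamma inside the open interval (a(1 - r_A/r_B), a(r_B/r_A - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import fitness, rhs_full
from .params import ModelParams

__all__ = [
    "EquilibriumResult",
    "FixedOutcome",
    "StabilityFlags",
    "equilibria_fixed",
    "stability_flags",
    "classify_fixed",
    "gamma_coexistence_interval",
]

#: |condition - 1| below this is reported as a marginal (degenerate) case
MARGIN_TOL = 1e-12


class DegenerateCaseError(ValueError):
    """A marginal (measure-zero) parameter combination was encountered."""


class InternalConsistencyError(RuntimeError):
    """Analytic stability conditions disagree with the numerical Jacobian."""


@dataclass(frozen=True)
class EquilibriumResult:
    """An equilibrium (p_A*, N*) with its stability and label."""

    p_A_star: float
    N_star: float
    stable: bool
    label: str  # A_only | B_only | interior | trivial


@dataclass(frozen=True)
class StabilityFlags:
    A_only_stable: bool
    B_only_stable: bool
    det_positive: bool
    cond_A: float
    cond_B: float
    det: float


@dataclass(frozen=True)
class FixedOutcome:
    """Outcome of competition in a fixed environment.

    ``outcome`` is one of A_wins, B_wins, coexistence, bistable — plus
    the non-silent extras ``degenerate`` (a stability condition sits
    exactly on its marginal value) and ``divergent`` (only reachable with
    effective, environment-shifted parameters whose interior abundance
    is unphysical; the coarse-grained N/A regime).
    """

    outcome: str
    equilibria: tuple[EquilibriumResult, ...]
    flags: StabilityFlags

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "equilibria": [
                {
                    "p_A_star": e.p_A_star,
                    "N_star": e.N_star,
                    "stable": e.stable,
                    "label": e.label,
                }
                for e in self.equilibria
            ],
            "conditions": {
                "A_only_stable": self.flags.A_only_stable,
                "B_only_stable": self.flags.B_only_stable,
                "cond_A": self.flags.cond_A,
                "cond_B": self.flags.cond_B,
                "det": self.flags.det,
            },
        }


def stability_flags(params: ModelParams) -> StabilityFlags:
    """Invasion conditions for the boundary equilibria and det of the community matrix."""
    cond_A = (params.a_21 + params.gamma) / params.a_11 * params.r_A / params.r_B
    cond_B = (params.a_12 - params.gamma) / params.a_22 * params.r_B / params.r_A
    det = params.a_11 * params.a_22 - (params.a_12 - params.gamma) * (
        params.a_21 + params.gamma
    )
    return StabilityFlags(
        A_only_stable=cond_A > 1.0,
        B_only_stable=cond_B > 1.0,
        det_positive=det > 0.0,
        cond_A=cond_A,
        cond_B=cond_B,
        det=det,
    )


def _interior(params: ModelParams):
    """Closed-form interior equilibrium, or None when degenerate/non-physical."""
    g = params.gamma
    num_p = params.r_A * params.a_22 - params.r_B * (params.a_12 - g)
    D = params.r_A * (params.a_22 - params.a_21 - g) + params.r_B * (
        params.a_11 - params.a_12 + g
    )
    det = params.a_11 * params.a_22 - (params.a_12 - g) * (params.a_21 + g)
    if D == 0.0 or det == 0.0:
        return None
    p_star = num_p / D
    N_star = D / det
    if not (0.0 < p_star < 1.0) or not N_star > 0.0:
        return None
    return p_star, N_star


def _jacobian_eigs(params: ModelParams, p: float, N: float, h: float = 1e-7):
    """Eigenvalues of the (p, N) Jacobian by central differences."""
    y0 = np.array([p, N])
    J = np.empty((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = h * max(1.0, abs(y0[j]))
        fp = rhs_full(0.0, y0 + step, params)
        fm = rhs_full(0.0, y0 - step, params)
        J[:, j] = (fp - fm) / (2 * step[j])
    return np.linalg.eigvals(J)


def equilibria_fixed(params: ModelParams) -> list[EquilibriumResult]:
    """All equilibria of the fixed-environment system with stability flags.

    The trivial equilibrium is always unstable (positive reproduction
    rates).  The interior equilibrium is included only when its fraction
    lies strictly inside (0, 1) with positive abundance; its stability
    follows from the invasion/determinant sign pattern and is
    cross-checked against the numerically evaluated Jacobian.
    """
    flags = stability_flags(params)
    out = [
        EquilibriumResult(0.0, 0.0, stable=False, label="trivial"),
        EquilibriumResult(
            1.0, params.r_A / params.a_11, stable=flags.A_only_stable, label="A_only"
        ),
        EquilibriumResult(
            0.0, params.r_B / params.a_22, stable=flags.B_only_stable, label="B_only"
        ),
    ]
    interior = _interior(params)
    if interior is not None:
        p_star, N_star = interior
        coexist = (not flags.A_only_stable) and (not flags.B_only_stable) and flags.det_positive
        eigs = _jacobian_eigs(params, p_star, N_star)
        numerically_stable = bool(np.all(eigs.real < 0))
        if max(abs(eigs.real)) > 1e-9 and numerically_stable != coexist:
            raise InternalConsistencyError(
                f"analytic stability ({coexist}) disagrees with Jacobian "
                f"eigenvalues {eigs} at the interior equilibrium"
            )
        out.append(
            EquilibriumResult(p_star, N_star, stable=coexist, label="interior")
        )
    return out


def classify_fixed(params: ModelParams) -> FixedOutcome:
    """Classify the fixed-environment outcome from the stability pattern."""
    flags = stability_flags(params)
    if abs(flags.cond_A - 1.0) < MARGIN_TOL or abs(flags.cond_B - 1.0) < MARGIN_TOL:
        return FixedOutcome("degenerate", tuple(equilibria_fixed(params)), flags)
    if flags.A_only_stable and flags.B_only_stable:
        outcome = "bistable"
    elif flags.A_only_stable:
        outcome = "A_wins"
    elif flags.B_only_stable:
        outcome = "B_wins"
    else:
        # both boundary states invadable; interior exists iff det > 0
        outcome = "coexistence" if flags.det_positive else "divergent"
    eqs = tuple(equilibria_fixed(params))
    if outcome == "coexistence" and not any(
        e.label == "interior" and e.stable for e in eqs
    ):
        raise InternalConsistencyError(
            "coexistence conditions hold but no stable interior equilibrium was found"
        )
    return FixedOutcome(outcome, eqs, flags)


def gamma_coexistence_interval(params: ModelParams) -> tuple[float, float] | None:
    """Open interval of HGT-balance rates gamma allowing coexistence.

    Only defined for equal competition rates a_ij = a, where coexistence
    requires a(1 - r_A/r_B) < gamma < a(r_B/r_A - 1).  Returns None when
    the interval is empty (r_A = r_B collapses it to the single point 0,
    treated as empty; boundary values are non-coexisting).
    """
    if not params.equal_competition:
        raise ValueError(
            "gamma_coexistence_interval requires equal competition rates a_ij = a"
        )
    a = params.a_11
    lo = a * (1.0 - params.r_A / params.r_B)
    hi = a * (params.r_B / params.r_A - 1.0)
    if not lo < hi:
        return None
    return (lo, hi)


def interior_fitness_residual(params: ModelParams) -> float:
    """Max |f_A|, |f_B| at the interior equilibrium (diagnostic; ~0 expected)."""
    interior = _interior(params)
    if interior is None:
        raise ValueError("no interior equilibrium for these parameters")
    f_A, f_B = fitness(params, interior)
    return max(abs(f_A), abs(f_B))
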