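"""Quantitative comparison of the full and coarse-grained descriptions.

The averaged (slow) system is an O(1/omega) approximation of the full
time-dependent dynamics.  The comparison metrics are the Euclidean
distance between the time-averaged population fractions of the two
descriptions and the relative error of the total abundances.  In the
exclusion/bistability regions the discrepancy is negligible; in the
coexistence regions it is larger but both descriptions agree
qualitatively (both predict interior fractions).  The averaged
description fails outright near the curve a (xi - kappa) + xi kappa = 0,
where its equilibrium abundance diverges while the true solution stays
bounded (the N/A regime).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coarse import (
    CoexistenceError,
    corrected_initial_conditions,
    integrate_slow,
)
from .dynamics import integrate_full
from .oscillation import InducedPayoffs, OscillatorySpec, compute_induced_payoffs
from .params import ModelParams, PopulationState, Trajectory
from .phase_space import classify_region, classify_region_unbalanced

__all__ = ["ComparisonMetrics", "NAReport", "time_average", "compare_full_vs_slow", "detect_na"]


@dataclass(frozen=True)
class ComparisonMetrics:
    frac_distance: float
    abundance_rel_error: float
    averaging_window: tuple[float, float]
    periods_averaged: int
    region: str
    full_average: tuple[float, float]  # (p_A, N)
    slow_average: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "frac_distance": self.frac_distance,
            "abundance_rel_error": self.abundance_rel_error,
            "averaging_window": list(self.averaging_window),
            "periods_averaged": self.periods_averaged,
            "region": self.region,
            "full_average": list(self.full_average),
            "slow_average": list(self.slow_average),
        }


@dataclass(frozen=True)
class NAReport:
    is_na: bool
    denominator: float
    on_boundary: bool
    full_bounded: bool | None = None


def time_average(
    traj: Trajectory,
    osc: OscillatorySpec | None = None,
    discard_fraction: float = 0.8,
    min_periods: int = 5,
) -> tuple[float, float]:
    """Trapezoidal time average (p_A, N) over whole environmental periods.

    The first ``discard_fraction`` of the horizon is discarded as
    transient; the average runs over the largest integer number of
    periods fitting the retained window (ending at the final time).  For
    constant-rate trajectories (``osc=None``) the plain average over the
    retained window is returned.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must lie in [0, 1)")
    t = traj.times
    t0 = t[0] + discard_fraction * (t[-1] - t[0])
    if osc is not None:
        T = osc.period
        n_per = int(np.floor((t[-1] - t0) / T))
        if n_per < min_periods:
            raise ValueError(
                f"retained window holds only {n_per} environmental periods "
                f"(need >= {min_periods}); integrate longer or discard less"
            )
        start = t[-1] - n_per * T
    else:
        n_per = 0
        start = t0
    mask = t >= start
    # include an interpolated point exactly at the window start
    tt = np.concatenate(([start], t[mask]))
    pp = np.concatenate(([np.interp(start, t, traj.p_A)], traj.p_A[mask]))
    nn = np.concatenate(([np.interp(start, t, traj.N)], traj.N[mask]))
    span = tt[-1] - tt[0]
    if span <= 0:
        raise ValueError("averaging window is empty")
    return (
        float(np.trapezoid(pp, tt) / span),
        float(np.trapezoid(nn, tt) / span),
    )


def _classify(params: ModelParams, payoffs: InducedPayoffs):
    if params.gamma == 0.0:
        return classify_region(params, payoffs)
    return classify_region_unbalanced(params, payoffs)


def compare_full_vs_slow(
    params: ModelParams,
    osc: OscillatorySpec,
    init: PopulationState,
    t_end: float | None = None,
    *,
    discard_fraction: float = 0.8,
) -> ComparisonMetrics:
    """Run both descriptions of one oscillating scenario and compare them.

    The full system is integrated with time-dependent rates and
    time-averaged over whole periods.  The coarse-grained comparator in
    coexistence regions is the analytic equilibrium of the averaged
    system (the slow system is autonomous and converges to it); in the
    exclusion/bistability regions it is the tail average of the slow
    trajectory started from the corrected initial conditions.
    """
    payoffs = compute_induced_payoffs(osc)
    res = _classify(params, payoffs)
    if res.region == "boundary":
        raise ValueError("scenario sits on a region boundary; comparison undefined")
    if res.region == "NA":
        raise CoexistenceError(
            "averaged abundance diverges (N/A regime); use detect_na for the report"
        )
    if t_end is None:
        t_end = 50.0 / min(params.r_A, params.r_B)
    full = integrate_full(params, osc, init, t_end)
    p_full, N_full = time_average(full, osc, discard_fraction)

    if res.region in ("I", "II", "III"):
        p_slow, N_slow = res.equilibrium.p_A_star, res.equilibrium.N_star
    else:
        slow_init = corrected_initial_conditions(init.p_A, init.N, params, osc)
        slow = integrate_slow(params, payoffs, slow_init, t_end)
        p_slow, N_slow = time_average(slow, None, discard_fraction)

    t0 = full.times[0] + discard_fraction * (full.times[-1] - full.times[0])
    n_per = int(np.floor((full.times[-1] - t0) / osc.period))
    frac_distance = float(np.sqrt(2.0) * abs(p_full - p_slow))
    return ComparisonMetrics(
        frac_distance=frac_distance,
        abundance_rel_error=float(abs(N_full - N_slow) / N_full),
        averaging_window=(float(full.times[-1] - n_per * osc.period), float(full.times[-1])),
        periods_averaged=n_per,
        region=res.region,
        full_average=(p_full, N_full),
        slow_average=(float(p_slow), float(N_slow)),
    )


def detect_na(
    params: ModelParams,
    osc: OscillatorySpec,
    init: PopulationState | None = None,
    t_end: float = 50.0,
    *,
    check_full: bool = True,
) -> NAReport:
    """Detect the failure regime of the averaged description.

    True when the coexistence *composition* conditions hold but the
    averaged abundance is non-positive or infinite
    (a (xi - kappa) + (gamma+xi)(gamma+kappa) <= 0).  When
    ``check_full`` is set, the full time-dependent system is integrated
    to report that the true solution stays below the divergence ceiling.
    """
    payoffs = compute_induced_payoffs(osc)
    a = params.a_11
    g = params.gamma
    u, v = g + payoffs.xi, g + payoffs.kappa
    den = a * (payoffs.xi - payoffs.kappa) + u * v
    composition_ok = (v < a * (params.r_B / params.r_A - 1.0)) and (
        u > a * (1.0 - params.r_A / params.r_B)
    )
    is_na = composition_ok and den <= 0.0
    on_boundary = composition_ok and abs(den) < 1e-12
    full_bounded = None
    if is_na and check_full:
        if init is None:
            init = PopulationState(0.5, max(params.r_A, params.r_B) / a)
        full = integrate_full(params, osc, init, t_end)
        full_bounded = not full.diverged
    return NAReport(
        is_na=bool(is_na),
        denominator=float(den),
        on_boundary=bool(on_boundary),
        full_bounded=full_bounded,
    )
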