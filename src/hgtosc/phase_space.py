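"""Phase-space classification of evolutionary outcomes in the (xi, kappa) plane.

For the single-allele scenario (equal competition rates a_ij = a,
r_A > r_B) the induced payoffs (xi, kappa) partition the plane into

    I    coexistence without synergy (xi < 0),
    II   coexistence with synergy, pure competition (0 < xi < a, kappa > -a),
    III  coexistence with synergy, parasitism or mutualism (xi > a or kappa < -a),
    IV   A outcompetes B (as in the fixed environment),
    V    bistability (either population can win),
    VI   B outcompetes A (reversal of the fixed-environment outcome),
    N/A  the averaged description fails: the coexistence *composition*
         exists but the averaged abundance diverges
         (a (xi - kappa) + xi kappa <= 0).

Coexistence requires kappa < a (r_B/r_A - 1) and xi > a (1 - r_A/r_B)
together with the positive-denominator condition.  Symbiosis type is read
off the signs of the cross-derivatives of total fitness at coexistence,
d(f_A + phi_A)/dp_B = -(a - gamma - xi) N and
d(f_B + phi_B)/dp_A = -(a + gamma + kappa) N: both negative is pure
competition, mixed signs parasitism, both positive mutualism.  Synergy
means the coexistence abundance N_c* exceeds the fixed-environment
abundance N_f*; it is decided by direct numerical comparison of the two
abundances.

Unbalanced average HGT (gamma != 0) shifts every threshold by gamma:
the same decision tree applies with gamma + xi and gamma + kappa in the
threshold comparisons and with determinant condition
a (xi - kappa) + (gamma + xi)(gamma + kappa) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fixed_env
from .fixed_env import EquilibriumResult
from .oscillation import InducedPayoffs, effective_competition
from .params import ModelParams

__all__ = [
    "ClassificationResult",
    "classify_region",
    "classify_region_unbalanced",
    "synergy_flag",
    "region_map",
]

BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class ClassificationResult:
    """Region label, symbiosis type and synergy for one (xi, kappa) point."""

    region: str  # I | II | III | IV | V | VI | NA | boundary
    symbiosis: str  # pure_competition | parasitism_B_on_A | parasitism_A_on_B |
    #               mutualism | not_applicable
    synergy: bool
    equilibrium: EquilibriumResult | None = None
    N_c: float | None = None
    N_f: float | None = None
    coexistence_destroyed: bool = False

    def as_dict(self) -> dict:
        d = {
            "region": self.region,
            "symbiosis": self.symbiosis,
            "synergy": self.synergy,
            "coexistence_destroyed": self.coexistence_destroyed,
        }
        if self.equilibrium is not None:
            d["p_A_star"] = self.equilibrium.p_A_star
            d["N_star"] = self.equilibrium.N_star
        if self.N_c is not None:
            d["N_c"] = self.N_c
        if self.N_f is not None:
            d["N_f"] = self.N_f
        return d


def _require_equal_a(params: ModelParams) -> float:
    if not params.equal_competition:
        raise ValueError("phase-space classification requires equal competition rates")
    return params.a_11


def _fixed_env_abundance(params: ModelParams) -> float:
    """Abundance of the fixed-environment attractor used as synergy baseline.

    For balanced HGT this is the winner's carrying capacity
    max(r_A, r_B)/a; with unbalanced HGT it is the abundance of the
    stable fixed-environment equilibrium (interior if the fixed
    environment coexists, the larger boundary abundance if bistable).
    """
    outcome = fixed_env.classify_fixed(params)
    stable = [e for e in outcome.equilibria if e.stable]
    if not stable:
        return max(params.r_A, params.r_B) / params.a_11
    return max(e.N_star for e in stable)


def synergy_flag(params: ModelParams, payoffs: InducedPayoffs):
    """Synergy decision by direct comparison of N_c* against N_f*.

    Returns ``(synergy, N_c, N_f)``; requires established coexistence of
    the averaged system.
    """
    a = _require_equal_a(params)
    eff = effective_competition(params, payoffs)
    eqs = fixed_env.equilibria_fixed(eff)
    interior = [e for e in eqs if e.label == "interior" and e.stable]
    if not interior:
        raise ValueError("synergy is only defined at an established coexistence")
    N_c = float(interior[0].N_star)
    N_f = float(_fixed_env_abundance(params))
    return (bool(N_c > N_f), N_c, N_f)


def _classify(params: ModelParams, payoffs: InducedPayoffs, tol: float) -> ClassificationResult:
    a = _require_equal_a(params)
    g = params.gamma
    xi, kappa = payoffs.xi, payoffs.kappa
    u = g + xi  # effective shift of a_12 threshold variable
    v = g + kappa
    kappa_thr = a * (params.r_B / params.r_A - 1.0)
    xi_thr = a * (1.0 - params.r_A / params.r_B)
    det = a * (xi - kappa) + u * v

    fixed_coexists = False
    if g != 0.0:
        interval = fixed_env.gamma_coexistence_interval(params)
        fixed_coexists = interval is not None and interval[0] < g < interval[1]

    cond_kappa = v < kappa_thr
    cond_xi = u > xi_thr

    # boundary detection on every decision line that is about to be used
    on_main = abs(v - kappa_thr) < tol or abs(u - xi_thr) < tol
    if on_main or (cond_kappa and cond_xi and abs(det) < tol):
        return ClassificationResult(
            region="boundary", symbiosis="not_applicable", synergy=False,
            coexistence_destroyed=False,
        )

    if cond_kappa and cond_xi:
        if det < 0.0:
            return ClassificationResult(
                region="NA", symbiosis="not_applicable", synergy=False,
                coexistence_destroyed=False,
            )
        # stable coexistence of the averaged system.  region="boundary" is
        # reserved for lines separating *distinct region labels*: u=0
        # (I|II) always; u=a and v=-a only where II sits on one side.
        # Inside region I or III these same lines only separate symbiosis
        # sub-regions, so the region label is kept and the symbiosis field
        # carries the "boundary" marker instead.
        on_II_edge = (abs(u - a) < tol and v > -a) or (abs(v + a) < tol and 0.0 < u < a)
        if abs(u) < tol or on_II_edge:
            return ClassificationResult(
                region="boundary", symbiosis="not_applicable", synergy=False
            )
        eff = effective_competition(params, payoffs)
        eqs = fixed_env.equilibria_fixed(eff)
        interior = next(e for e in eqs if e.label == "interior")
        synergy, N_c, N_f = synergy_flag(params, payoffs)
        if u < 0.0:
            region = "I"
        elif u < a and v > -a:
            region = "II"
        else:
            region = "III"
        dA = -(a - u)  # sign of d(f_A + phi_A)/dp_B
        dB = -(a + v)  # sign of d(f_B + phi_B)/dp_A
        if abs(dA) < tol or abs(dB) < tol:
            symbiosis = "boundary"
        elif dA < 0 and dB < 0:
            symbiosis = "pure_competition"
        elif dA > 0 and dB < 0:
            symbiosis = "parasitism_A_on_B"
        elif dA < 0 and dB > 0:
            symbiosis = "parasitism_B_on_A"
        else:
            symbiosis = "mutualism"
        return ClassificationResult(
            region=region,
            symbiosis=symbiosis,
            synergy=synergy,
            equilibrium=interior,
            N_c=N_c,
            N_f=N_f,
        )

    destroyed = fixed_coexists
    if cond_xi and not cond_kappa:
        region = "IV"  # A-only stable, B-only unstable: A wins
    elif cond_kappa and not cond_xi:
        region = "VI"  # B wins, reversing the fixed-environment outcome
    else:
        region = "V"  # both boundary states stable: bistability
    return ClassificationResult(
        region=region,
        symbiosis="not_applicable",
        synergy=False,
        coexistence_destroyed=destroyed,
    )


def classify_region(
    params: ModelParams, payoffs: InducedPayoffs, tol: float = BOUNDARY_TOL
) -> ClassificationResult:
    """Classify a balanced-HGT (gamma = 0) point of the (xi, kappa) plane."""
    if params.gamma != 0.0:
        raise ValueError("classify_region requires gamma = 0; use classify_region_unbalanced")
    return _classify(params, payoffs, tol)


def classify_region_unbalanced(
    params: ModelParams, payoffs: InducedPayoffs, tol: float = BOUNDARY_TOL
) -> ClassificationResult:
    """Classification with unbalanced average HGT (any gamma).

    Thresholds are shifted by gamma (gamma + xi, gamma + kappa) and the
    determinant condition becomes
    a (xi - kappa) + (gamma + xi)(gamma + kappa) > 0.  The result's
    ``coexistence_destroyed`` flag reports the case where the fixed
    environment coexists (gamma inside its coexistence interval) but the
    oscillating environment does not.
    """
    return _classify(params, payoffs, tol)


def region_map(
    params: ModelParams,
    xi_values: np.ndarray | None = None,
    kappa_values: np.ndarray | None = None,
    *,
    extent: float = 0.3,
    step: float = 0.005,
) -> pd.DataFrame:
    """Classify every node of a (xi, kappa) grid.

    Defaults reproduce the reference phase diagram: xi, kappa in
    [-extent, extent] at the given step.  Returns one row per node with
    columns xi, kappa, region, symbiosis, synergy, p_A_star, N_star.
    """
    if xi_values is None:
        n = int(round(2 * extent / step)) + 1
        xi_values = np.linspace(-extent, extent, n)
    if kappa_values is None:
        n = int(round(2 * extent / step)) + 1
        kappa_values = np.linspace(-extent, extent, n)
    classify = classify_region if params.gamma == 0.0 else classify_region_unbalanced
    rows = []
    for kappa in kappa_values:
        for xi in xi_values:
            res = classify(params, InducedPayoffs(xi=float(xi), kappa=float(kappa)))
            rows.append(
                {
                    "xi": float(xi),
                    "kappa": float(kappa),
                    "region": res.region,
                    "symbiosis": res.symbiosis,
                    "synergy": res.synergy,
                    "p_A_star": res.equilibrium.p_A_star if res.equilibrium else np.nan,
                    "N_star": res.equilibrium.N_star if res.equilibrium else np.nan,
                }
            )
    return pd.DataFrame(rows)


def region_areas(df: pd.DataFrame) -> dict:
    """Fraction of grid nodes carrying each region label."""
    counts = df["region"].value_counts(normalize=True)
    return {str(k): float(v) for k, v in counts.items()}
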