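"""Event-driven stochastic simulation of the elementary processes.

The continuum model is the large-size limit of a birth-death-transfer
process on integer counts (N_A, N_B) = V * (n_A, n_B), where V is the
system size converting model abundances (densities) to individuals:

    reproduction of i        at rate r_i N_i,
    competition death of i   at rate (a_ij / V) N_i N_j   (including i = j),
    conversion B -> A        at rate (h_BA / V) N_A N_B,
    conversion A -> B        at rate (h_AB / V) N_A N_B,

with donor and recipient drawn uniformly from their populations; a
conversion copies the donor allele into the recipient, so it conserves
N_A + N_B.  Only the *balance* h_BA - h_AB = gamma enters the mean-field
limit; the split is a modelling choice exposed through the baseline
bidirectional rate h_0 (default h_AB = max(0, -gamma) + h_0,
h_BA = max(0, gamma) + h_0).

Time-dependent (oscillating) rates are handled by thinning: events are
proposed at constant upper-bound rates and accepted with probability
rate(tau)/bound.  Negative instantaneous reproduction rates are realised
as an additional density-independent death channel.  The simulation is
exactly reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .oscillation import FourierSeries, OscillatorySpec
from .params import ModelParams, PopulationState

__all__ = ["StochasticConfig", "StochasticTrajectory", "gillespie_run", "ensemble_mean"]

EVENT_NAMES = {
    0: "birth_A",
    1: "birth_B",
    2: "death_A_within",
    3: "death_A_between",
    4: "death_B_between",
    5: "death_B_within",
    6: "conversion_B_to_A",
    7: "conversion_A_to_B",
    8: "death_A_env",
    9: "death_B_env",
}


@dataclass(frozen=True)
class StochasticConfig:
    """Configuration of one stochastic run."""

    params: ModelParams
    system_size: float
    init: PopulationState
    t_end: float
    seed: int
    h_0: float = 0.0
    osc: OscillatorySpec | None = None
    h_AB: float | None = None
    h_BA: float | None = None

    def __post_init__(self) -> None:
        if self.system_size < 1:
            raise ValueError("system_size must be >= 1")
        if self.h_0 < 0:
            raise ValueError("baseline HGT rate h_0 must be non-negative")
        g = self.params.gamma
        if (self.h_AB is None) != (self.h_BA is None):
            raise ValueError("provide both h_AB and h_BA or neither")
        if self.h_AB is None:
            object.__setattr__(self, "h_AB", max(0.0, -g) + self.h_0)
            object.__setattr__(self, "h_BA", max(0.0, g) + self.h_0)
        if self.h_AB < 0 or self.h_BA < 0:
            raise ValueError("directional HGT rates must be non-negative")
        if abs((self.h_BA - self.h_AB) - g) > 1e-12:
            raise ValueError(
                f"h_BA - h_AB = {self.h_BA - self.h_AB} must equal gamma = {g}"
            )


@dataclass
class StochasticTrajectory:
    """Recorded stochastic run: counts over time, plus run flags."""

    times: np.ndarray
    n_A: np.ndarray  # integer counts
    n_B: np.ndarray
    system_size: float
    rng_seed: int
    event_types: np.ndarray | None = None
    extinct: bool = False
    truncated: bool = False

    @property
    def density_A(self) -> np.ndarray:
        return self.n_A / self.system_size

    @property
    def density_B(self) -> np.ndarray:
        return self.n_B / self.system_size

    @property
    def density_total(self) -> np.ndarray:
        return (self.n_A + self.n_B) / self.system_size

    def to_frame(self):
        import pandas as pd

        d = {"t": self.times, "n_A": self.n_A, "n_B": self.n_B}
        if self.event_types is not None:
            d["event_type"] = [
                EVENT_NAMES.get(int(e), "none") for e in self.event_types
            ]
        return pd.DataFrame(d)


def _fourier_arrays(series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if series is None or not isinstance(series, FourierSeries):
        if series is not None and not series.is_zero:
            raise ValueError(
                "the stochastic engine supports Fourier oscillation components only"
            )
        return (np.empty(0), np.empty(0, np.int64), np.empty(0))
    amps = np.array([t.amplitude for t in series.terms], dtype=float)
    ks = np.array([t.harmonic for t in series.terms], dtype=np.int64)
    phs = np.array([t.phase for t in series.terms], dtype=float)
    return amps, ks, phs


@njit(cache=True)
def _feval(tau, amps, ks, phs):
    s = 0.0
    for i in range(len(amps)):
        s += amps[i] * np.sin(ks[i] * tau + phs[i])
    return s


@njit(cache=True)
def _kernel(
    seed,
    NA,
    NB,
    rA,
    rB,
    a11,
    a12,
    a21,
    a22,
    gamma,
    h0,
    V,
    t_end,
    omega,
    ampA,
    kA,
    phA,
    ampB,
    kB,
    phB,
    ampG,
    kG,
    phG,
    sample_times,
    record_events,
    max_events,
):
    np.random.seed(seed)
    sumA = np.sum(np.abs(ampA))
    sumB = np.sum(np.abs(ampB))
    sumG = np.sum(np.abs(ampG))
    oscillating = (len(ampA) + len(ampB) + len(ampG)) > 0
    # constant upper bounds for the time-dependent channels (thinning)
    rA_hi = rA + sumA
    rB_hi = rB + sumB
    dA_hi = max(0.0, sumA - rA)  # density-independent death from negative r_A(tau)
    dB_hi = max(0.0, sumB - rB)
    hBA_hi = h0 + max(0.0, gamma + sumG)
    hAB_hi = h0 + max(0.0, -(gamma - sumG))

    ns = len(sample_times)
    outA = np.empty(ns, np.int64)
    outB = np.empty(ns, np.int64)
    si = 0

    cap = max_events if record_events else 0
    ev_t = np.empty(cap)
    ev_nA = np.empty(cap, np.int64)
    ev_nB = np.empty(cap, np.int64)
    ev_type = np.empty(cap, np.int64)
    n_ev = 0

    t = 0.0
    extinct = False
    truncated = False
    while True:
        w0 = rA_hi * NA
        w1 = rB_hi * NB
        w2 = a11 / V * NA * NA
        w3 = a12 / V * NA * NB
        w4 = a21 / V * NA * NB
        w5 = a22 / V * NB * NB
        w6 = hBA_hi / V * NA * NB
        w7 = hAB_hi / V * NA * NB
        w8 = dA_hi * NA
        w9 = dB_hi * NB
        W = w0 + w1 + w2 + w3 + w4 + w5 + w6 + w7 + w8 + w9
        if W <= 0.0:
            break
        tn = t + np.random.exponential(1.0 / W)
        while si < ns and sample_times[si] < tn:
            outA[si] = NA
            outB[si] = NB
            si += 1
        if tn > t_end:
            break
        t = tn
        u = np.random.random() * W
        tau = omega * t
        event = -1
        if u < w0:
            accept = True
            if oscillating:
                rate = max(0.0, rA + _feval(tau, ampA, kA, phA))
                accept = np.random.random() * rA_hi <= rate
            if accept:
                NA += 1
                event = 0
        elif u < w0 + w1:
            accept = True
            if oscillating:
                rate = max(0.0, rB + _feval(tau, ampB, kB, phB))
                accept = np.random.random() * rB_hi <= rate
            if accept:
                NB += 1
                event = 1
        elif u < w0 + w1 + w2:
            NA -= 1
            event = 2
        elif u < w0 + w1 + w2 + w3:
            NA -= 1
            event = 3
        elif u < w0 + w1 + w2 + w3 + w4:
            NB -= 1
            event = 4
        elif u < w0 + w1 + w2 + w3 + w4 + w5:
            NB -= 1
            event = 5
        elif u < w0 + w1 + w2 + w3 + w4 + w5 + w6:
            accept = True
            if oscillating:
                g = gamma + _feval(tau, ampG, kG, phG)
                rate = h0 + max(0.0, g)
                accept = np.random.random() * hBA_hi <= rate
            if accept:
                NA += 1
                NB -= 1
                event = 6
        elif u < w0 + w1 + w2 + w3 + w4 + w5 + w6 + w7:
            accept = True
            if oscillating:
                g = gamma + _feval(tau, ampG, kG, phG)
                rate = h0 + max(0.0, -g)
                accept = np.random.random() * hAB_hi <= rate
            if accept:
                NA -= 1
                NB += 1
                event = 7
        elif u < w0 + w1 + w2 + w3 + w4 + w5 + w6 + w7 + w8:
            rate = max(0.0, -(rA + _feval(tau, ampA, kA, phA)))
            if np.random.random() * dA_hi <= rate:
                NA -= 1
                event = 8
        else:
            rate = max(0.0, -(rB + _feval(tau, ampB, kB, phB)))
            if np.random.random() * dB_hi <= rate:
                NB -= 1
                event = 9
        if event >= 0 and record_events:
            if n_ev >= cap:
                truncated = True
                break
            ev_t[n_ev] = t
            ev_nA[n_ev] = NA
            ev_nB[n_ev] = NB
            ev_type[n_ev] = event
            n_ev += 1
        if NA + NB == 0:
            extinct = True
            break
    while si < ns:
        outA[si] = NA
        outB[si] = NB
        si += 1
    if NA + NB == 0:
        extinct = True
    return (
        outA,
        outB,
        ev_t[:n_ev],
        ev_nA[:n_ev],
        ev_nB[:n_ev],
        ev_type[:n_ev],
        extinct,
        truncated,
    )


def gillespie_run(
    config: StochasticConfig,
    record: str = "events",
    sample_times: np.ndarray | None = None,
    max_events: int = 2_000_000,
) -> StochasticTrajectory:
    """Run one exact stochastic realisation.

    ``record="events"`` stores every event (time, counts, type);
    ``record="checkpoints"`` stores counts at ``sample_times`` only,
    which is the memory-friendly mode for large system sizes.
    """
    if record not in ("events", "checkpoints"):
        raise ValueError("record must be 'events' or 'checkpoints'")
    p = config.params
    V = float(config.system_size)
    NA0 = int(round(config.init.n_A * V))
    NB0 = int(round(config.init.n_B * V))
    osc = config.osc
    ampA, kA, phA = _fourier_arrays(osc.r_tilde_A if osc else None)
    ampB, kB, phB = _fourier_arrays(osc.r_tilde_B if osc else None)
    ampG, kG, phG = _fourier_arrays(osc.gamma_tilde if osc else None)
    omega = osc.omega if osc is not None else 0.0
    if sample_times is None:
        sample_times = np.linspace(0.0, config.t_end, 101)
    sample_times = np.asarray(sample_times, dtype=float)

    # the kernel sees h0 + directional split via gamma; pass the explicit split
    h0_eff = min(config.h_AB, config.h_BA)
    outA, outB, ev_t, ev_nA, ev_nB, ev_type, extinct, truncated = _kernel(
        config.seed,
        NA0,
        NB0,
        p.r_A,
        p.r_B,
        p.a_11,
        p.a_12,
        p.a_21,
        p.a_22,
        p.gamma,
        h0_eff,
        V,
        config.t_end,
        omega,
        ampA,
        kA,
        phA,
        ampB,
        kB,
        phB,
        ampG,
        kG,
        phG,
        sample_times,
        record == "events",
        max_events,
    )
    if record == "events":
        return StochasticTrajectory(
            times=ev_t,
            n_A=ev_nA,
            n_B=ev_nB,
            system_size=V,
            rng_seed=config.seed,
            event_types=ev_type,
            extinct=bool(extinct),
            truncated=bool(truncated),
        )
    return StochasticTrajectory(
        times=sample_times,
        n_A=outA,
        n_B=outB,
        system_size=V,
        rng_seed=config.seed,
        extinct=bool(extinct),
        truncated=bool(truncated),
    )


def ensemble_mean(
    config: StochasticConfig, n_seeds: int, sample_times: np.ndarray
) -> dict:
    """Ensemble statistics of density trajectories over consecutive seeds.

    Returns mean and standard error of the mean for the A/B densities at
    each sample time, computed over seeds config.seed .. config.seed+n-1.
    """
    from dataclasses import replace

    sample_times = np.asarray(sample_times, dtype=float)
    dens_A = np.empty((n_seeds, len(sample_times)))
    dens_B = np.empty((n_seeds, len(sample_times)))
    for i in range(n_seeds):
        run = gillespie_run(
            replace(config, seed=config.seed + i),
            record="checkpoints",
            sample_times=sample_times,
        )
        dens_A[i] = run.density_A
        dens_B[i] = run.density_B
    return {
        "times": sample_times,
        "mean_A": dens_A.mean(axis=0),
        "mean_B": dens_B.mean(axis=0),
        "sem_A": dens_A.std(axis=0, ddof=1) / np.sqrt(n_seeds),
        "sem_B": dens_B.std(axis=0, ddof=1) / np.sqrt(n_seeds),
    }
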