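"""Fast-oscillating environments and the game they induce.

The environment enters through time-periodic reproduction and
gene-transfer balance rates, r_i(tau) = r_i + rt_i(tau) and
gamma(tau) = gamma + gt(tau), where tau = omega*t is the fast time,
each oscillatory part has zero mean over the period 2*pi, and omega > 1
separates the environmental timescale from the population dynamics.

Averaging over the fast time produces an *induced game* between the two
populations whose payoffs are

    xi    = (1/omega) <hat(rt_B) * gt>,
    kappa = (1/omega) <hat(rt_A) * gt>,

where hat(.) denotes the zero-mean periodic primitive and <.> the mean
over one period.  Note the asymmetric pairing: each population's induced
payoff involves the *competitor's* reproduction oscillation.  The payoffs
shift the effective between-population competition rates,
a_12 -> a_12 - xi and a_21 -> a_21 + kappa, so the whole fixed-environment
analysis applies to the averaged system with these effective rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import ModelParams

__all__ = [
    "Harmonic",
    "FourierSeries",
    "TabulatedSeries",
    "OscillatorySpec",
    "InducedPayoffs",
    "zero_mean_primitive",
    "compute_induced_payoffs",
    "effective_competition",
]

_QUAD_NODES = 4096  # trapezoid on a uniform periodic grid is spectrally accurate


@dataclass(frozen=True)
class Harmonic:
    """One Fourier term amplitude * sin(harmonic * tau + phase)."""

    amplitude: float
    harmonic: int = 1
    phase: float = 0.0

    def __post_init__(self) -> None:
        if int(self.harmonic) != self.harmonic or self.harmonic < 1:
            raise ValueError(f"harmonic must be an integer >= 1, got {self.harmonic}")


class FourierSeries:
    """Finite zero-mean Fourier series on [0, 2*pi).

    Harmonics >= 1 guarantee zero mean analytically, so primitives and
    the period-averaged products needed for the induced payoffs are exact
    (orthogonality of harmonics).
    """

    def __init__(self, terms=()):
        self.terms = tuple(
            t if isinstance(t, Harmonic) else Harmonic(*t) for t in terms
        )

    @classmethod
    def sine(cls, amplitude: float, harmonic: int = 1) -> "FourierSeries":
        return cls([Harmonic(amplitude, harmonic, 0.0)])

    @classmethod
    def cosine(cls, amplitude: float, harmonic: int = 1) -> "FourierSeries":
        return cls([Harmonic(amplitude, harmonic, np.pi / 2)])

    @classmethod
    def zero(cls) -> "FourierSeries":
        return cls(())

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        for term in self.terms:
            out = out + term.amplitude * np.sin(term.harmonic * tau + term.phase)
        return out if out.shape else float(out)

    def mean(self) -> float:
        return 0.0

    @property
    def is_zero(self) -> bool:
        return all(t.amplitude == 0.0 for t in self.terms)

    @property
    def amplitude_bound(self) -> float:
        """Upper bound on |f(tau)| (sum of |amplitudes|)."""
        return float(sum(abs(t.amplitude) for t in self.terms))

    def primitive(self) -> "FourierSeries":
        """Zero-mean primitive: d(primitive)/dtau recovers the series."""
        # primitive of A sin(k tau + phi) is -(A/k) cos(k tau + phi)
        #                                  = (A/k) sin(k tau + phi - pi/2)
        return FourierSeries(
            [
                Harmonic(t.amplitude / t.harmonic, t.harmonic, t.phase - np.pi / 2)
                for t in self.terms
            ]
        )

    def __repr__(self) -> str:
        return f"FourierSeries({list(self.terms)!r})"


class TabulatedSeries:
    """Periodic zero-mean function given by values on a uniform tau grid.

    Secondary representation for environments that are not naturally a
    short Fourier series; evaluation uses periodic linear interpolation,
    primitives and products use FFT-based spectral quadrature.
    """

    def __init__(self, values, mean_tol: float = 1e-10):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or len(values) < 8:
            raise ValueError("values must be a 1-D array with at least 8 samples")
        m = float(values.mean())
        if abs(m) > mean_tol:
            raise ValueError(
                f"tabulated component must have zero mean over the period "
                f"(|mean| = {abs(m):.3e} > {mean_tol:.1e})"
            )
        self.values = values
        self.grid = np.linspace(0.0, 2 * np.pi, len(values), endpoint=False)

    def __call__(self, tau):
        tau = np.mod(np.asarray(tau, dtype=float), 2 * np.pi)
        ext_grid = np.append(self.grid, 2 * np.pi)
        ext_vals = np.append(self.values, self.values[0])
        out = np.interp(tau, ext_grid, ext_vals)
        return out if out.shape else float(out)

    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.values == 0.0))

    @property
    def amplitude_bound(self) -> float:
        return float(np.max(np.abs(self.values)))

    def primitive(self) -> "TabulatedSeries":
        n = len(self.values)
        spec = np.fft.rfft(self.values)
        k = np.arange(len(spec))
        with np.errstate(divide="ignore", invalid="ignore"):
            prim = np.where(k > 0, spec / (1j * k), 0.0)
        vals = np.fft.irfft(prim, n)
        vals -= vals.mean()
        return TabulatedSeries(vals)


def zero_mean_primitive(component):
    """Periodic primitive hat(f) with d hat(f)/dtau = f and zero mean.

    Requires a zero-mean input; otherwise no periodic primitive exists.
    The additive constant is fixed to make the primitive itself zero-mean
    (it drops out of the induced payoffs anyway because gt has zero mean).
    """
    if abs(component.mean()) > 1e-10:
        raise ValueError("component must have zero mean to admit a periodic primitive")
    return component.primitive()


def _product_mean(f, g) -> float:
    """Mean over one period of f(tau) * g(tau)."""
    if isinstance(f, FourierSeries) and isinstance(g, FourierSeries):
        # <A sin(k tau + phi) B sin(k tau + psi)> = (A B / 2) cos(phi - psi)
        total = 0.0
        for tf in f.terms:
            for tg in g.terms:
                if tf.harmonic == tg.harmonic:
                    total += 0.5 * tf.amplitude * tg.amplitude * np.cos(tf.phase - tg.phase)
        return total
    tau = np.linspace(0.0, 2 * np.pi, _QUAD_NODES, endpoint=False)
    return float(np.mean(f(tau) * g(tau)))


@dataclass(frozen=True)
class OscillatorySpec:
    """Zero-mean periodic rate oscillations plus the environmental frequency.

    Components are functions of the fast time tau = omega * t with period
    2*pi; ``omega > 1`` encodes the timescale separation.
    """

    omega: float
    r_tilde_A: FourierSeries | TabulatedSeries = None
    r_tilde_B: FourierSeries | TabulatedSeries = None
    gamma_tilde: FourierSeries | TabulatedSeries = None

    def __post_init__(self) -> None:
        if not self.omega > 1:
            raise ValueError(f"omega must exceed 1 (fast environment), got {self.omega}")
        for name in ("r_tilde_A", "r_tilde_B", "gamma_tilde"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, FourierSeries.zero())

    @property
    def period(self) -> float:
        """Environmental period in slow-time units, 2*pi/omega."""
        return 2 * np.pi / self.omega

    @property
    def is_zero(self) -> bool:
        return (
            self.r_tilde_A.is_zero and self.r_tilde_B.is_zero and self.gamma_tilde.is_zero
        )

    def rates_at(self, t, params: ModelParams):
        """Instantaneous (r_A, r_B, gamma) at slow time t (tau = omega*t)."""
        tau = self.omega * t
        return (
            params.r_A + self.r_tilde_A(tau),
            params.r_B + self.r_tilde_B(tau),
            params.gamma + self.gamma_tilde(tau),
        )

    def with_omega(self, omega: float) -> "OscillatorySpec":
        return replace(self, omega=omega)


@dataclass(frozen=True)
class InducedPayoffs:
    """Payoffs (xi, kappa) of the environment-induced game.

    xi acts in favour of A (fitness term phi_A = N (1 - p_A) xi) and kappa
    against A's opponent B (phi_B = -N kappa p_A).  Both scale as 1/omega
    and vanish for infinitely fast environments.
    """

    xi: float
    kappa: float

    @property
    def is_zero(self) -> bool:
        return self.xi == 0.0 and self.kappa == 0.0


def compute_induced_payoffs(osc: OscillatorySpec) -> InducedPayoffs:
    """Environment-induced payoffs from the rate oscillations.

    xi pairs the primitive of the *competitor's* reproduction oscillation
    (hat rt_B) with the HGT-balance oscillation; kappa pairs hat(rt_A)
    with it.  Exact via orthogonality for Fourier components, spectral
    quadrature otherwise.
    """
    gt = osc.gamma_tilde
    xi = _product_mean(zero_mean_primitive(osc.r_tilde_B), gt) / osc.omega
    kappa = _product_mean(zero_mean_primitive(osc.r_tilde_A), gt) / osc.omega
    return InducedPayoffs(xi=float(xi), kappa=float(kappa))


def effective_competition(params: ModelParams, payoffs: InducedPayoffs) -> ModelParams:
    """Effective averaged-environment parameters.

    Shifts the between-population competition rates by the induced
    payoffs (a_12 -> a_12 - xi, a_21 -> a_21 + kappa).  The result is
    flagged ``effective`` because a_12 - xi may legitimately be negative
    (mutualism-side regime).
    """
    return params.replace(
        a_12=params.a_12 - payoffs.xi,
        a_21=params.a_21 + payoffs.kappa,
        effective=True,
    )
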