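"""Core data containers for the two-population competition-with-HGT model.

Two microbial populations, A and B, differ by a single gene allele and
compete for a shared resource while exchanging the allele by horizontal
gene transfer (HGT).  The model state is described either by the raw
abundances ``(n_A, n_B)`` or, canonically, by the fraction of A and the
total abundance ``(p_A, N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["ModelParams", "PopulationState", "Trajectory"]


@dataclass(frozen=True)
class ModelParams:
    """Averaged/fixed-environment rates of the two-population model.

    Parameters
    ----------
    r_A, r_B:
        Reproduction rates of populations A and B (1/time, > 0).
    a_11, a_22:
        Within-population competition rates (1/(time*abundance), > 0).
    a_12, a_21:
        Between-population competition rates.  Strictly positive for a
        physical (purely competitive) ecosystem; an *effective* parameter
        set produced by environment averaging may carry a non-positive
        between-population rate, in which case ``effective=True`` relaxes
        the positivity requirement.
    gamma:
        Gene-transfer balance rate (1/(time*abundance)); ``gamma > 0``
        means net allele flow from B to A.
    effective:
        Marks parameter sets whose between-population rates were shifted
        by environment-induced payoffs (a_12 -> a_12 - xi,
        a_21 -> a_21 + kappa) and may therefore be negative.
    """

    r_A: float
    r_B: float
    a_11: float
    a_12: float
    a_21: float
    a_22: float
    gamma: float = 0.0
    effective: bool = False

    def __post_init__(self) -> None:
        if not (self.r_A > 0 and self.r_B > 0):
            raise ValueError(
                f"reproduction rates must be positive, got r_A={self.r_A}, r_B={self.r_B}"
            )
        if not (self.a_11 > 0 and self.a_22 > 0):
            raise ValueError(
                f"within-population competition rates must be positive, "
                f"got a_11={self.a_11}, a_22={self.a_22}"
            )
        if not self.effective and not (self.a_12 > 0 and self.a_21 > 0):
            raise ValueError(
                f"between-population competition rates must be positive, "
                f"got a_12={self.a_12}, a_21={self.a_21} "
                "(use effective=True for environment-shifted rates)"
            )

    @classmethod
    def symmetric(
        cls, r_A: float, r_B: float, a: float, gamma: float = 0.0
    ) -> "ModelParams":
        """Equal-competition parameter set a_ij = a (single-allele scenario)."""
        return cls(r_A=r_A, r_B=r_B, a_11=a, a_12=a, a_21=a, a_22=a, gamma=gamma)

    @property
    def equal_competition(self) -> bool:
        """True when all four competition rates coincide."""
        a = self.a_11
        return self.a_12 == a and self.a_21 == a and self.a_22 == a

    @property
    def competition_matrix(self) -> np.ndarray:
        """Community matrix [[a_11, a_12 - gamma], [a_21 + gamma, a_22]]."""
        return np.array(
            [
                [self.a_11, self.a_12 - self.gamma],
                [self.a_21 + self.gamma, self.a_22],
            ]
        )

    def as_dict(self) -> dict:
        return {
            "r_A": self.r_A,
            "r_B": self.r_B,
            "a_11": self.a_11,
            "a_12": self.a_12,
            "a_21": self.a_21,
            "a_22": self.a_22,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationState:
    """State of the community: fraction of A and total abundance.

    ``p_B`` is always ``1 - p_A`` and is never stored independently.
    """

    p_A: float
    N: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_A <= 1.0:
            raise ValueError(f"p_A must lie in [0, 1], got {self.p_A}")
        if self.N < 0.0:
            raise ValueError(f"total abundance N must be non-negative, got {self.N}")

    @property
    def p_B(self) -> float:
        return 1.0 - self.p_A

    @property
    def n_A(self) -> float:
        return self.p_A * self.N

    @property
    def n_B(self) -> float:
        return (1.0 - self.p_A) * self.N

    @classmethod
    def from_counts(cls, n_A: float, n_B: float) -> "PopulationState":
        N = n_A + n_B
        return cls(p_A=n_A / N if N > 0 else 0.0, N=N)

    def as_array(self) -> np.ndarray:
        return np.array([self.p_A, self.N])


@dataclass
class Trajectory:
    """Time-discretised solution of the model in ``(p_A, N)`` coordinates."""

    times: np.ndarray
    p_A: np.ndarray
    N: np.ndarray
    rate_mode: str = "constant"  # constant | oscillating | coarse_grained
    diverged: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_A = np.asarray(self.p_A, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if not (len(self.times) == len(self.p_A) == len(self.N)):
            raise ValueError("times, p_A and N must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def p_B(self) -> np.ndarray:
        return 1.0 - self.p_A

    @property
    def n_A(self) -> np.ndarray:
        return self.p_A * self.N

    @property
    def n_B(self) -> np.ndarray:
        return (1.0 - self.p_A) * self.N

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(p_A=float(self.p_A[-1]), N=float(self.N[-1]))

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[PopulationState]:
        for p, n in zip(self.p_A, self.N):
            yield PopulationState(p_A=float(p), N=float(n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "p_A": self.p_A,
                "p_B": self.p_B,
                "N": self.N,
                "n_A": self.n_A,
                "n_B": self.n_B,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
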