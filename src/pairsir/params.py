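"""Model parameters for pairwise SIR dynamics on clustered regular networks.

The epidemic runs on a static, undirected, regular network of ``N`` nodes of
degree ``n``.  Infection passes across each susceptible--infected link at rate
``tau`` and infected nodes recover at rate ``gamma``.  The global clustering
coefficient ``phi`` measures the fraction of connected triples that are closed
into triangles and enters the model only through the moment closures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "ModelParams",
    "ValidationError",
    "DegenerateStateError",
    "NoFeasibleRootError",
    "NoEquilibriumError",
    "CLOSURES",
]

#: Closure tags accepted by the closed ODE systems and fast subsystems.
CLOSURES = ("simple", "compact_improved")


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class DegenerateStateError(ValidationError):
    """Raised when a closure or correlation is evaluated at a state where a
    required singles count vanishes and the expression has no finite limit."""


class NoFeasibleRootError(RuntimeError):
    """Raised when a steady-state polynomial has no root in the biologically
    feasible interval (0, n]."""


class NoEquilibriumError(RuntimeError):
    """Raised when the fast subsystem admits no interior quasi-equilibrium for
    the requested parameters, or relaxation fails to converge."""


@dataclass(frozen=True)
class ModelParams:
    """Parameter tuple (N, n, tau, gamma, phi) of the pairwise model.

    Parameters
    ----------
    N : float
        Population size (number of nodes), > 0.
    n : float
        Common degree of the regular network, >= 2 (typically an integer >= 3).
    tau : float
        Per-link transmission rate, 1/time, >= 0.
    gamma : float
        Recovery rate, 1/time, > 0.
    phi : float
        Global clustering coefficient, dimensionless, in [0, 1].

    The derived constant ``xi = (n - 1) / n`` appears throughout the closed
    equations and is exposed as a property so it can never be stored
    inconsistently.
    """

    N: float = 10_000.0
    n: float = 5.0
    tau: float = 1.0
    gamma: float = 1.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValidationError(f"population size N must be positive, got {self.N}")
        if not self.n >= 2:
            raise ValidationError(f"degree n must be >= 2, got {self.n}")
        if not self.tau >= 0:
            raise ValidationError(f"transmission rate tau must be >= 0, got {self.tau}")
        if not self.gamma > 0:
            raise ValidationError(f"recovery rate gamma must be > 0, got {self.gamma}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValidationError(f"clustering coefficient phi must lie in [0, 1], got {self.phi}")

    @property
    def xi(self) -> float:
        """The combinatorial factor (n - 1)/n of the closures."""
        return (self.n - 1.0) / self.n

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        import dataclasses

        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {"N": self.N, "n": self.n, "tau": self.tau, "gamma": self.gamma, "phi": self.phi}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        """Build parameters from a config mapping, ignoring unrelated keys."""
        keys = {"N", "n", "tau", "gamma", "phi"}
        return cls(**{k: float(v) for k, v in mapping.items() if k in keys})


@dataclass
class PairwiseState:
    """Expected counts of singles and pairs: [S], [I], [SI], [SS], [II].

    Recovered nodes are implicit: [R] = N - [S] - [I].  Pairs are counted once
    in each direction, so [SS] and [II] carry even-count semantics and
    [SI] = [IS].  All fields are continuous mean-field expectations; no
    integrality is imposed.
    """

    S: float
    I: float
    SI: float
    SS: float
    II: float

    def as_array(self):
        import numpy as np

        return np.array([self.S, self.I, self.SI, self.SS, self.II], dtype=float)

    @classmethod
    def from_array(cls, y) -> "PairwiseState":
        return cls(S=float(y[0]), I=float(y[1]), SI=float(y[2]), SS=float(y[3]), II=float(y[4]))

    def validate(self, params: ModelParams, tol: float = 0.0) -> None:
        """Check the admissibility invariants, allowing slack ``tol``.

        Raises :class:`ValidationError` when a count is negative, the singles
        exceed N, or a pair count exceeds the available stubs (n x singles).
        """
        n, N = params.n, params.N
        checks = [
            (self.S >= -tol, "S >= 0"),
            (self.I >= -tol, "I >= 0"),
            (self.SI >= -tol, "SI >= 0"),
            (self.SS >= -tol, "SS >= 0"),
            (self.II >= -tol, "II >= 0"),
            (self.S + self.I <= N + tol, "S + I <= N"),
            (self.SS <= n * self.S + tol, "SS <= n*S"),
            (self.II <= n * self.I + tol, "II <= n*I"),
            (self.SI <= n * self.S + tol, "SI <= n*S"),
            (self.SI <= n * self.I + tol, "SI <= n*I"),
        ]
        for ok, label in checks:
            if not ok:
                raise ValidationError(f"pairwise state violates {label}: {self}")
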