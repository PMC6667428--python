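"""Closed pairwise SIR systems and their numerical integration.

The unclosed pairwise SIR model tracks expected singles and pairs:

    d[S]/dt  = -tau [SI]
    d[I]/dt  =  tau [SI] - gamma [I]
    d[SI]/dt =  tau ([SSI] - [ISI] - [SI]) - gamma [SI]
    d[SS]/dt = -2 tau [SSI]
    d[II]/dt =  2 tau ([ISI] + [SI]) - 2 gamma [II]

Substituting a closure for the triples [SSI] and [ISI] makes the system
self-contained.  Two closed systems are provided, one per closure tag
("simple" and "compact_improved").

Divisions by [S] or [I] are evaluated in a factored form: every term that
carries a 1/[I] or 1/[I]^2 factor is multiplied by at least one power of [SI]
or [II], and when that numerator is exactly zero the term is defined as 0.
This matches the continuous limits of the closed equations and keeps the
solver stable through extinction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import CLOSURES, ModelParams, PairwiseState, ValidationError

__all__ = [
    "Trajectory",
    "rhs_closed",
    "initial_conditions",
    "integrate_epidemic",
    "final_epidemic_size",
    "EXTINCTION_THRESHOLD",
]

#: An epidemic counts as extinct once [I] drops below this (far below one node).
EXTINCTION_THRESHOLD = 1e-6

#: Default solver tolerances; the fast/slow structure makes the system mildly
#: stiff near t = 0, so an adaptive stiff-capable method is used.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def _safe_div(num: float, den: float) -> float:
    """num/den with the convention 0/0 = 0 (continuous limit of closure terms)."""
    if num == 0.0:
        return 0.0
    return num / den


def _check_closure(closure: str) -> None:
    if closure not in CLOSURES:
        raise ValueError(f"closure must be one of {CLOSURES}, got {closure!r}")


def _rhs_vector(y: np.ndarray, params: ModelParams, closure: str) -> np.ndarray:
    S, I, SI, SS, II = y
    n, N, tau, gamma, phi, xi = params.n, params.N, params.tau, params.gamma, params.phi, params.xi

    if closure == "simple":
        # [SSI] = xi SS SI / S * ((1-phi) + phi N SI / (n S I))
        SSI = xi * (1.0 - phi) * _safe_div(SS * SI, S) + xi * phi * N / n * _safe_div(SS * SI * SI, S * S * I)
        # [ISI] = xi SI^2 / S * ((1-phi) + phi N II / (n I^2))
        ISI = xi * (1.0 - phi) * _safe_div(SI * SI, S) + xi * phi * N / n * _safe_div(SI * SI * II, S * I * I)
    else:
        # compact improved: clustered part shares the denominator
        # D = [SS]/[S] + [II]/[I]  (one power of [SI] cancelled)
        D = _safe_div(SS, S) + _safe_div(II, I)
        SSI = (n - 1.0) * ((1.0 - phi) / n * _safe_div(SS * SI, S) + phi * _safe_div(SS * SI, S * D))
        ISI = (n - 1.0) * ((1.0 - phi) / n * _safe_div(SI * SI, S) + phi * _safe_div(SI * II, I * D))

    dS = -tau * SI
    dI = tau * SI - gamma * I
    dSI = tau * (SSI - ISI - SI) - gamma * SI
    dSS = -2.0 * tau * SSI
    dII = 2.0 * tau * (ISI + SI) - 2.0 * gamma * II
    return np.array([dS, dI, dSI, dSS, dII])


def rhs_closed(state: PairwiseState, params: ModelParams, closure: str) -> PairwiseState:
    """Time derivatives of (S, I, SI, SS, II) under the requested closure.

    Returns a :class:`PairwiseState` whose fields hold d/dt of each count.
    """
    _check_closure(closure)
    return PairwiseState.from_array(_rhs_vector(state.as_array(), params, closure))


def initial_conditions(params: ModelParams, I0: float = 1.0) -> PairwiseState:
    """Random-labelling initial conditions with I0 initially infected nodes.

    S = N - I0, I = I0, and the pairs take their random-labelling values
    SI = n I0 S / N, SS = n S^2 / N, II = n I0^2 / N, so that all correlation
    factors equal one at t = 0.
    """
    N, n = params.N, params.n
    if not 0 < I0 < N:
        raise ValidationError(f"I0 must lie strictly between 0 and N, got {I0}")
    S0 = N - I0
    return PairwiseState(
        S=S0,
        I=I0,
        SI=n * I0 * S0 / N,
        SS=n * S0 * S0 / N,
        II=n * I0 * I0 / N,
    )


@dataclass
class Trajectory:
    """Numerical solution of a closed pairwise system.

    ``y`` has shape (5, len(times)) with rows S, I, SI, SS, II.
    """

    times: np.ndarray
    y: np.ndarray
    params: ModelParams
    closure: str
    I0: float
    R: Optional[np.ndarray] = None  # implied recovered count, integrated as dR/dt = gamma I

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")

    @property
    def S(self) -> np.ndarray:
        return self.y[0]

    @property
    def I(self) -> np.ndarray:
        return self.y[1]

    @property
    def SI(self) -> np.ndarray:
        return self.y[2]

    @property
    def SS(self) -> np.ndarray:
        return self.y[3]

    @property
    def II(self) -> np.ndarray:
        return self.y[4]

    def state_at(self, index: int) -> PairwiseState:
        return PairwiseState.from_array(self.y[:, index])

    @property
    def final_state(self) -> PairwiseState:
        return self.state_at(-1)

    @property
    def extinct(self) -> bool:
        return bool(self.I[-1] < EXTINCTION_THRESHOLD)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "S": self.S, "I": self.I, "SI": self.SI, "SS": self.SS, "II": self.II}
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write time,S,I,SI,SS,II to CSV plus a JSON metadata sidecar."""
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {"params": self.params.as_dict(), "closure": self.closure, "I0": self.I0}
            with open(str(path) + ".json", "w") as handle:
                json.dump(meta, handle, indent=2)


def integrate_epidemic(
    params: ModelParams,
    closure: str,
    I0: float = 1.0,
    t_max: float = 1000.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_eval: Optional[np.ndarray] = None,
) -> Trajectory:
    """Integrate the closed pairwise system from random-labelling conditions.

    Uses an adaptive stiff-capable solver (LSODA).  The default horizon
    ``t_max = 1000`` is long enough for the epidemic to die out at the
    parameter scales of interest (rates of order one).
    """
    _check_closure(closure)
    y0 = np.append(initial_conditions(params, I0).as_array(), 0.0)  # last entry: recovered

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        d = _rhs_vector(y[:5], params, closure)
        return np.append(d, params.gamma * y[1])

    sol = solve_ivp(
        rhs,
        (0.0, float(t_max)),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed for closure={closure!r}, params={params}: {sol.message}")
    return Trajectory(times=sol.t, y=sol.y[:5], params=params, closure=closure, I0=float(I0), R=sol.y[5])


def final_epidemic_size(
    params: ModelParams,
    closure: str,
    I0: float = 1.0,
    t_max: float = 1000.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Attack rate (N - S(t_max)) / N: the fraction ever infected, seeds included."""
    traj = integrate_epidemic(params, closure, I0=I0, t_max=t_max, rtol=rtol, atol=atol)
    return float((params.N - traj.S[-1]) / params.N)
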