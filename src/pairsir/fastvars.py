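"""Fast correlation variables alpha = [SI]/[I] and delta = [II]/[I].

Early in an epidemic these two ratios equilibrate much faster than prevalence
itself, so their quasi-equilibrium (the steady state of the planar "fast"
subsystem) characterises the initial growth and hence the epidemic threshold
R = tau * alpha* / gamma.

For each closure the module provides the planar right-hand side, the null
clines, the Bendixson divergence used to exclude limit cycles, the invariant
triangular region

    D = {(alpha, delta): 0 <= alpha <= n, 0 <= delta <= n - alpha},

and two independent routes to the quasi-equilibrium (relaxation of the fast
ODEs and a direct root find seeded by the asymptotic expansion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import CLOSURES, ModelParams, NoEquilibriumError

__all__ = [
    "FastState",
    "StabilityReport",
    "NullClines",
    "rhs_fast",
    "nullclines",
    "bendixson_divergence",
    "stability_conditions",
    "quasi_equilibrium",
    "in_region_D",
]

#: Pole-exclusion window for null-cline evaluation; plotting code must window
#: poles explicitly rather than receive huge floats.
POLE_TOL = 1e-9


@dataclass(frozen=True)
class FastState:
    """The fast-variable pair (alpha, delta) = ([SI]/[I], [II]/[I])."""

    alpha: float
    delta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.delta])


def in_region_D(fast: FastState, params: ModelParams) -> bool:
    """Closed-boundary membership test for the invariant triangle D."""
    n = params.n
    return 0.0 <= fast.alpha <= n and 0.0 <= fast.delta <= n - fast.alpha


def _check_closure(closure: str) -> None:
    if closure not in CLOSURES:
        raise ValueError(f"closure must be one of {CLOSURES}, got {closure!r}")


def _rhs_fast_vector(v: np.ndarray, params: ModelParams, closure: str) -> np.ndarray:
    alpha, delta = v
    n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi
    if closure == "simple":
        da = (
            -tau * alpha
            + tau * xi * n * (1.0 - phi) * alpha
            + tau * xi * phi * alpha**2
            - tau * xi / n * phi * alpha**2 * delta
            - tau * alpha**2
        )
        dd = 2.0 * tau * alpha - gamma * delta + 2.0 * tau * xi / n * phi * alpha**2 * delta - tau * alpha * delta
    else:
        da = (
            -tau * alpha
            - tau * alpha**2
            + tau * (n - 1.0) * ((1.0 - phi) * alpha + phi * alpha * (n - delta) / (n + delta))
        )
        dd = (
            2.0 * tau * alpha
            - gamma * delta
            + 2.0 * tau * (n - 1.0) * phi * alpha * delta / (n + delta)
            - tau * alpha * delta
        )
    return np.array([da, dd])


def rhs_fast(fast: FastState, params: ModelParams, closure: str) -> tuple[float, float]:
    """(d alpha/dt, d delta/dt) for the requested closure."""
    _check_closure(closure)
    da, dd = _rhs_fast_vector(fast.as_array(), params, closure)
    return float(da), float(dd)


class NullClines(NamedTuple):
    """Null clines of the planar fast system.

    For the simple closure both are functions of alpha: ``first`` is
    delta_1(alpha) (the d alpha/dt = 0 cline) and ``second`` is
    delta_2(alpha) (the d delta/dt = 0 cline).  For the compact improved
    closure ``first`` is delta_n(alpha) and ``second`` is alpha_n(delta),
    the latter taking delta as its argument.
    """

    first: Callable[[float], float]
    second: Callable[[float], float]
    closure: str


def _guard_pole(den: float, what: str) -> None:
    if abs(den) < POLE_TOL:
        raise ZeroDivisionError(f"null cline {what} evaluated within {POLE_TOL} of a pole")


def nullclines(params: ModelParams, closure: str) -> NullClines:
    """Return the two null clines of the fast system as callables.

    Evaluation within 1e-9 of a singularity raises ``ZeroDivisionError``.
    For the simple closure with phi = 0 the d alpha/dt cline degenerates to
    the vertical line alpha = n - 2 and cannot be written as delta(alpha);
    requesting it raises ``ZeroDivisionError`` as well.
    """
    _check_closure(closure)
    n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi

    if closure == "simple":

        def delta_1(alpha: float) -> float:
            _guard_pole(xi * phi, "delta_1 (requires phi > 0)")
            _guard_pole(alpha, "delta_1 at alpha = 0")
            return n / (xi * phi) * ((xi * n * (1.0 - phi) - 1.0) / alpha + xi * phi - 1.0)

        def delta_2(alpha: float) -> float:
            den = gamma + tau * alpha - 2.0 * tau * xi / n * phi * alpha**2
            _guard_pole(den, "delta_2")
            return 2.0 * tau * alpha / den

        return NullClines(first=delta_1, second=delta_2, closure=closure)

    def delta_n(alpha: float) -> float:
        den = alpha + 2.0 * phi * (n - 1.0) - (n - 2.0)
        _guard_pole(den, "delta_n")
        return n * ((n - 2.0) - alpha) / den

    def alpha_n(delta: float) -> float:
        den = tau * (-(delta**2) + (2.0 * (n - 1.0) * phi - (n - 2.0)) * delta + 2.0 * n)
        _guard_pole(den, "alpha_n")
        return gamma * delta * (n + delta) / den

    return NullClines(first=delta_n, second=alpha_n, closure=closure)


def bendixson_divergence(fast: FastState, params: ModelParams, closure: str) -> float:
    """Divergence B(alpha, delta) of the fast field scaled by 1/alpha.

    If B keeps one sign on D no periodic orbit can exist there (Bendixson),
    which upgrades local stability of the unique interior steady state to
    global stability on D.
    """
    _check_closure(closure)
    if fast.alpha <= 0:
        raise ZeroDivisionError("Bendixson divergence requires alpha > 0")
    n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi
    if closure == "simple":
        return -2.0 * tau - gamma / fast.alpha + phi * (tau * xi / n) * (n - fast.delta + 2.0 * fast.alpha)
    return -2.0 * tau - gamma / fast.alpha + 2.0 * tau * phi * n * (n - 1.0) / (n + fast.delta) ** 2


@dataclass(frozen=True)
class StabilityReport:
    """Feasibility and global-stability conditions on phi for degree n.

    ``feasibility_ok``
        phi < (n-2)/(n-1): the simple-closure fast system has an interior
        steady state (above this bound the disease dies out).
    ``bendixson_ok``
        phi < 2n/(3(n-1)): the Bendixson argument excludes limit cycles for
        the simple closure; beyond it global stability is not certified
        (numerics suggest it still holds, but no claim is made).
    ``improved_feasibility_ok``
        2 phi < (n-2)/(n-1): the sign condition in the invariance argument of
        the compact improved fast system.
    ``delta2_singularity_in_range``
        Edge regime: the pole of the delta_2 null cline falls inside (0, n).
        Root bracketing still applies; flagged for transparency.
    """

    feasibility_ok: bool
    bendixson_ok: bool
    improved_feasibility_ok: bool
    bounds: dict
    delta2_singularity_in_range: bool = False


def stability_conditions(params: ModelParams) -> StabilityReport:
    """Evaluate the closed-form stability/feasibility bounds on phi."""
    n, phi = params.n, params.phi
    if n <= 2:
        bounds = {"feasibility": 0.0, "bendixson": 2.0 * n / (3.0 * (n - 1.0)), "improved_feasibility": 0.0}
        return StabilityReport(False, False, False, bounds)
    bounds = {
        "feasibility": (n - 2.0) / (n - 1.0),
        "bendixson": 2.0 * n / (3.0 * (n - 1.0)),
        "improved_feasibility": (n - 2.0) / (2.0 * (n - 1.0)),
    }
    # pole of delta_2: positive root of (2 tau xi phi / n) a^2 - tau a - gamma = 0
    sing_in_range = False
    tau, gamma, xi = params.tau, params.gamma, params.xi
    c2 = 2.0 * tau * xi * phi / n
    if c2 > 0 and tau > 0:
        a_pole = (tau + math.sqrt(tau**2 + 4.0 * c2 * gamma)) / (2.0 * c2)
        sing_in_range = 0.0 < a_pole < n
    return StabilityReport(
        feasibility_ok=phi < bounds["feasibility"],
        bendixson_ok=phi < bounds["bendixson"],
        improved_feasibility_ok=2.0 * phi < bounds["feasibility"],
        bounds=bounds,
        delta2_singularity_in_range=sing_in_range,
    )


#: Relaxation convergence threshold on the sup-norm of the fast field.
RELAX_TOL = 1e-10
#: Relaxation horizon in units of 1/gamma; exceeding it raises an error.  Near
#: the die-out boundary phi -> (n-2)/(n-1) the slow eigenvalue of the fast
#: system approaches zero, so the horizon is generous; integration proceeds in
#: chunks and exits as soon as the field norm is small, which keeps the cost
#: low away from the boundary.
RELAX_HORIZON = 2000.0


def _relaxation_start(params: ModelParams, I0: float = 1.0) -> np.ndarray:
    """Fast-variable image of the random-labelling initial conditions:
    alpha(0) = n S0/N, delta(0) = n I0/N."""
    return np.array([params.n * (params.N - I0) / params.N, params.n * I0 / params.N])


def _feasible(params: ModelParams, closure: str) -> bool:
    if closure == "simple":
        return params.n > 2 and params.phi < (params.n - 2.0) / (params.n - 1.0)
    return params.n > 2  # the compact improved system is essentially unconstrained


def quasi_equilibrium(params: ModelParams, closure: str, method: str = "ode_relaxation") -> FastState:
    """Unique interior steady state of the fast subsystem inside D.

    ``method="ode_relaxation"`` integrates the fast ODEs from the image of
    the standard initial conditions until the field's sup-norm drops below
    1e-10 (error if not within t = 200/gamma).  ``method="root_find"`` solves
    rhs = 0 directly, seeded by the first-order asymptotic expansion in phi.
    The two routes agree to well within 1e-6 on feasible parameters.
    """
    _check_closure(closure)
    if params.tau <= 0:
        raise NoEquilibriumError("quasi-equilibrium requires tau > 0 (no transmission, no interior state)")
    if not _feasible(params, closure):
        raise NoEquilibriumError(
            f"no interior quasi-equilibrium: closure={closure!r}, n={params.n}, phi={params.phi} "
            f"violates the feasibility condition"
        )

    if method == "ode_relaxation":
        v = _relaxation_start(params)
        t_end = RELAX_HORIZON / params.gamma
        chunk = 20.0 / params.gamma
        t = 0.0
        while t < t_end:
            sol = solve_ivp(
                lambda _t, y: _rhs_fast_vector(y, params, closure),
                (0.0, chunk),
                v,
                method="LSODA",
                rtol=1e-12,
                atol=1e-14,
            )
            if not sol.success:
                raise NoEquilibriumError(f"fast-system relaxation failed: {sol.message}")
            v = sol.y[:, -1]
            t += chunk
            if np.max(np.abs(_rhs_fast_vector(v, params, closure))) < RELAX_TOL:
                return FastState(alpha=float(v[0]), delta=float(v[1]))
        raise NoEquilibriumError(
            f"fast-system relaxation did not converge within t = {RELAX_HORIZON}/gamma "
            f"(closure={closure!r}, params={params})"
        )

    if method == "root_find":
        from .thresholds import expansion  # lazy: thresholds imports FastState from here

        exp = expansion(params, closure)
        n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi
        alpha_guess = min(max(exp.alpha_at_phi, 1e-3), params.n - 1e-3)
        den = gamma + tau * alpha_guess - 2.0 * tau * xi / n * phi * alpha_guess**2
        delta_guess = 2.0 * tau * alpha_guess / den if den > 0 else 1.0
        sol = root(
            lambda y: _rhs_fast_vector(y, params, closure),
            np.array([alpha_guess, delta_guess]),
            tol=1e-13,
        )
        if not sol.success:
            raise NoEquilibriumError(f"root find for the fast steady state failed: {sol.message}")
        fast = FastState(alpha=float(sol.x[0]), delta=float(sol.x[1]))
        if fast.alpha <= 0 or not in_region_D(fast, params):
            raise NoEquilibriumError(f"root find converged outside D: {fast}")
        return fast

    raise ValueError(f"method must be 'ode_relaxation' or 'root_find', got {method!r}")
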