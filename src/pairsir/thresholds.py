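"""Epidemic thresholds for clustered regular networks.

The growth-rate threshold of the pairwise model is R = tau * alpha* / gamma,
where alpha* = [SI]/[I] at the quasi-equilibrium of the fast subsystem.  For
each closure, alpha* is the feasible root of a cubic steady-state equation:

* simple closure: a cubic in alpha whose leading coefficient vanishes
  identically at phi = 0, where the feasible root is alpha = n - 2;
* compact improved closure: a cubic in delta (with the shorthands
  A = (n-2) - 2 phi (n-1) and B = gamma/tau), mapped back to alpha through
  alpha = (n-2) - 2 (n-1) phi delta / (n + delta).

First-order asymptotic expansions in phi give closed-form approximations to
the roots and hence analytic thresholds R^c (simple) and R^cci (compact
improved).  A comparison suite implements alternative thresholds from the
literature: Keeling's quasi-equilibrium correlation C*_SI, the
next-generation-matrix R0, the motif-closure R0 of Li et al., Miller's
percolation expansion for clustered regular networks, and the household
reproduction number R* for households of size three with regular global
degree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .fastvars import FastState, stability_conditions
from .params import CLOSURES, ModelParams, NoFeasibleRootError, ValidationError

__all__ = [
    "CubicCoefficients",
    "ExpansionResult",
    "ThresholdResult",
    "HouseholdParams",
    "cubic_coefficients",
    "solve_steady_state",
    "expansion",
    "threshold",
    "keeling_CSI_star",
    "ngm_R0",
    "li_R0",
    "miller_R0_regular",
    "household_R_star",
    "household_phi_from_mu_D",
    "household_mu_D_from_phi",
]

#: Relative threshold below which the cubic's leading coefficient is treated
#: as zero and the polynomial degree is reduced (the simple-closure cubic
#: degenerates exactly at phi = 0).
DEGENERATE_LEAD_TOL = 1e-12


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients (c3, c2, c1, c0) of a steady-state cubic, highest first.

    ``variable`` records whether the cubic is in alpha (simple closure) or in
    delta (compact improved closure); ``aux`` holds the intermediates used to
    build it.
    """

    c3: float
    c2: float
    c1: float
    c0: float
    closure: str
    variable: str
    aux: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.c3, self.c2, self.c1, self.c0])


def cubic_coefficients(params: ModelParams, closure: str) -> CubicCoefficients:
    """Steady-state cubic of the fast subsystem for the requested closure."""
    if closure not in CLOSURES:
        raise ValueError(f"closure must be one of {CLOSURES}, got {closure!r}")
    n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi
    if closure == "simple":
        c3 = 2.0 * tau * xi * phi * (1.0 - xi * phi)
        c2 = tau * xi * n * phi - 2.0 * tau * xi**2 * n * phi * (1.0 - phi) - tau * n
        c1 = -n * (tau + gamma) + tau * xi * n**2 * (1.0 - phi) + gamma * xi * n * phi
        c0 = gamma * xi * n**2 * (1.0 - phi) - gamma * n
        return CubicCoefficients(c3, c2, c1, c0, closure=closure, variable="alpha")
    if tau <= 0:
        raise ValidationError("compact improved cubic requires tau > 0 (B = gamma/tau)")
    A = (n - 2.0) - 2.0 * phi * (n - 1.0)
    B = gamma / tau
    c3 = -A - B
    c2 = -n * (n - 2.0) - A**2 - 2.0 * n * B
    c1 = -n * (n - 2.0) * A + 2.0 * n * A - n**2 * B
    c0 = 2.0 * n**2 * (n - 2.0)
    return CubicCoefficients(c3, c2, c1, c0, closure=closure, variable="delta", aux={"A": A, "B": B})


def _real_roots(coeffs: np.ndarray) -> np.ndarray:
    """Real roots of a polynomial, reducing degree when leading terms vanish."""
    scale = np.max(np.abs(coeffs))
    if scale == 0:
        return np.array([])
    c = coeffs.copy()
    while len(c) > 1 and abs(c[0]) < DEGENERATE_LEAD_TOL * scale:
        c = c[1:]
    if len(c) <= 1:
        return np.array([])
    roots = np.roots(c)
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots))]
    return np.sort(real.real)


def _map_delta_to_alpha(delta: float, params: ModelParams) -> float:
    """alpha = (n-2) - 2 (n-1) phi delta / (n + delta), from the alpha null cline."""
    n, phi = params.n, params.phi
    return (n - 2.0) - (n - 1.0) * phi * 2.0 * delta / (n + delta)


def _delta_at_alpha_simple(alpha: float, params: ModelParams) -> float:
    """Steady-state delta given alpha for the simple closure (delta_2 cline)."""
    n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi
    return 2.0 * tau * alpha / (gamma + tau * alpha - 2.0 * tau * xi / n * phi * alpha**2)


def solve_steady_state(coeffs: CubicCoefficients, params: ModelParams) -> FastState:
    """Feasible root of the steady-state cubic as a fast-variable pair.

    All real roots are computed; the unique root in (0, n] is selected.  For
    the compact improved closure the cubic is in delta and the feasible delta
    root is mapped to alpha.  If several roots fall in (0, n], the one
    continuous with the phi -> 0 limit (closest to the asymptotic expansion)
    is chosen and a multiplicity warning is issued.
    """
    n = params.n
    roots = _real_roots(coeffs.as_array())
    feasible = [r for r in roots if 1e-12 < r <= n * (1.0 + 1e-12)]
    if not feasible:
        report = stability_conditions(params)
        raise NoFeasibleRootError(
            f"no real root in (0, {n}] for closure={coeffs.closure!r}; "
            f"feasibility flags: {report}"
        )
    if len(feasible) > 1:
        exp = expansion(params, coeffs.closure)
        target = exp.value_at_phi
        feasible.sort(key=lambda r: abs(r - target))
        warnings.warn(
            f"multiple feasible roots {feasible} in (0, {n}]; choosing the one closest "
            f"to the asymptotic expansion ({target:.6g})",
            RuntimeWarning,
        )
    root_value = float(feasible[0])
    if coeffs.variable == "alpha":
        return FastState(alpha=root_value, delta=_delta_at_alpha_simple(root_value, params))
    return FastState(alpha=_map_delta_to_alpha(root_value, params), delta=root_value)


@dataclass(frozen=True)
class ExpansionResult:
    """First-order asymptotic expansion of the steady-state root in phi.

    ``order0`` and ``order1`` are the coefficients of the expanded variable
    (alpha for the simple closure, delta for the compact improved closure);
    ``value_at_phi`` is the truncated series order0 + phi * order1 evaluated
    at the parameters' phi, and ``alpha_at_phi`` is the corresponding alpha
    (identical to value_at_phi for the simple closure).
    """

    order0: float
    order1: float
    value_at_phi: float
    alpha_at_phi: float
    closure: str
    variable: str


def expansion(params: ModelParams, closure: str) -> ExpansionResult:
    """First-order expansion of the feasible steady-state root in powers of phi."""
    if closure not in CLOSURES:
        raise ValueError(f"closure must be one of {CLOSURES}, got {closure!r}")
    n, tau, gamma, phi = params.n, params.tau, params.gamma, params.phi
    if n <= 2:
        raise ValidationError("expansion requires n > 2 (alpha_0 = n - 2 must be positive)")
    if closure == "simple":
        alpha0 = n - 2.0
        alpha1 = -2.0 * (n - 1.0) / n**2 * (
            (2.0 * tau * (n - 1.0) * (n - 2.0) + gamma * n) / (tau * (n - 2.0) + gamma)
        )
        value = alpha0 + phi * alpha1
        return ExpansionResult(alpha0, alpha1, value, value, closure=closure, variable="alpha")
    delta0 = 2.0 * tau * (n - 2.0) / (gamma + tau * (n - 2.0))
    delta1 = (
        2.0 * tau * (n - 1.0) * delta0 * (n - 4.0 + delta0)
        / (gamma * (n + 3.0 * delta0) + tau * (n - 2.0) * (n + 3.0 * delta0 - 4.0))
    )
    value = delta0 + phi * delta1
    alpha = (n - 2.0) - phi * 4.0 * tau * (n - 1.0) * (n - 2.0) / (tau * (n + 2.0) * (n - 2.0) + gamma * n)
    return ExpansionResult(delta0, delta1, value, alpha, closure=closure, variable="delta")


@dataclass(frozen=True)
class ThresholdResult:
    """A threshold value R with its method tag and supporting context.

    The epidemic grows when R > 1 and dies out when R < 1.  ``valid``
    reflects the feasibility flags of the fast system at these parameters;
    ``extras`` carries method-specific by-products (expansion coefficients,
    decompositions).
    """

    R: float
    method: str
    quasi_eq: Optional[FastState] = None
    valid: bool = True
    notes: str = ""
    extras: dict = field(default_factory=dict)


def threshold(params: ModelParams, closure: str, method: str = "cubic_numeric") -> ThresholdResult:
    """Growth-rate threshold R = tau alpha* / gamma for the requested closure.

    ``method="cubic_numeric"`` solves the steady-state cubic; ``"asymptotic"``
    uses the first-order expansion in phi.  For the simple closure the
    asymptotic result is also reported in the R-parametrised form
    R^c = R - phi a (tau/gamma) (aR + 1)/(R + 1) with a = 2(n-1)/n.
    """
    if closure not in CLOSURES:
        raise ValueError(f"closure must be one of {CLOSURES}, got {closure!r}")
    n, tau, gamma = params.n, params.tau, params.gamma
    report = stability_conditions(params)
    valid = report.feasibility_ok if closure == "simple" else n > 2
    if method == "cubic_numeric":
        fast = solve_steady_state(cubic_coefficients(params, closure), params)
        return ThresholdResult(R=tau * fast.alpha / gamma, method="cubic_numeric", quasi_eq=fast, valid=valid)
    if method == "asymptotic":
        exp = expansion(params, closure)
        R_val = tau * exp.alpha_at_phi / gamma
        extras = {"order0": exp.order0, "order1": exp.order1}
        if closure == "simple":
            R_uncl = tau * (n - 2.0) / gamma
            a = 2.0 * (n - 1.0) / n
            extras["R_parametrised"] = R_uncl - params.phi * a * tau / gamma * (a * R_uncl + 1.0) / (R_uncl + 1.0)
        return ThresholdResult(R=R_val, method="asymptotic", valid=valid, extras=extras)
    raise ValueError(f"method must be 'cubic_numeric' or 'asymptotic', got {method!r}")


def keeling_CSI_star(params: ModelParams) -> float:
    """Quasi-equilibrium correlation C*_SI of Keeling's early-growth analysis.

    Solves, with beta = tau n,

        1 + C - n xi (1 - C)(1 - phi)
          + 2 beta xi phi C^2 / (gamma + beta C - 2 xi beta C^2 phi) = 0

    for C in (0, 1) after clearing the denominator (whose sign is monitored).
    At phi = 0 the closed form is C*_SI = (n - 2)/n.  Through C_SI = alpha/n
    this equation is equivalent to the simple-closure steady-state cubic.
    """
    n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi
    if n <= 2 or phi >= (n - 2.0) / (n - 1.0):
        raise NoFeasibleRootError(
            f"Keeling C*_SI requires n > 2 and phi < (n-2)/(n-1); got n={n}, phi={phi}"
        )
    if phi == 0.0:
        return (n - 2.0) / n
    beta = tau * n

    def den(C: float) -> float:
        return gamma + beta * C - 2.0 * xi * beta * C**2 * phi

    def cleared(C: float) -> float:
        return (1.0 + C - n * xi * (1.0 - C) * (1.0 - phi)) * den(C) + 2.0 * beta * xi * phi * C**2

    lo, hi = 1e-9, 1.0 - 1e-9
    grid = np.linspace(lo, hi, 2001)
    den_vals = den(grid)
    if np.any(den_vals <= 0) and np.any(den_vals >= 0):
        warnings.warn("denominator of the C*_SI equation changes sign in (0, 1)", RuntimeWarning)
    vals = cleared(grid)
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(cleared, a, b, xtol=1e-15, rtol=8.9e-16)))
    if not roots:
        raise NoFeasibleRootError("no root of the C*_SI equation in (0, 1)")
    target = expansion(params, "simple").value_at_phi / n
    roots.sort(key=lambda r: abs(r - target))
    return roots[0]


def ngm_R0(params: ModelParams, quasi_eq: Optional[FastState] = None) -> ThresholdResult:
    """Next-generation-matrix R0 for the simple-closure pairwise model.

    Orders the infected compartments as ([I], [SI]); builds the new-infection
    matrix F and transition matrix V at the disease-free state (with the fast
    variables at their quasi-equilibrium) and returns the leading eigenvalue
    of F V^{-1}.  ``extras`` carries the first-order expansion R0 = r0 +
    phi r1 obtained by expanding the eigenvalue around phi = 0.
    """
    n, tau, gamma, phi, xi = params.n, params.tau, params.gamma, params.phi, params.xi
    if quasi_eq is None:
        quasi_eq = solve_steady_state(cubic_coefficients(params, "simple"), params)
    alpha, delta = quasi_eq.alpha, quasi_eq.delta
    F = np.array([[0.0, tau], [0.0, tau * (n - 1.0) * (1.0 - phi) + tau * xi * phi * alpha]])
    V = np.array([[gamma, 0.0], [0.0, (tau + gamma) + tau * xi / n * alpha * delta * phi]])
    eigvals = np.linalg.eigvals(F @ np.linalg.inv(V))
    R0 = float(np.max(eigvals.real))
    # first-order expansion around phi = 0 (alpha_0 = n-2, delta_0 from the
    # unclustered fast steady state); the phi-derivative of the eigenvalue
    # does not involve alpha_1 or delta_1 because F and V depend on them only
    # through O(phi) terms.
    alpha0 = n - 2.0
    delta0 = 2.0 * tau * alpha0 / (gamma + tau * alpha0)
    r0 = tau * (n - 1.0) / (tau + gamma)
    r1 = r0 * (-2.0 / n - tau * (n - 1.0) * alpha0 * delta0 / (n**2 * (tau + gamma)))
    return ThresholdResult(
        R=R0,
        method="ngm",
        quasi_eq=quasi_eq,
        valid=stability_conditions(params).feasibility_ok,
        extras={"r0": r0, "r1": r1, "first_order": r0 + phi * r1},
    )


def li_R0(params: ModelParams) -> ThresholdResult:
    """Motif-closure R0 of Li et al.: R0 = (n-1) tau / (tau + gamma + tau phi)."""
    n, tau, gamma, phi = params.n, params.tau, params.gamma, params.phi
    R0 = (n - 1.0) * tau / (tau + gamma + tau * phi)
    first_order = (n - 1.0) * tau / (tau + gamma) * (1.0 - phi * tau / (tau + gamma))
    return ThresholdResult(R=R0, method="li", extras={"first_order": first_order})


def miller_R0_regular(params: ModelParams) -> ThresholdResult:
    """Miller's percolation R0 specialised to clustered regular networks.

    With transmissibility T = tau/(tau + gamma) and each node in
    n(n-1) phi / 2 triangles on average,

        R0 = (n-1) T - (n-1) phi T^2.
    """
    n, tau, gamma, phi = params.n, params.tau, params.gamma, params.phi
    T = tau / (tau + gamma)
    n_tri = 0.5 * n * (n - 1.0) * phi
    R0 = (n - 1.0) * T - 2.0 * n_tri / n * T**2
    return ThresholdResult(R=R0, method="miller", extras={"T": T, "mean_triangles": n_tri})


@dataclass(frozen=True)
class HouseholdParams:
    """Rates for the size-three household model with regular global degree.

    ``lambda_G`` is the infection rate across global links, ``lambda_L`` the
    within-household rate, ``gamma`` the recovery rate and ``mu_D`` the
    (regular) number of global contacts per node.
    """

    lambda_G: float
    lambda_L: float
    gamma: float
    mu_D: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_G < 0 or self.lambda_L < 0 or self.mu_D < 0:
            raise ValidationError("household rates and mean degree must be >= 0")
        if not self.gamma > 0:
            raise ValidationError("household recovery rate gamma must be > 0")


def household_phi_from_mu_D(mu_D: float) -> float:
    """Clustering of the size-three household network: phi = 2/(2 + mu_D(3 + mu_D))."""
    return 2.0 / (2.0 + mu_D * (3.0 + mu_D))


def household_mu_D_from_phi(phi: float) -> float:
    """Inverse map: mu_D = sqrt(1 + 8/phi)/2 - 3/2 (requires phi in (0, 1])."""
    if not 0.0 < phi <= 1.0:
        raise ValidationError(f"phi must lie in (0, 1] to derive mu_D, got {phi}")
    return 0.5 * math.sqrt(1.0 + 8.0 / phi) - 1.5


def household_R_star(hh: HouseholdParams, phi: Optional[float] = None) -> ThresholdResult:
    """Household reproduction number R* for households of size three.

    With M(theta) = theta/(gamma + theta) the escape-complement probability
    and mu_T the mean number of secondary within-household cases,

        mu_T = 2 [1 - M(lambda_L)^2 - M(2 lambda_L)(1 - M(lambda_L))],
        R*   = (1 - M(lambda_G)) ((1 + mu_T) mu_D - 1).

    If ``phi`` is given, mu_D is derived from it (phi = 0 would require an
    infinite global degree and raises an error).  ``extras`` exposes the
    decomposition R* = T1 + T2 sqrt(1 + 8/phi) and the small-phi series
    T1 + 2 sqrt(2) T2 / sqrt(phi) + T2 sqrt(phi) / (4 sqrt(2)).
    """
    gamma = hh.gamma

    def M(theta: float) -> float:
        return theta / (gamma + theta)

    if phi is not None:
        if phi == 0.0:
            raise ValidationError("phi = 0 corresponds to infinite global degree mu_D")
        mu_D = household_mu_D_from_phi(phi)
    else:
        mu_D = hh.mu_D
    mu_T = 2.0 * (1.0 - M(hh.lambda_L) ** 2 - M(2.0 * hh.lambda_L) * (1.0 - M(hh.lambda_L)))
    one_minus_MG = 1.0 - M(hh.lambda_G)
    R_star = one_minus_MG * ((1.0 + mu_T) * mu_D - 1.0)
    T1 = -one_minus_MG - 1.5 * one_minus_MG * (1.0 + mu_T)
    T2 = 0.5 * one_minus_MG * (1.0 + mu_T)
    extras = {"mu_D": mu_D, "mu_T": mu_T, "T1": T1, "T2": T2}
    if phi is not None:
        extras["series_small_phi"] = T1 + 2.0 * math.sqrt(2.0) * T2 / math.sqrt(phi) + T2 * math.sqrt(phi) / (
            4.0 * math.sqrt(2.0)
        )
    return ThresholdResult(R=R_star, method="household", extras=extras)


def threshold_table(param_grid, methods=("cubic_numeric", "asymptotic"), closures=CLOSURES):
    """Tabulate thresholds over an iterable of ModelParams.

    Returns a pandas DataFrame with columns n, tau, gamma, phi, closure,
    method, R, valid.  Infeasible combinations are recorded with R = NaN and
    valid = False rather than aborting.
    """
    import pandas as pd

    rows = []
    for params in param_grid:
        for closure in closures:
            for method in methods:
                try:
                    res = threshold(params, closure, method)
                    R_val, valid = res.R, res.valid
                except (NoFeasibleRootError, ValidationError):
                    R_val, valid = float("nan"), False
                rows.append(
                    {
                        "n": params.n,
                        "tau": params.tau,
                        "gamma": params.gamma,
                        "phi": params.phi,
                        "closure": closure,
                        "method": method,
                        "R": R_val,
                        "valid": valid,
                    }
                )
    return pd.DataFrame(rows)
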