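"""Reproduction harness: sweeps, threshold contours, time courses, phase planes.

Everything here is deterministic plumbing over the model modules: it sweeps
the (tau, n, phi) space comparing thresholds with final epidemic sizes,
extracts critical R = 1 contours by bisection, reports prevalence and
fast-variable time courses, and samples phase-plane geometry (null clines,
the boundary alpha + delta = n, and a relaxation trajectory) for a given
closure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .fastvars import _relaxation_start, _rhs_fast_vector, nullclines, quasi_equilibrium
from .pairwise import final_epidemic_size, integrate_epidemic
from .params import ModelParams, NoEquilibriumError, NoFeasibleRootError, ValidationError
from .thresholds import threshold

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_threshold_sweep",
    "extract_threshold_contour",
    "timecourse_report",
    "fast_variable_plateau",
    "phase_plane_report",
    "EPIDEMIC_SIZE_THRESHOLD",
]

#: Attack-rate threshold separating "no epidemic" from "epidemic" in surface
#: classifications; well above the seed fraction I0/N = 1e-4 used by default.
EPIDEMIC_SIZE_THRESHOLD = 0.01


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a threshold/final-size sweep."""

    tau_grid: Sequence[float] = tuple(np.round(np.arange(0.05, 2.0001, 0.05), 10))
    n_grid: Sequence[float] = tuple(range(3, 16))
    phi_list: Sequence[float] = (0.0, 0.15, 0.3, 0.45, 0.6)
    gamma: float = 1.0
    N: float = 10_000.0
    closure: str = "simple"
    I0: float = 1.0
    t_max: float = 1000.0

    def __post_init__(self) -> None:
        for name, grid in (("tau_grid", self.tau_grid), ("n_grid", self.n_grid)):
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise ValidationError(f"{name} must be non-empty and strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in self.phi_list):
            raise ValidationError("phi_list values must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "tau_grid": list(map(float, self.tau_grid)),
            "n_grid": list(map(float, self.n_grid)),
            "phi_list": list(map(float, self.phi_list)),
            "gamma": self.gamma,
            "N": self.N,
            "closure": self.closure,
            "I0": self.I0,
            "t_max": self.t_max,
        }


@dataclass
class SweepResult:
    """One record per grid point plus the generating spec."""

    records: pd.DataFrame
    spec: SweepSpec

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.records.to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".json", "w") as handle:
                json.dump({"spec": self.spec.as_dict()}, handle, indent=2)


def _threshold_or_nan(params: ModelParams, closure: str, method: str) -> tuple[float, bool]:
    if params.tau == 0.0:
        return 0.0, True  # no transmission: R = tau alpha / gamma = 0
    try:
        res = threshold(params, closure, method)
        return res.R, res.valid
    except (NoFeasibleRootError, ValidationError, NoEquilibriumError):
        return float("nan"), False


def run_threshold_sweep(spec: SweepSpec) -> SweepResult:
    """Compute final size and both threshold variants over the whole grid.

    Individual grid-point failures are recorded in their row (NaN values,
    ``feasible=False``) and never abort the sweep.
    """
    rows = []
    for phi in spec.phi_list:
        for n in spec.n_grid:
            for tau in spec.tau_grid:
                params = ModelParams(N=spec.N, n=float(n), tau=float(tau), gamma=spec.gamma, phi=float(phi))
                R_cubic, feasible = _threshold_or_nan(params, spec.closure, "cubic_numeric")
                R_asym, _ = _threshold_or_nan(params, spec.closure, "asymptotic")
                try:
                    size = final_epidemic_size(params, spec.closure, I0=spec.I0, t_max=spec.t_max)
                    error = ""
                except Exception as exc:  # per-row failure capture
                    size, error = float("nan"), str(exc)
                rows.append(
                    {
                        "n": float(n),
                        "tau": float(tau),
                        "phi": float(phi),
                        "final_size": size,
                        "R_cubic": R_cubic,
                        "R_asymptotic": R_asym,
                        "feasible": feasible,
                        "error": error,
                    }
                )
    return SweepResult(records=pd.DataFrame(rows), spec=spec)


def extract_threshold_contour(
    spec: SweepSpec,
    method: str = "cubic_numeric",
    target: float = 1.0,
    tol: float = 1e-8,
    phi: Optional[float] = None,
) -> pd.DataFrame:
    """Critical tau at which R crosses ``target`` for each degree n.

    Bisects R(tau) - target over the range of ``spec.tau_grid`` (R is
    monotone increasing in tau at fixed n and phi; asserted via the bracket
    endpoints).  Rows without a sign change in the bracket are omitted with a
    warning.  Returns a DataFrame with columns n, phi, tau_critical.
    """
    phi_val = spec.phi_list[0] if phi is None else phi
    tau_lo, tau_hi = float(spec.tau_grid[0]), float(spec.tau_grid[-1])
    rows = []
    for n in spec.n_grid:

        def R_of_tau(tau: float, n=float(n)) -> float:
            params = ModelParams(N=spec.N, n=n, tau=tau, gamma=spec.gamma, phi=float(phi_val))
            R_val, _ = _threshold_or_nan(params, spec.closure, method)
            return R_val

        R_lo, R_hi = R_of_tau(tau_lo), R_of_tau(tau_hi)
        if not (np.isfinite(R_lo) and np.isfinite(R_hi)) or (R_lo - target) * (R_hi - target) > 0:
            warnings.warn(
                f"no R = {target} crossing in tau bracket [{tau_lo}, {tau_hi}] for n={n}, phi={phi_val}",
                RuntimeWarning,
            )
            continue
        if not R_lo < R_hi:
            warnings.warn(f"R(tau) not increasing over the bracket for n={n}; skipping", RuntimeWarning)
            continue
        tau_crit = brentq(lambda t: R_of_tau(t) - target, tau_lo, tau_hi, xtol=tol)
        rows.append({"n": float(n), "phi": float(phi_val), "tau_critical": float(tau_crit)})
    return pd.DataFrame(rows)


def timecourse_report(
    params: ModelParams,
    closure: str,
    I0: float = 1.0,
    t_max: float = 1000.0,
    n_points: int = 2001,
) -> pd.DataFrame:
    """Table of (t, prevalence, alpha, delta) along the closed-system solution.

    alpha and delta are computed from the trajectory as [SI]/[I] and
    [II]/[I]; at t = 0 they equal the fast-variable images n S0/N and n I0/N
    of the initial conditions.
    """
    t_eval = np.linspace(0.0, t_max, n_points)
    traj = integrate_epidemic(params, closure, I0=I0, t_max=t_max, t_eval=t_eval)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(traj.I > 0, traj.SI / traj.I, np.nan)
        delta = np.where(traj.I > 0, traj.II / traj.I, np.nan)
    return pd.DataFrame(
        {"time": traj.times, "prevalence": traj.I / params.N, "alpha": alpha, "delta": delta}
    )


def fast_variable_plateau(report: pd.DataFrame, params: ModelParams):
    """Plateau values of (alpha, delta) read off a time-course report.

    The plateau is the flattest point of alpha(t) in the quasi-stationary
    window: after the fast relaxation transient (a few multiples of
    1/(tau + gamma)) and before the prevalence peak, where the fast variables
    have converged but the susceptible pool is still nearly full.
    """
    t = report["time"].to_numpy()
    alpha = report["alpha"].to_numpy()
    prev = report["prevalence"].to_numpy()
    peak = int(np.argmax(prev))
    t_relax = 3.0 / (params.tau + params.gamma)
    window = np.nonzero((t >= t_relax) & (np.arange(len(t)) < max(peak, 1)))[0]
    if len(window) < 3:
        idx = peak
    else:
        dalpha = np.abs(np.gradient(alpha[window], t[window]))
        idx = window[int(np.argmin(dalpha))]
    return float(alpha[idx]), float(report["delta"].iloc[idx])


def phase_plane_report(params: ModelParams, closure: str, n_samples: int = 400) -> pd.DataFrame:
    """Sample the fast-system phase plane for plotting.

    Returns a DataFrame with columns alpha, delta, source where source is one
    of ``nullcline1``, ``nullcline2``, ``boundary``, ``trajectory``.  Null
    clines are sampled on a grid over D's ranges with singular points
    windowed out; the trajectory starts from the fast-variable image of the
    standard initial conditions and is integrated until it lies within 1e-6
    of the quasi-equilibrium.  If the parameters are infeasible, only the
    boundary and the trajectory are reported, with a warning.
    """
    n = params.n
    rows = []

    clines = nullclines(params, closure)
    alpha_grid = np.linspace(1e-6, n, n_samples)
    for a in alpha_grid:
        try:
            d = clines.first(float(a))
        except ZeroDivisionError:
            continue
        if -0.5 * n <= d <= 1.5 * n:
            rows.append({"alpha": float(a), "delta": float(d), "source": "nullcline1"})
    if closure == "simple":
        for a in alpha_grid:
            try:
                d = clines.second(float(a))
            except ZeroDivisionError:
                continue
            if -0.5 * n <= d <= 1.5 * n:
                rows.append({"alpha": float(a), "delta": float(d), "source": "nullcline2"})
    else:
        for d in np.linspace(0.0, n, n_samples):
            try:
                a = clines.second(float(d))
            except ZeroDivisionError:
                continue
            if -0.5 * n <= a <= 1.5 * n:
                rows.append({"alpha": float(a), "delta": float(d), "source": "nullcline2"})

    for a in np.linspace(0.0, n, n_samples):
        rows.append({"alpha": float(a), "delta": float(n - a), "source": "boundary"})

    try:
        steady = quasi_equilibrium(params, closure, method="ode_relaxation")
    except NoEquilibriumError as exc:
        warnings.warn(f"infeasible parameters, phase plane without steady trajectory: {exc}", RuntimeWarning)
        steady = None

    v0 = _relaxation_start(params)
    t_end = 200.0 / params.gamma
    sol = solve_ivp(
        lambda _t, y: _rhs_fast_vector(y, params, closure),
        (0.0, t_end),
        v0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    t_samples = np.linspace(0.0, t_end, 4 * n_samples)
    path = sol.sol(t_samples)
    if steady is not None:
        dist = np.hypot(path[0] - steady.alpha, path[1] - steady.delta)
        hits = np.nonzero(dist < 1e-6)[0]
        cut = hits[0] + 1 if len(hits) else len(t_samples)
    else:
        cut = len(t_samples)
    for a, d in zip(path[0, :cut], path[1, :cut]):
        rows.append({"alpha": float(a), "delta": float(d), "source": "trajectory"})
    return pd.DataFrame(rows)
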