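"""Numerical solution of the donor-decay reaction-diffusion equation.

The excited-population density N(r, t) on the distribution support obeys

    dN/dt = -(1/tau_d) N - (1/tau_d) (r0/r)^6 N + d/dr( D p(r) d(N/p)/dr )

with N(r, 0) = p(r) and zero-flux (reflecting) boundaries: without decay and
sink the diffusion operator must conserve the number of chains, which forces
reflecting ends. The transfer efficiency is E = 1 - (1/tau_d) ∫ Q dt with
survival Q(t) = ∫ N dr, and the effective distance follows from E.

Two solvers are provided:

* :func:`solve_time_integrated` — integrates the PDE over t analytically,
  leaving a symmetric tridiagonal boundary-value problem for
  n(r) = ∫ N dt. Deterministic and fast; the production path.
* :func:`solve_time_domain` — stiff method-of-lines integration of the full
  PDE; retained as the validation oracle (it also yields Q(t)).

The flux D p d(N/p)/dr is discretized in conservative finite-volume form in
the variable u = N/p; where p is below 1e-12 of its maximum the flux is set
to zero and the node is pinned, avoiding 0/0 at the support edges where the
well-behaved distributions vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.linalg import solveh_banded

from .distributions import DistanceDistribution, normalize
from .errors import InvalidParametersError, SolverError, UndefinedDistanceError
from .fret_core import Photophysics, augmented_j, efficiency_to_reff

__all__ = [
    "HSEProblem",
    "HSESolution",
    "solve",
    "solve_time_integrated",
    "solve_time_domain",
    "rescaled_solve",
]

_PIN_FRACTION = 1e-12  # nodes with p <= 1e-12 * max(p) carry no flux


@dataclass(frozen=True)
class HSEProblem:
    """One solve: distribution, photophysics, diffusion coefficient, grid."""

    dist: DistanceDistribution
    photo: Photophysics
    d: float
    n_space: int = 800
    solver_mode: str = "time_integrated"
    time_horizon_factor: float = 25.0
    include_decay: bool = True
    include_sink: bool = True

    def __post_init__(self) -> None:
        if self.d < 0:
            raise InvalidParametersError("diffusion coefficient must be >= 0")
        if self.n_space < 200:
            raise InvalidParametersError("n_space must be >= 200")
        if self.solver_mode not in ("time_domain", "time_integrated"):
            raise InvalidParametersError(f"unknown solver_mode {self.solver_mode!r}")
        if not self.dist.normalized:
            raise InvalidParametersError("distribution must be normalized")


@dataclass(frozen=True)
class HSESolution:
    """Result of one solve."""

    efficiency: float
    r_eff: float
    j: float
    mass_residual: float
    converged: bool
    r_nodes: np.ndarray = field(repr=False)
    p0: np.ndarray = field(repr=False)
    n_field: np.ndarray = field(repr=False)
    survival_t: np.ndarray | None = field(default=None, repr=False)
    survival_q: np.ndarray | None = field(default=None, repr=False)


def _grid_and_density(problem: HSEProblem):
    """Uniform node grid, trapezoid volumes, discretely renormalized density."""
    dist = problem.dist
    r = np.linspace(dist.r_min, dist.r_max, problem.n_space)
    h = r[1] - r[0]
    vol = np.full(problem.n_space, h)
    vol[0] = vol[-1] = 0.5 * h
    p = dist.norm * dist.kernel(r)
    mass_residual = abs(float(vol @ p) - 1.0)
    p = p / (vol @ p)  # make the discrete mass exactly 1
    return r, h, vol, p, mass_residual


def _sink_rates(problem: HSEProblem, r: np.ndarray) -> np.ndarray:
    """Local deactivation rate k(r) = decay + FRET sink (ns^-1)."""
    k_d = problem.photo.k_d
    k = np.zeros_like(r)
    if problem.include_decay:
        k += k_d
    if problem.include_sink:
        k += k_d * (problem.photo.r0 / r) ** 6
    return k


def _half_conductances(d: float, p: np.ndarray, h: float) -> np.ndarray:
    """c_{i+1/2} = D * p_{i+1/2} / h, zeroed where either endpoint is pinned."""
    eps = _PIN_FRACTION * p.max()
    c = d * 0.5 * (p[:-1] + p[1:]) / h
    c[np.minimum(p[:-1], p[1:]) <= eps] = 0.0
    return c


def solve_time_integrated(problem: HSEProblem) -> HSESolution:
    """Solve the time-integrated boundary-value problem for n(r) = ∫ N dt.

    Integrating the PDE over t in [0, inf) gives

        -p(r) = -k(r) n(r) + d/dr( D p d(n/p)/dr ),

    a symmetric positive-definite tridiagonal system in u = n/p.
    """
    if not problem.include_decay:
        raise InvalidParametersError("time-integrated solve requires the decay term")
    r, h, vol, p, mass_residual = _grid_and_density(problem)
    k = _sink_rates(problem, r)
    c = _half_conductances(problem.d, p, h)
    eps = _PIN_FRACTION * p.max()
    active = p > eps

    diag = k * p * vol
    diag[:-1] += c
    diag[1:] += c
    upper = -c.copy()
    rhs = p * vol
    # pinned nodes: u is irrelevant (n = p*u = 0); keep the system nonsingular
    diag[~active] = 1.0
    rhs[~active] = 0.0
    upper[~active[:-1] | ~active[1:]] = 0.0

    ab = np.zeros((2, r.size))
    ab[0, 1:] = upper
    ab[1, :] = diag
    try:
        u = solveh_banded(ab, rhs, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SolverError(
            f"banded solve failed ({exc}); try refining n_space"
        ) from exc
    n_field = p * u
    if n_field.min() < -1e-9:
        raise SolverError("time-integrated field has significant negative values")

    efficiency = 1.0 - problem.photo.k_d * float(vol @ n_field)
    return _finalize(problem, efficiency, r, p, n_field, mass_residual)


def _finalize(problem, efficiency, r, p, n_field, mass_residual, t=None, q=None):
    if not (problem.include_sink and problem.include_decay):
        # diagnostic runs without the full physics: E is zero up to roundoff
        efficiency, r_eff = max(efficiency, 0.0), np.inf
    elif efficiency <= 0.0:
        raise UndefinedDistanceError(
            f"transfer efficiency {efficiency:.3g} <= 0; no effective distance"
        )
    else:
        efficiency = min(efficiency, 1.0 - 1e-15)
        r_eff = efficiency_to_reff(efficiency, problem.photo.r0)
    return HSESolution(
        efficiency=efficiency,
        r_eff=r_eff,
        j=augmented_j(problem.d, problem.photo.tau_d, problem.photo.r0),
        mass_residual=mass_residual,
        converged=True,
        r_nodes=r,
        p0=p,
        n_field=n_field,
        survival_t=t,
        survival_q=q,
    )


def _rate_matrix(problem: HSEProblem):
    """Sparse generator A with dN/dt = A N (method of lines)."""
    r, h, vol, p, mass_residual = _grid_and_density(problem)
    k = _sink_rates(problem, r)
    c = _half_conductances(problem.d, p, h)
    eps = _PIN_FRACTION * p.max()
    active = p > eps

    n = r.size
    main = -k.copy()
    lo = np.zeros(n - 1)
    up = np.zeros(n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_p = np.where(active, 1.0 / np.where(active, p, 1.0), 0.0)
    # right flux into node i, left flux out of node i
    main[:-1] -= c * inv_p[:-1] / vol[:-1]
    up += c * inv_p[1:] / vol[:-1]
    main[1:] -= c * inv_p[1:] / vol[1:]
    lo += c * inv_p[:-1] / vol[1:]
    main[~active] = 0.0
    a = sparse.diags_array([lo, main, up], offsets=[-1, 0, 1], format="csc")
    return a, r, h, vol, p, mass_residual


def solve_time_domain(problem: HSEProblem) -> HSESolution:
    """Stiff method-of-lines integration of the full PDE.

    The survival integral ∫ Q dt is carried as an extra quadrature state so
    it converges with the integrator tolerance; the tail beyond the horizon
    is completed analytically from the terminal decay rate.
    """
    a, r, h, vol, p, mass_residual = _rate_matrix(problem)
    n = r.size
    t_end = problem.time_horizon_factor * problem.photo.tau_d

    top = sparse.hstack([a, sparse.csc_array((n, 1))])
    bottom = sparse.hstack([sparse.csr_array(vol[None, :]), sparse.csc_array((1, 1))])
    aug = sparse.vstack([top, bottom]).tocsc()

    y0 = np.concatenate([p, [0.0]])

    def rhs(_t, y):
        return aug @ y

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="BDF",
        jac=aug,
        rtol=1e-9,
        atol=1e-13,
        dense_output=True,
    )
    if not sol.success:
        raise SolverError(f"time-domain integration failed: {sol.message}")

    t_grid = np.linspace(0.0, t_end, 801)
    states = sol.sol(t_grid)
    q = vol @ states[:n, :]
    n_final = sol.y[:n, -1]
    if n_final.min() < -1e-9 or q.min() < -1e-9:
        raise SolverError("time-domain field has significant negative values")

    q_int = sol.y[n, -1]
    # analytic tail from the terminal single-exponential decay rate
    q_end, q_prev = q[-1], q[-2]
    if q_end > 0.0 and q_prev > q_end:
        lam = np.log(q_prev / q_end) / (t_grid[-1] - t_grid[-2])
        q_int += q_end / lam
    efficiency = 1.0 - problem.photo.k_d * q_int
    return _finalize(problem, efficiency, r, p, n_final, mass_residual, t=t_grid, q=q)


def rescaled_solve(problem: HSEProblem) -> HSESolution:
    """Solve in dimensionless coordinates s = r/r0, z = t/tau_d.

    The rescaled equation has unit decay rate, sink 1/s^6 and diffusion
    coefficient J = D tau_d / r0²; the efficiency (hence Reff) is invariant.
    """
    dist = problem.dist
    r0 = problem.photo.r0
    scaled = DistanceDistribution(
        model=dist.model,
        b=dist.b / r0,
        r_min=dist.r_min / r0,
        r_max=dist.r_max / r0,
        a=None if dist.a is None else dist.a * r0**2,
    )
    scaled = normalize(scaled)
    j = augmented_j(problem.d, problem.photo.tau_d, r0)
    sub = dc_replace(
        problem,
        dist=scaled,
        photo=Photophysics(tau_d=1.0, r0=1.0),
        d=j,
        solver_mode="time_integrated",
    )
    inner = solve_time_integrated(sub)
    return dc_replace(
        inner,
        r_eff=inner.r_eff * r0,
        j=j,
        r_nodes=inner.r_nodes * r0,
        p0=inner.p0 / r0,
    )


def solve(problem: HSEProblem) -> HSESolution:
    """Dispatch on ``problem.solver_mode``."""
    if problem.solver_mode == "time_domain":
        return solve_time_domain(problem)
    return solve_time_integrated(problem)
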