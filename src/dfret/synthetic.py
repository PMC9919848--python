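"""Synthetic experiments and a Brownian-dynamics transfer-efficiency oracle.

The Monte Carlo estimator simulates overdamped donor-acceptor distance
motion with drift D * d(ln p)/dr and reflecting boundaries, whose stationary
law is the chain's distance distribution p(r). Donor decay and the
distance-dependent transfer sink are handled by per-trajectory survival
weighting (no trajectories are killed, which removes the decay variance):

    E = 1 - (1/tau_d) * E[ ∫ exp(-t/tau_d) * exp(-∫ k_fret(r(t')) dt') dt ]

This estimator is independent of the PDE discretization and serves as the
cross-solver oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import PolynomialModel
from .distributions import DistanceDistribution, sample
from .errors import InvalidParametersError, StabilityError
from .fret_core import Photophysics
from .global_fit import Observation
from .hse import HSEProblem, solve_time_integrated
from .hsje import HSJEInput, hsje_reff

try:  # numba accelerates the trajectory loop ~100x but is optional
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


__all__ = [
    "SyntheticTruth",
    "TrajectoryEnsembleSpec",
    "generate_dataset",
    "brownian_efficiency",
    "equilibrate_positions",
]

_DRIFT_GRID_N = 4001
_SUPPORT_FRACTION = 1e-10  # reflect at the first node where p exceeds this * max p
_WEIGHT_CUTOFF = 1e-8  # stop a trajectory once its survival weight is negligible
_MAX_DLNP = 50.0  # 1/A; clamps the log-density gradient near the support edge


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a synthetic multi-condition experiment."""

    dist: DistanceDistribution
    d_ref: float
    conditions: tuple
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParametersError("noise_sd must be >= 0")
        if not self.conditions:
            raise InvalidParametersError("need at least one condition")


@dataclass(frozen=True)
class TrajectoryEnsembleSpec:
    """Monte Carlo ensemble controls."""

    n_traj: int = 10_000
    dt: float | None = None  # upper bound on the adaptive step (ns)
    seed: int = 0
    max_time: float | None = None  # ns; default 25 * tau_d
    dx_step: float = 0.4  # A; bounds the diffusive step sqrt(2 D dt)
    hazard_frac: float = 0.05  # bounds dt * local deactivation rate

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise InvalidParametersError("n_traj must be >= 1")


def generate_dataset(
    truth: SyntheticTruth,
    coeffs: PolynomialModel | None = None,
    via: str = "hsje",
    strict: bool = False,
) -> list[Observation]:
    """Noiseless predictions per condition plus seeded Gaussian noise.

    ``via='hsje'`` uses the closed-form surrogate; ``via='hse'`` solves the
    PDE per condition for oracle-grade data.
    """
    if via not in ("hsje", "hse"):
        raise InvalidParametersError(f"via must be 'hsje' or 'hse', got {via!r}")
    rng = np.random.default_rng(truth.seed)
    out = []
    for cond in truth.conditions:
        d = truth.d_ref * cond.d_scale
        if via == "hsje":
            r_eff = hsje_reff(
                HSJEInput(
                    dist=truth.dist,
                    photo=Photophysics(tau_d=cond.tau_d, r0=cond.r0),
                    d=d,
                    coeffs=coeffs,
                    strict=strict,
                )
            )
        else:
            r_eff = solve_time_integrated(
                HSEProblem(
                    dist=truth.dist,
                    photo=Photophysics(tau_d=cond.tau_d, r0=cond.r0),
                    d=d,
                )
            ).r_eff
        noisy = r_eff + rng.normal(0.0, truth.noise_sd) if truth.noise_sd else r_eff
        sigma = truth.noise_sd if truth.noise_sd > 0 else 1.0
        out.append(Observation(condition=cond, r_eff_obs=noisy, sigma=sigma))
    return out


@_njit(cache=False)
def _trajectory_loop(
    r_init,
    r_lo,
    r_hi,
    grid_r,
    dlnp,
    d,
    k_d,
    r0_sixth,
    tau_d,
    dt_max,
    max_time,
    fret_on,
    weight_mode,
    seed,
    dx_step,
    hazard_frac,
):
    np.random.seed(seed)
    n = r_init.shape[0]
    integrals = np.zeros(n)
    finals = np.empty(n)
    dt_spatial = 0.5 * dx_step * dx_step / d if d > 0.0 else 1e300
    inv_h = (grid_r.shape[0] - 1) / (grid_r[-1] - grid_r[0])
    g_lo = grid_r[0]
    n_grid = grid_r.shape[0]
    for i in range(n):
        r = r_init[i]
        t = 0.0
        log_sf = 0.0  # ln of the FRET survival factor
        k_f = k_d * r0_sixth / r**6 if fret_on else 0.0
        g = 1.0  # exp(-t/tau_d + log_sf)
        acc = 0.0
        while t < max_time:
            dt = dt_max
            if hazard_frac / (k_d + k_f) < dt:
                dt = hazard_frac / (k_d + k_f)
            if dt_spatial < dt:
                dt = dt_spatial
            if d > 0.0:
                # linear interpolation on the uniform drift grid
                pos = (r - g_lo) * inv_h
                idx = int(pos)
                if idx < 0:
                    idx = 0
                elif idx > n_grid - 2:
                    idx = n_grid - 2
                frac = pos - idx
                drift = d * (dlnp[idx] * (1.0 - frac) + dlnp[idx + 1] * frac)
                if np.abs(drift) * dt > 0.25:
                    dt = 0.25 / np.abs(drift)
                r_new = r + drift * dt + np.sqrt(2.0 * d * dt) * np.random.standard_normal()
                # reflect into [r_lo, r_hi]
                for _ in range(100):
                    if r_new < r_lo:
                        r_new = 2.0 * r_lo - r_new
                    elif r_new > r_hi:
                        r_new = 2.0 * r_hi - r_new
                    else:
                        break
                if r_new < r_lo or r_new > r_hi:
                    r_new = 0.5 * (r_lo + r_hi)
            else:
                r_new = r
            k_f_new = k_d * r0_sixth / r_new**6 if fret_on else 0.0
            if weight_mode:
                log_sf -= 0.5 * (k_f + k_f_new) * dt
                t_new = t + dt
                g_new = np.exp(-t_new / tau_d + log_sf)
                acc += 0.5 * (g + g_new) * dt
                g = g_new
                t = t_new
                if g < _WEIGHT_CUTOFF:
                    break
            else:
                t += dt
            r = r_new
            k_f = k_f_new
        integrals[i] = acc
        finals[i] = r
    return integrals, finals


def _drift_table(dist: DistanceDistribution):
    """Reflecting bounds and clamped d(ln p)/dr on a fine grid."""
    r_full = np.linspace(dist.r_min, dist.r_max, _DRIFT_GRID_N)
    p_full = dist.norm * dist.kernel(r_full)
    support = p_full > _SUPPORT_FRACTION * p_full.max()
    idx = np.nonzero(support)[0]
    r_lo, r_hi = r_full[idx[0]], r_full[idx[-1]]
    grid_r = np.linspace(r_lo, r_hi, _DRIFT_GRID_N)
    p = np.maximum(dist.norm * dist.kernel(grid_r), 1e-300)
    dlnp = np.gradient(np.log(p), grid_r)
    dlnp = np.clip(dlnp, -_MAX_DLNP, _MAX_DLNP)
    return r_lo, r_hi, grid_r, dlnp


def _prepare(dist, photo, d, spec, fret_on=True):
    if not dist.normalized:
        raise InvalidParametersError("distribution must be normalized")
    if dist.r_min <= 0:
        raise InvalidParametersError("Monte Carlo requires r_min > 0")
    r_lo, r_hi, grid_r, dlnp = _drift_table(dist)
    max_hazard = photo.k_d * (1.0 + (photo.r0 / r_lo) ** 6)
    dt_max = 0.05 * photo.tau_d
    if spec.dt is not None:
        if spec.dt * max_hazard >= 0.1:
            raise StabilityError(
                f"dt={spec.dt} ns violates dt * max_hazard < 0.1 "
                f"(max hazard {max_hazard:.3g}/ns at r={r_lo:.3g} A)"
            )
        dt_max = spec.dt
    max_time = spec.max_time if spec.max_time is not None else 25.0 * photo.tau_d
    r_init = sample(dist, spec.n_traj, spec.seed)
    r_init = np.clip(r_init, r_lo, r_hi)
    return r_init, r_lo, r_hi, grid_r, dlnp, dt_max, max_time


def brownian_efficiency(
    dist: DistanceDistribution,
    photo: Photophysics,
    d: float,
    spec: TrajectoryEnsembleSpec,
    fret_on: bool = True,
) -> tuple[float, float]:
    """Monte Carlo transfer efficiency and its standard error."""
    r_init, r_lo, r_hi, grid_r, dlnp, dt_max, max_time = _prepare(
        dist, photo, d, spec
    )
    integrals, _ = _trajectory_loop(
        r_init,
        r_lo,
        r_hi,
        grid_r,
        dlnp,
        float(d),
        photo.k_d,
        photo.r0**6,
        photo.tau_d,
        dt_max,
        max_time,
        fret_on,
        True,
        spec.seed,
        spec.dx_step,
        spec.hazard_frac,
    )
    e = 1.0 - photo.k_d * float(np.mean(integrals))
    se = photo.k_d * float(np.std(integrals, ddof=1)) / np.sqrt(len(integrals))
    return e, se


def equilibrate_positions(
    dist: DistanceDistribution,
    d: float,
    t_final: float,
    n_traj: int,
    seed: int = 0,
    start_at: float | None = None,
    dx_step: float = 1.2,
) -> np.ndarray:
    """Positions after free diffusion for t_final (no decay, no sink).

    Used to verify that the stationary law of the simulated motion is p(r).
    A coarser spatial step than the efficiency estimator's default is enough
    here; there is no hazard integral to resolve.
    """
    if d <= 0:
        raise InvalidParametersError("need d > 0 to equilibrate")
    spec = TrajectoryEnsembleSpec(
        n_traj=n_traj, seed=seed, max_time=t_final, dx_step=dx_step
    )
    photo = Photophysics(tau_d=1e9, r0=1.0)  # inert photophysics
    r_init, r_lo, r_hi, grid_r, dlnp, dt_max, max_time = _prepare(
        dist, photo, d, spec
    )
    if start_at is not None:
        r_init = np.full(n_traj, float(np.clip(start_at, r_lo, r_hi)))
    _, finals = _trajectory_loop(
        r_init,
        r_lo,
        r_hi,
        grid_r,
        dlnp,
        float(d),
        photo.k_d,
        photo.r0**6,
        photo.tau_d,
        min(dt_max, 0.02 * (r_hi - r_lo) ** 2 / (2.0 * d)),
        max_time,
        False,
        False,
        seed,
        spec.dx_step,
        spec.hazard_frac,
    )
    return finals
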