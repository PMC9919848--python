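"""Diffusion profiles Reff(D), diffusion-influence profiles DI(X), and the
sigmoid fit DI(X) = (X/X0)^M / (1 + (X/X0)^M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .distributions import DistanceDistribution
from .errors import (
    DegenerateAmplitudeError,
    FitConvergenceError,
    FitRangeError,
    InvalidParametersError,
)
from .fret_core import (
    Photophysics,
    diffusion_influence,
    dynamic_limit_R,
    static_limit_L,
)
from .hse import HSEProblem, solve

__all__ = [
    "DiffusionProfile",
    "DIProfile",
    "SigmoidFit",
    "default_d_grid",
    "compute_profile",
    "to_di_profile",
    "fit_sigmoid",
    "sigmoid",
    "symmetry_diagnostic",
]

MIN_FIT_AMPLITUDE = 1.0  # A; refuse DI fits for narrower L - R gaps


def default_d_grid(n: int = 32, d_min: float = 1e-3, d_max: float = 1e6) -> np.ndarray:
    """Log-spaced diffusion-coefficient grid (Å²/ns)."""
    return np.geomspace(d_min, d_max, n)


@dataclass(frozen=True)
class DiffusionProfile:
    """Reff over a diffusion-coefficient scan for one (dist, photo) pair."""

    d: np.ndarray
    j: np.ndarray
    x: np.ndarray
    r_eff: np.ndarray
    dist: DistanceDistribution
    photo: Photophysics

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "D_A2_per_ns": self.d,
                "J": self.j,
                "X": self.x,
                "Reff_angstrom": self.r_eff,
            }
        )


@dataclass(frozen=True)
class DIProfile:
    """Normalized diffusion-influence profile DI(X) with its L, R anchors."""

    x: np.ndarray
    di: np.ndarray
    limit_l: float
    limit_r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"X": self.x, "DI": self.di})


@dataclass(frozen=True)
class SigmoidFit:
    x0: float
    m: float
    rms_residual: float
    asymmetry_diagnostic: float

    def __call__(self, x):
        return sigmoid(x, self.x0, self.m)


def sigmoid(x, x0: float, m: float):
    """DI(X) = (X/X0)^M / (1 + (X/X0)^M), evaluated stably in log space."""
    with np.errstate(divide="ignore"):
        t = m * (np.log(np.asarray(x, dtype=float)) - np.log(x0))
    out = np.where(t > 0, 1.0 / (1.0 + np.exp(-t)), np.exp(t) / (1.0 + np.exp(t)))
    return out if out.ndim else float(out)


def compute_profile(
    dist: DistanceDistribution,
    photo: Photophysics,
    d_values,
    n_space: int = 800,
    solver_mode: str = "time_integrated",
) -> DiffusionProfile:
    """One PDE solve per diffusion coefficient; rows sorted by D."""
    d_values = np.sort(np.asarray(d_values, dtype=float))
    if d_values.size < 2:
        raise InvalidParametersError("need at least two diffusion coefficients")
    r_eff = np.empty_like(d_values)
    j = np.empty_like(d_values)
    for i, d in enumerate(d_values):
        sol = solve(
            HSEProblem(
                dist=dist, photo=photo, d=d, n_space=n_space, solver_mode=solver_mode
            )
        )
        r_eff[i] = sol.r_eff
        j[i] = sol.j
    return DiffusionProfile(
        d=d_values, j=j, x=np.sqrt(j), r_eff=r_eff, dist=dist, photo=photo
    )


def to_di_profile(
    profile: DiffusionProfile, limit_l: float, limit_r: float
) -> DIProfile:
    """Normalize a diffusion profile by its closed-form limits."""
    di = np.array(
        [diffusion_influence(v, limit_l, limit_r) for v in profile.r_eff]
    )
    return DIProfile(x=profile.x, di=di, limit_l=limit_l, limit_r=limit_r)


def di_profile(
    dist: DistanceDistribution,
    photo: Photophysics,
    d_values=None,
    n_space: int = 800,
) -> DIProfile:
    """Convenience: full pipeline from distribution to DI(X)."""
    if d_values is None:
        d_values = default_d_grid()
    prof = compute_profile(dist, photo, d_values, n_space=n_space)
    limit_l = static_limit_L(dist, photo.r0)
    limit_r = dynamic_limit_R(dist)
    return to_di_profile(prof, limit_l, limit_r)


def fit_sigmoid(
    di_profile: DIProfile,
    min_amplitude: float = MIN_FIT_AMPLITUDE,
    require_full_range: bool = True,
) -> SigmoidFit:
    """Unweighted least squares of DI against ln X, parameterized in (ln X0, M).

    Requires the profile to span DI < 0.1 and DI > 0.9 so that both the
    midpoint and the steepness are identifiable.
    """
    if di_profile.limit_l - di_profile.limit_r < min_amplitude:
        raise DegenerateAmplitudeError(
            f"profile amplitude {di_profile.limit_l - di_profile.limit_r:.3g} A "
            f"is below {min_amplitude} A"
        )
    x, di = np.asarray(di_profile.x), np.asarray(di_profile.di)
    if require_full_range and not (di.min() < 0.1 and di.max() > 0.9):
        raise FitRangeError(
            f"profile spans DI in [{di.min():.3f}, {di.max():.3f}]; "
            "need DI < 0.1 and DI > 0.9"
        )
    ln_x = np.log(x)
    # start: interpolated DI = 0.5 crossing; mid-range steepness
    ln_x0_start = float(np.interp(0.5, di, ln_x))
    theta0 = np.array([ln_x0_start, 1.5])

    def residuals(theta):
        return sigmoid(x, np.exp(theta[0]), theta[1]) - di

    res = least_squares(
        residuals,
        theta0,
        bounds=([ln_x.min() - 5.0, 1e-3], [ln_x.max() + 5.0, 50.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise FitConvergenceError(
            f"sigmoid fit did not converge from start {theta0}: {res.message}"
        )
    x0, m = float(np.exp(res.x[0])), float(res.x[1])
    rms = float(np.sqrt(np.mean(res.fun**2)))
    fit = SigmoidFit(x0=x0, m=m, rms_residual=rms, asymmetry_diagnostic=np.nan)
    asym = symmetry_diagnostic(di_profile, fit)
    return SigmoidFit(x0=x0, m=m, rms_residual=rms, asymmetry_diagnostic=asym)


def symmetry_diagnostic(di_profile: DIProfile, fit: SigmoidFit) -> float:
    """Max |DI(lnX0+u) + DI(lnX0-u) - 1| over the symmetric ln-X range.

    Point symmetry of the profile about (ln X0, 1/2) is the second numerical
    quality control: an under-resolved PDE solve breaks it.
    """
    ln_x = np.log(np.asarray(di_profile.x))
    di = np.asarray(di_profile.di)
    ln_x0 = np.log(fit.x0)
    span = min(ln_x0 - ln_x.min(), ln_x.max() - ln_x0)
    if span <= 0:
        return float("nan")
    u = np.linspace(0.0, span, 201)
    upper = np.interp(ln_x0 + u, ln_x, di)
    lower = np.interp(ln_x0 - u, ln_x, di)
    return float(np.max(np.abs(upper + lower - 1.0)))
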