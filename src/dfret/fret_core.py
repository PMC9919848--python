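"""Förster-law conversions and the closed-form transfer limits.

Rates are in ns⁻¹, distances in Å, efficiencies dimensionless. The static
limit L is the effective distance at zero diffusion; the dynamic limit R is
the effective distance at infinite diffusion, the inverse sixth root of the
inverse-sixth moment of the distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .distributions import DistanceDistribution, inverse_sixth_moment
from .errors import (
    DegenerateAmplitudeError,
    DomainError,
    InvalidParametersError,
    NegativeTransferError,
    UndefinedDistanceError,
)

__all__ = [
    "Photophysics",
    "TransferObservables",
    "forster_rate",
    "kfret_from_rates",
    "reff_from_kfret",
    "efficiency_to_reff",
    "reff_to_efficiency",
    "static_efficiency",
    "static_limit_L",
    "dynamic_limit_R",
    "augmented_j",
    "profile_abscissa_x",
    "diffusion_influence",
]

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-11, limit=400)


@dataclass(frozen=True)
class Photophysics:
    """Donor photophysics: lifetime tau_d (ns) and Förster radius r0 (Å)."""

    tau_d: float
    r0: float
    k_rad: float | None = None
    k_nrad: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau_d > 0 and self.r0 > 0):
            raise InvalidParametersError("tau_d and r0 must be positive")
        if (self.k_rad is None) != (self.k_nrad is None):
            raise InvalidParametersError("k_rad and k_nrad must be given together")
        if self.k_rad is not None:
            if abs(self.k_rad + self.k_nrad - self.k_d) > 1e-9:
                raise InvalidParametersError("k_rad + k_nrad must equal 1/tau_d")

    @property
    def k_d(self) -> float:
        """Donor-only decay rate, 1/tau_d (ns⁻¹)."""
        return 1.0 / self.tau_d


@dataclass(frozen=True)
class TransferObservables:
    """Derived transfer quantities for one condition."""

    efficiency: float
    k_fret: float
    k_da: float
    r_eff: float


def forster_rate(photo: Photophysics, r: float) -> float:
    """Distance-dependent transfer rate k_d * (r0/r)^6."""
    if np.any(np.asarray(r) <= 0):
        raise DomainError("distance must be positive")
    return photo.k_d * (photo.r0 / r) ** 6


def kfret_from_rates(k_da: float, k_d: float) -> float:
    """Effective transfer rate from donor decay rates with/without acceptor."""
    if k_d <= 0:
        raise DomainError("k_d must be positive")
    if k_da < k_d:
        raise NegativeTransferError(f"k_da={k_da} < k_d={k_d}")
    return k_da - k_d


def reff_from_kfret(k_fret: float, photo: Photophysics) -> float:
    """Effective distance solving k_fret = k_d (r0/Reff)^6."""
    if k_fret <= 0:
        raise UndefinedDistanceError("k_fret must be positive")
    return photo.r0 * (photo.k_d / k_fret) ** (1.0 / 6.0)


def efficiency_to_reff(efficiency: float, r0: float) -> float:
    """Reff = r0 * ((1-E)/E)^(1/6); defined for 0 < E < 1."""
    if not 0.0 < efficiency < 1.0:
        raise UndefinedDistanceError(f"efficiency must be in (0, 1), got {efficiency}")
    return r0 * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0)


def reff_to_efficiency(r_eff: float, r0: float) -> float:
    """Inverse of :func:`efficiency_to_reff`."""
    if r_eff <= 0:
        raise DomainError("r_eff must be positive")
    u = (r_eff / r0) ** 6
    return 1.0 / (1.0 + u)


def observables_from_reff(r_eff: float, photo: Photophysics) -> TransferObservables:
    e = reff_to_efficiency(r_eff, photo.r0)
    k_fret = photo.k_d * e / (1.0 - e)
    return TransferObservables(
        efficiency=e, k_fret=k_fret, k_da=photo.k_d + k_fret, r_eff=r_eff
    )


def static_efficiency(dist: DistanceDistribution, r0: float) -> float:
    """Ensemble transfer efficiency at zero diffusion: ∫ p(r) r0⁶/(r⁶+r0⁶) dr."""
    if not dist.normalized:
        raise InvalidParametersError("distribution must be normalized")
    val, _ = integrate.quad(
        lambda r: dist.norm * dist.kernel(r) * r0**6 / (r**6 + r0**6),
        dist.r_min,
        dist.r_max,
        **_QUAD_OPTS,
    )
    return val


def static_limit_L(dist: DistanceDistribution, r0: float) -> float:
    """Effective distance in the absence of diffusion.

    L = r0 * ((1 - S)^-1 - 1)^(1/6) with S = ∫ p(r) r⁶/(r⁶+r0⁶) dr, which is
    identical to routing the static efficiency through
    :func:`efficiency_to_reff`.
    """
    if dist.r_min <= 0:
        raise DomainError("static limit requires r_min > 0")
    e = static_efficiency(dist, r0)
    if e <= 0.0 or e >= 1.0:
        raise UndefinedDistanceError(f"static efficiency {e} leaves Reff undefined")
    return efficiency_to_reff(e, r0)


def dynamic_limit_R(dist: DistanceDistribution) -> float:
    """Effective distance at infinite diffusion: ⟨r⁻⁶⟩^(-1/6)."""
    m6 = inverse_sixth_moment(dist)
    if not np.isfinite(m6) or m6 <= 0:
        raise UndefinedDistanceError("inverse-sixth moment is degenerate")
    return m6 ** (-1.0 / 6.0)


def augmented_j(d: float, tau_d: float, r0: float) -> float:
    """Dimensionless augmented diffusion coefficient J = D * tau_d / r0²."""
    if tau_d <= 0 or r0 <= 0 or d < 0:
        raise DomainError("need d >= 0, tau_d > 0, r0 > 0")
    return d * tau_d / r0**2


def profile_abscissa_x(d: float, tau_d: float, r0: float) -> float:
    """X = sqrt(J), the natural abscissa of diffusion-influence profiles."""
    return float(np.sqrt(augmented_j(d, tau_d, r0)))


def diffusion_influence(
    r_eff: float,
    limit_l: float,
    limit_r: float,
    clip_tol: float = 1e-3,
    min_amplitude: float = 1e-6,
) -> float:
    """Normalized profile position (Reff - L)/(R - L), in [0, 1].

    Values within ``clip_tol`` outside [0, 1] (numerical overshoot of a PDE
    solve) are clipped; larger excursions raise.
    """
    amplitude = limit_l - limit_r
    if amplitude <= min_amplitude:
        raise DegenerateAmplitudeError(
            f"L - R = {amplitude:.3g} A is below the amplitude threshold"
        )
    di = (r_eff - limit_l) / (limit_r - limit_l)
    if di < -clip_tol or di > 1.0 + clip_tol:
        raise DomainError(f"diffusion influence {di} far outside [0, 1]")
    return float(min(max(di, 0.0), 1.0))
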