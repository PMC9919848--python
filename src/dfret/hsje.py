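"""Closed-form effective-distance surrogate.

Composes, without any PDE solve: the static limit L, the dynamic limit R,
the abscissa X = sqrt(D*tau_d)/r0, the calibrated sigmoid parameters
X0(rho) and M(rho) with rho = R0/rL, the diffusion influence
DI = (X/X0)^M / (1 + (X/X0)^M), and finally

    Reff = DI * (R - L) + L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .calibration import PolynomialModel, published_coefficients
from .distributions import DistanceDistribution
from .errors import DegenerateAmplitudeError, ValidityError
from .fret_core import (
    Photophysics,
    TransferObservables,
    dynamic_limit_R,
    observables_from_reff,
    profile_abscissa_x,
    static_limit_L,
)
from .profiles import sigmoid

__all__ = [
    "HSJEInput",
    "validity_check",
    "hsje_breakdown",
    "hsje_reff",
    "hsje_di",
    "hsje_predict_observables",
]


@dataclass(frozen=True)
class HSJEInput:
    """One closed-form evaluation: distribution, photophysics, D, coefficients."""

    dist: DistanceDistribution
    photo: Photophysics
    d: float
    coeffs: PolynomialModel | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        if self.coeffs is None:
            object.__setattr__(self, "coeffs", published_coefficients())
        validity_check(self.photo, self.dist.r_min, self.coeffs, strict=self.strict)


def validity_check(
    photo: Photophysics,
    rl: float,
    coeffs: PolynomialModel | None = None,
    strict: bool = False,
) -> list[str]:
    """Flag inputs outside the coefficient model's calibrated ranges.

    Returns the list of violations; raises instead when ``strict`` is set.
    """
    coeffs = coeffs or published_coefficients()
    problems = []
    lo, hi = coeffs.r0_range
    if not lo <= photo.r0 <= hi:
        problems.append(f"R0={photo.r0} A outside calibrated range [{lo}, {hi}] A")
    lo, hi = coeffs.rl_range
    if not lo <= rl <= hi:
        problems.append(f"rL={rl} A outside calibrated range [{lo}, {hi}] A")
    if photo.r0 / rl < coeffs.ratio_min:
        problems.append(
            f"R0/rL={photo.r0 / rl:.3g} below ratio constraint {coeffs.ratio_min}"
        )
    if problems:
        if strict:
            raise ValidityError("; ".join(problems))
        for msg in problems:
            warnings.warn(msg, stacklevel=3)
    return problems


def hsje_breakdown(inp: HSJEInput) -> dict:
    """All intermediate quantities of one closed-form evaluation."""
    photo = inp.photo
    limit_l = static_limit_L(inp.dist, photo.r0)
    limit_r = dynamic_limit_R(inp.dist)
    if limit_l - limit_r <= 1e-9:
        raise DegenerateAmplitudeError(
            f"L - R = {limit_l - limit_r:.3g} A: amplitude degenerate"
        )
    ratio = photo.r0 / inp.dist.r_min
    x = profile_abscissa_x(inp.d, photo.tau_d, photo.r0)
    x0 = float(inp.coeffs.x0(ratio))
    m = float(inp.coeffs.m(ratio))
    di = sigmoid(x, x0, m) if x > 0.0 else 0.0
    r_eff = di * (limit_r - limit_l) + limit_l
    return {
        "L": limit_l,
        "R": limit_r,
        "ratio": ratio,
        "X": x,
        "X0": x0,
        "M": m,
        "DI": float(di),
        "Reff": float(r_eff),
    }


def hsje_reff(inp: HSJEInput) -> float:
    """Closed-form effective distance (Å)."""
    return hsje_breakdown(inp)["Reff"]


def hsje_di(inp: HSJEInput) -> float:
    """Closed-form diffusion influence, in [0, 1]."""
    return hsje_breakdown(inp)["DI"]


def hsje_predict_observables(inp: HSJEInput) -> TransferObservables:
    """Efficiency/rates implied by the closed-form effective distance."""
    return observables_from_reff(hsje_reff(inp), inp.photo)
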