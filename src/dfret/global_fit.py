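"""Global least-squares fit of chain structure and dynamics.

A multi-condition dataset of effective distances (each condition carries its
own donor lifetime, Förster radius, and a dimensionless multiplier on the
reference diffusion coefficient encoding viscosity variation) is fitted by
minimizing the weighted sum of squared Reff residuals under the closed-form
surrogate. Free parameters: the reference diffusion coefficient, the
distribution length scale b, and optionally the left support limit rL.
Positive parameters are optimized on a log scale for conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .calibration import PolynomialModel, published_coefficients
from .distributions import DistanceDistribution, choose_r_max, normalize
from .errors import (
    DomainError,
    FitConvergenceError,
    InvalidParametersError,
    NegativeTransferError,
    UnidentifiableError,
)
from .fret_core import (
    dynamic_limit_R,
    efficiency_to_reff,
    static_limit_L,
)
from .profiles import sigmoid

__all__ = [
    "Condition",
    "Observation",
    "FitModel",
    "FitResult",
    "reff_from_intensity",
    "predict_reff",
    "fit_global",
    "load_observations",
    "observations_to_frame",
]


@dataclass(frozen=True)
class Condition:
    """One measurement condition."""

    label: str
    tau_d: float
    r0: float
    d_scale: float = 1.0
    temperature: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau_d > 0 and self.r0 > 0 and self.d_scale > 0):
            raise InvalidParametersError("tau_d, r0 and d_scale must be positive")


@dataclass(frozen=True)
class Observation:
    """One measured effective distance with its uncertainty."""

    condition: Condition
    r_eff_obs: float
    sigma: float

    def __post_init__(self) -> None:
        if self.r_eff_obs <= 0 or self.sigma <= 0:
            raise InvalidParametersError("r_eff_obs and sigma must be positive")


@dataclass
class FitModel:
    """Free-parameter layout and start values for :func:`fit_global`."""

    d_ref: float
    b: float
    rl: float
    dist_model: str = "ideal_chain_shifted"
    a: float | None = None
    free_rl: bool = False
    d_ref_bounds: tuple = (1e-6, 1e9)
    b_bounds: tuple | None = None  # default: (b/5, 5b)
    rl_bounds: tuple | None = None  # default: coefficient-model rl range


@dataclass(frozen=True)
class FitResult:
    estimates: dict
    stderr: dict
    ssr: float
    residuals: np.ndarray = field(repr=False)
    jacobian_condition: float
    converged: bool
    n_starts: int
    start_ssrs: tuple


def reff_from_intensity(i_da: float, i_d: float, r0: float) -> float:
    """Effective distance from steady-state intensities: E = 1 - I_DA/I_D."""
    if i_da <= 0 or i_d <= 0:
        raise DomainError("intensities must be positive")
    if i_da >= i_d:
        raise NegativeTransferError("I_DA >= I_D implies no transfer")
    return efficiency_to_reff(1.0 - i_da / i_d, r0)


def _build_dist(model: str, b: float, rl: float, r_max: float, a=None):
    return normalize(
        DistanceDistribution(model=model, b=b, r_min=rl, r_max=r_max, a=a)
    )


def predict_reff(
    model: FitModel,
    condition: Condition,
    coeffs: PolynomialModel | None = None,
    r_max: float | None = None,
) -> float:
    """Closed-form prediction for one condition at the model's parameters."""
    coeffs = coeffs or published_coefficients()
    if r_max is None:
        r_max = choose_r_max(model.dist_model, b=model.b, r_min=model.rl, a=model.a)
    dist = _build_dist(model.dist_model, model.b, model.rl, r_max, model.a)
    return _predict_many(dist, [condition], model.d_ref, coeffs)[0]


def _predict_many(dist, conditions, d_ref, coeffs) -> np.ndarray:
    """Vector of predictions sharing one distribution; L/R cached per R0."""
    limits: dict[float, tuple[float, float]] = {}
    limit_r = dynamic_limit_R(dist)
    out = np.empty(len(conditions))
    for i, cond in enumerate(conditions):
        if cond.r0 not in limits:
            limits[cond.r0] = (static_limit_L(dist, cond.r0), limit_r)
        limit_l, lr = limits[cond.r0]
        ratio = cond.r0 / dist.r_min
        x = np.sqrt(d_ref * cond.d_scale * cond.tau_d) / cond.r0
        di = sigmoid(x, float(coeffs.x0(ratio)), float(coeffs.m(ratio)))
        out[i] = di * (lr - limit_l) + limit_l
    return out


def _check_identifiability(observations) -> None:
    j = np.array(
        [o.condition.d_scale * o.condition.tau_d / o.condition.r0**2
         for o in observations]
    )
    if j.size and (j.max() - j.min()) / j.max() < 1e-9:
        raise UnidentifiableError(
            "all conditions share the same augmented diffusion coefficient; "
            "the reference diffusion coefficient is not identifiable"
        )


def fit_global(
    observations: list[Observation],
    model0: FitModel,
    coeffs: PolynomialModel | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Bounded nonlinear least squares over (ln D_ref, ln b[, rL])."""
    coeffs = coeffs or published_coefficients()
    _check_identifiability(observations)
    n_free = 2 + int(model0.free_rl)
    if len(observations) < n_free:
        raise UnidentifiableError(
            f"{len(observations)} observations cannot identify {n_free} parameters"
        )

    b_bounds = model0.b_bounds or (model0.b / 5.0, model0.b * 5.0)
    rl_bounds = model0.rl_bounds or coeffs.rl_range
    # one generous support limit for the whole fit (tail < 1e-6 at b upper bound)
    r_max = choose_r_max(
        model0.dist_model, b=b_bounds[1], r_min=rl_bounds[1], a=model0.a
    )

    conditions = [o.condition for o in observations]
    obs = np.array([o.r_eff_obs for o in observations])
    sig = np.array([o.sigma for o in observations])

    def unpack(theta):
        d_ref, b = np.exp(theta[0]), np.exp(theta[1])
        rl = theta[2] if model0.free_rl else model0.rl
        return d_ref, b, rl

    def residuals(theta):
        d_ref, b, rl = unpack(theta)
        dist = _build_dist(model0.dist_model, b, rl, r_max, model0.a)
        return (_predict_many(dist, conditions, d_ref, coeffs) - obs) / sig

    lo = [np.log(model0.d_ref_bounds[0]), np.log(b_bounds[0])]
    hi = [np.log(model0.d_ref_bounds[1]), np.log(b_bounds[1])]
    if model0.free_rl:
        lo.append(rl_bounds[0])
        hi.append(rl_bounds[1])
    lo, hi = np.array(lo), np.array(hi)

    theta0 = [np.log(model0.d_ref), np.log(model0.b)]
    if model0.free_rl:
        theta0.append(model0.rl)
    theta0 = np.clip(np.array(theta0), lo + 1e-9, hi - 1e-9)

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.normal(0.0, [0.7, 0.15, 0.2][: theta0.size])
        starts.append(np.clip(theta0 + jitter, lo + 1e-9, hi - 1e-9))

    best = None
    start_ssrs = []
    for start in starts:
        try:
            res = least_squares(
                residuals, start, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            start_ssrs.append(np.inf)
            continue
        ssr = float(res.cost * 2.0)
        start_ssrs.append(ssr)
        if res.success and (best is None or ssr < best[0]):
            best = (ssr, res)
    if best is None:
        raise FitConvergenceError(
            f"no start converged; starts tried: {[list(s) for s in starts]}"
        )
    ssr, res = best

    d_ref, b, rl = unpack(res.x)
    estimates = {"d_ref": d_ref, "b": b, "rl": rl}

    jac = res.jac
    _, sv, _ = np.linalg.svd(jac, full_matrices=False)
    cond_number = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    cov = np.linalg.pinv(jac.T @ jac)
    theta_se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    stderr = {"d_ref": d_ref * theta_se[0], "b": b * theta_se[1]}
    stderr["rl"] = theta_se[2] if model0.free_rl else 0.0

    return FitResult(
        estimates=estimates,
        stderr=stderr,
        ssr=ssr,
        residuals=res.fun * sig,
        jacobian_condition=cond_number,
        converged=True,
        n_starts=len(starts),
        start_ssrs=tuple(start_ssrs),
    )


def load_observations(path) -> list[Observation]:
    """Read the dataset CSV dialect.

    Columns: label, tau_d_ns, r0_angstrom, d_scale, sigma_angstrom and either
    reff_angstrom or the intensity pair (i_da, i_d).
    """
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        cond = Condition(
            label=str(row["label"]),
            tau_d=float(row["tau_d_ns"]),
            r0=float(row["r0_angstrom"]),
            d_scale=float(row.get("d_scale", 1.0)),
        )
        if "reff_angstrom" in df.columns and not pd.isna(row.get("reff_angstrom")):
            r_eff = float(row["reff_angstrom"])
        else:
            r_eff = reff_from_intensity(
                float(row["i_da"]), float(row["i_d"]), cond.r0
            )
        out.append(
            Observation(condition=cond, r_eff_obs=r_eff,
                        sigma=float(row["sigma_angstrom"]))
        )
    return out


def observations_to_frame(observations: list[Observation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [o.condition.label for o in observations],
            "tau_d_ns": [o.condition.tau_d for o in observations],
            "r0_angstrom": [o.condition.r0 for o in observations],
            "d_scale": [o.condition.d_scale for o in observations],
            "reff_angstrom": [o.r_eff_obs for o in observations],
            "sigma_angstrom": [o.sigma for o in observations],
        }
    )
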