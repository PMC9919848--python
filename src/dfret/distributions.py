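"""End-to-end distance-distribution models.

Four model kernels are supported, all defined on a truncated support
``[r_min, r_max]`` (angstrom):

``ideal_chain_legacy``
    p(r) ∝ r² exp(−3r²/(2b²)) — the one-parameter random-coil model; on an
    untruncated support b equals the root-mean-square end-to-end distance.
``skewed_gaussian_legacy``
    p(r) ∝ r² exp(−a(b − r)²) — the two-parameter skewed Gaussian.
``ideal_chain_shifted`` / ``skewed_gaussian_shifted``
    Same kernels in the shifted coordinate r0 = r − r_min, which forces
    p(r_min) = 0 and removes the density jump at the left support edge.

The skewed-Gaussian exponent convention exp(−a(b − r)²) (a in Å⁻²) is
isolated in :func:`_kernel_skewed`; change it there if a different grouping
is ever required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

from .errors import DivergenceError, DomainError, InvalidParametersError

__all__ = [
    "MODELS",
    "DistanceDistribution",
    "make_distribution",
    "evaluate_pdf",
    "normalize",
    "inverse_sixth_moment",
    "sample",
    "choose_r_max",
]

MODELS = (
    "ideal_chain_legacy",
    "skewed_gaussian_legacy",
    "ideal_chain_shifted",
    "skewed_gaussian_shifted",
)

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-11, limit=400)


def _kernel_ideal(r, b):
    r = np.asarray(r, dtype=float)
    return r * r * np.exp(-1.5 * (r / b) ** 2)


def _kernel_skewed(r, a, b):
    # exponent convention: exp(-a*(b - r)^2), a in 1/A^2
    r = np.asarray(r, dtype=float)
    return r * r * np.exp(-a * (b - r) ** 2)


@dataclass(frozen=True)
class DistanceDistribution:
    """A (possibly unnormalized) end-to-end distance density on [r_min, r_max].

    Parameters
    ----------
    model : str
        One of :data:`MODELS`.
    b : float
        Length-scale parameter (Å).
    r_min, r_max : float
        Support limits (Å); ``r_max`` defaults to :func:`choose_r_max`.
    a : float, optional
        Skewness parameter (Å⁻²), skewed-Gaussian models only.
    norm : float
        Multiplier such that ``norm * kernel`` integrates to 1 on the support;
        set by :func:`normalize`.
    """

    model: str
    b: float
    r_min: float
    r_max: float
    a: float | None = None
    norm: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InvalidParametersError(f"unknown model {self.model!r}")
        if not (self.r_min >= 0.0 and self.r_max > self.r_min):
            raise InvalidParametersError(
                f"need 0 <= r_min < r_max, got [{self.r_min}, {self.r_max}]"
            )
        if not (np.isfinite(self.b) and self.b > 0):
            raise InvalidParametersError(f"b must be positive, got {self.b}")
        if "skewed" in self.model:
            if self.a is None or not np.isfinite(self.a) or self.a <= 0:
                raise InvalidParametersError(
                    f"skewed-Gaussian models need a > 0, got a={self.a}"
                )

    @property
    def shifted(self) -> bool:
        return self.model.endswith("_shifted")

    @property
    def normalized(self) -> bool:
        return self.norm is not None

    def kernel(self, r):
        """Unnormalized model kernel evaluated at r (vectorized, no domain check)."""
        r = np.asarray(r, dtype=float)
        x = r - self.r_min if self.shifted else r
        x = np.where(x < 0.0, 0.0, x)
        if self.model.startswith("ideal_chain"):
            return _kernel_ideal(x, self.b)
        return _kernel_skewed(x, self.a, self.b)

    def pdf(self, r):
        """Normalized density at r; raises outside the support."""
        return evaluate_pdf(self, r)

    def to_dict(self) -> dict:
        d = {"model": self.model, "b": self.b, "r_min": self.r_min, "r_max": self.r_max}
        if self.a is not None:
            d["a"] = self.a
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceDistribution":
        dist = cls(
            model=d["model"],
            b=float(d["b"]),
            r_min=float(d.get("r_min", d.get("rL", 0.0))),
            r_max=float(d.get("r_max", d.get("rR"))),
            a=float(d["a"]) if d.get("a") is not None else None,
        )
        return normalize(dist)

    @classmethod
    def from_json(cls, path) -> "DistanceDistribution":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_file(cls, path) -> "DistanceDistribution":
        """Load a {model, a, b, r_min, r_max} record from JSON or YAML."""
        path = str(path)
        if path.endswith((".yaml", ".yml")):
            import yaml

            with open(path) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_json(path)


def make_distribution(
    model: str,
    b: float,
    r_min: float,
    r_max: float | None = None,
    a: float | None = None,
    tail_tolerance: float = 1e-6,
) -> DistanceDistribution:
    """Construct and normalize a distribution, choosing r_max if not given."""
    if r_max is None:
        r_max = choose_r_max(model, b=b, r_min=r_min, a=a, tail_tolerance=tail_tolerance)
    return normalize(DistanceDistribution(model=model, b=b, r_min=r_min, r_max=r_max, a=a))


def normalize(dist: DistanceDistribution) -> DistanceDistribution:
    """Return a copy with ``norm`` set so the density integrates to 1."""
    total, _ = integrate.quad(dist.kernel, dist.r_min, dist.r_max, **_QUAD_OPTS)
    if not np.isfinite(total) or total <= 0.0:
        raise InvalidParametersError(
            f"kernel integral on [{dist.r_min}, {dist.r_max}] is {total}"
        )
    return replace(dist, norm=1.0 / total)


def _require_normalized(dist: DistanceDistribution) -> None:
    if not dist.normalized:
        raise InvalidParametersError("distribution must be normalized first")


def evaluate_pdf(dist: DistanceDistribution, r):
    """Normalized density (Å⁻¹) at r; r must lie in [r_min, r_max]."""
    _require_normalized(dist)
    r = np.asarray(r, dtype=float)
    if np.any(r < dist.r_min - 1e-12) or np.any(r > dist.r_max + 1e-12):
        raise DomainError(
            f"r outside support [{dist.r_min}, {dist.r_max}]"
        )
    out = dist.norm * dist.kernel(r)
    return float(out) if out.ndim == 0 else out


def inverse_sixth_moment(dist: DistanceDistribution) -> float:
    """⟨r⁻⁶⟩ = ∫ p(r) r⁻⁶ dr over the support (Å⁻⁶)."""
    _require_normalized(dist)
    if dist.r_min <= 0.0:
        raise DivergenceError("inverse-sixth moment diverges for r_min <= 0")
    val, _ = integrate.quad(
        lambda r: dist.norm * dist.kernel(r) / r**6, dist.r_min, dist.r_max, **_QUAD_OPTS
    )
    return val


def mean_distance(dist: DistanceDistribution) -> float:
    """First moment ⟨r⟩ on the truncated support (Å)."""
    _require_normalized(dist)
    val, _ = integrate.quad(
        lambda r: dist.norm * dist.kernel(r) * r, dist.r_min, dist.r_max, **_QUAD_OPTS
    )
    return val


def _cdf_grid(dist: DistanceDistribution, n: int = 20001):
    r = np.linspace(dist.r_min, dist.r_max, n)
    p = dist.norm * dist.kernel(r)
    cdf = integrate.cumulative_trapezoid(p, r, initial=0.0)
    cdf /= cdf[-1]
    return r, cdf


def sample(dist: DistanceDistribution, n: int, seed: int) -> np.ndarray:
    """Inverse-CDF samples; deterministic for a fixed seed."""
    _require_normalized(dist)
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    r, cdf = _cdf_grid(dist)
    # collapse flat CDF stretches so np.interp stays well defined
    keep = np.concatenate(([True], np.diff(cdf) > 0))
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf[keep], r[keep])


def tabulate(dist: DistanceDistribution, r_grid: Sequence[float]):
    """Return (r, p(r)) arrays suitable for CSV export."""
    r = np.asarray(r_grid, dtype=float)
    return r, evaluate_pdf(dist, r)


def choose_r_max(
    model: str,
    b: float,
    r_min: float,
    a: float | None = None,
    tail_tolerance: float = 1e-6,
) -> float:
    """Smallest grid-friendly right limit whose untruncated tail mass is below tol.

    The tail criterion is evaluated on the untruncated kernel (support
    [r_min, ∞)); the returned value is rounded up to 0.5 Å.
    """
    if not (0.0 < tail_tolerance <= 1e-3):
        raise DomainError("tail_tolerance must be in (0, 1e-3]")
    probe = DistanceDistribution(
        model=model, b=b, r_min=r_min, r_max=r_min + 1000.0 * b, a=a
    )
    total, _ = integrate.quad(probe.kernel, r_min, np.inf, **_QUAD_OPTS)
    if not np.isfinite(total) or total <= 0.0:
        raise InvalidParametersError("kernel is not integrable on [r_min, inf)")

    def tail_excess(r_hi: float) -> float:
        t, _ = integrate.quad(probe.kernel, r_hi, np.inf, **_QUAD_OPTS)
        return t / total - tail_tolerance

    lo, hi = r_min + b, r_min + 2.0 * b
    while tail_excess(hi) > 0.0:
        hi += 2.0 * b
        if hi > r_min + 1000.0 * b:  # pragma: no cover - pathological kernels
            raise InvalidParametersError("tail does not decay; cannot choose r_max")
    if tail_excess(lo) <= 0.0:
        hi = lo
        lo = r_min + 1e-9
    root = optimize.brentq(tail_excess, lo, hi, xtol=1e-6)
    return float(np.ceil(root * 2.0) / 2.0)
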