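"""Matérn covariance with smoothness fixed at 1, and its reparametrisations.

The spatial dependence model is the Matérn family

    cov(Δ) = σ² · 2^(1-λ)/Γ(λ) · (κΔ)^λ · K_λ(κΔ),

with smoothness λ fixed at 1 throughout (it is poorly identified from binary
data, and the sparse-precision representation used elsewhere in this package
assumes it).  The *range of influence* is ρ = √(8λ)/κ, the distance at which
the correlation has decayed to roughly 0.1 (0.1397 exactly for λ = 1).  The
marginal variance is tied to the precision-scale parameter τ by
σ² = 1/(2π κ² τ²).

This module is the dense, analytic side of the story: exact correlation and
covariance evaluation used directly for small problems and as the oracle
against which the sparse finite-element representation is checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import kv

__all__ = [
    "MaternParams",
    "matern_correlation",
    "range_from_kappa",
    "kappa_from_range",
    "sigma2_from_kappa_tau",
    "tau_from_sigma2_kappa",
    "dense_covariance",
]

_TWO_PI = 2.0 * math.pi


def range_from_kappa(kappa: float, lam: float = 1.0) -> float:
    """Range of influence ρ = √(8λ)/κ in km."""
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    return math.sqrt(8.0 * lam) / kappa


def kappa_from_range(rng: float, lam: float = 1.0) -> float:
    """Inverse of :func:`range_from_kappa`."""
    if rng <= 0:
        raise ValueError(f"range must be positive, got {rng}")
    return math.sqrt(8.0 * lam) / rng


def sigma2_from_kappa_tau(kappa: float, tau: float) -> float:
    """Marginal variance σ² = 1/(2π κ² τ²)."""
    if kappa <= 0 or tau <= 0:
        raise ValueError("kappa and tau must be positive")
    return 1.0 / (_TWO_PI * kappa**2 * tau**2)


def tau_from_sigma2_kappa(sigma2: float, kappa: float) -> float:
    """Inverse of :func:`sigma2_from_kappa_tau` in τ."""
    if sigma2 <= 0 or kappa <= 0:
        raise ValueError("sigma2 and kappa must be positive")
    return 1.0 / math.sqrt(_TWO_PI * sigma2 * kappa**2)


@dataclass(frozen=True)
class MaternParams:
    """Parameters of a λ=1 Matérn field: (σ², κ) with τ kept consistent.

    Exactly one of the two parametrisations pins the other:
    σ² = 1/(2π κ² τ²).  ``lam`` is stored but frozen at 1.
    """

    sigma2: float
    kappa: float
    lam: float = 1.0
    tau: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lam != 1.0:
            raise ValueError("smoothness lam is fixed at 1")
        if self.sigma2 <= 0 or self.kappa <= 0:
            raise ValueError("sigma2 and kappa must be positive")
        if self.tau is None:
            object.__setattr__(
                self, "tau", tau_from_sigma2_kappa(self.sigma2, self.kappa)
            )
        else:
            if self.tau <= 0:
                raise ValueError("tau must be positive")
            implied = sigma2_from_kappa_tau(self.kappa, self.tau)
            if not math.isclose(implied, self.sigma2, rel_tol=1e-10):
                raise ValueError(
                    f"inconsistent parametrisation: sigma2={self.sigma2} but "
                    f"1/(2*pi*kappa^2*tau^2)={implied}"
                )

    @property
    def range_km(self) -> float:
        return range_from_kappa(self.kappa, self.lam)

    @classmethod
    def from_range(cls, range_km: float, sigma2: float) -> "MaternParams":
        return cls(sigma2=sigma2, kappa=kappa_from_range(range_km))

    @classmethod
    def from_kappa_tau(cls, kappa: float, tau: float) -> "MaternParams":
        return cls(sigma2=sigma2_from_kappa_tau(kappa, tau), kappa=kappa, tau=tau)


def matern_correlation(delta, params: MaternParams):
    """Matérn correlation κΔ·K₁(κΔ) at distance(s) ``delta`` (km).

    The Δ=0 limit is handled by an explicit branch so the diagonal is
    exactly 1.  Accepts a scalar or an array; negative distances raise.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("distances must be non-negative")
    x = params.kappa * delta
    with np.errstate(invalid="ignore"):
        corr = np.where(x > 0, x * kv(1, np.where(x > 0, x, 1.0)), 1.0)
    # K_1 underflows to 0 for large x; the product is then 0, which is right.
    corr = np.nan_to_num(corr, nan=0.0)
    if corr.ndim == 0:
        return float(corr)
    return corr


def dense_covariance(locations: np.ndarray, params: MaternParams) -> np.ndarray:
    """n×n Matérn covariance matrix over planar locations (km).

    Diagonal is exactly σ²; duplicate locations get covariance σ².
    """
    locations = np.asarray(locations, dtype=float)
    if locations.ndim != 2 or locations.shape[1] != 2:
        raise ValueError("locations must be an (n, 2) array")
    if not np.all(np.isfinite(locations)):
        raise ValueError("locations contain non-finite coordinates")
    dist = cdist(locations, locations)
    cov = params.sigma2 * matern_correlation(dist, params)
    np.fill_diagonal(cov, params.sigma2)
    return cov
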