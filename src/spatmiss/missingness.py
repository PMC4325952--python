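"""Simulation of missing binary outcomes under MCAR, MAR and MNAR.

Each record's probability of being missing follows a logistic model

    logit π_i = μ                  (MCAR)
    logit π_i = μ + ν · X_i        (MAR, X a fully observed covariate)
    logit π_i = μ + ν · y_i        (MNAR, y the outcome itself),

with ν = log(OR) per one-unit covariate increase and μ calibrated so the
expected fraction missing over the realised driver values equals the
scenario's target proportion.  Missing indicators are independent Bernoulli
draws; the mask never destroys the underlying truth (see
:meth:`SpatialDataset` semantics), so downstream comparisons against the
complete data remain possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datasets import SpatialDataset

__all__ = ["MissingnessModel", "calibrate_mu", "simulate_mask", "apply_mask"]

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass(frozen=True)
class MissingnessModel:
    """One missing-data mechanism with its calibrated intercept.

    ``driver`` names the covariate column driving MAR masks, or is
    ``"outcome"`` for MNAR; ignored for MCAR.  ``nu`` is log(OR) and must be
    0 exactly for MCAR.
    """

    mechanism: str
    target_prop: float
    nu: float = 0.0
    driver: str | None = None
    mu: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.target_prop < 1.0):
            raise ValueError("target_prop must be in [0, 1)")
        if self.mechanism == "MCAR" and self.nu != 0.0:
            raise ValueError("MCAR requires nu == 0")
        if self.mechanism == "MNAR":
            object.__setattr__(self, "driver", "outcome")
        if self.mechanism == "MAR" and self.driver is None:
            raise ValueError("MAR requires a driver covariate")

    @classmethod
    def from_odds_ratio(
        cls, mechanism: str, target_prop: float, odds_ratio: float = 1.0,
        driver: str | None = None,
    ) -> "MissingnessModel":
        nu = 0.0 if mechanism == "MCAR" else math.log(odds_ratio)
        return cls(mechanism=mechanism, target_prop=target_prop, nu=nu,
                   driver=driver)


def _driver_values(model: MissingnessModel, dataset: SpatialDataset) -> np.ndarray:
    if model.mechanism == "MCAR":
        return np.zeros(dataset.n)
    if model.mechanism == "MNAR":
        if not dataset.observed.all():
            raise ValueError(
                "MNAR masks need the full pre-masking outcome vector"
            )
        return dataset.outcome.astype(float)
    return dataset.covariates[model.driver].to_numpy(dtype=float)


def calibrate_mu(model: MissingnessModel, driver_values: np.ndarray) -> float:
    """Solve for μ so the mean missingness probability over the realised
    driver values equals ``target_prop`` (finite-population calibration).

    MCAR has the closed form μ = logit(target); MAR/MNAR use monotone
    root-finding to |error| < 1e-8.
    """
    target = model.target_prop
    if target == 0.0:
        return -800.0  # expit underflows to exactly 0: nothing goes missing
    if model.mechanism == "MCAR" or model.nu == 0.0:
        return float(logit(target))
    d = np.asarray(driver_values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("driver values must be finite")

    def mean_prob(mu):
        return float(np.mean(expit(mu + model.nu * d))) - target

    spread = abs(model.nu) * (np.abs(d).max() + 1.0)
    lo = logit(target) - spread - 40.0
    hi = logit(target) + spread + 40.0
    if mean_prob(lo) > 0 or mean_prob(hi) < 0:
        raise ValueError("target proportion unattainable for this driver")
    mu = brentq(mean_prob, lo, hi, xtol=1e-12)
    if abs(mean_prob(mu)) > 1e-8:
        raise RuntimeError("mu calibration did not reach tolerance")
    return float(mu)


def calibrate(model: MissingnessModel, dataset: SpatialDataset) -> MissingnessModel:
    """Return a copy of ``model`` with μ calibrated on this dataset."""
    mu = calibrate_mu(model, _driver_values(model, dataset))
    return replace(model, mu=mu)


def simulate_mask(
    model: MissingnessModel, dataset: SpatialDataset, rng_seed
) -> np.ndarray:
    """Independent Bernoulli missing indicators (True = missing)."""
    m = model if model.mu is not None else calibrate(model, dataset)
    d = _driver_values(m, dataset)
    pi = expit(m.mu + m.nu * d)
    rng = np.random.default_rng(rng_seed)
    return rng.random(dataset.n) < pi


def apply_mask(dataset: SpatialDataset, mask: np.ndarray) -> SpatialDataset:
    """Flag masked rows unobserved; outcome values are retained internally
    for later truth comparison."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (dataset.n,):
        raise ValueError("mask length mismatch")
    out = dataset.copy()
    out.observed = dataset.observed & ~mask
    return out


def export_masks(masks: np.ndarray, path) -> None:
    """Audit dump: replicates × n matrix of 0/1 missing flags."""
    np.savetxt(path, np.asarray(masks, dtype=int), fmt="%d", delimiter="\t")
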