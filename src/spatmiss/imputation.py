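"""Multiple imputation of missing binary outcomes and Rubin's-rules pooling.

Unobserved outcomes are imputed from the posterior predictive distribution
of an imputation model (the spatial logistic model with both covariates, or
a non-spatial comparator): a success probability is drawn jointly from the
posterior, then a Bernoulli outcome from it.  Each completed dataset is
refitted with the analysis model and the M per-imputation summaries are
pooled:

* α and β on the identity scale with Rubin's rules — point = mean of the M
  posterior means, total variance = W + (1 + 1/M)·B with W the mean
  posterior variance and B the between-imputation sample variance;
* σ² and the range on the log scale (their posteriors are right-skewed),
  back-transformed with the lognormal moment identities
  E = exp(m + V/2), Var = (exp(V) − 1)·exp(2m + V).

The number of imputations M follows the missingness fraction: 3 at 5%,
5 at 10–25%, 10 at 50–75%, keeping pooled efficiency roughly constant
across scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import SpatialDataset
from .inference import FitResult, posterior_predict

__all__ = [
    "ImputationSet",
    "PooledEstimate",
    "n_imputations",
    "impute_once",
    "make_imputations",
    "rubin_combine",
    "combine_lognormal",
    "pool_fit",
]

_M_POLICY = {0.05: 3, 0.10: 5, 0.15: 5, 0.25: 5, 0.50: 10, 0.75: 10}


@dataclass
class ImputationSet:
    completed_datasets: list
    source_mask: np.ndarray

    @property
    def M(self) -> int:
        return len(self.completed_datasets)


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    variance: float
    within: float
    between: float
    M: int
    scale: str = "identity"

    @property
    def sd(self) -> float:
        return math.sqrt(max(self.variance, 0.0))


def n_imputations(prop_missing: float) -> int:
    """M = 3 / 5 / 10 depending on the missingness fraction; off-policy
    fractions snap to the nearest policy value with a warning."""
    if prop_missing in _M_POLICY:
        return _M_POLICY[prop_missing]
    import warnings as _w

    nearest = min(_M_POLICY, key=lambda p: abs(p - prop_missing))
    _w.warn(
        f"no imputation-count rule for {prop_missing:g}; using the "
        f"{nearest:g} rule",
        stacklevel=2,
    )
    return _M_POLICY[nearest]


def impute_once(
    fit_result: FitResult, dataset: SpatialDataset, rng_seed
) -> SpatialDataset:
    """One completed dataset: posterior-predictive probabilities at the
    unobserved rows, then Bernoulli outcomes; observed rows untouched."""
    if not fit_result.converged:
        raise ValueError("refusing to impute from an unconverged fit")
    unobs = ~dataset.observed
    if not unobs.any():
        return dataset.copy()
    p = posterior_predict(fit_result, dataset, rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 1]))
    draws = (rng.random(p.size) < p).astype(np.int8)
    outcome = dataset.outcome.copy()
    outcome[unobs] = draws
    return dataset.with_outcome(outcome)


def make_imputations(
    fit_result: FitResult, dataset: SpatialDataset, M: int, rng_seed
) -> ImputationSet:
    seeds = np.random.SeedSequence(rng_seed).generate_state(M) % (2**31)
    completed = [
        impute_once(fit_result, dataset, int(s)) for s in seeds
    ]
    return ImputationSet(
        completed_datasets=completed, source_mask=~dataset.observed
    )


def rubin_combine(
    estimates: Sequence[float], variances: Sequence[float]
) -> PooledEstimate:
    """Rubin's rules on whatever scale the inputs live on."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1 or est.size == 0:
        raise ValueError("estimates and variances must be equal-length vectors")
    M = est.size
    point = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1)) if M > 1 else 0.0
    total = W + (1.0 + 1.0 / M) * B
    return PooledEstimate(point=point, variance=total, within=W, between=B, M=M)


def combine_lognormal(
    log_estimates: Sequence[float], log_variances: Sequence[float]
) -> PooledEstimate:
    """Rubin's rules on the log scale, back-transformed with lognormal
    moments: point = exp(m + V/2), variance = (exp(V) − 1)·exp(2m + V)."""
    log_est = np.asarray(log_estimates, dtype=float)
    log_var = np.asarray(log_variances, dtype=float)
    if not (np.all(np.isfinite(log_est)) and np.all(np.isfinite(log_var))):
        raise ValueError("log-scale inputs must be finite")
    pooled = rubin_combine(log_est, log_var)
    m, V = pooled.point, pooled.variance
    if not math.isfinite(V):
        raise ValueError("non-finite pooled log-scale variance")
    point = math.exp(m + V / 2.0)
    variance = (math.exp(V) - 1.0) * math.exp(2.0 * m + V)
    return PooledEstimate(
        point=point,
        variance=variance,
        within=pooled.within,
        between=pooled.between,
        M=pooled.M,
        scale="log",
    )


@dataclass
class PooledFit:
    """Rubin-pooled analogue of a FitResult."""

    pooled: dict            # name -> PooledEstimate
    member_fits: list       # per-imputation FitResults
    M: int
    warnings: list = field(default_factory=list)

    @property
    def range_km(self) -> float:
        return self.pooled["range"].point

    def param(self, name: str, stat: str = "point") -> float:
        pe = self.pooled[name]
        return pe.point if stat in ("point", "median", "mean") else pe.sd

    def member_ranges(self) -> list[float]:
        return [f.summary["range"]["median"] for f in self.member_fits]

    def to_series(self):
        import pandas as pd

        out = {"M": self.M}
        for name, pe in self.pooled.items():
            out[f"{name}_point"] = pe.point
            out[f"{name}_sd"] = pe.sd
        return pd.Series(out)


def pool_fit(member_fits: Sequence[FitResult]) -> PooledFit:
    """Pool per-imputation analysis fits.

    α/β: identity scale, per-imputation point = posterior mean, variance =
    posterior SD².  σ²/range: log scale, using the mean and variance of the
    log-transformed grid posterior, back-transformed to the original scale.
    """
    fits = [f for f in member_fits if f is not None]
    if not fits:
        raise ValueError("all member fits failed")
    dropped = len(member_fits) - len(fits)
    warnings = []
    if dropped:
        warnings.append(f"{dropped} member fit(s) excluded")
    pooled: dict[str, PooledEstimate] = {}
    reg_names = [
        k for k in fits[0].summary if k == "alpha" or k.startswith("beta_")
    ]
    for name in reg_names:
        pooled[name] = rubin_combine(
            [f.summary[name]["mean"] for f in fits],
            [f.summary[name]["sd"] ** 2 for f in fits],
        )
    if fits[0].spatial:
        for name in ("sigma2", "range"):
            pooled[name] = combine_lognormal(
                [f.summary[name]["log_mean"] for f in fits],
                [f.summary[name]["log_var"] for f in fits],
            )
    return PooledFit(
        pooled=pooled, member_fits=list(fits), M=len(fits), warnings=warnings
    )
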