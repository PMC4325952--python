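"""The tabular unit every stage of the study consumes: point-referenced
binary outcomes with covariates and an observation mask."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpatialDataset", "read_dataset", "write_dataset"]

#: canonical covariate column order: (log herd size, herd density)
COVARIATE_COLUMNS = ("log_herd_size", "herd_density")


@dataclass
class SpatialDataset:
    """Point data for one region: locations (km), covariates, binary outcome.

    ``outcome`` always holds the full simulated truth; ``observed`` flags which
    entries the analysis is allowed to see.  Masking never destroys the truth,
    so the study can later compare estimates against it.
    """

    locations: np.ndarray          # (n, 2) km, planar UTM-like frame
    covariates: pd.DataFrame       # (n, p)
    outcome: np.ndarray            # (n,) int 0/1
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        self.outcome = np.asarray(self.outcome, dtype=np.int8)
        n = self.locations.shape[0]
        if self.locations.shape != (n, 2):
            raise ValueError("locations must be (n, 2)")
        if len(self.covariates) != n or len(self.outcome) != n:
            raise ValueError("locations, covariates and outcome lengths differ")
        if self.observed is None:
            self.observed = np.ones(n, dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != (n,):
            raise ValueError("observed mask has wrong length")
        obs_vals = self.outcome[self.observed]
        if obs_vals.size and not np.isin(obs_vals, [0, 1]).all():
            raise ValueError("observed outcomes must be 0/1")

    @property
    def n(self) -> int:
        return self.locations.shape[0]

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def prevalence(self) -> float:
        """Fraction positive among observed outcomes."""
        obs = self.outcome[self.observed]
        return float(obs.mean()) if obs.size else float("nan")

    def covariate_matrix(self, columns=None) -> np.ndarray:
        cols = list(columns) if columns is not None else list(self.covariates.columns)
        return self.covariates[cols].to_numpy(dtype=float)

    def restrict_observed(self) -> "SpatialDataset":
        """Drop unobserved rows entirely."""
        keep = self.observed
        return SpatialDataset(
            locations=self.locations[keep],
            covariates=self.covariates.loc[keep].reset_index(drop=True),
            outcome=self.outcome[keep],
            observed=np.ones(int(keep.sum()), dtype=bool),
        )

    def with_outcome(self, outcome: np.ndarray, observed=None) -> "SpatialDataset":
        obs = observed if observed is not None else np.ones(self.n, dtype=bool)
        return SpatialDataset(
            locations=self.locations.copy(),
            covariates=self.covariates.copy(),
            outcome=np.asarray(outcome, dtype=np.int8),
            observed=np.asarray(obs, dtype=bool).copy(),
        )

    def copy(self) -> "SpatialDataset":
        return replace(
            self,
            locations=self.locations.copy(),
            covariates=self.covariates.copy(),
            outcome=self.outcome.copy(),
            observed=self.observed.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"x_km": self.locations[:, 0], "y_km": self.locations[:, 1]}
        )
        for col in self.covariates.columns:
            df[col] = self.covariates[col].to_numpy()
        df["outcome"] = self.outcome
        df["observed"] = self.observed.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpatialDataset":
        cov_cols = [
            c for c in df.columns if c not in ("x_km", "y_km", "outcome", "observed")
        ]
        observed = (
            df["observed"].to_numpy().astype(bool)
            if "observed" in df
            else np.ones(len(df), dtype=bool)
        )
        return cls(
            locations=df[["x_km", "y_km"]].to_numpy(dtype=float),
            covariates=df[cov_cols].reset_index(drop=True),
            outcome=df["outcome"].to_numpy(),
            observed=observed,
        )


def write_dataset(dataset: SpatialDataset, path) -> None:
    """Write as tab-delimited text with header."""
    dataset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_dataset(path) -> SpatialDataset:
    return SpatialDataset.from_frame(pd.read_csv(path, sep="\t"))
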