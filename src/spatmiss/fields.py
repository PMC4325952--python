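"""Latent-field backends for the spatial logistic model.

Two interchangeable representations of the latent Matérn field:

* :class:`SpdeFieldModel` — the sparse GMRF representation on a triangulation
  (the production route; scales to thousands of locations).
* :class:`DenseFieldModel` — the exact dense-covariance representation with
  the field evaluated at the data locations themselves (small n only; used
  as the reference in cross-checks against sampling-based inference).

Both expose the same surface: a projector ``A`` (n × dim), the precision
``Q(κ, τ)``, a root K with KᵀK = Q, and the log-determinant of Q.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .matern import MaternParams, dense_covariance
from .mesh import Mesh, SpdeOperator, make_projector

__all__ = ["SpdeFieldModel", "DenseFieldModel", "sparse_logdet"]


def sparse_logdet(M: sp.spmatrix) -> float:
    """log |det M| via sparse LU; intended for SPD matrices."""
    lu = splu(M.tocsc())
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


class SpdeFieldModel:
    """GMRF field on a mesh, projected to data locations barycentrically."""

    def __init__(self, mesh: Mesh, locations: np.ndarray):
        self.mesh = mesh
        self.op = SpdeOperator(mesh)
        self.A = make_projector(mesh, locations).weights
        self.dim = mesh.n_vertices
        self._log_c = np.log(self.op.C.diagonal())

    def precision(self, kappa: float, tau: float) -> sp.csc_matrix:
        return self.op.precision(kappa, tau)

    def precision_root(self, kappa: float, tau: float) -> sp.csc_matrix:
        return self.op.precision_root(kappa, tau)

    def logdet_precision(self, kappa: float, tau: float) -> float:
        # Q = (τ²/2)(κ²C + G) C⁻¹ (κ²C + G); the middle factor is diagonal
        V = self.dim
        M = (kappa * kappa) * self.op.C + self.op.G
        return (
            V * math.log(tau * tau / 2.0)
            - float(self._log_c.sum())
            + 2.0 * sparse_logdet(M)
        )


class DenseFieldModel:
    """Exact Matérn field at the data locations; A is the identity."""

    def __init__(self, locations: np.ndarray):
        self.locations = np.asarray(locations, dtype=float)
        n = self.locations.shape[0]
        self.A = sp.identity(n, format="csr")
        self.dim = n

    def _cov_chol(self, kappa: float, tau: float) -> np.ndarray:
        params = MaternParams.from_kappa_tau(kappa, tau)
        cov = dense_covariance(self.locations, params)
        cov[np.diag_indices_from(cov)] += 1e-10 * params.sigma2
        return np.linalg.cholesky(cov)

    def precision(self, kappa: float, tau: float) -> sp.csc_matrix:
        L = self._cov_chol(kappa, tau)
        inv = np.linalg.inv(L.T) @ np.linalg.inv(L)
        return sp.csc_matrix(inv)

    def precision_root(self, kappa: float, tau: float) -> sp.csc_matrix:
        # Q = Σ⁻¹ = L⁻ᵀ L⁻¹, so K = L⁻¹ satisfies KᵀK = Q
        L = self._cov_chol(kappa, tau)
        return sp.csc_matrix(np.linalg.inv(L))

    def logdet_precision(self, kappa: float, tau: float) -> float:
        L = self._cov_chol(kappa, tau)
        return -2.0 * float(np.sum(np.log(np.diag(L))))
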