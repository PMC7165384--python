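"""Small dense/sparse linear-algebra helpers shared by the fitting code.

All latent precisions handled here are modest (a few thousand rows at
most), so factorisations are done densely with LAPACK; sparse matrices
are accepted and densified on entry.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = [
    "as_dense",
    "Chol",
    "sample_gaussian_precision",
]


def as_dense(mat) -> np.ndarray:
    if sp.issparse(mat):
        return mat.toarray()
    return np.asarray(mat, dtype=float)


class Chol:
    """Cholesky factorisation of a symmetric positive-definite matrix.

    Wraps ``scipy.linalg.cho_factor`` with the handful of derived
    quantities the Laplace machinery needs: solves, log-determinant,
    marginal variances and draws from N(mu, Q^{-1}).
    """

    def __init__(self, Q) -> None:
        A = as_dense(Q)
        self.n = A.shape[0]
        # lower factor L with Q = L L^T
        self._L = sla.cholesky(A, lower=True, check_finite=False)

    def solve(self, b: np.ndarray) -> np.ndarray:
        return sla.cho_solve((self._L, True), b, check_finite=False)

    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._L))))

    def inv(self) -> np.ndarray:
        return self.solve(np.eye(self.n))

    def marginal_variances(self) -> np.ndarray:
        # diag(Q^{-1}) via the inverse of the triangular factor
        Linv = sla.solve_triangular(
            self._L, np.eye(self.n), lower=True, check_finite=False
        )
        return np.sum(Linv**2, axis=0)

    def sample(self, rng: np.random.Generator, n: int = 1,
               mean: np.ndarray | None = None) -> np.ndarray:
        """Draws from N(mean, Q^{-1}); shape (n, dim)."""
        w = rng.standard_normal((self.n, n))
        # x = L^{-T} w  has covariance Q^{-1}
        x = sla.solve_triangular(self._L, w, lower=True, trans="T",
                                 check_finite=False)
        out = x.T
        if mean is not None:
            out = out + mean
        return out


def sample_gaussian_precision(Q, rng: np.random.Generator, n: int = 1,
                              mean: np.ndarray | None = None) -> np.ndarray:
    """Convenience wrapper: n draws from N(mean, Q^{-1})."""
    return Chol(Q).sample(rng, n=n, mean=mean)
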