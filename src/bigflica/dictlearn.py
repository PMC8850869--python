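"""Voxel-space reduction by l1-regularized sparse coding (DicL).

The transposed convention used here codes data *columns* (voxels) sparsely
over a norm-constrained subject-space basis: ``V ~= A @ D`` with
``V`` (rows x voxels), ``A`` (rows x n_atoms) the dense feature-loadings
basis whose columns satisfy ``||A_j||_2 <= 1``, and ``D`` (n_atoms x voxels)
the sparse spatial dictionary.  The loss minimized is

    l(A, D) = sum_i ||V_i - A D_i||^2 + lambda * ||D_i||_1
    s.t.     A_j' A_j <= 1  for every column j of A,

where i runs over voxels.  The downstream linked ICA consumes A, not D.

Optimization is batch block-coordinate descent: a coordinate-descent lasso
over D (vectorized across voxels, which all share the design matrix A)
alternated with per-atom least-squares updates of A projected onto the unit
ball.  Both half-steps decrease the loss, so the per-epoch objective trace
is monotone non-increasing.  Atoms that end an epoch unused are re-seeded
from the worst-reconstructed voxel with a still-zero code row, which leaves
the objective unchanged.  Overcomplete dictionaries (n_atoms exceeding both
matrix dimensions) are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["DictionaryModel", "dicl_fit", "dicl_objective", "reduce_modality"]

try:  # JIT the hot coordinate-descent kernel when numba is available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@dataclass
class DictionaryModel:
    """Fitted sparse dictionary factorization ``V ~= A @ D``."""

    A: np.ndarray
    D: sparse.csc_matrix
    lambda_: float
    L_double_star: int
    objective_trace: list = field(default_factory=list)
    seed: int = 0

    @property
    def fitted(self) -> bool:
        return self.A is not None and self.D is not None


def dicl_objective(model_or_A, V: np.ndarray, D=None, lambda_: float | None = None) -> float:
    """Evaluate the displayed loss exactly: ``||V - A D||_F^2 + lambda ||D||_1``."""
    if isinstance(model_or_A, DictionaryModel):
        A = model_or_A.A
        D = model_or_A.D
        lambda_ = model_or_A.lambda_
    else:
        A = model_or_A
    Dd = D.toarray() if sparse.issparse(D) else np.asarray(D)
    V = np.asarray(V)
    if A.shape[1] != Dd.shape[0] or A.shape[0] != V.shape[0] or Dd.shape[1] != V.shape[1]:
        raise ValueError(
            f"dimension mismatch: V {V.shape}, A {A.shape}, D {Dd.shape}"
        )
    resid = V - A @ Dd
    return float(np.sum(resid**2) + lambda_ * np.sum(np.abs(Dd)))


@_njit
def _lasso_cd_kernel(R, G, D, diag, lam_half, n_sweeps):  # pragma: no cover - numba
    L, P = R.shape
    idx = np.empty(P, dtype=np.int64)
    delta = np.empty(P)
    for _ in range(n_sweeps):
        for j in range(L):
            if diag[j] <= 1e-12:
                continue
            nnz = 0
            for p in range(P):
                rho = R[j, p] + diag[j] * D[j, p]
                if rho > lam_half:
                    d_new = (rho - lam_half) / diag[j]
                elif rho < -lam_half:
                    d_new = (rho + lam_half) / diag[j]
                else:
                    d_new = 0.0
                dd = d_new - D[j, p]
                if dd != 0.0:
                    D[j, p] = d_new
                    idx[nnz] = p
                    delta[nnz] = dd
                    nnz += 1
            if nnz == 0:
                continue
            for l in range(L):
                g = G[l, j]
                if g == 0.0:
                    continue
                for q in range(nnz):
                    R[l, idx[q]] -= g * delta[q]
    return D


def _lasso_cd(R, G, D, lam_half, n_sweeps):
    """Coordinate descent on the shared-design lasso, vectorized across voxels.

    R holds the correlation residuals ``A^T V - G D`` (n_atoms x n_vox) and
    is updated in place along with D.  Each coordinate update solves its
    scalar subproblem exactly (soft threshold), so the loss never increases.
    """
    diag = np.ascontiguousarray(np.diag(G))
    if _HAVE_NUMBA:
        return _lasso_cd_kernel(
            np.ascontiguousarray(R), np.ascontiguousarray(G), D, diag,
            float(lam_half), int(n_sweeps),
        )
    L = G.shape[0]
    for _ in range(n_sweeps):
        for j in range(L):
            if diag[j] <= 1e-12:
                continue
            rho = R[j] + diag[j] * D[j]
            d_new = np.sign(rho) * np.maximum(np.abs(rho) - lam_half, 0.0) / diag[j]
            delta = d_new - D[j]
            nz = np.abs(delta) > 0
            if nz.any():
                R[:, nz] -= np.outer(G[:, j], delta[nz])
                D[j] = d_new
    return D


def dicl_fit(
    V: np.ndarray,
    L_double_star: int,
    lambda_: float = 1.0,
    epochs: int = 50,
    seed: int = 0,
    n_cd_sweeps: int = 5,
) -> DictionaryModel:
    """Fit the sparse dictionary factorization by batch block-coordinate descent.

    Parameters
    ----------
    V : ndarray, shape (rows, n_vox)
        Input matrix (rows = subjects, or reduced dimension L_star).
    L_double_star : int
        Number of dictionary atoms (may exceed both dimensions of V).
    lambda_ : float
        Sparsity weight; must be positive.
    epochs : int
        Outer alternations; the objective is recorded once per epoch.
    seed : int
        Seeds the initialization (A starts from randomly chosen, norm-clipped
        data columns) and dead-atom re-seeding.
    n_cd_sweeps : int
        Full coordinate sweeps of the lasso step per epoch.
    """
    V = np.asarray(V, dtype=np.float64)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite entries in input")
    if lambda_ <= 0:
        raise ValueError(f"lambda must be > 0, got {lambda_}")
    if L_double_star < 1:
        raise ValueError("L_double_star must be >= 1")
    rows, n_vox = V.shape
    rng = np.random.default_rng(seed)

    # Init: atoms from randomly chosen data columns, clipped to the unit ball.
    cols = rng.choice(n_vox, size=L_double_star, replace=L_double_star > n_vox)
    A = V[:, cols].copy()
    A += 1e-6 * rng.standard_normal(A.shape)  # break ties for repeated columns
    norms = np.linalg.norm(A, axis=0)
    norms[norms < 1e-12] = 1.0
    A /= np.maximum(norms, 1.0)
    A = A / np.maximum(np.linalg.norm(A, axis=0), 1e-12)  # unit columns

    D = np.zeros((L_double_star, n_vox))
    lam_half = lambda_ / 2.0
    trace: list[float] = []

    for _ in range(epochs):
        # Sparse-coding half-step: lasso in D with shared design A.
        G = A.T @ A
        R = A.T @ V - G @ D
        D = _lasso_cd(R, G, D, lam_half, n_cd_sweeps)

        # Basis half-step (per-atom least squares, projected onto the ball).
        B = V @ D.T                      # rows x L**
        C = D @ D.T                      # L** x L**
        cdiag = np.diag(C)
        for j in range(L_double_star):
            if cdiag[j] <= 1e-12:
                continue
            u = A[:, j] + (B[:, j] - A @ C[:, j]) / cdiag[j]
            nrm = np.linalg.norm(u)
            if nrm > 1.0:
                u /= nrm
            A[:, j] = u

        trace.append(dicl_objective(A, V, D, lambda_))

        # Re-seed dead atoms from the worst-reconstructed voxel; the code row
        # stays zero so the objective is untouched.
        dead = np.flatnonzero(cdiag <= 1e-12)
        if dead.size:
            resid_norm = np.sum((V - A @ D) ** 2, axis=0)
            worst = np.argsort(resid_norm)[::-1]
            for r, j in enumerate(dead):
                v = V[:, worst[r % n_vox]]
                nrm = np.linalg.norm(v)
                if nrm > 1e-12:
                    A[:, j] = v / nrm

    return DictionaryModel(
        A=A,
        D=sparse.csc_matrix(D),
        lambda_=lambda_,
        L_double_star=L_double_star,
        objective_trace=trace,
        seed=seed,
    )


def reduce_modality(model: DictionaryModel) -> np.ndarray:
    """Return the feature-loadings matrix A fed to the linked ICA."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    return model.A
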