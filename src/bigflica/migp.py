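"""Streaming approximate truncated SVD over the feature dimension (MIGP)
and its multimodal extension (mMIGP).

MIGP reduces a subjects x features matrix ``Y`` (N x P) to its top left
singular vectors without holding more than one column chunk plus an m-column
sketch in memory.  Chunks of columns are folded into a running sketch
``B = U_m S_m`` whose Gram matrix equals that of the columns seen so far
(exactly so whenever the internal rank m is at least the data rank), so the
final left singular structure matches an exact SVD in that regime.

The multimodal extension runs MIGP per modality, concatenates the resulting
subject bases column-wise, runs a second MIGP on the concatenation to obtain
a shared subject basis U, and projects each modality onto it:
``V(k) = U^T Y(k)``.  A reduced-space subject mode H* is mapped back to
subject space by ``H = U H*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data import ModalityData

__all__ = ["MMIGPResult", "migp", "mmigp", "explained_variance", "backproject_subject_mode"]


@dataclass
class MMIGPResult:
    """Shared reduced subject basis and per-modality projections.

    Attributes
    ----------
    U : ndarray, shape (N, L_star)
        Orthonormal-column shared subject basis.
    singular_values : ndarray, shape (L_star,)
        Non-increasing singular values of the second-stage reduction.
    V_per_modality : list of ndarray, each (L_star, Pk)
        ``U^T @ Y(k)`` for each z-scored modality.
    per_modality_bases : list of (U_tilde, S_tilde) or None
        First-stage per-modality bases, kept for diagnostics.
    L_star : int
    """

    U: np.ndarray
    singular_values: np.ndarray
    V_per_modality: list
    L_star: int
    per_modality_bases: list | None = None


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def migp(
    Y: np.ndarray,
    L_star: int,
    m: int | None = None,
    chunk: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Streaming approximation of the top-``L_star`` left singular pairs of Y.

    Parameters
    ----------
    Y : ndarray, shape (N, P)
        Data matrix, streamed in column chunks (deterministic column order).
    L_star : int
        Number of singular pairs to return; ``1 <= L_star <= min(N, m)``.
    m : int, optional
        Internal sketch rank; default ``min(N, 2 * L_star)`` ("keep more
        than you need").  When ``m >= rank(Y)`` the stream is lossless.
    chunk : int, optional
        Columns per chunk; default ``10 * m``.  ``chunk >= P`` reduces to a
        single exact truncated SVD.

    Returns
    -------
    U_tilde : ndarray, shape (N, L_star)
        Approximate top left singular vectors (columns sign-fixed so the
        largest-magnitude entry is positive).
    S_tilde : ndarray, shape (L_star,)
        Approximate singular values, non-increasing.
    """
    Y = np.asarray(Y, dtype=np.float64)
    N, P = Y.shape
    if not 1 <= L_star <= N:
        raise ValueError(f"L_star={L_star} must be in [1, N={N}]")
    if m is None:
        m = min(N, 2 * L_star)
    if m < L_star:
        raise ValueError(f"internal rank m={m} < L_star={L_star}")
    m = min(m, N)
    if chunk is None:
        chunk = 10 * m
    if chunk < 1:
        raise ValueError("chunk must be >= 1")

    sketch = None  # N x (<= m), columns scaled by singular values
    for start in range(0, P, chunk):
        block = Y[:, start : start + chunk]
        stacked = block if sketch is None else np.hstack([sketch, block])
        U, s, _ = linalg.svd(stacked, full_matrices=False)
        keep = min(m, s.size)
        sketch = U[:, :keep] * s[:keep]

    U, s, _ = linalg.svd(sketch, full_matrices=False)
    return _fix_signs(U[:, :L_star]), s[:L_star]


def mmigp(
    dataset: list[ModalityData],
    L_star: int,
    m: int | None = None,
    chunk: int | None = None,
    keep_bases: bool = False,
) -> MMIGPResult:
    """Multimodal MIGP: per-modality reduction, concatenation, second reduction.

    All modalities must be z-scored and share the subject count.  The
    concatenation uses the unweighted unit-norm singular vectors U_tilde(k);
    relative modality signal levels are left to the downstream linked-ICA
    noise model.
    """
    if not dataset:
        raise ValueError("empty dataset")
    N = dataset[0].n_subjects
    for mod in dataset:
        if mod.n_subjects != N:
            raise ValueError(
                f"inconsistent subject count: {mod.name!r} has {mod.n_subjects}, expected {N}"
            )
        if not mod.zscored:
            raise ValueError(f"modality {mod.name!r} must be z-scored before mMIGP")
    if L_star > N:
        raise ValueError(f"L_star={L_star} > n_subjects={N}")

    bases = []
    for mod in dataset:
        Lk = min(L_star, mod.n_features)
        bases.append(migp(mod.matrix, Lk, m=m, chunk=chunk))

    concat = np.hstack([U for U, _ in bases])
    U, s = migp(concat, min(L_star, concat.shape[1]), m=m, chunk=chunk)
    V = [U.T @ mod.matrix for mod in dataset]
    return MMIGPResult(
        U=U,
        singular_values=s,
        V_per_modality=V,
        L_star=U.shape[1],
        per_modality_bases=bases if keep_bases else None,
    )


def explained_variance(result: MMIGPResult, dataset: list[ModalityData]) -> float:
    """Fraction of the dataset's total sum of squares captured by the basis U.

    Computed as ``sum_k ||U^T Y(k)||_F^2 / sum_k ||Y(k)||_F^2``; equals 1 at
    ``L_star = N`` (or data rank) and is monotone non-decreasing in L_star.
    """
    captured = sum(float(np.sum((result.U.T @ mod.matrix) ** 2)) for mod in dataset)
    total = sum(float(np.sum(mod.matrix**2)) for mod in dataset)
    if total == 0:
        raise ValueError("dataset has zero total sum of squares")
    return captured / total


def backproject_subject_mode(U: np.ndarray, H_star: np.ndarray) -> np.ndarray:
    """Map a reduced-space subject mode back to subject space: ``H = U @ H*``."""
    U = np.asarray(U)
    H_star = np.asarray(H_star)
    if U.shape[1] != H_star.shape[0]:
        raise ValueError(
            f"inner dimensions disagree: U is {U.shape}, H* is {H_star.shape}"
        )
    return U @ H_star
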