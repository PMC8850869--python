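"""Variational-Bayes linked ICA core.

Fits the joint generative model

    Y(k) = H W(k) X(k) + E(k),    k = 1..K

where H (rows x L) is the subject mode shared by all modalities, W(k) is a
positive diagonal matrix of per-component modality weights, X(k) are the
modality-specific spatial sources, and E(k) is Gaussian noise with a
modality-specific precision.  The rows of the inputs may be subjects (N) or
a reduced subject basis (L*) produced upstream; in the reduced case the
fitted subject mode is H* and must be back-projected with the reduction
basis to reach subject space.

Variational family
------------------
Internally the model is parametrized as ``Y(k) = H S(k) + E(k)`` with
``S(k) = W(k) X(k)``; W and X are recovered at the end by fixing the scale
convention (H* columns unit RMS, unit-RMS spatial maps, all scale carried by
W >= 0).  The mean-field posterior factorizes over

* rows of H — Gaussian, shared covariance, standard-normal prior;
* elements of S(k) — each a 3-class zero-mean Gaussian mixture (a narrow
  "off" class, a middle class and a broad class), giving the heavy-tailed
  non-Gaussian source prior that drives the ICA unmixing.  Class precisions
  are ``alpha_kl * gamma_c`` with fixed relative precisions ``gamma`` and a
  Gamma-distributed automatic-relevance-determination (ARD) scale
  ``alpha_kl`` per modality and component, so surplus components shrink to
  empty;
* mixture weights — Dirichlet per modality and component;
* noise precisions — Gamma per modality.

Every update is the exact optimum of its factor given the others, so the
variational free energy (evidence lower bound) is non-decreasing over
iterations; a decrease beyond numerical tolerance raises
:class:`FreeEnergyError`.  Fits are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "FlicaModel",
    "SpatialMaps",
    "FreeEnergyError",
    "flica_fit",
    "reconstruct_spatial_maps",
    "modality_weight_matrix",
    "modality_similarity",
]

# Fixed relative precisions of the 3 source-prior classes (off / mid / broad).
_GAMMA_CLASSES = np.array([100.0, 1.0, 0.01])
_A0 = _B0 = 1e-3   # Gamma hyperprior on ARD precisions
_C0 = _D0 = 1e-3   # Gamma hyperprior on noise precisions
_DELTA0 = 1.0      # Dirichlet hyperprior on mixture weights


class FreeEnergyError(RuntimeError):
    """Raised when the free energy decreases beyond numerical tolerance."""

    def __init__(self, iteration: int, drop: float):
        super().__init__(
            f"free energy decreased by {drop:.3e} at iteration {iteration}"
        )
        self.iteration = iteration


@dataclass
class FlicaModel:
    """Fitted linked-ICA decomposition.

    ``H_star`` has unit-RMS columns; per-modality scale sits in ``W`` and
    the spatial sources ``X`` have unit RMS rows (zero rows for components
    that are empty in a modality).
    """

    H_star: np.ndarray
    W: list
    X: list
    noise_precision: list
    free_energy_trace: np.ndarray
    L: int
    priors: dict
    seed: int
    n_iter_run: int = 0
    converged: bool = False
    empty_components: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class SpatialMaps:
    """Per-modality z-scored component maps re-expanded onto the input masks."""

    maps: list                      # list of (L, P_full) arrays
    modality_names: list
    grids: list                     # list of (mask_indices, grid_shape, affine) or None

    def to_volume(self, k: int) -> np.ndarray:
        """Return modality k's maps as a 4D array (grid + component axis)."""
        mask, grid_shape, _ = self.grids[k]
        if mask is None or grid_shape is None:
            raise ValueError("modality has no voxel grid")
        L = self.maps[k].shape[0]
        vol = np.zeros((int(np.prod(grid_shape)), L))
        vol[mask] = self.maps[k].T
        return vol.reshape(*grid_shape, L, order="F")


def _as_matrices(inputs):
    from .data import ModalityData

    mats, names = [], []
    for i, item in enumerate(inputs):
        if isinstance(item, ModalityData):
            mats.append(item.matrix)
            names.append(item.name)
        else:
            mats.append(np.asarray(item, dtype=np.float64))
            names.append(f"modality{i}")
    return mats, names


def _gamma_elbo(a, b, a0, b0):
    """E_q[log p(x)] - E_q[log q(x)] for Gamma(shape, rate) prior/posterior."""
    e_x = a / b
    e_log = digamma(a) - np.log(b)
    lp = a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * e_log - b0 * e_x
    lq = a * np.log(b) - gammaln(a) + (a - 1.0) * e_log - b * e_x
    return float(np.sum(lp - lq))


def _dirichlet_elbo(delta, delta0):
    """E_q[log p(pi)] - E_q[log q(pi)] for Dirichlet prior/posterior (per row)."""
    e_log = digamma(delta) - digamma(delta.sum(axis=-1, keepdims=True))
    lp = (
        gammaln(np.sum(np.full_like(delta, delta0), axis=-1))
        - np.sum(gammaln(np.full_like(delta, delta0)), axis=-1)
        + np.sum((delta0 - 1.0) * e_log, axis=-1)
    )
    lq = (
        gammaln(delta.sum(axis=-1))
        - np.sum(gammaln(delta), axis=-1)
        + np.sum((delta - 1.0) * e_log, axis=-1)
    )
    return float(np.sum(lp - lq))


def flica_fit(
    inputs,
    L: int,
    n_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
) -> FlicaModel:
    """Fit the linked-ICA model to K matrices sharing their row dimension.

    Parameters
    ----------
    inputs : list of ndarray or ModalityData
        K matrices (rows x Pk): raw z-scored data Y(k), projected data V(k)
        or dictionary loadings A(k).
    L : int
        Number of components; must satisfy ``L < min(rows, min_k Pk)``.
    n_iter, tol : int, float
        Stop after ``n_iter`` sweeps or when the relative free-energy change
        drops below ``tol``.
    seed : int
        Seeds the initialization perturbation only; fits are deterministic.
    """
    mats, _ = _as_matrices(inputs)
    K = len(mats)
    if K == 0:
        raise ValueError("no input matrices")
    n = mats[0].shape[0]
    for Y in mats:
        if Y.shape[0] != n:
            raise ValueError("all inputs must share the row count")
        if not np.all(np.isfinite(Y)):
            raise ValueError("non-finite entries in input")
    P = [Y.shape[1] for Y in mats]
    if L >= min(n, min(P)):
        raise ValueError(
            f"L={L} too large for inputs with rows={n}, min features={min(P)}"
        )

    rng = np.random.default_rng(seed)
    gam = _GAMMA_CLASSES
    log_gam = np.log(gam)

    # ---- initialization ------------------------------------------------
    # Subject mode from the top-L left singular vectors of the concatenated
    # inputs (via the Gram matrix), unit-RMS columns, 1% seeded perturbation.
    gram = np.zeros((n, n))
    for Y in mats:
        gram += Y @ Y.T
    evals, evecs = linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:L]
    M = evecs[:, order] * np.sqrt(n)
    M = M + 0.01 * rng.standard_normal(M.shape)
    SigH = np.zeros((L, L))

    S = [np.zeros((L, p)) for p in P]
    S2 = [np.zeros((L, p)) for p in P]
    Rc = [np.full((3, L, p), 1.0 / 3.0) for p in P]
    M2c = [np.zeros((3, L, p)) for p in P]
    Rho = [np.ones((3, L)) for _ in range(K)]
    e_tau = np.ones(K)
    e_log_tau = np.zeros(K)
    a_tau = np.full(K, _C0)
    b_tau = np.full(K, _D0)
    e_alpha = [np.ones(L) for _ in range(K)]
    e_log_alpha = [np.zeros(L) for _ in range(K)]
    a_alpha = [np.full(L, _A0) for _ in range(K)]
    b_alpha = [np.full(L, _B0) for _ in range(K)]
    delta = [np.full((L, 3), _DELTA0) for _ in range(K)]
    e_log_pi = [np.full((L, 3), np.log(1.0 / 3.0)) for _ in range(K)]

    ysq = [float(np.sum(Y**2)) for Y in mats]
    trace = []
    converged = False
    it = 0

    for it in range(1, n_iter + 1):
        Q = M.T @ M + n * SigH

        # ---- sources S(k): exact mixture update, coordinate sweep over rows
        for k in range(K):
            G = M.T @ mats[k]                      # L x Pk
            Sk, S2k, Rck, M2ck = S[k], S2[k], Rc[k], M2c[k]
            for l in range(L):
                b_l = e_tau[k] * (G[l] - Q[l] @ Sk + Q[l, l] * Sk[l])
                rho = e_tau[k] * Q[l, l] + e_alpha[k][l] * gam        # (3,)
                mu = b_l[None, :] / rho[:, None]                      # (3, Pk)
                # Class log-weights relative to class 0.  The naive form
                # b^2/(2 rho_c) can reach ~1e9, whose float error alone would
                # scramble the responsibilities; the difference across classes
                # is computed analytically instead (rho_c differ only by
                # alpha * (gamma_c - gamma_0)), which is exact.
                quad = (
                    0.5 * (b_l[None, :] ** 2)
                    * (e_alpha[k][l] * (gam[0] - gam))[:, None]
                    / (rho[:, None] * rho[0])
                )
                log_r = (
                    e_log_pi[k][l][:, None]
                    + 0.5 * log_gam[:, None]
                    - 0.5 * np.log(rho)[:, None]
                    + quad
                )
                log_r -= logsumexp(log_r, axis=0, keepdims=True)
                r = np.exp(log_r)
                Rck[:, l, :] = r
                M2ck[:, l, :] = mu**2 + (1.0 / rho)[:, None]
                Sk[l] = np.sum(r * mu, axis=0)
                S2k[l] = np.sum(r * M2ck[:, l, :], axis=0)
                Rho[k][:, l] = rho

        # ---- subject mode H --------------------------------------------
        M2S = []
        for k in range(K):
            m2s = S[k] @ S[k].T
            np.fill_diagonal(m2s, S2[k].sum(axis=1))
            M2S.append(m2s)
        prec = np.eye(L)
        for k in range(K):
            prec += e_tau[k] * M2S[k]
        SigH = linalg.inv(prec)
        SigH = 0.5 * (SigH + SigH.T)
        T = [mats[k] @ S[k].T for k in range(K)]   # n x L each
        rhs = np.zeros((n, L))
        for k in range(K):
            rhs += e_tau[k] * T[k]
        M = rhs @ SigH
        Q = M.T @ M + n * SigH

        # ---- ARD precisions and mixture weights ------------------------
        for k in range(K):
            ss = np.einsum("clj,c,clj->l", Rc[k], gam, M2c[k])
            a_alpha[k] = np.full(L, _A0 + 0.5 * P[k])
            b_alpha[k] = _B0 + 0.5 * ss
            e_alpha[k] = a_alpha[k] / b_alpha[k]
            e_log_alpha[k] = digamma(a_alpha[k]) - np.log(b_alpha[k])
            delta[k] = _DELTA0 + Rc[k].sum(axis=2).T          # (L, 3)
            e_log_pi[k] = digamma(delta[k]) - digamma(
                delta[k].sum(axis=1, keepdims=True)
            )

        # ---- noise precisions ------------------------------------------
        esq = np.empty(K)
        for k in range(K):
            esq[k] = ysq[k] - 2.0 * float(np.sum(M * T[k])) + float(np.sum(Q * M2S[k]))
            # Relative floor: keeps the noise precision finite and the free
            # energy numerically stable on (near-)noiseless degenerate inputs.
            esq[k] = max(esq[k], 1e-10 * max(ysq[k], 1e-300))
            a_tau[k] = _C0 + 0.5 * n * P[k]
            b_tau[k] = _D0 + 0.5 * esq[k]
            e_tau[k] = a_tau[k] / b_tau[k]
            e_log_tau[k] = digamma(a_tau[k]) - np.log(b_tau[k])

        # ---- free energy -----------------------------------------------
        F = 0.0
        for k in range(K):
            F += 0.5 * n * P[k] * (e_log_tau[k] - np.log(2 * np.pi)) - 0.5 * e_tau[k] * esq[k]
            # E[log p(S, C)] under the mixture prior
            prior_term = (
                e_log_pi[k].T[:, :, None]
                + 0.5 * (e_log_alpha[k][None, :, None] + log_gam[:, None, None])
                - 0.5 * np.log(2 * np.pi)
                - 0.5 * e_alpha[k][None, :, None] * gam[:, None, None] * M2c[k]
            )
            F += float(np.sum(Rc[k] * prior_term))
            # - E[log q(S, C)]  (mixture entropy)
            with np.errstate(divide="ignore", invalid="ignore"):
                log_rck = np.where(Rc[k] > 0, np.log(np.maximum(Rc[k], 1e-300)), 0.0)
            F -= float(np.sum(Rc[k] * log_rck))
            F += float(
                np.sum(Rc[k] * (0.5 * np.log(2 * np.pi * np.e / Rho[k]))[:, :, None])
            )
            F += _gamma_elbo(a_alpha[k], b_alpha[k], _A0, _B0)
            F += _dirichlet_elbo(delta[k], _DELTA0)
            F += _gamma_elbo(a_tau[k], b_tau[k], _C0, _D0)
        sign, logdet = np.linalg.slogdet(SigH)
        F += -0.5 * (float(np.sum(M**2)) + n * float(np.trace(SigH)))
        F += 0.5 * n * (L + logdet)  # entropy of q(H) minus prior log(2pi) terms cancel
        trace.append(F)

        if len(trace) > 1:
            prev = trace[-2]
            drop = prev - F
            if drop > tol * max(1.0, abs(prev)):
                raise FreeEnergyError(it, drop)
            if abs(F - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break

    # ---- finalize: scale convention and sign fixing --------------------
    h_rms = np.sqrt(np.mean(M**2, axis=0) + np.diag(SigH))
    h_rms = np.maximum(h_rms, 1e-300)
    H_star = M / h_rms
    W, X = [], []
    for k in range(K):
        s_rms = np.sqrt(np.mean(S2[k], axis=1))
        Xk = np.where(s_rms[:, None] > 1e-12, S[k] / np.maximum(s_rms, 1e-300)[:, None], 0.0)
        W.append(h_rms * s_rms)
        X.append(Xk)
    # Orient each component so its pooled spatial skewness is positive.
    for l in range(L):
        skew = sum(float(np.sum(X[k][l] ** 3)) for k in range(K))
        if skew < 0:
            H_star[:, l] *= -1.0
            for k in range(K):
                X[k][l] *= -1.0
    wmax = np.max(np.stack([w for w in W]), axis=0)
    empty = np.flatnonzero(wmax < 1e-8 * max(float(wmax.max()), 1e-300))

    return FlicaModel(
        H_star=H_star,
        W=W,
        X=X,
        noise_precision=[float(t) for t in e_tau],
        free_energy_trace=np.asarray(trace),
        L=L,
        priors={
            "gamma_classes": gam.tolist(),
            "ard": (_A0, _B0),
            "noise": (_C0, _D0),
            "dirichlet": _DELTA0,
        },
        seed=seed,
        n_iter_run=it,
        converged=converged,
        empty_components=empty,
    )


def reconstruct_spatial_maps(model: FlicaModel, U, dataset) -> SpatialMaps:
    """Voxel-wise regression of the data on the subject mode, z-scored per map.

    For every voxel the OLS coefficients of that voxel's subject series on H
    are computed; each component-modality coefficient map is then converted
    to z-scores (across voxels) and re-expanded onto the original grid with
    zeros at any dropped zero-variance voxels.

    ``U`` is the reduction basis when the model was fitted in reduced space
    (H = U @ H*), or None when H* is already in subject space.
    """
    from .data import ModalityData
    from .migp import backproject_subject_mode

    H = backproject_subject_mode(U, model.H_star) if U is not None else model.H_star
    L = model.L
    if np.linalg.matrix_rank(H) < L:
        raise ValueError("subject mode is rank deficient; cannot regress")
    HtH = H.T @ H
    maps, names, grids = [], [], []
    for mod in dataset:
        if isinstance(mod, ModalityData):
            Y = mod.matrix
            names.append(mod.name)
            grids.append((mod.mask, mod.grid_shape, mod.affine))
            dropped = mod.dropped
        else:
            Y = np.asarray(mod)
            names.append(f"modality{len(names)}")
            grids.append((None, None, None))
            dropped = np.empty(0, dtype=int)
        if Y.shape[0] != H.shape[0]:
            raise ValueError("dataset subject count does not match the subject mode")
        B = linalg.solve(HtH, H.T @ Y, assume_a="pos")    # L x P
        mu = B.mean(axis=1, keepdims=True)
        sd = B.std(axis=1, ddof=1, keepdims=True)
        sd[sd < 1e-300] = 1.0
        Z = (B - mu) / sd
        if dropped.size:
            full = np.zeros((L, Y.shape[1] + dropped.size))
            keep = np.setdiff1d(np.arange(full.shape[1]), dropped)
            full[:, keep] = Z
            Z = full
        maps.append(Z)
    return SpatialMaps(maps=maps, modality_names=names, grids=grids)


def modality_weight_matrix(model: FlicaModel) -> np.ndarray:
    """Stack diag(W(k)) into a mode x modality matrix, columns sum to one."""
    Wmat = np.stack(model.W, axis=1)                      # L x K
    colsum = Wmat.sum(axis=0)
    colsum[colsum <= 0] = 1.0
    return Wmat / colsum


def modality_similarity(Wmat: np.ndarray) -> np.ndarray:
    """Cosine similarity between modality columns of the weight matrix."""
    Wmat = np.asarray(Wmat, dtype=np.float64)
    if Wmat.shape[1] < 2:
        raise ValueError("need at least two modalities")
    norms = np.linalg.norm(Wmat, axis=0)
    if np.any(norms < 1e-300):
        raise ValueError("zero modality column: similarity undefined")
    Wn = Wmat / norms
    C = Wn.T @ Wn
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)
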