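"""Multimodal ground-truth simulator for recovery experiments.

Each dataset has N subjects and K_m modalities on a common 3D grid.  Shared
components have one spatial map used by every modality; each modality also
carries a fixed number of unique components whose weight is zero in every
other modality.  A spatial map is a weighted sum of two white-noise images —
the full grid with weight 0.05 and a randomly placed 5x5x5 cube with weight
0.95 — lightly Gaussian-smoothed, so sources are spatially compact and
non-Gaussian.  Data per modality:

    Y = H W X + sigma * E

with Gaussian subject loadings H, positive component weights W drawn
Uniform(0.5, 1.5), and smoothed Gaussian noise E.  ``sigma`` is solved so
that the realized variance ratio var(vec(HWX)) / var(vec(sigma E)) equals
the configured signal-to-noise ratio.  Voxels are z-score normalized before
the data are returned, mirroring how real modalities enter the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import ModalityData, zscore_features

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_spatial_map", "simulate_dataset", "empirical_snr"]

_CUBE = 5  # edge length of the high-weight cube


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the reference design: 500 subjects, two modalities of
    30x30x30 images (27,000 voxels), 25 shared components plus 5 unique
    components per modality, and a light smoothing of 1 voxel.
    """

    n_subjects: int = 500
    grid: tuple[int, int, int] = (30, 30, 30)
    n_shared: int = 25
    n_unique_per_modality: int = 5
    n_modalities: int = 2
    snr: float = 1.0
    smooth_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < _CUBE for g in self.grid):
            raise ValueError(f"grid {self.grid} cannot contain a {_CUBE}^3 cube")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class SimulationTruth:
    """Ground truth for recovery scoring."""

    H: np.ndarray                 # N x n_components (shared first, then unique blocks)
    W: list                       # per modality, length n_components (zeros off-modality)
    X: list                       # per modality, n_components x n_vox
    sigma: list                   # per modality noise scale
    noise: list                   # per modality sigma * E (stored for SNR checks)
    realized_snr: list = field(default_factory=list)
    n_shared: int = 0


def simulate_spatial_map(
    grid: tuple[int, int, int],
    seed_or_rng,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """One ground-truth source map on ``grid``.

    0.05 x full-grid white noise + 0.95 x white noise confined to a 5x5x5
    cube at a uniformly random position, then Gaussian-smoothed.
    """
    if any(g < _CUBE for g in grid):
        raise ValueError(f"grid {grid} smaller than the {_CUBE}^3 cube")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    full = rng.standard_normal(grid)
    cube = np.zeros(grid)
    corner = [rng.integers(0, g - _CUBE + 1) for g in grid]
    sl = tuple(slice(c, c + _CUBE) for c in corner)
    cube[sl] = rng.standard_normal((_CUBE,) * 3)
    m = 0.05 * full + 0.95 * cube
    if smooth_sigma > 0:
        m = gaussian_filter(m, smooth_sigma)
    return m


def simulate_dataset(config: SimulationConfig):
    """Generate one multimodal dataset with known ground truth.

    Returns ``(dataset, truth)`` where ``dataset`` is a list of z-scored
    :class:`~bigflica.data.ModalityData` and ``truth`` holds H, W, X, the
    noise scale and the realized SNR per modality.
    """
    rng = np.random.default_rng(config.seed)
    n_vox = int(np.prod(config.grid))
    Km = config.n_modalities
    n_comp = config.n_shared + Km * config.n_unique_per_modality

    shared_maps = np.stack(
        [
            simulate_spatial_map(config.grid, rng, config.smooth_sigma).ravel(order="F")
            for _ in range(config.n_shared)
        ]
    ) if config.n_shared else np.zeros((0, n_vox))

    H = rng.standard_normal((config.n_subjects, n_comp))

    X_per_mod, W_per_mod = [], []
    for k in range(Km):
        X = np.zeros((n_comp, n_vox))
        W = np.zeros(n_comp)
        X[: config.n_shared] = shared_maps
        W[: config.n_shared] = rng.uniform(0.5, 1.5, size=config.n_shared)
        lo = config.n_shared + k * config.n_unique_per_modality
        hi = lo + config.n_unique_per_modality
        for row in range(lo, hi):
            X[row] = simulate_spatial_map(config.grid, rng, config.smooth_sigma).ravel(order="F")
        W[lo:hi] = rng.uniform(0.5, 1.5, size=config.n_unique_per_modality)
        X_per_mod.append(X)
        W_per_mod.append(W)

    dataset, sigmas, noises, snrs = [], [], [], []
    for k in range(Km):
        signal = H @ (W_per_mod[k][:, None] * X_per_mod[k])
        sig_var = float(np.var(signal))
        if sig_var <= 0:
            raise ValueError("zero signal variance: SNR is infeasible")
        E = rng.standard_normal((config.n_subjects, n_vox))
        if config.smooth_sigma > 0:
            E = np.stack(
                [
                    gaussian_filter(e.reshape(config.grid, order="F"), config.smooth_sigma).ravel(order="F")
                    for e in E
                ]
            )
        noise_var = float(np.var(E))
        sigma = np.sqrt(sig_var / (config.snr * noise_var))
        scaled = sigma * E
        Y = signal + scaled
        sigmas.append(sigma)
        noises.append(scaled)
        snrs.append(sig_var / float(np.var(scaled)))
        dataset.append(
            zscore_features(ModalityData(name=f"mod{k}", matrix=Y, grid_shape=config.grid,
                                         mask=np.arange(n_vox)))
        )

    truth = SimulationTruth(
        H=H,
        W=W_per_mod,
        X=X_per_mod,
        sigma=sigmas,
        noise=noises,
        realized_snr=snrs,
        n_shared=config.n_shared,
    )
    return dataset, truth


def empirical_snr(truth: SimulationTruth, modality: int = 0) -> float:
    """The realized variance ratio var(vec(HWX)) / var(vec(sigma E))."""
    signal = truth.H @ (truth.W[modality][:, None] * truth.X[modality])
    noise_var = float(np.var(truth.noise[modality]))
    if noise_var <= 0:
        raise ValueError("zero noise variance")
    return float(np.var(signal)) / noise_var
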