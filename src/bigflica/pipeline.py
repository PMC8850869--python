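"""End-to-end pipeline: (optional mMIGP) -> (optional DicL) -> linked ICA
-> spatial-map reconstruction.

When both reductions are enabled the order is always mMIGP first, then
dictionary learning on the projected data (running them the other way round
is supported by the underlying functions but is less efficient, so the
pipeline does not offer it).  Dimension feasibility (L < min(L*, L**)) is
checked before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .dictlearn import dicl_fit, reduce_modality
from .flica import FlicaModel, flica_fit, reconstruct_spatial_maps
from .migp import MMIGPResult, mmigp

__all__ = ["PipelineConfig", "PipelineResult", "run_decomposition"]


@dataclass
class PipelineConfig:
    """Structured configuration for one decomposition run."""

    L: int = 25
    # mMIGP stage
    use_migp: bool = False
    L_star: int = 100
    migp_m: int | None = None
    migp_chunk: int | None = None
    # DicL stage
    use_dicl: bool = False
    L_double_star: int = 1000
    dicl_lambda: float = 1.0
    dicl_epochs: int = 50
    dicl_seed: int = 0
    # FLICA stage
    n_iter: int = 1000
    tol: float = 1e-6
    flica_seed: int = 0

    def validate(self, n_subjects: int) -> None:
        limits = []
        if self.use_migp:
            limits.append(self.L_star)
        if self.use_dicl:
            limits.append(self.L_double_star)
        limits.append(n_subjects)
        if self.L >= min(limits):
            raise ValueError(
                f"infeasible dimensions: L={self.L} must be < min of "
                f"{'L*=' + str(self.L_star) + ', ' if self.use_migp else ''}"
                f"{'L**=' + str(self.L_double_star) + ', ' if self.use_dicl else ''}"
                f"n_subjects={n_subjects}"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    model: FlicaModel
    migp_result: MMIGPResult | None
    dicl_models: list | None
    spatial_maps: object
    config: PipelineConfig
    stage_dims: dict = field(default_factory=dict)


def run_decomposition(dataset, config: PipelineConfig) -> PipelineResult:
    """Run reductions and the linked ICA on a z-scored dataset.

    ``dataset`` is a list of z-scored :class:`~bigflica.data.ModalityData`.
    Returns the fitted model, intermediate reductions, and z-scored spatial
    maps reconstructed in the original voxel space.
    """
    n = dataset[0].n_subjects
    config.validate(n)
    dims = {"input": [(m.n_subjects, m.n_features) for m in dataset]}

    migp_res = None
    if config.use_migp:
        migp_res = mmigp(dataset, config.L_star, m=config.migp_m, chunk=config.migp_chunk)
        inputs = migp_res.V_per_modality
        dims["migp"] = [v.shape for v in inputs]
    else:
        inputs = [m.matrix for m in dataset]

    dicl_models = None
    if config.use_dicl:
        dicl_models = [
            dicl_fit(
                V,
                config.L_double_star,
                lambda_=config.dicl_lambda,
                epochs=config.dicl_epochs,
                seed=config.dicl_seed + i,
            )
            for i, V in enumerate(inputs)
        ]
        inputs = [reduce_modality(m) for m in dicl_models]
        dims["dicl"] = [a.shape for a in inputs]

    model = flica_fit(
        inputs, config.L, n_iter=config.n_iter, tol=config.tol, seed=config.flica_seed
    )
    U = migp_res.U if migp_res is not None else None
    smaps = reconstruct_spatial_maps(model, U, dataset)
    dims["H"] = (n, config.L)
    return PipelineResult(
        model=model,
        migp_result=migp_res,
        dicl_models=dicl_models,
        spatial_maps=smaps,
        config=config,
        stage_dims=dims,
    )


def subject_mode(result: PipelineResult) -> np.ndarray:
    """The subject-space mode matrix H (back-projected when mMIGP was used)."""
    if result.migp_result is not None:
        return result.migp_result.U @ result.model.H_star
    return result.model.H_star
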