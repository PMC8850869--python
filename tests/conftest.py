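import numpy as np
import pytest

import bigflica as bf


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated multimodal dataset with ground truth (fast fixture)."""
    cfg = bf.SimulationConfig(
        n_subjects=150,
        grid=(10, 10, 10),
        n_shared=8,
        n_unique_per_modality=2,
        n_modalities=2,
        snr=4.0,
        seed=7,
    )
    dataset, truth = bf.simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def tiny_fit(tiny_sim):
    """Linked-ICA fit on the tiny simulation (shared across tests)."""
    cfg, dataset, truth = tiny_sim
    n_comp = truth.H.shape[1]
    model = bf.flica_fit(
        [m.matrix for m in dataset], L=n_comp, n_iter=250, tol=1e-6, seed=0
    )
    return dataset, truth, model
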