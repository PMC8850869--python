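"""Data containers and plumbing for multimodal subject x feature matrices.

A *modality* is one image-derived feature map type per subject (a task
contrast, an FA map, a grey-matter volume map, ...).  Volumetric modalities
are read from 4D NIfTI-1 files with an optional 3D binary mask; surface or
precomputed modalities come in as plain matrices (optionally from an HDF5
container).  Phenotype and confound tables are TSV.

Conventions
-----------
* Rows are subjects, in the order of the dataset manifest (the single source
  of subject identity).
* Columns of a volumetric modality are ordered by ascending linear voxel
  index in x-fastest (Fortran) order within the mask.
* Z-scoring standardizes each feature across subjects using the sample
  standard deviation (ddof=1); zero-variance features are dropped and their
  indices recorded so spatial maps can later be re-expanded with zeros.
* Missing phenotype entries are never imputed; missing *modalities* for a
  subject are imputed by the column mean over the non-missing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ModalityData",
    "PhenotypeTable",
    "ConfoundMatrix",
    "load_modality",
    "load_matrix_h5",
    "save_matrix_h5",
    "zscore_features",
    "impute_missing_modality",
    "regress_confounds",
    "read_phenotypes",
    "read_confounds",
]


@dataclass
class ModalityData:
    """One modality's subjects x features matrix plus geometry metadata.

    Parameters
    ----------
    name : str
        Label for the modality.
    matrix : ndarray, shape (n_subjects, n_features)
        Real-valued data, one row per subject.
    mask : ndarray of int, optional
        Linear voxel indices (Fortran order) into ``grid_shape`` for each
        column; ``None`` for non-volumetric data.
    grid_shape : tuple of int, optional
        The 3D image grid the mask indexes into.
    affine : ndarray, optional
        NIfTI affine preserved for map export.
    zscored : bool
        Whether :func:`zscore_features` has been applied.
    dropped : ndarray of int
        Original column indices removed as zero-variance during z-scoring.
    """

    name: str
    matrix: np.ndarray
    mask: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None
    zscored: bool = False
    dropped: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError(f"modality {self.name!r}: matrix must be 2D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.intp)
            if self.mask.size != self.matrix.shape[1] + self.dropped.size:
                raise ValueError(
                    f"modality {self.name!r}: mask length {self.mask.size} does "
                    f"not match feature count {self.matrix.shape[1]}"
                )

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PhenotypeTable:
    """Subjects x phenotypes matrix with explicit missingness (NaN)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("phenotype values/names shape mismatch")


@dataclass
class ConfoundMatrix:
    """Subjects x confounds matrix; complete (no missing entries)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("confound values/names shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("confound matrix contains non-finite entries")


def _load_nifti(path):
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def load_modality(images, mask=None, name: str = "modality") -> ModalityData:
    """Build a :class:`ModalityData` from a 4D NIfTI (or array) and mask.

    ``images`` may be a path to a 4D NIfTI-1 file, a 4D array with the
    subject axis last, or an already-extracted 2D subjects x features array.
    ``mask`` is a path to a 3D NIfTI, a 3D boolean/integer array, or None
    (full grid retained).  Columns are ordered by ascending linear voxel
    index in Fortran (x-fastest) order within the mask.
    """
    affine = None
    if isinstance(images, (str, bytes)) or hasattr(images, "__fspath__"):
        data, affine = _load_nifti(images)
    else:
        data = np.asarray(images, dtype=np.float64)

    if data.ndim == 2:
        if mask is not None:
            raise ValueError("mask given but image data is already a 2D matrix")
        return ModalityData(name=name, matrix=data)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image or 2D matrix, got ndim={data.ndim}")

    grid_shape = data.shape[:3]
    if mask is None:
        mask_arr = np.ones(grid_shape, dtype=bool)
    else:
        if isinstance(mask, (str, bytes)) or hasattr(mask, "__fspath__"):
            mask_arr, _ = _load_nifti(mask)
        else:
            mask_arr = np.asarray(mask)
        if mask_arr.shape != grid_shape:
            raise ValueError(
                f"mask grid {mask_arr.shape} does not match image grid {grid_shape}"
            )
        mask_arr = mask_arr != 0

    # Fortran order => linear index runs x-fastest.
    flat_mask = mask_arr.reshape(-1, order="F")
    idx = np.flatnonzero(flat_mask)
    n_subjects = data.shape[3]
    flat = data.reshape(-1, n_subjects, order="F")  # (n_vox, N)
    matrix = np.ascontiguousarray(flat[idx].T)
    return ModalityData(
        name=name,
        matrix=matrix,
        mask=idx,
        grid_shape=grid_shape,
        affine=affine,
    )


def load_matrix_h5(path, name: str | None = None) -> ModalityData:
    """Read a plain-matrix modality container (HDF5: `matrix`, `subjects`, `features`)."""
    with h5py.File(path, "r") as f:
        matrix = f["matrix"][()]
        label = name or f.attrs.get("name", "modality")
    return ModalityData(name=str(label), matrix=matrix)


def save_matrix_h5(path, data: ModalityData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=data.matrix)
        f.create_dataset(
            "subjects", data=np.array([f"sub-{i:05d}" for i in range(data.n_subjects)], dtype="S")
        )
        f.create_dataset("features", data=np.arange(data.n_features))
        f.attrs["name"] = data.name


def zscore_features(data: ModalityData) -> ModalityData:
    """Standardize each feature across subjects (sample sd, ddof=1).

    Features with standard deviation below 1e-12 are dropped; their original
    column indices are recorded in ``dropped`` so maps can be re-expanded
    with zeros.  Idempotent within floating-point tolerance.
    """
    Y = data.matrix
    if not np.all(np.isfinite(Y)):
        raise ValueError(f"modality {data.name!r}: non-finite entries; impute first")
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1) if Y.shape[0] > 1 else np.zeros(Y.shape[1])
    # threshold relative to column magnitude: a constant column of large
    # values carries float-noise sd well above any absolute cutoff
    keep = sd >= 1e-12 * np.maximum(1.0, np.abs(mu))
    dropped_new = np.flatnonzero(~keep)
    Z = (Y[:, keep] - mu[keep]) / sd[keep]

    # Map newly dropped columns back to original indexing when columns were
    # already dropped in a previous pass.
    if data.dropped.size:
        surviving = np.setdiff1d(
            np.arange(Y.shape[1] + data.dropped.size), data.dropped, assume_unique=False
        )
        dropped_all = np.sort(np.concatenate([data.dropped, surviving[dropped_new]]))
    else:
        dropped_all = dropped_new

    mask = data.mask
    return replace(
        data,
        matrix=Z,
        zscored=True,
        dropped=dropped_all,
        mask=mask,
    )


def impute_missing_modality(
    dataset: list[ModalityData], missing: np.ndarray
) -> list[ModalityData]:
    """Replace missing subject rows by the column mean over non-missing subjects.

    ``missing`` is a boolean (n_subjects, n_modalities) indicator.  A modality
    missing for every subject cannot be imputed and raises.
    """
    missing = np.asarray(missing, dtype=bool)
    n_subj = dataset[0].n_subjects
    if missing.shape != (n_subj, len(dataset)):
        raise ValueError(
            f"missing indicator shape {missing.shape} != ({n_subj}, {len(dataset)})"
        )
    out = []
    for k, mod in enumerate(dataset):
        miss_k = missing[:, k]
        if not miss_k.any():
            out.append(mod)
            continue
        if miss_k.all():
            raise ValueError(f"modality {mod.name!r} is missing for all subjects; unimputable")
        Y = mod.matrix.copy()
        col_mean = Y[~miss_k].mean(axis=0)
        Y[miss_k] = col_mean
        out.append(replace(mod, matrix=Y))
    return out


def regress_confounds(y: np.ndarray, confounds: ConfoundMatrix) -> np.ndarray:
    """OLS-residualize each column of ``y`` against the confounds.

    Missing entries (NaN) in ``y`` are handled listwise per column: the fit
    uses only observed rows, residuals are written back at those rows, and
    missing entries stay missing.  An intercept is always included.
    """
    y = np.asarray(y, dtype=np.float64)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    C = confounds.values
    n = C.shape[0]
    if y.shape[0] != n:
        raise ValueError("subject count mismatch between y and confounds")

    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify collinear confound columns by incremental rank growth.
        bad = []
        acc = np.ones((n, 1))
        for j in range(C.shape[1]):
            cand = np.column_stack([acc, C[:, j]])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                bad.append(confounds.names[j])
            else:
                acc = cand
        raise ValueError(f"rank-deficient confound matrix; collinear columns: {bad}")

    resid = np.full_like(y, np.nan)
    for q in range(y.shape[1]):
        obs = np.isfinite(y[:, q])
        n_obs = int(obs.sum())
        if n_obs <= X.shape[1]:
            raise ValueError(
                f"column {q}: {n_obs} observed rows <= {X.shape[1]} regressors"
            )
        Xo = X[obs]
        beta, *_ = np.linalg.lstsq(Xo, y[obs, q], rcond=None)
        resid[obs, q] = y[obs, q] - Xo @ beta
    return resid[:, 0] if squeeze else resid


def read_phenotypes(path) -> PhenotypeTable:
    """Read a TSV of subject x phenotype values; blanks/NaN are missing."""
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(values=df.to_numpy(dtype=np.float64), names=list(df.columns))


def read_confounds(path) -> ConfoundMatrix:
    """Read a TSV confound table; deduplicate identical columns."""
    df = pd.read_csv(path, sep="\t")
    df = df.loc[:, ~df.T.duplicated()]
    return ConfoundMatrix(values=df.to_numpy(dtype=np.float64), names=list(df.columns))
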