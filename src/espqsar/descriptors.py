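"""ESP grid descriptors and their PCA reduction.

Each aligned molecule is described by the electrostatic potential sampled
at every node of the descriptor grid (the alignment grid subsampled by
stride 2, e.g. 0.106 Å -> 0.212 Å), flattened x-fastest into a K-vector.
K is large (106 nodes per axis gives K = 106^3 = 1,191,016), so the
training-set descriptor matrix is reduced by mean-centred PCA; test
molecules are projected with the fitted model, never refitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import Molecule
from .fields import DensityBackend, GridSpec, PromoleculeBackend, solve_poisson

__all__ = [
    "DescriptorMatrix",
    "PCAModel",
    "esp_descriptor",
    "descriptor_matrix",
    "pca_fit",
    "pca_project",
    "save_descriptors",
    "load_descriptors",
    "save_pca",
    "load_pca",
]


@dataclass
class DescriptorMatrix:
    """Per-molecule ESP vectors: ``rows[i]`` is molecule ``molecule_ids[i]``."""

    molecule_ids: list[str]
    rows: np.ndarray  # (n, K)

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if len(self.molecule_ids) != self.rows.shape[0]:
            raise ValueError("one descriptor row per molecule id required")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("descriptor rows must be finite")

    @property
    def K(self) -> int:
        return self.rows.shape[1]

    def subset(self, ids) -> "DescriptorMatrix":
        index = {m: i for i, m in enumerate(self.molecule_ids)}
        sel = [index[i] for i in ids]
        return DescriptorMatrix(molecule_ids=list(ids), rows=self.rows[sel])


@dataclass
class PCAModel:
    """Mean-centred principal components of a training descriptor matrix.

    ``components`` rows are orthonormal K-vectors ordered by decreasing
    explained variance. When the requested width exceeds the matrix rank,
    the trailing components are zero vectors so projections keep a fixed
    width (scores there are identically zero).
    """

    mean: np.ndarray
    components: np.ndarray          # (n_comp, K)
    explained_variance: np.ndarray  # (n_comp,)

    @property
    def n_comp(self) -> int:
        return self.components.shape[0]


def esp_descriptor(
    aligned_molecule: Molecule,
    descriptor_grid: GridSpec,
    backend: DensityBackend | None = None,
) -> np.ndarray:
    """ESP K-vector of an aligned molecule on the descriptor grid.

    The molecule's charge density is evaluated on the descriptor grid and
    Poisson's equation solved there; the potential is flattened with the
    x index varying fastest.
    """
    backend = backend or PromoleculeBackend()
    rho = backend.density(aligned_molecule, descriptor_grid)
    phi = solve_poisson(rho)
    return phi.flatten()


def descriptor_matrix(
    molecules, descriptor_grid: GridSpec, backend: DensityBackend | None = None
) -> DescriptorMatrix:
    backend = backend or PromoleculeBackend()
    rows = np.array(
        [esp_descriptor(m, descriptor_grid, backend) for m in molecules]
    )
    return DescriptorMatrix(molecule_ids=[m.id for m in molecules], rows=rows)


def pca_fit(train_matrix: DescriptorMatrix, n_comp: int | None = None) -> PCAModel:
    """Fit mean-centred PCA by singular value decomposition.

    ``n_comp`` defaults to the number of training samples. Components
    beyond the matrix rank are zero-padded. Component signs are fixed by
    making each component's largest-magnitude loading positive.
    """
    X = train_matrix.rows
    n, K = X.shape
    if n_comp is None:
        n_comp = n
    if n_comp < 1:
        raise ValueError("n_comp must be at least 1")
    if n_comp > n:
        raise ValueError(f"n_comp={n_comp} exceeds the {n} fitted samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(n - 1, 1)
    tol = s[0] * max(n, K) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    r = min(rank, n_comp)
    components = np.zeros((n_comp, K))
    explained = np.zeros(n_comp)
    components[:r] = Vt[:r]
    explained[:r] = var[:r]
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(r):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PCAModel(mean=mean, components=components, explained_variance=explained)


def pca_project(model: PCAModel, vector: np.ndarray) -> np.ndarray:
    """Scores of a K-vector (or an (n, K) stack) in the component basis."""
    v = np.asarray(vector, dtype=float)
    if v.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"vector length {v.shape[-1]} != descriptor length {model.mean.shape[0]}"
        )
    return (v - model.mean) @ model.components.T


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_descriptors(matrix: DescriptorMatrix, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("rows", data=matrix.rows)
        fh.create_dataset(
            "molecule_ids",
            data=np.array(matrix.molecule_ids, dtype=h5py.string_dtype()),
        )


def load_descriptors(path) -> DescriptorMatrix:
    import h5py

    with h5py.File(path, "r") as fh:
        rows = fh["rows"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s)
               for s in fh["molecule_ids"][...]]
    return DescriptorMatrix(molecule_ids=ids, rows=rows)


def save_pca(model: PCAModel, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("mean", data=model.mean)
        fh.create_dataset("components", data=model.components)
        fh.create_dataset("explained_variance", data=model.explained_variance)


def load_pca(path) -> PCAModel:
    import h5py

    with h5py.File(path, "r") as fh:
        return PCAModel(
            mean=fh["mean"][...],
            components=fh["components"][...],
            explained_variance=fh["explained_variance"][...],
        )
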