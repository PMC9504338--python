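"""Principal component analysis of selected coordinates.

The covariance of the superposed, optionally mass-weighted coordinates is
diagonalized; eigenvectors ("principal components") describe collective
motions, and per-frame projections onto the leading components feed the
Markov-state-model stage.  The first component's per-atom arrows form the
"porcupine" representation of the dominant motion.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .fluct import _superposed_coords
from .traj_io import AtomSelection, Trajectory


@dataclass
class PCAModel:
    mean_structure: np.ndarray   # (n_atoms, 3) Angstrom
    eigenvectors: np.ndarray     # (3n, n_components) orthonormal columns
    eigenvalues: np.ndarray      # descending; Angstrom^2 (amu-weighted if mass_weighted)
    mass_weights: np.ndarray     # amu per atom (ones if unweighted)
    mass_weighted: bool

    @property
    def n_atoms(self) -> int:
        return self.mean_structure.shape[0]

    def n_components_for_variance(self, fraction: float = 0.8, cap: int = 10) -> int:
        """Smallest component count explaining >= ``fraction`` of total variance."""
        total = self.eigenvalues.sum()
        if total <= 0:
            return 1
        cum = np.cumsum(self.eigenvalues) / total
        k = int(np.searchsorted(cum, fraction) + 1)
        return min(k, cap, self.eigenvalues.size)


def fit_pca(traj: Trajectory, selection: AtomSelection,
            mass_weighted: bool = False, reference: str = "mean") -> PCAModel:
    """Eigendecomposition of the coordinate covariance (1/(F-1) normalized).

    Frames are superposed internally with the same convention as the
    fluctuation module.  Eigenvector sign is fixed by making each column's
    largest-magnitude entry positive, so refits on identical data are
    bit-reproducible.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if len(selection) == 0:
        raise ValueError("selection is empty")
    masses = traj.topology.masses[selection.indices]
    aligned = _superposed_coords(traj, selection, reference,
                                 masses if mass_weighted else None)
    F, n, _ = aligned.shape
    mean = aligned.mean(axis=0)
    X = (aligned - mean).reshape(F, 3 * n)
    w = np.repeat(masses, 3) if mass_weighted else np.ones(3 * n)
    Xw = X * np.sqrt(w)
    # SVD of the centered data avoids forming the 3n x 3n covariance explicitly
    _, s, Vt = np.linalg.svd(Xw, full_matrices=False)
    eigenvalues = s ** 2 / (F - 1)
    eigenvectors = Vt.T
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    for k in range(eigenvectors.shape[1]):
        i = int(np.argmax(np.abs(eigenvectors[:, k])))
        if eigenvectors[i, k] < 0:
            eigenvectors[:, k] = -eigenvectors[:, k]
    return PCAModel(mean_structure=mean, eigenvectors=eigenvectors,
                    eigenvalues=eigenvalues,
                    mass_weights=masses if mass_weighted else np.ones(n),
                    mass_weighted=mass_weighted)


def project(traj: Trajectory, selection: AtomSelection, model: PCAModel,
            n_components: int = 2, reference: str = "mean") -> np.ndarray:
    """Per-frame scores on the first ``n_components`` principal components."""
    if n_components > model.eigenvectors.shape[1]:
        raise ValueError(f"requested {n_components} components, model has "
                         f"{model.eigenvectors.shape[1]}")
    if len(selection) != model.n_atoms:
        raise ValueError("selection size does not match the fitted model")
    aligned = _superposed_coords(traj, selection, reference,
                                 model.mass_weights if model.mass_weighted else None)
    # re-anchor on the model's mean so scores are comparable across trajectories
    F = aligned.shape[0]
    X = (aligned - model.mean_structure).reshape(F, -1)
    w = np.repeat(model.mass_weights, 3) if model.mass_weighted else 1.0
    return (X * np.sqrt(w)) @ model.eigenvectors[:, :n_components]


def porcupine_vectors(model: PCAModel, component: int = 0, scale: float = 1.0):
    """Per-atom arrows for one principal component, anchored at the mean.

    Returns an array of rows (atom index, anchor xyz, arrow xyz) suitable for
    TSV export to molecular viewers.
    """
    if not 0 <= component < model.eigenvectors.shape[1]:
        raise ValueError(f"component {component} out of range")
    if model.eigenvalues[component] <= 1e-12:
        warnings.warn(f"component {component} has (near-)zero eigenvalue; arrows are noise")
    arrows = scale * model.eigenvectors[:, component].reshape(-1, 3)
    out = np.empty((model.n_atoms, 7))
    out[:, 0] = np.arange(model.n_atoms)
    out[:, 1:4] = model.mean_structure
    out[:, 4:7] = arrows
    return out
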