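"""Rigid-body superposition, RMSD/RMSF, and dynamic cross-correlation.

The dynamic cross-correlation matrix (DCCM) between residues i and j is

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

with dr the displacement of each residue's anchor atom from its mean
position after least-squares superposition of every frame onto a common
reference.  The reference defaults to the once-iterated average structure
(align all frames to frame 0, average, re-align to that average); pass
``reference="first"`` to use frame 0 directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_io import AtomSelection, Trajectory


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference:
    ``transformed = (mobile - mobile_center) @ rotation + reference_center``."""

    rotation: np.ndarray      # 3x3, proper (det = +1)
    translation: np.ndarray   # reference_center - mobile_center @ rotation
    rmsd: float               # Angstrom, weighted

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation + self.translation


@dataclass
class CorrelationMatrix:
    """Residue-residue DCCM with an optional display mask.

    ``values`` is symmetric with unit diagonal wherever the residue
    fluctuates; ``defined[i]`` is False for zero-variance residues, whose
    rows/columns hold 0 rather than NaN.  ``display_mask`` marks entries
    with |C| below the display floor (masked for plotting only — network
    construction always consumes the raw values).
    """

    values: np.ndarray
    defined: np.ndarray
    min_abs: float = 0.0

    @property
    def display_mask(self) -> np.ndarray:
        return np.abs(self.values) < self.min_abs

    def masked_values(self) -> np.ndarray:
        out = self.values.copy()
        out[self.display_mask] = np.nan
        return out


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted least-squares rigid superposition (Kabsch, reflection excluded).

    Raises on fewer than 3 atoms or degenerate (collinear) reference geometry.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    cx = w @ X
    cy = w @ Y
    Xc = X - cx
    Yc = Y - cy
    # degenerate geometry check: reference spread must span >= 2 dimensions
    spread = np.linalg.svd(Yc * np.sqrt(w)[:, None], compute_uv=False)
    if spread[1] < 1e-10 * max(spread[0], 1.0):
        raise ValueError("reference geometry is degenerate (collinear or coincident atoms)")
    H = (Xc * w[:, None]).T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    diff = Xc @ R - Yc
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return SuperpositionResult(rotation=R, translation=cy - cx @ R, rmsd=rmsd)


def _batch_superpose(X: np.ndarray, ref: np.ndarray,
                     weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch superposition of a frame stack (F, n, 3) onto one reference.

    Returns (aligned coordinates, per-frame weighted RMSD).  Same math as
    :func:`kabsch_superpose`, batched over frames with stacked 3x3 SVDs.
    """
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float) / np.sum(weights)
    cy = w @ ref
    Yc = ref - cy
    spread = np.linalg.svd(Yc * np.sqrt(w)[:, None], compute_uv=False)
    if spread[1] < 1e-10 * max(spread[0], 1.0):
        raise ValueError("reference geometry is degenerate (collinear or coincident atoms)")
    cx = np.einsum("n,fni->fi", w, X)
    Xc = X - cx[:, None, :]
    H = np.einsum("fni,nj->fij", Xc * w[:, None], Yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.tile(np.eye(3), (X.shape[0], 1, 1))
    D[:, 2, 2] = d
    R = U @ D @ Vt
    XcR = Xc @ R
    diff = XcR - Yc
    rmsd = np.sqrt(np.einsum("n,fni,fni->f", w, diff, diff))
    return XcR + cy, rmsd


def _superposed_coords(traj: Trajectory, selection: AtomSelection,
                       reference: str = "mean",
                       weights: np.ndarray | None = None) -> np.ndarray:
    """All frames of the selection superposed onto the chosen reference."""
    X = traj.coordinates[:, selection.indices, :]
    aligned, _ = _batch_superpose(X, X[0], weights)
    if reference == "first" or X.shape[0] == 1:
        return aligned
    if reference != "mean":
        raise ValueError(f"unknown superposition reference {reference!r}")
    out, _ = _batch_superpose(X, aligned.mean(axis=0), weights)
    return out


def rmsd_series(traj: Trajectory, selection: AtomSelection,
                reference_frame: int = 0,
                weights: np.ndarray | None = None,
                equilibration_fraction: float = 0.2):
    """Per-frame superposed RMSD against a reference frame.

    Returns ``(series, summary)`` where summary holds the mean and standard
    deviation over the equilibrated window (the first
    ``equilibration_fraction`` of frames discarded).
    """
    if len(selection) == 0:
        raise ValueError("selection is empty")
    F = traj.n_frames
    if not 0 <= reference_frame < F:
        raise ValueError(f"reference frame {reference_frame} outside [0, {F})")
    X = traj.coordinates[:, selection.indices, :]
    _, series = _batch_superpose(X, X[reference_frame], weights)
    start = int(np.floor(equilibration_fraction * F))
    window = series[start:] if start < F else series
    summary = {"mean": float(window.mean()), "sd": float(window.std(ddof=0)),
               "window_start_frame": start}
    return series, summary


def rmsf(traj: Trajectory, selection: AtomSelection,
         reference: str = "mean", weights: np.ndarray | None = None) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the mean position (Angstrom)."""
    if len(selection) == 0:
        raise ValueError("selection is empty")
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    aligned = _superposed_coords(traj, selection, reference, weights)
    mean = aligned.mean(axis=0)
    dev = aligned - mean
    return np.sqrt(np.mean(np.einsum("fij,fij->fi", dev, dev), axis=0))


def dccm(traj: Trajectory, selection: AtomSelection, min_abs: float = 0.3,
         reference: str = "mean", weights: np.ndarray | None = None) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of the selected atoms.

    Entries with |C| below ``min_abs`` are flagged in the display mask (the
    conventional plotting floor is 0.3); the stored values are never floored.
    Zero-variance atoms give defined=False rows holding 0, not NaN.
    """
    if len(selection) == 0:
        raise ValueError("selection is empty")
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    aligned = _superposed_coords(traj, selection, reference, weights)
    dev = aligned - aligned.mean(axis=0)                    # (F, n, 3)
    A = dev.transpose(1, 0, 2).reshape(dev.shape[1], -1)    # (n, 3F) for BLAS
    inner = (A @ A.T) / dev.shape[0]
    var = np.diag(inner).copy()
    defined = var > 1e-300
    denom = np.sqrt(np.where(defined, var, 1.0))
    C = inner / denom[:, None] / denom[None, :]
    C[~defined, :] = 0.0
    C[:, ~defined] = 0.0
    C[np.ix_(defined, defined)] = np.clip(C[np.ix_(defined, defined)], -1.0, 1.0)
    np.fill_diagonal(C, np.where(defined, 1.0, 0.0))
    C = 0.5 * (C + C.T)
    return CorrelationMatrix(values=C, defined=defined, min_abs=min_abs)
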