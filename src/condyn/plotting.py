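"""Matplotlib helpers for the standard diagnostic figures."""

from __future__ import annotations

import numpy as np

from .fluct import CorrelationMatrix
from .msm import ImpliedTimescales


def plot_dccm(corr: CorrelationMatrix, ax=None, cmap: str = "RdBu_r"):
    """Heatmap of the DCCM with the |C| display floor applied."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(corr.masked_values(), vmin=-1, vmax=1, cmap=cmap, origin="lower")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.figure.colorbar(im, ax=ax, label="C$_{ij}$")
    return ax


def plot_its(its: ImpliedTimescales, ax=None):
    """Implied timescales vs lag with the tau = t line marking resolution."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    lags_ns = its.lags * its.frame_spacing
    for k in range(its.timescales.shape[1]):
        ax.plot(lags_ns, its.timescales_ns[:, k], "o-", label=f"t{k + 2}")
    ax.plot(lags_ns, lags_ns, "k--", lw=1)
    ax.fill_between(lags_ns, 0, lags_ns, color="0.85")
    ax.set_xlabel("lag time (ns)")
    ax.set_ylabel("implied timescale (ns)")
    ax.set_yscale("log")
    ax.legend()
    return ax


def plot_free_energy_surface(scores: np.ndarray, ax=None, bins: int = 80):
    """-ln(density) over the first two PC scores (kT units, shifted to 0)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    H, xe, ye = np.histogram2d(scores[:, 0], scores[:, 1], bins=bins)
    with np.errstate(divide="ignore"):
        G = -np.log(H.T / H.max())
    im = ax.imshow(G, extent=(xe[0], xe[-1], ye[0], ye[-1]), origin="lower",
                   aspect="auto", cmap="viridis")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.figure.colorbar(im, ax=ax, label="free energy (kT)")
    return ax
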