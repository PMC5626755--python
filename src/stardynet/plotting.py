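"""Basic plots: DCCM heatmap with the three-band coloring, PMF profiles."""

from __future__ import annotations

import numpy as np

from .essential_dynamics import CorrelationMatrix
from .wham import PmfProfile

__all__ = ["plot_dccm", "plot_pmf"]


def plot_dccm(corr: CorrelationMatrix, path=None, threshold: float = 0.25):
    """Heatmap of a cross-correlation matrix.

    The diverging colormap is centred so the conventional reading bands
    (correlated >= threshold, anti-correlated <= -threshold, weak between)
    are visually separated; band boundaries are drawn on the colorbar.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.matrix, cmap="RdBu_r", vmin=-1.0, vmax=1.0,
                   origin="lower")
    cbar = fig.colorbar(im, ax=ax, label=r"$C_{ij}$")
    for y in (-threshold, threshold):
        cbar.ax.axhline(y, color="k", lw=0.8)
    ax.set_xlabel("node j")
    ax.set_ylabel("node i")
    ax.set_title("dynamic cross-correlation map")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_pmf(profile: PmfProfile, path=None):
    """1D PMF with error bars, or 2D PMF as a masked free-energy surface."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if isinstance(profile.bin_centers, tuple):
        xc, yc = profile.bin_centers
        masked = np.ma.masked_invalid(profile.free_energy.T)
        im = ax.pcolormesh(xc, yc, masked, shading="auto", cmap="viridis")
        fig.colorbar(im, ax=ax, label="free energy (kcal/mol)")
        ax.set_xlabel("reaction coordinate (A)")
        ax.set_ylabel("auxiliary coordinate")
    else:
        x = profile.bin_centers
        ok = profile.defined
        if profile.errors is not None:
            ax.errorbar(x[ok], profile.free_energy[ok],
                        yerr=profile.errors[ok], errorevery=10, lw=1.2,
                        elinewidth=0.8, capsize=2)
        else:
            ax.plot(x[ok], profile.free_energy[ok], lw=1.2)
        ax.set_xlabel("reaction coordinate (A)")
        ax.set_ylabel("PMF (kcal/mol)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
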