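"""Figure helpers: metagene line+ribbon plots and change heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .profiles import AlignedMatrix, MetageneProfile


def plot_metagene(profiles: dict[str, MetageneProfile], ax=None,
                  ylabel: str = "log2 normalized coverage"):
    """Mean lines with shaded 95% bootstrap ribbons, one per condition.

    The gene-body span (between the flanks) is shaded gray; x runs from
    upstream flank through the scaled body to the downstream flank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for name, prof in profiles.items():
        x = np.arange(len(prof.mean))
        ax.plot(x, prof.mean, label=name, lw=1.2)
        ax.fill_between(x, prof.ci_lo, prof.ci_hi, alpha=0.25, lw=0)
        if prof.flank_bins:
            ax.axvspan(prof.flank_bins, len(prof.mean) - prof.flank_bins,
                       color="0.9", zorder=0)
            ax.set_xticks([prof.flank_bins, len(prof.mean) - prof.flank_bins])
            ax.set_xticklabels(["TSS", "TES"])
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax


def plot_change_heatmap(matrix: AlignedMatrix, ax=None, sort_by_length: bool = True,
                        cmap: str = "RdBu_r", vmax: float | None = None):
    """Genes x bins heatmap; NaN bins render gray; for TSS-anchored
    matrices the per-gene end is traced as a black line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vals = matrix.values
    order = np.arange(len(matrix.gene_ids))
    if sort_by_length and matrix.gene_end_bin is not None:
        order = np.argsort(matrix.gene_end_bin)
    vals = vals[order]
    if vmax is None:
        vmax = float(np.nanquantile(np.abs(vals), 0.98)) or 1.0
    cmap_obj = plt.get_cmap(cmap).copy()
    cmap_obj.set_bad("0.75")
    im = ax.imshow(vals, aspect="auto", interpolation="nearest",
                   cmap=cmap_obj, vmin=-vmax, vmax=vmax)
    if matrix.gene_end_bin is not None:
        ax.plot(matrix.gene_end_bin[order], np.arange(len(order)),
                color="black", lw=0.8)
    ax.set_xlabel(f"{matrix.anchor}-anchored {matrix.bin_width}-bp bins")
    ax.set_ylabel("genes")
    plt.colorbar(im, ax=ax, label="log2 change")
    return ax
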