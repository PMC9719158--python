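"""Static diagnostic plots: contact heatmaps, chimera diagnostics, dot plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .digest_links import CoverageProfile
from .model import ContactMatrix, HiCMap

__all__ = [
    "plot_contact_matrix",
    "plot_diagnostic",
    "plot_collinearity",
    "plot_downsampling",
]


def plot_contact_matrix(
    matrix: ContactMatrix, hic_map: HiCMap | None = None, path=None, log: bool = True
):
    """Heatmap of binned link counts; grey lines mark contig boundaries."""
    counts = matrix.counts.astype(float)
    if log:
        counts = np.log10(counts + 1)
    fig, ax = plt.subplots(figsize=(7, 7))
    im = ax.imshow(counts, cmap="Reds", origin="lower", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="log10(links + 1)" if log else "links")
    chrom_of_bin = matrix.bins["chromosome"].to_numpy()
    edges = np.flatnonzero(chrom_of_bin[1:] != chrom_of_bin[:-1]) + 0.5
    for e in edges:
        ax.axhline(e, color="black", lw=0.8)
        ax.axvline(e, color="black", lw=0.8)
    if hic_map is not None:
        for chrom in hic_map.chromosomes():
            grp = hic_map.table[hic_map.table["chromosome"] == chrom]
            sl = matrix.chromosome_slice(chrom)
            for _, r in grp.iterrows():
                b = sl.start + r["offset"] / matrix.bin_size - 0.5
                ax.axhline(b, color="grey", lw=0.3)
                ax.axvline(b, color="grey", lw=0.3)
    ax.set_xlabel(f"bin ({matrix.bin_size:,} bp)")
    ax.set_ylabel(f"bin ({matrix.bin_size:,} bp)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_diagnostic(
    profile: CoverageProfile, alignments: pd.DataFrame | None = None, path=None
):
    """Per-contig chimera diagnostic: coverage track + marker chromosome track."""
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(8, 5), sharex=True, height_ratios=[2, 1]
    )
    x = (np.arange(len(profile.values)) + 0.5) * profile.window / 1e6
    ax1.plot(x, profile.values, lw=0.7, color="steelblue")
    ax1.axhline(profile.values.mean(), color="grey", ls="--", lw=0.8, label="mean")
    ax1.axhline(profile.values.mean() / 8, color="red", ls=":", lw=0.8, label="mean / 8")
    ax1.set_ylabel("physical coverage")
    ax1.legend(fontsize=8)
    ax1.set_title(profile.contig_id)
    if alignments is not None:
        sub = alignments[alignments["contig_id"] == profile.contig_id]
        chroms = sorted(set(sub["guide_chr"]))
        for i, chrom in enumerate(chroms):
            s = sub[sub["guide_chr"] == chrom]
            ax2.scatter(s["contig_pos"] / 1e6, s["guide_pos"], s=4, label=str(chrom))
        if chroms:
            ax2.legend(fontsize=7, title="guide chr")
    ax2.set_xlabel("contig position (Mb)")
    ax2.set_ylabel("guide position")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_collinearity(points: pd.DataFrame, path=None):
    """Marker dot plot: pseudomolecule vs guide position, panel per chromosome."""
    chroms = sorted(set(points["chromosome"]))
    n = max(1, len(chroms))
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        sub = points[points["chromosome"] == chrom]
        ax.scatter(sub["pseudo_pos"] / 1e6, sub["guide_pos"], s=2)
        ax.set_title(str(chrom))
        ax.set_xlabel("pseudomolecule (Mb)")
        ax.set_ylabel("guide position")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_downsampling(results: pd.DataFrame, path=None):
    """Median per-chromosome r against the thinning fraction (log x)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    med = results.groupby("fraction")["r"].median()
    ax.plot(med.index, med.to_numpy(), "o-")
    ax.set_xscale("log")
    ax.set_xlabel("retained fraction")
    ax.set_ylabel("median Pearson r vs baseline")
    ax.set_ylim(-1.05, 1.05)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
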