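"""Genomic relative-frequency profiles of top-ranked genes along the cM axis.

For each chromosome the cM axis is tiled into half-open bins of fixed width;
the relative frequency of a bin is the number of top-ranked genes in the bin
divided by the number of all catalog genes in the bin (normalising for local
gene density). Bins without catalog genes are undefined (NaN) and excluded
from the per-chromosome median. QTL regions can be attached for overlay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import GeneCatalog, QTLRegionSet


@dataclass(frozen=True)
class FrequencyProfile:
    """Binned relative frequencies per chromosome with medians and QTL overlay."""

    table: pd.DataFrame  # chromosome, bin_start, bin_end, n_catalog, n_top, rel_freq
    medians: dict[int, float]
    bin_width_cM: float
    qtl_regions: pd.DataFrame | None = None


def relative_frequency_profile(
    top_genes: set[str] | list[str] | tuple[str, ...],
    catalog: GeneCatalog,
    bin_width_cM: float = 1.0,
    qtl: QTLRegionSet | None = None,
) -> FrequencyProfile:
    """Per-bin fraction of catalog genes that are top-ranked, per chromosome."""
    if bin_width_cM <= 0:
        raise ValueError("bin_width_cM must be positive")
    top = set(top_genes)
    if not top <= set(catalog.gene_ids):
        raise ValueError("top_genes must be a subset of the catalog")

    tbl = catalog.table
    is_top = tbl["gene_id"].isin(top).to_numpy()
    rows = []
    medians: dict[int, float] = {}
    for c, length in enumerate(catalog.chrom_lengths_cM, start=1):
        edges = np.arange(0.0, length, bin_width_cM)
        edges = np.append(edges, length)
        on_c = (tbl["chromosome"] == c).to_numpy()
        pos = tbl.loc[on_c, "position_cM"].to_numpy()
        n_all, _ = np.histogram(pos, bins=edges)
        n_top, _ = np.histogram(tbl.loc[on_c & is_top, "position_cM"].to_numpy(),
                                bins=edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_all > 0, n_top / np.maximum(n_all, 1), np.nan)
        for i in range(len(edges) - 1):
            rows.append(
                {
                    "chromosome": c,
                    "bin_start": edges[i],
                    "bin_end": edges[i + 1],
                    "n_catalog": int(n_all[i]),
                    "n_top": int(n_top[i]),
                    "rel_freq": freq[i],
                }
            )
        defined = freq[n_all > 0]
        medians[c] = float(np.median(defined)) if len(defined) else float("nan")
    return FrequencyProfile(
        table=pd.DataFrame(rows),
        medians=medians,
        bin_width_cM=float(bin_width_cM),
        qtl_regions=None if qtl is None else qtl.regions.copy(),
    )


def plot_profile(profile: FrequencyProfile, path: str) -> None:
    """Frequency-vs-cM panels per chromosome with QTL shading and median line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(profile.table["chromosome"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.2 * len(chroms)),
                             sharex=False)
    if len(chroms) == 1:
        axes = [axes]
    for ax, c in zip(axes, chroms):
        sub = profile.table[profile.table["chromosome"] == c]
        mid = (sub["bin_start"] + sub["bin_end"]) / 2.0
        ax.plot(mid, sub["rel_freq"], ".", ms=3, color="black")
        ax.axhline(profile.medians[c], lw=1, color="tab:blue")
        if profile.qtl_regions is not None:
            for _, row in profile.qtl_regions.iterrows():
                if int(row["chromosome"]) == c:
                    ax.axvspan(row["cM_start"], row["cM_end"], color="0.8", zorder=0)
        ax.set_ylabel(f"chr {c}")
        ax.set_ylim(-0.02, 1.02)
    axes[-1].set_xlabel("position (Kosambi cM)")
    fig.suptitle("relative frequency of top-ranked genes per cM bin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
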