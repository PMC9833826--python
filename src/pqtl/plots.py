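"""Plot helpers: Manhattan scans, mirrored protein/trait scans, hotspot
density tracks and OPLS loading plots.  Plots are presentation artifacts;
all quantitative assertions in the package run on tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import natural_chrom_key

__all__ = ["manhattan", "mirrored_manhattan", "hotspot_track", "loading_plot"]


def _genome_coords(snp_meta: pd.DataFrame):
    """Cumulative x-coordinates and chromosome tick positions."""
    chroms = sorted(snp_meta["chrom"].astype(str).unique(), key=natural_chrom_key)
    offset, offsets, ticks = 0, {}, {}
    for c in chroms:
        offsets[c] = offset
        span = int(snp_meta.loc[snp_meta["chrom"].astype(str) == c, "pos"].max())
        ticks[c] = offset + span / 2
        offset += span + 1
    x = snp_meta["pos"].to_numpy() + np.array(
        [offsets[str(c)] for c in snp_meta["chrom"]])
    return x, ticks


def manhattan(assoc: pd.DataFrame, snp_meta: pd.DataFrame, path,
              title: str = "", sig_line: float | None = 1e-4) -> None:
    meta = snp_meta.loc[assoc["snp_id"]]
    x, ticks = _genome_coords(meta)
    logp = -np.log10(assoc["p"].to_numpy())
    colors = [("#1f77b4" if natural_chrom_key(c)[0] % 2 else "#ff7f0e")
              for c in meta["chrom"].astype(str)]
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.scatter(x, logp, s=6, c=colors, linewidths=0)
    if sig_line:
        ax.axhline(-np.log10(sig_line), color="red", lw=0.8, ls="--")
    ax.set_xticks(list(ticks.values()), list(ticks.keys()))
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mirrored_manhattan(protein_assoc: pd.DataFrame, trait_assoc: pd.DataFrame,
                       snp_meta: pd.DataFrame, path, title: str = "") -> None:
    """Protein scan above the axis, trait scan mirrored below."""
    fig, ax = plt.subplots(figsize=(9, 4))
    for assoc, sign, color in ((protein_assoc, 1, "#1f77b4"),
                               (trait_assoc, -1, "#2ca02c")):
        meta = snp_meta.loc[assoc["snp_id"]]
        x, ticks = _genome_coords(meta)
        ax.scatter(x, sign * -np.log10(assoc["p"].to_numpy()), s=6, c=color,
                   linewidths=0)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(list(ticks.values()), list(ticks.keys()))
    ax.set_ylabel(r"$-\log_{10} p$ (trait below)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def hotspot_track(report: pd.DataFrame, path, title: str = "") -> None:
    """Per-bin trans-regulated feature counts along the genome."""
    fig, ax = plt.subplots(figsize=(9, 2.5))
    x = np.arange(len(report))
    ax.bar(x, report["n_features"],
           color=np.where(report["hotspot"], "crimson", "grey"), width=1.0)
    edges = report.groupby("chrom", sort=False).apply(
        lambda g: g.index[0], include_groups=False)
    ax.set_xticks(edges.to_numpy(), edges.index)
    ax.set_ylabel("trans features / bin")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def loading_plot(prioritization: pd.DataFrame, path, title: str = "") -> None:
    """Predictive vs orthogonal loadings, highlighting selected proteins."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sel = prioritization["selected"].astype(bool)
    ax.scatter(prioritization.loc[~sel, "p1"], prioritization.loc[~sel, "o1"],
               s=8, c="lightgrey", linewidths=0, label="other")
    ax.scatter(prioritization.loc[sel, "p1"], prioritization.loc[sel, "o1"],
               s=12, c="crimson", linewidths=0, label="selected")
    ax.axhline(0, color="black", lw=0.5)
    ax.axvline(0, color="black", lw=0.5)
    ax.set_xlabel("predictive loading (p1)")
    ax.set_ylabel("orthogonal loading (o1)")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
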