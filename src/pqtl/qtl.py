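"""cis/trans QTL classification, variant annotation and hotspot detection.

A cis call requires the SNP within +-10 Mb of the feature's gene (distance
to the nearer gene boundary, 0 if overlapping), window-local FDR-adjusted
p < 1e-4, and q < 0.1; a trans call requires the SNP beyond the window or
on another chromosome, genome-wide FDR-adjusted p < 5e-8, and q < 0.1.
The lead SNP is the smallest p in the qualifying set, ties broken by
genomic position, so classification is invariant to SNP input order.

Trans hotspots are scored by tiling the genome in fixed bins, counting
distinct trans-regulated features per bin through their lead SNPs, and
flagging bins whose count exceeds a Poisson upper tail at the genome-wide
mean rate after BH correction across bins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneModel, RunConfig, natural_chrom_key
from .multitest import qvalues

log = logging.getLogger(__name__)

__all__ = ["classify_qtl", "annotate_variants", "detect_hotspots",
           "significant_snps"]

QTL_COLUMNS = ["feature_id", "snp_id", "chrom", "pos", "distance_bp", "call",
               "p", "q", "adjusted_p", "n_sig_snps", "intragenic", "consequence"]


def _distances(gene: GeneModel, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    d = np.full(len(pos), np.inf)
    same = chrom == str(gene.chromosome)
    p = pos[same]
    inside = (p >= gene.start) & (p <= gene.end)
    dd = np.minimum(np.abs(p - gene.start), np.abs(p - gene.end)).astype(float)
    dd[inside] = 0.0
    d[same] = dd
    return d


def _lead_index(sub: pd.DataFrame) -> int:
    """Row label of the lead SNP: min p, ties by (chrom order, position)."""
    best_p = sub["p"].min()
    ties = sub[sub["p"] == best_p]
    key = ties.apply(
        lambda r: (natural_chrom_key(r["chrom"]), int(r["pos"])), axis=1
    )
    return key.sort_values(kind="stable").index[0]


def _qualify(assoc: pd.DataFrame, gene: GeneModel | None,
             snp_meta: pd.DataFrame, cfg: RunConfig):
    """Annotate one feature's association table with distance and the
    window-local / global FDR-adjusted p-values; return cis and trans
    qualifying subsets."""
    a = assoc.merge(snp_meta[["chrom", "pos"]], left_on="snp_id",
                    right_index=True, how="left")
    chrom = a["chrom"].astype(str).to_numpy()
    pos = a["pos"].to_numpy()
    if gene is not None:
        a["distance_bp"] = _distances(gene, chrom, pos)
    else:
        a["distance_bp"] = np.inf
    local = a["distance_bp"] <= cfg.cis_window_bp
    a["global_adj_p"] = qvalues(a["p"].to_numpy(), method="bh")
    a["local_adj_p"] = np.nan
    if local.any():
        a.loc[local, "local_adj_p"] = qvalues(a.loc[local, "p"].to_numpy(),
                                              method="bh")
    cis = a[local & (a["local_adj_p"] < cfg.local_p_cut) & (a["q"] < cfg.q_cut)]
    trans = a[~local & (a["global_adj_p"] < cfg.global_p_cut)
              & (a["q"] < cfg.q_cut)]
    return a, cis, trans


def classify_qtl(assoc: pd.DataFrame, genes: dict[str, GeneModel],
                 snp_meta: pd.DataFrame,
                 cfg: RunConfig | None = None) -> pd.DataFrame:
    """Classify associations into per-feature cis/trans QTL calls.

    ``assoc`` is the scan table (feature_id, snp_id, p, q, ...); ``genes``
    maps feature id -> its gene model (features without a gene get trans
    calls only, with a warning).  Returns one row per (feature, call
    type) with the lead SNP.
    """
    cfg = cfg or RunConfig()
    out = []
    if len(assoc) == 0:
        return annotate_variants(pd.DataFrame(columns=QTL_COLUMNS[:10]),
                                 snp_meta, list(genes.values()))
    for fid, sub in assoc.groupby("feature_id", sort=True):
        gene = genes.get(fid)
        if gene is None:
            log.warning("feature %s has no gene model; cis calls skipped", fid)
        a, cis, trans = _qualify(sub.reset_index(drop=True), gene,
                                 snp_meta, cfg)
        for call, qual, adj_col in (("cis", cis, "local_adj_p"),
                                    ("trans", trans, "global_adj_p")):
            if qual.empty:
                continue
            lead = qual.loc[_lead_index(qual)]
            out.append({
                "feature_id": fid,
                "snp_id": lead["snp_id"],
                "chrom": str(lead["chrom"]),
                "pos": int(lead["pos"]),
                "distance_bp": float(lead["distance_bp"]),
                "call": call,
                "p": float(lead["p"]),
                "q": float(lead["q"]),
                "adjusted_p": float(lead[adj_col]),
                "n_sig_snps": int(len(qual)),
            })
    calls = pd.DataFrame(out, columns=QTL_COLUMNS[:10])
    return annotate_variants(calls, snp_meta, list(genes.values()))


def annotate_variants(calls: pd.DataFrame, snp_meta: pd.DataFrame,
                      genes: list[GeneModel]) -> pd.DataFrame:
    """Add intragenic flags and pass through consequence labels.

    A variant is intragenic when its position falls inside any gene
    interval on its chromosome; the consequence label is copied verbatim
    from the input annotation ("unannotated" when absent).
    """
    calls = calls.copy()
    if calls.empty:
        calls["intragenic"] = pd.Series(dtype=bool)
        calls["consequence"] = pd.Series(dtype=str)
        return calls
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(str(g.chromosome), []).append(g)
    intragenic = [
        any(g.start <= r.pos <= g.end for g in by_chrom.get(str(r.chrom), []))
        for r in calls.itertuples()
    ]
    calls["intragenic"] = intragenic
    conseq = snp_meta["consequence"] if "consequence" in snp_meta else pd.Series(dtype=str)
    labels = calls["snp_id"].map(conseq)
    calls["consequence"] = labels.replace("", "unannotated").fillna("unannotated")
    return calls


def significant_snps(assoc: pd.DataFrame, genes: dict[str, GeneModel],
                     snp_meta: pd.DataFrame, cfg: RunConfig | None = None,
                     mode: str = "cis") -> dict[str, set[str]]:
    """Per-feature sets of SNPs passing the cis rule (``mode="cis"``) or
    the genome-wide q threshold (``mode="q"``, used for trait scans)."""
    cfg = cfg or RunConfig()
    sets: dict[str, set[str]] = {}
    if len(assoc) == 0:
        return sets
    for fid, sub in assoc.groupby("feature_id", sort=True):
        if mode == "q":
            sets[fid] = set(sub.loc[sub["q"] < cfg.q_cut, "snp_id"])
            continue
        gene = genes.get(fid)
        if gene is None:
            sets[fid] = set()
            continue
        _, cis, _ = _qualify(sub.reset_index(drop=True), gene, snp_meta, cfg)
        sets[fid] = set(cis["snp_id"])
    return sets


def detect_hotspots(calls: pd.DataFrame, chrom_length_bp: dict[str, int],
                    bin_bp: int = 4_000_000,
                    alpha: float = 1e-3) -> pd.DataFrame:
    """Poisson enrichment scan for trans-hotspot bins.

    ``calls`` is a classify_qtl output; only trans rows contribute, each
    feature once per bin through its lead SNP.  The null rate is the
    genome-wide mean count per bin; a bin is flagged when its Poisson
    upper-tail p survives BH across bins at ``alpha``.
    """
    bins = []
    for chrom in sorted(chrom_length_bp, key=natural_chrom_key):
        length = chrom_length_bp[chrom]
        start = 1
        while start <= length:
            bins.append((str(chrom), start, min(start + bin_bp - 1, length)))
            start += bin_bp
    report = pd.DataFrame(bins, columns=["chrom", "start", "end"])
    report["n_features"] = 0
    trans = calls[calls["call"] == "trans"] if len(calls) else calls
    if len(trans) == 0:
        report["p"] = np.nan
        report["q"] = np.nan
        report["hotspot"] = False
        return report
    counts = np.zeros(len(report), dtype=int)
    keys = {(r.chrom, r.start): i for i, r in enumerate(report.itertuples())}
    for r in trans.itertuples():
        start = ((int(r.pos) - 1) // bin_bp) * bin_bp + 1
        idx = keys.get((str(r.chrom), start))
        if idx is not None:
            counts[idx] += 1
    report["n_features"] = counts
    rate = counts.mean()
    p = stats.poisson.sf(counts - 1, rate)  # P(X >= count)
    report["p"] = p
    report["q"] = qvalues(np.clip(p, np.nextafter(0, 1), 1.0), method="bh")
    report["hotspot"] = (report["q"] < alpha) & (counts > 0)
    return report
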