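"""Readers and writers for the tabular interchange formats.

All tables are UTF-8 TSV with a header row and ``NA`` for missing.
Genotypes can additionally be ingested from VCF (biallelic SNPs only),
gene models from BED (0-based half-open, converted on read) or GFF3
(1-based inclusive, used as-is).  Every ``write_*`` has a ``read_*``
counterpart and the pair round-trips losslessly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    SNP_META_COLUMNS,
    AbundanceMatrix,
    GeneModel,
    GenotypePanel,
    RunConfig,
    TraitTable,
    frame_to_genes,
    genes_to_frame,
)

log = logging.getLogger(__name__)

_NA = "NA"


def read_genotypes(path, format_tag: str = "tsv", meta_path=None) -> GenotypePanel:
    """Read a strains x SNPs dosage table (TSV) or a VCF.

    TSV: first column strain id, remaining columns one per SNP, values in
    {0, 1, 2, NA}; SNP annotation comes from ``meta_path`` (TSV with
    columns snp_id, chrom, pos, ref, alt, consequence, host_gene) or
    defaults to empty annotation.  VCF: per-sample GT fields are collapsed
    to alternate-allele dosages; non-biallelic records are skipped.
    """
    if format_tag == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA, ""],
                         keep_default_na=False,
                     float_precision="round_trip")
        df.index = df.index.astype(str).rename(None)
        vals = np.full(df.shape, np.nan)
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                if pd.isna(v):
                    continue
                try:
                    f = float(v)
                except (TypeError, ValueError):
                    f = -1.0
                if f not in (0.0, 1.0, 2.0):
                    raise ValueError(
                        f"{path}: invalid dosage {v!r} at strain "
                        f"{df.index[i]!r}, SNP {col!r}"
                    )
                vals[i, j] = f
        dosage = pd.DataFrame(vals, index=df.index,
                              columns=df.columns.astype(str).rename(None))
        if meta_path is not None:
            meta = read_snp_meta(meta_path)
        else:
            meta = pd.DataFrame(
                {"chrom": "", "pos": 1, "ref": "", "alt": "",
                 "consequence": "", "host_gene": ""},
                index=dosage.columns,
            )
        return GenotypePanel(dosage, meta.loc[dosage.columns])
    if format_tag == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format_tag!r}")


def _read_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    snp_ids, rows, meta_rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("skipping non-biallelic record %s:%s", var.CHROM, var.POS)
            continue
        vid = var.ID or f"{var.CHROM}_{var.POS}"
        if vid in snp_ids:
            raise ValueError(f"duplicate SNP id {vid!r} in VCF")
        dos = []
        for gt in var.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            dos.append(float(sum(alleles)) if len(alleles) == 2 else np.nan)
        snp_ids.append(vid)
        rows.append(dos)
        meta_rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], "", ""))
    dosage = pd.DataFrame(np.asarray(rows, dtype=float).T if rows else
                          np.empty((len(strains), 0)),
                          index=pd.Index(strains, dtype=str),
                          columns=pd.Index(snp_ids, dtype=str))
    meta = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS,
                        index=dosage.columns)
    return GenotypePanel(dosage, meta)


def read_snp_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA],
                       keep_default_na=False,
                     float_precision="round_trip")
    meta.index = meta.index.astype(str)
    for col in SNP_META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"{path}: SNP metadata missing column {col!r}")
    meta["chrom"] = meta["chrom"].astype(str)
    meta["pos"] = meta["pos"].astype(int)
    for col in ("ref", "alt", "consequence", "host_gene"):
        meta[col] = meta[col].fillna("").astype(str)
    return meta[SNP_META_COLUMNS]


def write_genotypes(panel: GenotypePanel, path, meta_path=None) -> None:
    out = panel.dosage.copy()
    # dosages are whole numbers; write them without a trailing ".0"
    out = out.astype("Int64")
    out.index.name = "strain"
    out.to_csv(path, sep="\t", na_rep=_NA)
    if meta_path is not None:
        meta = panel.snp_meta.copy()
        meta.index.name = "snp_id"
        meta.to_csv(meta_path, sep="\t", na_rep=_NA)


def read_abundance(path) -> AbundanceMatrix:
    """Read samples x proteins TSV; columns: sample, strain, then proteins."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA, ""],
                     keep_default_na=False,
                     float_precision="round_trip")
    df.index = df.index.astype(str).rename(None)
    if "strain" not in df.columns:
        raise ValueError(f"{path}: abundance table needs a 'strain' column")
    strain = df["strain"].astype(str)
    values = df.drop(columns="strain").astype(float)
    values.columns = values.columns.astype(str)
    return AbundanceMatrix(values, strain)


def write_abundance(ab: AbundanceMatrix, path) -> None:
    out = ab.values.copy()
    out.insert(0, "strain", ab.sample_to_strain)
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep=_NA)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA, ""],
                     keep_default_na=False,
                     float_precision="round_trip")
    df.index = df.index.astype(str).rename(None)
    return TraitTable(df.astype(float))


def write_traits(tt: TraitTable, path) -> None:
    out = tt.values.copy()
    out.index.name = "strain"
    out.to_csv(path, sep="\t", na_rep=_NA)


def read_genes(path, format_tag: str = "tsv") -> list[GeneModel]:
    """Read gene models from TSV, BED or GFF3.

    BED records are 0-based half-open and converted to 1-based inclusive;
    TSV and GFF3 are 1-based inclusive already.
    """
    if format_tag == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False,
                     float_precision="round_trip")
        return frame_to_genes(df)
    if format_tag == "bed":
        genes = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: malformed BED line")
                chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"gene_{ln}"
                strand = parts[5] if len(parts) > 5 else "+"
                genes.append(GeneModel(name, chrom, start0 + 1, end, strand))
        return genes
    if format_tag == "gff3":
        genes = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{ln}: malformed GFF3 line")
                if parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("gene_id") or f"gene_{ln}"
                genes.append(GeneModel(gid, parts[0], int(parts[3]),
                                       int(parts[4]), parts[6]))
        return genes
    raise ValueError(f"unknown gene format {format_tag!r}")


def write_genes(genes, path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_table(path) -> pd.DataFrame:
    """Generic TSV result table (association tables, QTL calls, ...)."""
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False,
                     float_precision="round_trip")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_config(path) -> RunConfig:
    """Load a RunConfig from a YAML key-value file (nested sections allowed)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat: dict = {}

    def _flatten(d):
        for k, v in d.items():
            if isinstance(v, dict):
                _flatten(v)
            else:
                flat[k] = v

    _flatten(raw)
    return RunConfig.from_dict(flat)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
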