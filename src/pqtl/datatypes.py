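"""Core data containers for inbred-panel systems genetics.

All tabular containers wrap :class:`pandas.DataFrame` with a fixed
orientation and validated invariants:

* :class:`GenotypePanel` — strains x SNPs alternate-allele dosages plus
  per-SNP annotation.
* :class:`AbundanceMatrix` — samples x proteins log2 ratio-to-reference
  values with a sample-to-strain map.
* :class:`TraitTable` — strains x traits.
* :class:`GeneModel` — a gene interval, 1-based inclusive coordinates.
* :class:`RunConfig` — analysis thresholds and seeds.

Coordinates are 1-based inclusive everywhere after ingestion; missing
values are ``NaN`` (written as ``"NA"``).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import re

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "AbundanceMatrix",
    "TraitTable",
    "GeneModel",
    "RunConfig",
    "natural_chrom_key",
    "genes_to_frame",
    "frame_to_genes",
]

SNP_META_COLUMNS = ["chrom", "pos", "ref", "alt", "consequence", "host_gene"]


def natural_chrom_key(chrom: str) -> tuple[int, str]:
    """Sort key giving the natural chromosome order 1..19, X, Y, M.

    Unknown labels sort after the named ones, alphabetically.
    """
    c = str(chrom)
    c = re.sub(r"^chr", "", c, flags=re.IGNORECASE)
    if c.isdigit():
        return (int(c), "")
    special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    if c.upper() in special:
        return (special[c.upper()], "")
    return (1000, c)


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypePanel:
    """Strains x SNPs dosage matrix with per-SNP metadata.

    ``dosage`` holds alternate-allele counts in {0, 1, 2} (floats so that
    ``NaN`` can mark missing calls).  Inbred panels are expected to be
    essentially homozygous ({0, 2}); heterozygous 1 is accepted and used
    as-is.  ``snp_meta`` is indexed by SNP id with columns
    ``chrom, pos, ref, alt, consequence, host_gene``.
    """

    dosage: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dosage.index, "strain ids")
        _check_unique(self.dosage.columns, "SNP ids")
        if not self.dosage.columns.equals(self.snp_meta.index):
            raise ValueError("snp_meta index must match dosage columns")
        vals = self.dosage.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {vals[i, j]!r} at strain "
                f"{self.dosage.index[i]!r}, SNP {self.dosage.columns[j]!r}"
            )
        if (self.snp_meta["pos"].astype(int) < 1).any():
            raise ValueError("SNP positions must be >= 1")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_strains(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-SNP fraction of missing calls."""
        return self.dosage.isna().mean(axis=0)

    def maf(self) -> pd.Series:
        """Per-SNP minor-allele frequency among non-missing strains."""
        f = self.dosage.mean(axis=0, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_strains(self, strains) -> "GenotypePanel":
        return GenotypePanel(self.dosage.loc[list(strains)], self.snp_meta)


@dataclass
class AbundanceMatrix:
    """Samples x proteins log2 ratio-to-reference values.

    ``sample_to_strain`` maps each sample id (row) to its strain label;
    biological replicates of a strain are distinct samples.
    """

    values: pd.DataFrame
    sample_to_strain: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "feature ids")
        self.sample_to_strain = pd.Series(self.sample_to_strain)
        missing = self.values.index.difference(self.sample_to_strain.index)
        if len(missing):
            raise ValueError(f"samples without strain mapping: {list(missing)[:5]}")
        self.sample_to_strain = self.sample_to_strain.loc[self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def n_strains_per_feature(self) -> pd.Series:
        """Number of strains with at least one non-missing sample, per protein."""
        obs = self.values.notna().groupby(self.sample_to_strain).any()
        return obs.sum(axis=0)

    def check_strains(self, panel: GenotypePanel) -> None:
        unknown = set(self.sample_to_strain) - set(panel.strain_ids)
        if unknown:
            raise ValueError(f"samples map to strains absent from panel: {sorted(unknown)[:5]}")


@dataclass
class TraitTable:
    """Strains x traits, one row per strain."""

    values: pd.DataFrame
    trait_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "strain ids")
        _check_unique(self.values.columns, "trait ids")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; ``start``/``end`` are 1-based inclusive bp."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")

    def distance_to(self, chrom: str, pos: int) -> float:
        """bp distance from a position to the nearer gene boundary.

        0 if the position overlaps the gene, ``inf`` on another chromosome.
        """
        if str(chrom) != str(self.chromosome):
            return float("inf")
        if self.start <= pos <= self.end:
            return 0.0
        return float(min(abs(pos - self.start), abs(pos - self.end)))


def genes_to_frame(genes) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.chromosome, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chromosome", "start", "end", "strand"],
    )


def frame_to_genes(df: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(str(r.gene_id), str(r.chromosome), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples(index=False)
    ]


@dataclass
class RunConfig:
    """Analysis thresholds shared across the mapping/integration stages.

    Defaults follow the conventional inbred-panel pQTL rules: a +-10 Mb
    cis window, window-local adjusted p < 1e-4 for cis calls, global
    adjusted p < 5e-8 for trans calls, q < 0.1 overall, a 5% MAF floor,
    and features retained only when quantified in >= ``min_strains``
    strains (50, the "quantified in >50 mice" analogue).
    """

    cis_window_bp: int = 10_000_000
    local_p_cut: float = 1e-4
    global_p_cut: float = 5e-8
    q_cut: float = 0.1
    maf_min: float = 0.05
    min_strains: int = 50
    qvalue_method: str = "storey"
    corr_r_low: float = -0.3
    corr_r_high: float = 0.6
    corr_p_cut: float = 0.05
    hotspot_bin_bp: int = 4_000_000
    hotspot_alpha: float = 1e-3
    min_allele_group: int = 3
    require_concordance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cis_window_bp", "local_p_cut", "global_p_cut", "q_cut",
                     "maf_min", "min_strains", "hotspot_bin_bp", "hotspot_alpha",
                     "min_allele_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.qvalue_method not in ("storey", "bh"):
            raise ValueError("qvalue_method must be 'storey' or 'bh'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
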