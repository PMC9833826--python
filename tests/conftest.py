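import numpy as np
import pandas as pd
import pytest

from pqtl.datatypes import GenotypePanel
from pqtl.kinship import KinshipMatrix
from pqtl.simulate import SimConfig, simulate_all


def tiny_sim_config(seed=0, **kw):
    """A small but structurally complete panel for fast tests."""
    defaults = dict(
        n_strains=40, n_chromosomes=2, chrom_length_bp=50_000_000,
        n_snps=80, ld_block_bp=2_000_000, n_proteins=24, n_genes=24,
        cis_fraction=0.25, n_trans_hotspots=1, hotspot_targets=5,
        n_traits=3, seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate_all(tiny_sim_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_panel(dosage: np.ndarray, chrom=None, pos=None) -> GenotypePanel:
    """Wrap a raw dosage matrix into a GenotypePanel with stub metadata."""
    n, m = dosage.shape
    strains = [f"s{i}" for i in range(n)]
    snps = [f"snp{j}" for j in range(m)]
    meta = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "ref": "A", "alt": "G", "consequence": "", "host_gene": "",
    }, index=pd.Index(snps))
    return GenotypePanel(pd.DataFrame(dosage, index=strains, columns=snps),
                         meta)


def identity_kinship(n: int) -> KinshipMatrix:
    ids = pd.Index([f"s{i}" for i in range(n)])
    return KinshipMatrix(pd.DataFrame(np.eye(n), index=ids, columns=ids))
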