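"""Identity-by-state kinship from a genotype panel.

K_ij is the mean, over SNPs observed in both strains, of
``1 - |g_i - g_j| / 2`` where g are alternate-allele dosages.  Identical
genotypes give 1, opposite homozygotes give 0.  The diagonal is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel

__all__ = ["KinshipMatrix", "ibs_kinship"]


@dataclass
class KinshipMatrix:
    """Symmetric strains x strains IBS similarity in [0, 1], diagonal 1."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        K = self.values.to_numpy(dtype=float)
        if K.shape[0] != K.shape[1] or not self.values.index.equals(self.values.columns):
            raise ValueError("kinship must be square with matching labels")
        if not np.allclose(K, K.T, atol=1e-12):
            raise ValueError("kinship must be symmetric")
        if not np.allclose(np.diag(K), 1.0):
            raise ValueError("kinship diagonal must be 1")
        if K.min() < -1e-12 or K.max() > 1 + 1e-12:
            raise ValueError("kinship entries must lie in [0, 1]")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, strains) -> "KinshipMatrix":
        s = list(strains)
        return KinshipMatrix(self.values.loc[s, s])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values.to_numpy())[0])


def ibs_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Pairwise-complete IBS kinship over all SNPs of the panel."""
    G = panel.dosage.to_numpy(dtype=float)
    n = G.shape[0]
    if n < 2:
        raise ValueError("kinship needs at least 2 strains")
    obs = ~np.isnan(G)
    Gz = np.where(obs, G, 0.0)

    # sum over jointly observed SNPs of |g_i - g_j|, in blocks to bound memory
    S = np.zeros((n, n))
    C = np.zeros((n, n))
    step = max(1, int(2e7 // max(1, n * G.shape[1])))
    for i0 in range(0, n, step):
        i1 = min(n, i0 + step)
        diff = np.abs(Gz[i0:i1, None, :] - Gz[None, :, :])
        both = obs[i0:i1, None, :] & obs[None, :, :]
        S[i0:i1] = np.sum(np.where(both, diff, 0.0), axis=2)
        C[i0:i1] = both.sum(axis=2)
    off = ~np.eye(n, dtype=bool)
    if (C[off] == 0).any():
        i, j = np.argwhere((C == 0) & off)[0]
        raise ValueError(
            "no jointly observed SNPs for strain pair "
            f"({panel.strain_ids[i]!r}, {panel.strain_ids[j]!r})"
        )
    with np.errstate(invalid="ignore"):
        K = 1.0 - (S / C) / 2.0
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    ids = pd.Index(panel.strain_ids)
    return KinshipMatrix(pd.DataFrame(K, index=ids, columns=ids))
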