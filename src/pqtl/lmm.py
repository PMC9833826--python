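"""Restricted-maximum-likelihood mixed-model association engine.

The model for one feature (protein or trait) measured at the strain level
is

    y = 1 mu + x beta + u + e,   var(u) = sigma_u^2 K,   var(e) = sigma_e^2 I,

where K is the identity-by-state kinship of the panel.  Variance
components are estimated once per feature by REML on the null model
(beta = 0) via the eigendecomposition K = U diag(s) U^T: after rotating
y and the design by U^T the covariance is diagonal in
delta = sigma_e^2 / sigma_u^2, sigma_u^2 profiles out in closed form, and
the restricted likelihood is maximised over delta on a log grid followed
by bounded local refinement.  Each SNP is then tested by generalised
least squares under covariance sigma_u^2 (K + delta I) with delta fixed
from the null fit, and F = (beta / se)^2 on (1, n - 2) degrees of
freedom gives the p-value.

API follows the Model / Results convention: build
:class:`KinshipMixedModel` from data, call :meth:`fit`, then
:meth:`KinshipMixedModelResults.scan` for the genome scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypePanel
from .kinship import KinshipMatrix
from .multitest import qvalues

log = logging.getLogger(__name__)

__all__ = [
    "KinshipMixedModel",
    "KinshipMixedModelResults",
    "fit_null",
    "assoc_scan",
]

_TINY_P = np.nextafter(0.0, 1.0)

ASSOC_COLUMNS = ["feature_id", "snp_id", "n", "beta", "se", "F", "p", "q"]


def _reml_loglik(delta: np.ndarray, s: np.ndarray, yt: np.ndarray,
                 Xt: np.ndarray, xtx_logdet: float):
    """Profile REML log-likelihood at each delta (vectorised).

    Returns (ll, sigma_u2, beta) for a rotated response ``yt`` and rotated
    design ``Xt`` (n x q); ``s`` are the kinship eigenvalues.
    """
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    n, q = Xt.shape
    w = 1.0 / (s[None, :] + delta[:, None])          # (d, n)
    # normal-equation cross products per delta
    XtW = Xt.T[None, :, :] * w[:, None, :]            # (d, q, n)
    A = XtW @ Xt                                      # (d, q, q)
    b = XtW @ yt                                      # (d, q)
    beta = np.linalg.solve(A, b[..., None])[..., 0]   # (d, q)
    resid = yt[None, :] - beta @ Xt.T                 # (d, n)
    rss = np.sum(w * resid**2, axis=1)                # (d,)
    sigma_u2 = rss / (n - q)
    sign, logdet_A = np.linalg.slogdet(A)
    ll = 0.5 * (
        (n - q) * (np.log((n - q) / (2 * np.pi)) - 1.0 - np.log(rss))
        - np.sum(np.log(s[None, :] + delta[:, None]), axis=1)
        - logdet_A
        + xtx_logdet
    )
    return ll, sigma_u2, beta


class KinshipMixedModel:
    """One-feature mixed model ``y = 1 mu + u + e`` with var(u) ~ kinship.

    Parameters
    ----------
    y : pandas.Series
        Strain-level values of the feature; missing strains are dropped.
    kinship : KinshipMatrix
        IBS kinship covering at least the strains of ``y``.
    feature_id : str
        Label carried into results tables.
    """

    MIN_STRAINS = 8

    def __init__(self, y: pd.Series, kinship: KinshipMatrix,
                 feature_id: str = "feature"):
        y = pd.Series(y).astype(float).dropna()
        strains = [s for s in kinship.strain_ids if s in set(y.index)]
        if len(strains) < self.MIN_STRAINS:
            raise ValueError(
                f"{feature_id}: needs >= {self.MIN_STRAINS} strains with data, "
                f"got {len(strains)}"
            )
        self.y = y.loc[strains]
        if float(self.y.std(ddof=1)) == 0.0:
            raise ValueError(f"{feature_id}: zero variance feature")
        self.feature_id = feature_id
        self.strains = strains
        K = kinship.subset(strains).values.to_numpy()
        s, U = np.linalg.eigh(K)
        if s[0] < -1e-8:
            raise ValueError(
                f"kinship not PSD: min eigenvalue {s[0]:.3g} < -1e-8"
            )
        if s[0] < 1e-8:
            log.warning("kinship eigenvalues clipped; regularizing K by +1e-6*I")
            s, U = np.linalg.eigh(K + 1e-6 * np.eye(len(strains)))
        self._s = np.clip(s, 1e-8, None)
        self._U = U

    def fit(self, grid_size: int = 100,
            delta_bounds: tuple[float, float] = (1e-5, 1e5)
            ) -> "KinshipMixedModelResults":
        """REML fit of the null model over delta (grid + local refinement)."""
        n = len(self.y)
        yt = self._U.T @ self.y.to_numpy()
        Xt = (self._U.T @ np.ones(n)).reshape(n, 1)
        xtx_logdet = float(np.log(n))
        lo, hi = delta_bounds
        grid = np.logspace(np.log10(lo), np.log10(hi), grid_size)
        ll, _, _ = _reml_loglik(grid, self._s, yt, Xt, xtx_logdet)
        k = int(np.argmax(ll))
        a = grid[max(0, k - 1)]
        b = grid[min(grid_size - 1, k + 1)]
        res = optimize.minimize_scalar(
            lambda t: -_reml_loglik(10.0**t, self._s, yt, Xt, xtx_logdet)[0][0],
            bounds=(np.log10(a), np.log10(b)), method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(10.0**res.x)
        ll_opt, su2, beta = _reml_loglik(delta, self._s, yt, Xt, xtx_logdet)
        sigma_u2 = float(su2[0])
        return KinshipMixedModelResults(
            model=self,
            delta=delta,
            sigma_u2=sigma_u2,
            sigma_e2=sigma_u2 * delta,
            mu=float(beta[0, 0]),
            reml_loglik=float(ll_opt[0]),
            nobs=n,
        )

    def reml_loglik(self, delta: float) -> float:
        """Restricted log-likelihood of the null model at a given delta."""
        n = len(self.y)
        yt = self._U.T @ self.y.to_numpy()
        Xt = (self._U.T @ np.ones(n)).reshape(n, 1)
        return float(_reml_loglik(delta, self._s, yt, Xt, np.log(n))[0][0])


@dataclass
class KinshipMixedModelResults:
    """Null-model REML estimates plus the genome-scan method."""

    model: KinshipMixedModel
    delta: float
    sigma_u2: float
    sigma_e2: float
    mu: float
    reml_loglik: float
    nobs: int
    n_skipped_snps: int = field(default=0, init=False)

    @property
    def feature_id(self) -> str:
        return self.model.feature_id

    @property
    def heritability(self) -> float:
        """Narrow-sense heritability sigma_u^2 / (sigma_u^2 + sigma_e^2)."""
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "feature_id": self.feature_id,
                "n": self.nobs,
                "delta": self.delta,
                "sigma_u2": self.sigma_u2,
                "sigma_e2": self.sigma_e2,
                "mu": self.mu,
                "heritability": self.heritability,
                "reml_loglik": self.reml_loglik,
            }
        )

    def scan(self, panel: GenotypePanel, maf_min: float = 0.05,
             qvalue_method: str = "storey",
             refit_delta: bool = False) -> pd.DataFrame:
        """Test every SNP of ``panel`` against this feature.

        SNPs failing the MAF floor or monomorphic among the used strains
        are skipped (count in ``n_skipped_snps``).  With
        ``refit_delta=True`` the variance ratio is re-estimated by REML
        per SNP instead of reusing the null-model estimate (exact but
        slow; intended for validation).
        """
        strains = self.model.strains
        G = panel.dosage.loc[strains].to_numpy(dtype=float)
        snp_ids = np.asarray(panel.snp_ids)
        n = len(strains)
        y = self.model.y.to_numpy()
        U, s = self.model._U, self.model._s
        w = 1.0 / (s + self.delta)
        yt = U.T @ y
        ot = U.T @ np.ones(n)

        complete = ~np.isnan(G).any(axis=0)
        freq = np.nanmean(G, axis=0) / 2.0
        with np.errstate(invalid="ignore"):
            maf = np.minimum(freq, 1.0 - freq)
        poly = np.nanstd(G, axis=0) > 0
        keep = poly & (maf >= maf_min)
        self.n_skipped_snps = int((~keep).sum())
        if self.n_skipped_snps:
            log.info("%s: skipped %d SNPs (monomorphic or MAF < %g)",
                     self.feature_id, self.n_skipped_snps, maf_min)
        if not keep.any():
            log.warning("%s: no testable SNPs", self.feature_id)
            return pd.DataFrame(columns=ASSOC_COLUMNS)

        rows: list[pd.DataFrame] = []
        fast = keep & complete
        if refit_delta:
            recs = [
                self._test_one_exact(G[:, j], y)
                for j in np.flatnonzero(keep)
            ]
            tab = pd.DataFrame(recs, columns=["n", "beta", "se", "F", "p"])
            tab.insert(0, "snp_id", snp_ids[keep])
            rows.append(tab)
        else:
            if fast.any():
                rows.append(self._scan_fast(G[:, fast], snp_ids[fast],
                                            yt, ot, w))
            slow = keep & ~complete
            for j in np.flatnonzero(slow):
                rec = self._test_one_missing(G[:, j], panel, snp_ids[j])
                if rec is not None:
                    rows.append(rec)
        tab = pd.concat(rows, ignore_index=True)
        tab.insert(0, "feature_id", self.feature_id)
        tab["q"] = qvalues(tab["p"].to_numpy(), method=qvalue_method)
        return tab[ASSOC_COLUMNS]

    def _scan_fast(self, G, snp_ids, yt, ot, w) -> pd.DataFrame:
        """Vectorised GLS for complete-genotype SNPs (shared rotation)."""
        n = len(yt)
        Gt = self.model._U.T @ G                       # (n, m)
        a11 = float(np.sum(w * ot * ot))
        a12 = (w * ot) @ Gt                            # (m,)
        a22 = np.sum(w[:, None] * Gt**2, axis=0)
        b1 = float(np.sum(w * ot * yt))
        b2 = (w * yt) @ Gt
        yy = float(np.sum(w * yt * yt))
        det = a11 * a22 - a12**2
        beta = (a11 * b2 - a12 * b1) / det
        mu = (a22 * b1 - a12 * b2) / det
        rss = yy - (mu * b1 + beta * b2)
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / (n - 2)
        var_beta = sigma2 * a11 / det
        with np.errstate(divide="ignore", invalid="ignore"):
            F = beta**2 / var_beta
        p = stats.f.sf(F, 1, n - 2)
        p = np.where(p <= 0, _TINY_P, p)
        return pd.DataFrame({
            "snp_id": snp_ids, "n": n, "beta": beta,
            "se": np.sqrt(var_beta), "F": F, "p": p,
        })

    def _test_one_missing(self, g, panel, snp_id):
        """Pairwise-complete GLS for a SNP with missing calls.

        Strains missing this genotype are dropped; the covariance
        K + delta I is restricted to the remaining strains and solved
        directly (no shared rotation available after subsetting).
        """
        mask = ~np.isnan(g)
        n = int(mask.sum())
        if n < 3 or np.std(g[mask]) == 0:
            self.n_skipped_snps += 1
            return None
        K = (self.model._U * self.model._s) @ self.model._U.T
        idx = np.flatnonzero(mask)
        V = K[np.ix_(idx, idx)] + self.delta * np.eye(n)
        y = self.model.y.to_numpy()[mask]
        X = np.column_stack([np.ones(n), g[mask]])
        beta, se, F, p = _gls_ftest(y, X, V)
        return pd.DataFrame({
            "snp_id": [snp_id], "n": [n], "beta": [beta],
            "se": [se], "F": [F], "p": [p],
        })

    def _test_one_exact(self, g, y):
        """Per-SNP REML refit of delta, then the same GLS F-test."""
        n = len(y)
        X = np.column_stack([np.ones(n), g])
        yt = self.model._U.T @ y
        Xt = self.model._U.T @ X
        xtx_logdet = float(np.linalg.slogdet(X.T @ X)[1])
        grid = np.logspace(-5, 5, 100)
        ll, _, _ = _reml_loglik(grid, self.model._s, yt, Xt, xtx_logdet)
        k = int(np.argmax(ll))
        a, b = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
        res = optimize.minimize_scalar(
            lambda t: -_reml_loglik(10.0**t, self.model._s, yt, Xt,
                                    xtx_logdet)[0][0],
            bounds=(np.log10(a), np.log10(b)), method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(10.0**res.x)
        K = (self.model._U * self.model._s) @ self.model._U.T
        V = K + delta * np.eye(n)
        beta, se, F, p = _gls_ftest(y, X, V)
        return n, beta, se, F, p


def _gls_ftest(y, X, V):
    """GLS fit of [1, x]; F-test of the slope on (1, n-2) df."""
    n = len(y)
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    A = Xw.T @ Xw
    b = Xw.T @ yw
    coef = np.linalg.solve(A, b)
    rss = float(np.sum((yw - Xw @ coef) ** 2))
    sigma2 = rss / (n - 2)
    var_beta = sigma2 * np.linalg.inv(A)[1, 1]
    F = float(coef[1] ** 2 / var_beta) if var_beta > 0 else np.inf
    p = float(stats.f.sf(F, 1, n - 2))
    return float(coef[1]), float(np.sqrt(var_beta)), F, max(p, _TINY_P)


def fit_null(y: pd.Series, kinship: KinshipMatrix,
             feature_id: str = "feature") -> KinshipMixedModelResults:
    """Convenience wrapper: build the model and REML-fit the null."""
    return KinshipMixedModel(y, kinship, feature_id=feature_id).fit()


def assoc_scan(y: pd.Series, panel: GenotypePanel, kinship: KinshipMatrix,
               fit: KinshipMixedModelResults | None = None,
               maf_min: float = 0.05, qvalue_method: str = "storey",
               refit_delta: bool = False) -> pd.DataFrame:
    """Scan all SNPs of ``panel`` against one strain-level feature."""
    if fit is None:
        fit = fit_null(y, kinship, feature_id=getattr(y, "name", "feature")
                       or "feature")
    return fit.scan(panel, maf_min=maf_min, qvalue_method=qvalue_method,
                    refit_delta=refit_delta)
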