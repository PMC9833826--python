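"""Orthogonal partial least squares with one predictive and one
orthogonal component.

The orthogonal-signal-correction algorithm: compute the PLS weight
w ~ X^T y, extract one component whose loading is orthogonal to w (this
captures structured X-variation uncorrelated with y), deflate X by it,
then fit the single predictive component on the deflated matrix.  Scores
of the two components are exactly orthogonal by construction; removing
the orthogonal step reduces the model to ordinary one-component PLS.

Columns are centred and unit-variance scaled by default, y is centred,
and the predictive component is oriented so that corr(t_p, y) >= 0.
Q^2 is estimated by leave-one-strain-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["OPLS", "OPLSResults", "fit_opls", "export_loadings"]


def _normalize(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("zero vector during OPLS extraction")
    return v / nrm


def _opls_core(X: np.ndarray, y: np.ndarray, orthogonal: bool = True):
    """One orthogonal + one predictive component on centred/scaled data."""
    w = _normalize(X.T @ y)
    t_o = np.zeros(len(y))
    p_o = np.zeros(X.shape[1])
    w_o = np.zeros(X.shape[1])
    Xd = X
    if orthogonal:
        t = X @ w
        p = X.T @ t / (t @ t)
        w_orth = p - (w @ p) * w
        # a roundoff-level residual means no orthogonal structure; extracting
        # it would deflate along an arbitrary (possibly y-aligned) direction
        if np.linalg.norm(w_orth) > 1e-8 * np.linalg.norm(p):
            w_o = _normalize(w_orth)
            t_o = X @ w_o
            p_o = X.T @ t_o / (t_o @ t_o)
            Xd = X - np.outer(t_o, p_o)
    w_p = _normalize(Xd.T @ y)
    t_p = Xd @ w_p
    p_p = Xd.T @ t_p / (t_p @ t_p)
    c = (y @ t_p) / (t_p @ t_p)
    return w_p, t_p, p_p, c, w_o, t_o, p_o


class OPLS:
    """Model one trait against the strain-level proteome.

    Parameters
    ----------
    X : DataFrame
        Strains x proteins; proteins with any missing value among the
        modelled strains are dropped (logged), as are zero-variance
        columns.  Strains with missing ``y`` are dropped.
    y : Series
        The trait, indexed by strain.
    scale : bool
        Unit-variance scaling of the columns (default True).
    """

    MIN_STRAINS = 10

    def __init__(self, X: pd.DataFrame, y: pd.Series, scale: bool = True):
        y = pd.Series(y).astype(float)
        strains = X.index.intersection(y.dropna().index)
        if len(strains) < self.MIN_STRAINS:
            raise ValueError(f"OPLS needs >= {self.MIN_STRAINS} complete strains")
        Xs = X.loc[strains]
        complete = Xs.notna().all(axis=0)
        nz = Xs.std(axis=0, ddof=1) > 0
        keep = complete & nz
        dropped = int((~keep).sum())
        if dropped:
            log.info("OPLS dropped %d proteins (missing or zero variance)",
                     dropped)
        if keep.sum() < 2:
            raise ValueError("fewer than 2 usable protein columns")
        self.X = Xs.loc[:, keep]
        self.y = y.loc[strains]
        if float(self.y.std(ddof=1)) == 0:
            raise ValueError("zero-variance response")
        self.scale = scale
        self.n_dropped = dropped

    def _prepare(self, X: np.ndarray, y: np.ndarray):
        mu_x = X.mean(axis=0)
        sd_x = X.std(axis=0, ddof=1) if self.scale else np.ones(X.shape[1])
        Xc = (X - mu_x) / sd_x
        mu_y = y.mean()
        return Xc, y - mu_y, mu_x, sd_x, mu_y

    def fit(self, cross_validate: bool = True) -> "OPLSResults":
        Xc, yc, mu_x, sd_x, mu_y = self._prepare(self.X.to_numpy(),
                                                 self.y.to_numpy())
        w_p, t_p, p_p, c, w_o, t_o, p_o = _opls_core(Xc, yc)
        # orient the predictive component along y
        if (t_p @ yc) < 0:
            w_p, t_p, p_p, c = -w_p, -t_p, -p_p, -c
        ssx = float(np.sum(Xc**2))
        ssy = float(np.sum(yc**2))
        r2x_pred = float(np.sum(np.outer(t_p, p_p) ** 2)) / ssx
        r2x_orth = float(np.sum(np.outer(t_o, p_o) ** 2)) / ssx
        resid = yc - t_p * c
        r2y = 1.0 - float(np.sum(resid**2)) / ssy
        q2 = self._loo_q2() if cross_validate else np.nan
        cols = self.X.columns
        return OPLSResults(
            model=self,
            scores_pred=pd.Series(t_p, index=self.X.index, name="t_pred"),
            scores_orth=pd.Series(t_o, index=self.X.index, name="t_orth"),
            loadings_pred=pd.Series(p_p, index=cols, name="p1"),
            loadings_orth=pd.Series(p_o, index=cols, name="o1"),
            weights_pred=pd.Series(w_p, index=cols, name="w_pred"),
            weights_orth=pd.Series(w_o, index=cols, name="w_orth"),
            coef_y=float(c),
            r2x_pred=r2x_pred,
            r2x_orth=r2x_orth,
            r2y=r2y,
            q2=q2,
            center_x=pd.Series(mu_x, index=cols),
            scale_x=pd.Series(sd_x, index=cols),
            center_y=float(mu_y),
        )

    def _loo_q2(self) -> float:
        """Leave-one-strain-out predictive Q^2."""
        X = self.X.to_numpy()
        y = self.y.to_numpy()
        n = len(y)
        press = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            Xi, yi = X[mask], y[mask]
            Xc, yc, mu_x, sd_x, mu_y = self._prepare(Xi, yi)
            sd_x = np.where(sd_x == 0, 1.0, sd_x)
            try:
                w_p, t_p, p_p, c, w_o, t_o, p_o = _opls_core(Xc, yc)
            except ValueError:
                continue
            x_new = (X[i] - mu_x) / sd_x
            t_o_new = x_new @ w_o
            x_corr = x_new - t_o_new * p_o
            y_hat = mu_y + (x_corr @ w_p) * c
            press += (y[i] - y_hat) ** 2
        ss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - press / ss if ss > 0 else np.nan


@dataclass
class OPLSResults:
    """Fitted scores, loadings and fit statistics of a 1+1 OPLS model."""

    model: OPLS
    scores_pred: pd.Series
    scores_orth: pd.Series
    loadings_pred: pd.Series
    loadings_orth: pd.Series
    weights_pred: pd.Series
    weights_orth: pd.Series
    coef_y: float
    r2x_pred: float
    r2x_orth: float
    r2y: float
    q2: float
    center_x: pd.Series
    scale_x: pd.Series
    center_y: float

    def summary(self) -> pd.Series:
        return pd.Series({
            "n_strains": len(self.scores_pred),
            "n_proteins": len(self.loadings_pred),
            "R2X_pred": self.r2x_pred,
            "R2X_orth": self.r2x_orth,
            "R2Y": self.r2y,
            "Q2": self.q2,
        })


def fit_opls(X: pd.DataFrame, y: pd.Series, scale: bool = True,
             cross_validate: bool = True) -> OPLSResults:
    """Convenience wrapper around ``OPLS(X, y).fit()``."""
    return OPLS(X, y, scale=scale).fit(cross_validate=cross_validate)


def export_loadings(results: OPLSResults,
                    corr_results: pd.DataFrame) -> pd.DataFrame:
    """Per-protein prioritization table combining loadings and correlations.

    ``corr_results`` is a correlate_features output restricted to the
    modelled trait; rows are matched on protein id and must cover the
    retained proteins exactly.
    """
    corr = corr_results.set_index("feature_a")
    prots = results.loadings_pred.index
    missing = prots.difference(corr.index)
    if len(missing):
        raise ValueError(
            f"correlation results missing proteins: {list(missing)[:5]}"
        )
    out = pd.DataFrame({
        "protein_id": prots,
        "p1": results.loadings_pred.to_numpy(),
        "o1": results.loadings_orth.to_numpy(),
        "r": corr.loc[prots, "r"].to_numpy(),
        "p": corr.loc[prots, "p"].to_numpy(),
        "selected": corr.loc[prots, "selected"].to_numpy(),
    })
    return out.reset_index(drop=True)
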