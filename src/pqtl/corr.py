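"""Reproducibility, normalization, robust correlation and differential tests.

Covers the strain-level statistics layer: quantile normalization and
strain-mean aggregation, intra/inter-strain coefficients of variation,
biweight midcorrelation (bicor) with Student-t p-values and BH q-values,
correlation-network edges, one-way ANOVA repeatability, and pooled/paired
Student t-tests with BH FDR for screen-style comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, TraitTable
from .multitest import qvalues

log = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize", "strain_aggregate", "cv_report", "bicor",
    "correlate_features", "correlate_pairs", "network_edges",
    "repeatability", "differential",
]


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the rank-average reference distribution.

    The reference is the mean across columns of the sorted values; each
    column's values are replaced by the reference value at their rank,
    tied values sharing the mean of their rank slots.  Columns with
    missing values are mapped through interpolated reference quantiles.
    """
    X = df.to_numpy(dtype=float)
    n, m = X.shape
    counts = (~np.isnan(X)).sum(axis=0)
    full = counts == n
    if full.all():
        ref = np.mean(np.sort(X, axis=0), axis=1)
    else:
        # reference from complete columns if any, else interpolate per column
        if full.any():
            ref = np.mean(np.sort(X[:, full], axis=0), axis=1)
        else:
            ref = np.nanmean(np.sort(X, axis=0), axis=1)
            ref = ref[~np.isnan(ref)]
    out = np.full_like(X, np.nan)
    for j in range(m):
        obs = ~np.isnan(X[:, j])
        k = obs.sum()
        if k == 0:
            continue
        ranks = stats.rankdata(X[obs, j], method="average")
        if k == len(ref):
            vals = np.interp(ranks, np.arange(1, k + 1), ref)
        else:
            qs = (ranks - 0.5) / k
            vals = np.quantile(ref, qs)
        out[obs, j] = vals
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def strain_aggregate(ab: AbundanceMatrix,
                     normalize: bool = False) -> pd.DataFrame:
    """Collapse samples to strain means (optionally quantile-normalizing
    samples first); a strain with no non-missing sample stays missing."""
    vals = ab.values
    if normalize:
        # samples are columns for QN of the sample distributions
        vals = quantile_normalize(vals.T).T
    return vals.groupby(ab.sample_to_strain).mean()


def cv_report(ab: AbundanceMatrix) -> dict:
    """Intra- and inter-strain coefficients of variation (percent).

    Log2 ratios are delogged to linear scale first; intra-strain CV is
    the per-protein median across strains with >= 2 replicates of
    100 * sd / mean, inter-strain CV is 100 * sd / mean across strain
    means.  Returns per-protein series and panel-level medians.
    """
    linear = 2.0 ** ab.values
    groups = linear.groupby(ab.sample_to_strain)
    n_rep = groups.count()
    g_mean = groups.mean()
    g_sd = groups.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * g_sd / g_mean
    cv = cv.where(n_rep >= 2)
    intra = cv.median(axis=0, skipna=True)
    strain_means = g_mean.where(n_rep >= 1)
    inter = 100.0 * strain_means.std(axis=0, ddof=1) / strain_means.mean(axis=0)
    return {
        "intra_strain_cv": intra,
        "inter_strain_cv": inter,
        "median_intra": float(intra.median(skipna=True)),
        "median_inter": float(inter.median(skipna=True)),
    }


def _bicor_transform(v: np.ndarray):
    """Median/MAD biweight transform; None signals zero MAD."""
    med = np.median(v)
    d = v - med
    mad = np.median(np.abs(d))
    if mad == 0:
        return None
    u = d / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return d * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two complete vectors.

    Observations are weighted by (1 - u^2)^2 with u the deviation from
    the median in units of 9 * MAD (unscaled), zeroing values beyond it,
    which makes the coefficient robust to gross outliers.  A zero-MAD
    vector triggers a Pearson fallback (logged); a constant vector gives
    NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("bicor needs two equal-length vectors, n >= 3")
    tx, ty = _bicor_transform(x), _bicor_transform(y)
    if tx is None or ty is None:
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        log.info("zero MAD; falling back to Pearson correlation")
        return float(stats.pearsonr(x, y)[0])
    denom = np.sqrt(np.sum(tx**2) * np.sum(ty**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(tx * ty) / denom)


def _corr_test(r: float, n: int) -> float:
    """Two-sided Student p for a correlation on n - 2 df."""
    if not np.isfinite(r) or n < 3:
        return float("nan")
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return np.nextafter(0.0, 1.0)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_features(strain_matrix: pd.DataFrame, traits: TraitTable,
                       r_low: float = -0.3, r_high: float = 0.6,
                       p_cut: float = 0.05) -> pd.DataFrame:
    """Pairwise-complete bicor of every (protein, trait) pair.

    Emits r, the Student t p-value, BH q across all pairs, and a
    ``selected`` flag for pairs with (r <= r_low or r >= r_high) and
    p < p_cut — the magnitude-plus-significance filter used to shortlist
    trait-associated proteins.
    """
    shared = strain_matrix.index.intersection(traits.values.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared strains")
    X = strain_matrix.loc[shared]
    T = traits.values.loc[shared]
    rows = []
    for trait in T.columns:
        tv = T[trait].to_numpy()
        for prot in X.columns:
            pv = X[prot].to_numpy()
            ok = ~(np.isnan(pv) | np.isnan(tv))
            n = int(ok.sum())
            r = bicor(pv[ok], tv[ok]) if n >= 3 else float("nan")
            rows.append((prot, trait, n, r, _corr_test(r, n)))
    out = pd.DataFrame(rows, columns=["feature_a", "feature_b", "n", "r", "p"])
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = qvalues(out.loc[ok, "p"].to_numpy(), method="bh")
    out["selected"] = ((out["r"] <= r_low) | (out["r"] >= r_high)) & \
        (out["p"] < p_cut)
    return out


def correlate_pairs(strain_matrix: pd.DataFrame) -> pd.DataFrame:
    """All protein-protein bicor pairs (upper triangle) with p and BH q."""
    cols = list(strain_matrix.columns)
    X = strain_matrix.to_numpy(dtype=float)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            ok = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
            n = int(ok.sum())
            r = bicor(X[ok, i], X[ok, j]) if n >= 3 else float("nan")
            rows.append((cols[i], cols[j], n, r, _corr_test(r, n)))
    out = pd.DataFrame(rows, columns=["feature_a", "feature_b", "n", "r", "p"])
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = qvalues(out.loc[ok, "p"].to_numpy(), method="bh")
    return out


def network_edges(results: pd.DataFrame, r_cutoff: float,
                  q_cut: float = 0.05) -> tuple[pd.DataFrame, pd.Series]:
    """Correlation-network edge list: pairs with |r| >= cutoff and q < q_cut.

    Returns the (undirected, deduplicated) edge table and a node-degree
    series.
    """
    ok = (results["r"].abs() >= r_cutoff) & (results["q"] < q_cut)
    edges = results.loc[ok, ["feature_a", "feature_b", "r", "q"]].copy()
    key = edges.apply(lambda r: tuple(sorted((r["feature_a"], r["feature_b"]))),
                      axis=1)
    edges = edges.loc[~key.duplicated()].reset_index(drop=True)
    degree = pd.concat([edges["feature_a"], edges["feature_b"]]
                       ).value_counts().sort_index()
    return edges, degree


def repeatability(values: pd.DataFrame) -> pd.Series:
    """Genetic repeatability R from a strain x replicate value table.

    One-way random-effects ANOVA: sigma2_within = MS_within,
    sigma2_between = max(0, (MS_between - MS_within) / n0) with
    n0 = (N - sum(n_i^2) / N) / (a - 1) the unbalanced-design group size,
    and R = sigma2_between / (sigma2_between + sigma2_within).

    ``values`` rows are strains, columns replicates (NaN for absent
    replicates).
    """
    groups = [row[~np.isnan(row)] for row in values.to_numpy(dtype=float)]
    groups = [g for g in groups if len(g) >= 1]
    a = len(groups)
    if a < 2 or sum(len(g) >= 2 for g in groups) < 2:
        raise ValueError("repeatability needs >= 2 strains with >= 2 replicates")
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - sum(len(g) ** 2 for g in groups) / N) / (a - 1)
    s2_between = max(0.0, (ms_between - ms_within) / n0)
    denom = s2_between + ms_within
    R = s2_between / denom if denom > 0 else 0.0
    return pd.Series({
        "R": R,
        "sigma2_between": s2_between,
        "sigma2_within": ms_within,
    })


def differential(data: pd.DataFrame, group_a, group_b,
                 paired: bool = False) -> pd.DataFrame:
    """Per-feature Student t-tests between two sample groups with BH FDR.

    ``data`` is samples x features; ``group_a`` / ``group_b`` are sample
    id lists.  Unpaired uses the classical pooled-variance two-sample t;
    paired pairs samples by list position and tests the differences.
    Zero-variance degenerate features get a missing p with a flag.
    """
    A = data.loc[list(group_a)].to_numpy(dtype=float)
    B = data.loc[list(group_b)].to_numpy(dtype=float)
    if paired and A.shape[0] != B.shape[0]:
        raise ValueError("paired groups must have equal size")
    if (A.shape[0] < 2) or (B.shape[0] < 2):
        raise ValueError("need >= 2 observations per group")
    rows = []
    for j, feat in enumerate(data.columns):
        x, y = A[:, j], B[:, j]
        ok_x, ok_y = ~np.isnan(x), ~np.isnan(y)
        if paired:
            ok = ok_x & ok_y
            d = x[ok] - y[ok]
            mean_diff = float(d.mean()) if len(d) else np.nan
            if len(d) < 2 or d.std(ddof=1) == 0:
                rows.append((feat, mean_diff, np.nan, np.nan, True))
                continue
            t, p = stats.ttest_rel(x[ok], y[ok])
        else:
            x, y = x[ok_x], y[ok_y]
            mean_diff = float(x.mean() - y.mean())
            if len(x) < 2 or len(y) < 2 or (x.std(ddof=1) == 0 and
                                            y.std(ddof=1) == 0):
                rows.append((feat, mean_diff, np.nan, np.nan, True))
                continue
            t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append((feat, mean_diff, float(t), float(p), False))
    out = pd.DataFrame(rows, columns=["feature_id", "mean_diff", "t", "p",
                                      "degenerate"])
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = qvalues(out.loc[ok, "p"].to_numpy(), method="bh")
    return out
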