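"""REML mixed-model engine: closed-form and brute-force oracles,
optimality, parameter recovery and calibration at unit-test scale."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pqtl.kinship import KinshipMatrix, ibs_kinship
from pqtl.lmm import KinshipMixedModel, assoc_scan, fit_null

from conftest import identity_kinship, make_panel, tiny_sim_config
from pqtl.simulate import simulate_genotypes


def direct_gls_oracle(y, x, K, sigma_u2, sigma_e2):
    """Textbook GLS with V = sigma_u2 K + sigma_e2 I formed explicitly."""
    n = len(y)
    V = sigma_u2 * K + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    resid = y - X @ beta
    rss = float(resid @ Vi @ resid)
    # rescale the working covariance by the per-SNP residual variance
    sigma2 = rss / (n - 2)
    var_beta = sigma2 * np.linalg.inv(A)[1, 1]
    F = beta[1] ** 2 / var_beta
    return float(stats.f.sf(F, 1, n - 2))


def _simulated_y(K, h2, rng, n=None):
    n = n or K.shape[0]
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    u = np.sqrt(h2) * (L @ rng.standard_normal(n))
    e = np.sqrt(1 - h2) * rng.standard_normal(n)
    return u + e


def test_identity_kinship_recovers_sample_variance(rng):
    # with K = I the rotated model is i.i.d.; total variance = REML variance
    n = 50
    kin = identity_kinship(n)
    y = pd.Series(rng.normal(2.0, 1.5, size=n), index=kin.strain_ids)
    fit = fit_null(y, kin)
    total = fit.sigma_u2 + fit.sigma_e2
    assert total == pytest.approx(float(y.var(ddof=1)), abs=1e-6)
    assert fit.mu == pytest.approx(float(y.mean()), abs=1e-8)


def test_reml_loglik_is_maximal_at_estimate(tiny_sim, rng):
    kin = tiny_sim["kinship"]
    y = pd.Series(_simulated_y(kin.values.to_numpy(), 0.5, rng),
                  index=kin.strain_ids)
    model = KinshipMixedModel(y, kin)
    fit = model.fit()
    ll_opt = model.reml_loglik(fit.delta)
    for delta in np.logspace(-5, 5, 60):
        assert model.reml_loglik(delta) <= ll_opt + 1e-9


def test_delta_recovery_equal_variances():
    # sigma_u2 = sigma_e2 = 1 on 200 simulated strains -> delta in [0.5, 2]
    panel, _ = simulate_genotypes(tiny_sim_config(
        seed=11, n_strains=200, n_snps=400))
    kin = ibs_kinship(panel)
    K = kin.values.to_numpy()
    deltas = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        y = pd.Series(_simulated_y(K, 0.5, rng), index=kin.strain_ids)
        deltas.append(fit_null(y, kin).delta)
    med = np.median(deltas)
    assert 0.5 <= med <= 2.0
    assert np.mean([(0.5 <= d <= 2.0) for d in deltas]) >= 0.75


def test_scan_with_identity_kinship_equals_ols_ftest(rng):
    n = 40
    kin = identity_kinship(n)
    dosage = rng.choice([0.0, 2.0], size=(n, 25))
    panel = make_panel(dosage)
    y = pd.Series(rng.normal(size=n), index=kin.strain_ids)
    tab = assoc_scan(y, panel, kin, maf_min=0.01)
    for row in tab.itertuples():
        x = dosage[:, int(row.snp_id[3:])]
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
        assert row.p == pytest.approx(ols.f_pvalue, abs=1e-8)
        assert row.beta == pytest.approx(ols.params[1], abs=1e-8)


def test_scan_matches_direct_gls_oracle(rng):
    panel, _ = simulate_genotypes(tiny_sim_config(seed=3, n_strains=25,
                                                  n_snps=60))
    kin = ibs_kinship(panel)
    K = kin.values.to_numpy()
    y = pd.Series(_simulated_y(K, 0.6, rng), index=kin.strain_ids)
    fit = fit_null(y, kin)
    tab = fit.scan(panel, maf_min=0.05)
    dosage = panel.dosage
    for row in tab.sample(25, random_state=0).itertuples():
        p_oracle = direct_gls_oracle(y.to_numpy(),
                                     dosage[row.snp_id].to_numpy(), K,
                                     fit.sigma_u2, fit.sigma_e2)
        assert row.p == pytest.approx(p_oracle, abs=1e-8)


def test_missing_genotypes_dropped_pairwise(rng):
    panel, _ = simulate_genotypes(tiny_sim_config(seed=5, n_strains=30,
                                                  n_snps=60))
    dosage = panel.dosage.copy()
    dosage.iloc[:5, 0] = np.nan
    panel_m = make_panel(dosage.to_numpy(),
                         chrom=panel.snp_meta["chrom"].tolist(),
                         pos=panel.snp_meta["pos"].tolist())
    panel_m.dosage.index = dosage.index
    panel_m.dosage.columns = dosage.columns
    panel_m.snp_meta.index = dosage.columns
    kin = ibs_kinship(panel)
    y = pd.Series(_simulated_y(kin.values.to_numpy(), 0.4, rng),
                  index=kin.strain_ids)
    fit = fit_null(y, kin)
    tab = fit.scan(panel_m, maf_min=0.05).set_index("snp_id")
    first = dosage.columns[0]
    if first in tab.index:
        assert tab.loc[first, "n"] == 25


def test_power_planted_effect_is_detected():
    panel, _ = simulate_genotypes(tiny_sim_config(seed=21, n_strains=75,
                                                  n_snps=120))
    kin = ibs_kinship(panel)
    K = kin.values.to_numpy()
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(300 + seed)
        x = panel.dosage.iloc[:, 10].to_numpy()
        beta = np.sqrt(1.0 / np.var(x, ddof=1))  # VE = 50% of unit base var
        y = pd.Series(x * beta + _simulated_y(K, 0.4, rng),
                      index=kin.strain_ids)
        tab = fit_null(y, kin).scan(panel).set_index("snp_id")
        if tab.loc[panel.snp_ids[10], "p"] < 1e-4:
            hits += 1
    assert hits >= int(0.9 * n_seeds)


def test_zero_variance_feature_rejected():
    kin = identity_kinship(12)
    y = pd.Series(np.ones(12), index=kin.strain_ids)
    with pytest.raises(ValueError, match="zero variance"):
        KinshipMixedModel(y, kin)


def test_non_psd_kinship_rejected():
    n = 10
    ids = pd.Index([f"s{i}" for i in range(n)])
    K = np.eye(n)
    K[0, 1] = K[1, 0] = 1.2  # violates PSD badly
    K = pd.DataFrame(np.clip(K, 0, 1) * 0 + K, index=ids, columns=ids)
    with pytest.raises(ValueError):
        # either the [0,1]-range check or the PSD check must fire
        from pqtl.kinship import KinshipMatrix
        kin = KinshipMatrix(K)
        KinshipMixedModel(pd.Series(np.random.default_rng(0).normal(size=n),
                                    index=ids), kin)


def test_monomorphic_snps_skipped(rng):
    n = 20
    kin = identity_kinship(n)
    dosage = np.zeros((n, 4))
    dosage[:, 0] = rng.choice([0.0, 2.0], size=n)
    panel = make_panel(dosage)
    y = pd.Series(rng.normal(size=n), index=kin.strain_ids)
    fit = fit_null(y, kin)
    tab = fit.scan(panel, maf_min=0.05)
    assert set(tab["snp_id"]) <= {"snp0"}
    assert fit.n_skipped_snps == 3


def test_heritability_bounds(tiny_sim, rng):
    kin = tiny_sim["kinship"]
    y = pd.Series(_simulated_y(kin.values.to_numpy(), 0.7, rng),
                  index=kin.strain_ids)
    fit = fit_null(y, kin)
    assert 0.0 <= fit.heritability <= 1.0
    assert fit.delta > 0 and fit.sigma_u2 >= 0 and fit.sigma_e2 >= 0
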