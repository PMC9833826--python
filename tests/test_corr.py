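"""Quantile normalization, CV, bicor, correlation filtering, network
edges, repeatability and differential tests against brute-force oracles."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pqtl.corr import (bicor, correlate_features, correlate_pairs, cv_report,
                       differential, network_edges, quantile_normalize,
                       repeatability, strain_aggregate)
from pqtl.datatypes import AbundanceMatrix, TraitTable


def bicor_oracle(x, y):
    """Direct formula evaluation, written independently of the package."""
    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w
    a, b = transform(np.asarray(x, float)), transform(np.asarray(y, float))
    return np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2))


# ---------------------------------------------------------------- QN ----


def test_qn_hand_grid():
    # columns are samples; brute-force rank/average oracle by hand:
    # sorted col means: rank1 (1+2)/2=1.5, rank2 (3+4)/2=3.5, rank3 (5+6)/2=5.5
    df = pd.DataFrame({"s1": [1.0, 3.0, 5.0], "s2": [6.0, 2.0, 4.0]})
    out = quantile_normalize(df)
    assert np.allclose(out["s1"], [1.5, 3.5, 5.5])
    assert np.allclose(out["s2"], [5.5, 1.5, 3.5])


def test_qn_monotone_transforms_collapse():
    x = np.array([0.1, 2.0, -1.0, 0.7, 1.1])
    df = pd.DataFrame({"a": x, "b": np.exp(x)})
    out = quantile_normalize(df)
    assert np.allclose(out["a"], out["b"])


def test_qn_ties_share_mean_rank_slot():
    df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
    out = quantile_normalize(df)
    assert out["a"][0] == out["a"][1]


# ------------------------------------------------------- aggregation ----


def _ab(values, strains):
    values = pd.DataFrame(values,
                          index=[f"x{i}" for i in range(len(values))])
    return AbundanceMatrix(values,
                           pd.Series(strains, index=values.index))


def test_strain_mean_of_identical_samples():
    ab = _ab([[1.0, 2.0], [1.0, 2.0], [0.0, 4.0]], ["A", "A", "B"])
    sm = strain_aggregate(ab)
    assert np.allclose(sm.loc["A"], [1.0, 2.0])
    assert np.allclose(sm.loc["B"], [0.0, 4.0])


def test_strain_with_no_observation_stays_missing():
    ab = _ab([[np.nan], [np.nan], [1.0]], ["A", "A", "B"])
    sm = strain_aggregate(ab)
    assert np.isnan(sm.loc["A", 0])


# ------------------------------------------------------------- CV ----


def test_cv_hand_value_ten_percent():
    # linear replicates 0.9, 1.0, 1.1: sd 0.1, mean 1.0 -> 10.0%
    vals = np.log2([[0.9], [1.0], [1.1]])
    ab = _ab(vals, ["A", "A", "A"])
    # single strain: need a second strain for the inter CV path
    vals2 = np.log2([[0.9], [1.0], [1.1], [1.2], [1.2]])
    ab = _ab(vals2, ["A", "A", "A", "B", "B"])
    rep = cv_report(ab)
    assert rep["intra_strain_cv"].iloc[0] == pytest.approx(
        np.mean([10.0, 0.0]), abs=1e-9)  # median of {10.0 (A), 0.0 (B)}


def test_cv_zero_for_identical_replicates():
    ab = _ab([[0.5], [0.5], [1.5], [1.5]], ["A", "A", "B", "B"])
    rep = cv_report(ab)
    assert rep["median_intra"] == pytest.approx(0.0)
    assert rep["median_inter"] > 0


def test_cv_increases_with_replicate_noise(rng):
    meds = []
    for sd in (0.05, 0.15, 0.3):
        base = rng.normal(size=(20, 30))
        vals = np.repeat(base, 3, axis=0) + rng.normal(
            0, sd, size=(60, 30))
        strains = np.repeat([f"s{i}" for i in range(20)], 3)
        meds.append(cv_report(_ab(vals, strains))["median_intra"])
    assert meds[0] < meds[1] < meds[2]


def test_cv_invariant_to_protein_order_and_empty_strains(rng):
    vals = rng.normal(size=(12, 6))
    strains = np.repeat(["a", "b", "c", "d"], 3)
    ab = _ab(vals, strains)
    rep1 = cv_report(ab)
    shuffled = ab.values[list(ab.values.columns[::-1])]
    ab2 = AbundanceMatrix(shuffled, ab.sample_to_strain)
    rep2 = cv_report(ab2)
    assert rep1["median_intra"] == rep2["median_intra"]
    # adding a strain with all-missing rows changes nothing
    extra = pd.DataFrame(np.nan, index=["z1", "z2"],
                         columns=ab.values.columns)
    ab3 = AbundanceMatrix(pd.concat([ab.values, extra]),
                          pd.concat([ab.sample_to_strain,
                                     pd.Series({"z1": "z", "z2": "z"})]))
    assert cv_report(ab3)["median_intra"] == rep1["median_intra"]


# ---------------------------------------------------------- bicor ----


def test_bicor_self_and_antisymmetry(rng):
    x = rng.normal(size=30)
    assert bicor(x, x) == pytest.approx(1.0)
    assert bicor(x, -x) == pytest.approx(-1.0)


def test_bicor_outlier_fixture_matches_oracle():
    # one gross y outlier at a central x deflates Pearson but not bicor
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    y = np.array([1.1, 2.2, 2.8, 50.0, 5.2, 5.8, 7.1, 7.9])
    r = bicor(x, y)
    assert r == pytest.approx(bicor_oracle(x, y), abs=1e-12)
    assert abs(r) > abs(stats.pearsonr(x, y)[0])


def test_bicor_matches_oracle_random(rng):
    for _ in range(20):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)


def test_bicor_zero_mad_falls_back_to_pearson(rng):
    x = np.array([1.0] * 8 + [2.0, 3.0])  # median-heavy: MAD = 0
    y = rng.normal(size=10)
    assert bicor(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)


def test_bicor_constant_vector_is_missing():
    assert np.isnan(bicor(np.ones(5), np.arange(5.0)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
def test_bicor_affine_invariance(seed, scale, shift):
    r = np.random.default_rng(seed)
    x, y = r.normal(size=12), r.normal(size=12)
    base = bicor(x, y)
    assert bicor(scale * x + shift, y) == pytest.approx(base, abs=1e-10)
    assert bicor(-x, y) == pytest.approx(-base, abs=1e-10)


# ------------------------------------------------ correlate / network ----


def test_correlation_p_closed_forms(rng):
    strains = [f"s{i}" for i in range(20)]
    x = rng.normal(size=20)
    sm = pd.DataFrame({"p1": x}, index=strains)
    traits = TraitTable(pd.DataFrame({"t_same": x}, index=strains))
    out = correlate_features(sm, traits)
    row = out.iloc[0]
    assert row["r"] == pytest.approx(1.0)
    assert row["p"] < 1e-12
    assert bool(row["selected"])


def test_missing_trait_rejected(rng):
    sm = pd.DataFrame(rng.normal(size=(10, 2)),
                      index=[f"s{i}" for i in range(10)])
    traits = TraitTable(pd.DataFrame(rng.normal(size=(2, 1)),
                                     index=["s0", "s1"], columns=["t"]))
    with pytest.raises(ValueError, match="shared strains"):
        correlate_features(sm, traits)


def test_selection_filter_is_a_union(rng):
    strains = [f"s{i}" for i in range(50)]
    base = rng.normal(size=50)
    sm = pd.DataFrame({
        "pos": base + rng.normal(0, 0.5, 50),       # strong positive
        "neg": -base + rng.normal(0, 1.5, 50),      # moderate negative
        "null": rng.normal(size=50),
    }, index=strains)
    traits = TraitTable(pd.DataFrame({"t": base}, index=strains))
    out = correlate_features(sm, traits).set_index("feature_a")
    assert bool(out.loc["pos", "selected"])
    if out.loc["neg", "r"] <= -0.3 and out.loc["neg", "p"] < 0.05:
        assert bool(out.loc["neg", "selected"])
    # a mid-magnitude positive r in (−0.3, 0.6) is never selected
    mid = out[(out["r"] > -0.3) & (out["r"] < 0.6)]
    assert not mid["selected"].any()


def test_network_edges_symmetric_and_thresholded(rng):
    strains = [f"s{i}" for i in range(30)]
    shared = rng.normal(size=30)
    sm = pd.DataFrame({
        "a": shared + rng.normal(0, 0.1, 30),
        "b": shared + rng.normal(0, 0.1, 30),
        "c": rng.normal(size=30),
    }, index=strains)
    results = correlate_pairs(sm)
    edges, degree = network_edges(results, r_cutoff=0.8)
    pairs = set(map(tuple, edges[["feature_a", "feature_b"]].to_numpy()))
    assert ("a", "b") in pairs or ("b", "a") in pairs
    assert len(pairs) == len(edges)  # each edge exactly once
    assert degree.get("a", 0) >= 1
    edges_all, _ = network_edges(results, r_cutoff=1.0)
    assert len(edges_all) == 0


def test_coregulated_block_forms_connected_component(rng):
    import networkx as nx
    strains = [f"s{i}" for i in range(40)]
    driver = rng.normal(size=40)
    cols = {f"blk{i}": driver + rng.normal(0, 0.3, 40) for i in range(5)}
    cols.update({f"noise{i}": rng.normal(size=40) for i in range(5)})
    sm = pd.DataFrame(cols, index=strains)
    edges, _ = network_edges(correlate_pairs(sm), r_cutoff=0.6)
    g = nx.Graph(list(map(tuple, edges[["feature_a", "feature_b"]].to_numpy())))
    comp = nx.node_connected_component(g, "blk0")
    assert {f"blk{i}" for i in range(5)} <= comp


# -------------------------------------------------------- repeatability ----


def test_repeatability_limits():
    perfect = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    assert repeatability(perfect)["R"] == pytest.approx(1.0)
    flat = pd.DataFrame([[1.0, 3.0], [2.0, 2.0], [1.5, 2.5]])
    # strain means all equal -> negative between-component clipped to 0
    assert repeatability(flat)["R"] == pytest.approx(0.0)


def test_repeatability_single_strain_rejected():
    with pytest.raises(ValueError):
        repeatability(pd.DataFrame([[1.0, 2.0]]))


def test_repeatability_matches_pingouin_icc(rng):
    vals = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1)) * 1.5
    R = repeatability(pd.DataFrame(vals))["R"]
    long = pd.DataFrame({
        "strain": np.repeat(np.arange(10), 4),
        "rater": np.tile(np.arange(4), 10),
        "y": vals.ravel(),
    })
    icc = pg.intraclass_corr(long, targets="strain", raters="rater",
                             ratings="y")
    icc1 = float(icc["ICC"].iloc[0])  # first row: one-way random, ICC(1,1)
    assert R == pytest.approx(icc1, abs=1e-10)


def test_repeatability_recovery_balanced_variances():
    Rs = []
    for seed in range(50):
        r = np.random.default_rng(seed)
        between = r.normal(0, 1.0, size=(20, 1))
        vals = between + r.normal(0, 1.0, size=(20, 4))
        Rs.append(repeatability(pd.DataFrame(vals))["R"])
    assert np.mean(Rs) == pytest.approx(0.5, abs=0.1)


# --------------------------------------------------------- differential ----


def test_unpaired_t_hand_value():
    data = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
                        index=list("abcdef"))
    out = differential(data, ["a", "b", "c"], ["d", "e", "f"])
    assert abs(out.loc[0, "t"]) == pytest.approx(3.674, abs=1e-3)
    assert out.loc[0, "p"] == pytest.approx(0.0213, abs=2e-4)


def test_paired_t_hand_value():
    # diffs 0.5, 1.0, 1.5: t = 3.464, df = 2, p ~ 0.0742
    data = pd.DataFrame({"f": [1.5, 2.0, 2.5, 1.0, 1.0, 1.0]},
                        index=list("abcdef"))
    out = differential(data, ["a", "b", "c"], ["d", "e", "f"], paired=True)
    assert out.loc[0, "t"] == pytest.approx(3.464, abs=1e-3)
    assert out.loc[0, "p"] == pytest.approx(0.0742, abs=2e-4)


def test_identical_groups_t_zero_p_one():
    data = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                        index=list("abcdef"))
    out = differential(data, ["a", "b", "c"], ["d", "e", "f"])
    assert out.loc[0, "t"] == pytest.approx(0.0)
    assert out.loc[0, "p"] == pytest.approx(1.0)


def test_degenerate_feature_flagged():
    data = pd.DataFrame({"f": [1.0, 1.0, 2.0, 2.0]}, index=list("abcd"))
    out = differential(data, ["a", "b"], ["c", "d"])
    assert bool(out.loc[0, "degenerate"])
    assert np.isnan(out.loc[0, "p"])


def test_bh_q_across_features_matches_oracle(rng):
    from statsmodels.stats.multitest import multipletests
    data = pd.DataFrame(rng.normal(size=(10, 25)),
                        index=[f"x{i}" for i in range(10)])
    out = differential(data, [f"x{i}" for i in range(5)],
                       [f"x{i}" for i in range(5, 10)])
    q_sm = multipletests(out["p"], method="fdr_bh")[1]
    assert np.allclose(out["q"], q_sm, atol=1e-12)
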