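"""Scaling, Pearson dissimilarity, ward.D, OLO, elbow, bootstrap,
enrichment, the supervised scheme, cohort comparison, PCA cos2."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from scarscape.clustering import (choose_k_elbow, classify_tcga, cluster,
                                  cluster_enrichment, compare_cohorts,
                                  optimal_leaf_order, pca_cos2,
                                  pearson_dissimilarity, scale_features,
                                  bootstrap_support, ward_linkage)


def _df(X, prefix="s"):
    return pd.DataFrame(np.asarray(X, dtype=float),
                        index=[f"{prefix}{i}" for i in range(len(X))])


# ---------------------------------------------------------------------------
# scaling and dissimilarity
# ---------------------------------------------------------------------------

def test_scale_features_rms_contract():
    scaled = scale_features(_df([[3.0, 1.0], [4.0, 2.0]]))
    # column [3,4]: rms = sqrt((9+16)/1) = 5
    assert scaled.iloc[:, 0].to_list() == pytest.approx([3 / 5, 4 / 5])
    rms = np.sqrt((scaled.to_numpy() ** 2).sum(axis=0) / (len(scaled) - 1))
    assert rms == pytest.approx([1.0, 1.0])


def test_scaling_is_idempotent(rng):
    m = _df(rng.random((10, 4)) + 0.1)
    once = scale_features(m)
    twice = scale_features(once)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_scale_features_matches_per_column_formula(rng):
    X = rng.random((20, 6)) + 0.05
    scaled = scale_features(_df(X)).to_numpy()
    expected = X / np.sqrt((X ** 2).sum(axis=0) / (X.shape[0] - 1))
    assert np.allclose(scaled, expected, atol=1e-12)


def test_scale_features_names_zero_column():
    m = _df([[1.0, 0.0], [2.0, 0.0]])
    m.columns = ["good", "dead"]
    with pytest.raises(ValueError, match="dead"):
        scale_features(m)


def test_pearson_dissimilarity_identical_and_anticorrelated():
    d = pearson_dissimilarity(_df([[1, 2, 3], [1, 2, 3], [3, 2, 1]]))
    assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert d.iloc[0, 2] == pytest.approx(2.0, abs=1e-12)
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)


def test_pearson_dissimilarity_matches_direct_formula(rng):
    X = rng.random((8, 5))
    d = pearson_dissimilarity(_df(X)).to_numpy()
    for i in range(8):
        for j in range(8):
            r = stats.pearsonr(X[i], X[j]).statistic
            assert d[i, j] == pytest.approx(1 - r, abs=1e-12)


def test_pearson_dissimilarity_rejects_constant_row():
    with pytest.raises(ValueError, match="s1"):
        pearson_dissimilarity(_df([[1, 2, 3], [5, 5, 5]]))


# ---------------------------------------------------------------------------
# ward.D linkage
# ---------------------------------------------------------------------------

# 6-point oracle instance: merge heights computed independently with
# R hclust(method="ward.D") on this exact matrix
WARD_ORACLE_D = np.array([
    [0.,     1.3703, 1.0657, 0.9062, 1.2577, 1.793],
    [1.3703, 0.,     2.0916, 1.6684, 1.4645, 1.8951],
    [1.0657, 2.0916, 0.,     1.3811, 2.3178, 2.7588],
    [0.9062, 1.6684, 1.3811, 0.,     1.6411, 2.3997],
    [1.2577, 1.4645, 2.3178, 1.6411, 0.,     0.8382],
    [1.793,  1.8951, 2.7588, 2.3997, 0.8382, 0.],
])
WARD_ORACLE_HEIGHTS = [0.8382, 0.9062, 1.329133, 1.960333, 3.2492]


def test_ward_heights_match_independent_oracle():
    Z = ward_linkage(WARD_ORACLE_D)
    assert sorted(Z[:, 2]) == pytest.approx(WARD_ORACLE_HEIGHTS, abs=1e-6)
    # first merges mirror the oracle tree: (4,5) then (0,3)
    assert set(Z[0, :2]) == {4, 5}
    assert set(Z[1, :2]) == {0, 3}


def hand_lance_williams(D):
    """Transparent dict-based ward.D recursion used as an oracle."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        si, sj = len(clusters[i]), len(clusters[j])
        new = {}
        for (a, b), dab in dist.items():
            if len({a, b} & {i, j}) == 0:
                new[(a, b)] = dab
        for k in clusters:
            if k in (i, j):
                continue
            sk = len(clusters[k])
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new[tuple(sorted((k, next_id)))] = (
                (si + sk) * dik + (sj + sk) * djk - sk * h) / (si + sj + sk)
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        dist = new
        next_id += 1
    return heights


def test_ward_matches_hand_recursion_on_random_instances(rng):
    for _ in range(20):
        X = rng.normal(size=(6, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        Z = ward_linkage(D)
        assert list(Z[:, 2]) == pytest.approx(hand_lance_williams(D), abs=1e-9)


def test_ward_identical_samples_merge_first_at_zero():
    X = np.array([[0., 0], [5, 5], [0, 0], [9, 1]])
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    Z = ward_linkage(D)
    assert set(Z[0, :2]) == {0, 2}
    assert Z[0, 2] == 0.0


def test_ward_duplicating_a_sample_keeps_other_topology(rng):
    for _ in range(5):
        X = rng.normal(size=(6, 3)) * 3
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        Z = ward_linkage(D)

        Xd = np.vstack([X, X[2] + rng.normal(0, 1e-9, size=3)])
        Dd = np.sqrt(((Xd[:, None, :] - Xd[None, :, :]) ** 2).sum(-1))
        Zd = ward_linkage(Dd)
        # the duplicate merges with its twin first, at ~zero height
        assert set(Zd[0, :2]) == {2, 6}
        assert Zd[0, 2] < 1e-6


def test_ward_rejects_nan():
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 0] = np.nan
    with pytest.raises(ValueError):
        ward_linkage(D)


# ---------------------------------------------------------------------------
# optimal leaf ordering
# ---------------------------------------------------------------------------

def _tree_orders(Z, n):
    """All leaf orders consistent with the tree (flip any internal node)."""
    members = {i: [i] for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        members[n + step] = (members[int(a)], members[int(b)])

    def expand(node):
        if isinstance(node, list):
            return [node]
        left, right = node
        outs = []
        for lo in expand(left):
            for ro in expand(right):
                outs.append(lo + ro)
                outs.append(ro + lo)
        return outs

    return expand(members[2 * n - 2])


def test_olo_matches_enumeration_small_n(rng):
    for n in (3, 5):
        for _ in range(10):
            X = rng.normal(size=(n, 3))
            D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            Z = ward_linkage(D)
            order = optimal_leaf_order(Z, D)
            cost = sum(D[a, b] for a, b in zip(order, order[1:]))
            best = min(
                sum(D[a, b] for a, b in zip(o, o[1:]))
                for o in _tree_orders(Z, n))
            assert cost == pytest.approx(best, abs=1e-9)


def test_olo_points_on_a_line_monotone():
    pos = np.array([0.0, 10, 1, 9, 2, 8])
    D = np.abs(pos[:, None] - pos[None, :])
    Z = ward_linkage(D)
    order = optimal_leaf_order(Z, D)
    values = pos[order]
    assert (np.all(np.diff(values) > 0) or np.all(np.diff(values) < 0))


# ---------------------------------------------------------------------------
# elbow and bootstrap
# ---------------------------------------------------------------------------

def _blob_matrix(rng, k=3, per=15, dim=6, sep=8.0):
    centers = rng.normal(size=(k, dim)) * sep
    rows = np.vstack([centers[i] + rng.normal(0, 0.4, size=(per, dim))
                      for i in range(k)])
    return _df(rows + 20.0)  # keep strictly positive for RMS scaling


def test_elbow_recovers_three_blobs(rng):
    m = _blob_matrix(rng)
    scaled = scale_features(m)
    Z = ward_linkage(pearson_dissimilarity(scaled))
    k, table = choose_k_elbow(scaled, Z, k_max=10)
    assert k == 3
    assert (table["wss"].diff().dropna() <= 1e-9).all()


def test_elbow_on_noise_warns_weak_curvature(rng):
    m = _df(rng.random((40, 6)) + 0.5)
    scaled = scale_features(m)
    Z = ward_linkage(pearson_dissimilarity(scaled))
    with pytest.warns(UserWarning, match="weak"):
        choose_k_elbow(scaled, Z, k_max=10)


def test_bootstrap_support_bounds_determinism_and_blobs(rng):
    m = _blob_matrix(rng, k=2, per=8, dim=8, sep=10.0)
    scaled = scale_features(m)
    Z = ward_linkage(pearson_dissimilarity(scaled))
    sup1 = bootstrap_support(m, Z, n_boot=60, seed=4)
    sup2 = bootstrap_support(m, Z, n_boot=60, seed=4)
    assert sup1.equals(sup2)
    assert ((sup1.support >= 0) & (sup1.support <= 1)).all()
    # the two top blobs are rock solid under feature resampling
    top_children = sup1[sup1["size"] == 8]
    assert (top_children.support >= 0.95).all()


def test_full_cluster_run_deterministic(rng):
    m = _blob_matrix(rng, k=3, per=10)
    r1 = cluster(m, n_boot=25, seed=11)
    r2 = cluster(m, n_boot=25, seed=11)
    assert np.array_equal(r1.linkage, r2.linkage)
    assert r1.leaf_order == r2.leaf_order
    assert r1.labels.equals(r2.labels)
    assert r1.bootstrap_support.equals(r2.bootstrap_support)
    assert sorted(r1.labels.unique()) == list(range(1, r1.k + 1))
    assert sorted(r1.leaf_order) == sorted(m.index)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_matches_hypergeometric_enumeration():
    labels = pd.Series([1] * 13 + [2] * 184,
                       index=[f"s{i}" for i in range(197)])
    trait = pd.DataFrame(
        {"geneX": [True] * 11 + [False] * 2 + [True] * 5 + [False] * 179},
        index=labels.index)
    row = cluster_enrichment(labels, trait).query("cluster == 1").iloc[0]
    table = [[11, 2], [5, 179]]
    _, p_expected = stats.fisher_exact(table)
    assert row.p == pytest.approx(p_expected, abs=1e-12)
    assert row.freq_in == pytest.approx(11 / 13)
    assert row.significant


def test_enrichment_flat_trait_p_one():
    labels = pd.Series([1] * 10 + [2] * 10,
                       index=[f"s{i}" for i in range(20)])
    trait = pd.DataFrame({"flat": [True, False] * 10}, index=labels.index)
    out = cluster_enrichment(labels, trait)
    assert np.allclose(out.p, 1.0)


def test_enrichment_zero_positive_trait_emits_p_one_row():
    labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
    trait = pd.DataFrame({"never": [False] * 4}, index=labels.index)
    out = cluster_enrichment(labels, trait)
    assert len(out) == 2
    assert (out.p == 1.0).all()
    assert (out.q >= out.p - 1e-15).all()


def test_bh_correction_is_joint_across_all_tests():
    rng = np.random.default_rng(0)
    labels = pd.Series(rng.integers(1, 4, size=60),
                       index=[f"s{i}" for i in range(60)])
    traits = pd.DataFrame(rng.random((60, 4)) < 0.3,
                          columns=list("wxyz"), index=labels.index)
    out = cluster_enrichment(labels, traits)
    from statsmodels.stats.multitest import multipletests
    assert out.q.to_numpy() == pytest.approx(
        multipletests(out.p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# supervised scheme, cohort comparison, PCA
# ---------------------------------------------------------------------------

def test_tcga_classification_precedence_and_fraction():
    flags = pd.DataFrame(
        {"ERG": [True, True, False, False],
         "ETV1": [False, False, False, False],
         "ETV4": [False, False, False, False],
         "FLI1": [False, False, False, False],
         "SPOP": [False, True, True, False],
         "FOXA1": [False, False, False, False],
         "IDH1": [False, False, False, False]},
        index=list("abcd"))
    classes, frac = classify_tcga(flags)
    assert classes.to_list() == ["ERG", "ERG", "SPOP", "unclassified"]
    assert frac == pytest.approx(0.75)


def test_compare_cohorts_identical_gives_null_results():
    rng = np.random.default_rng(2)
    a = pd.DataFrame(rng.random((30, 5)) < 0.3, columns=list("vwxyz"))
    out = compare_cohorts(a, a.copy(), tmb_a=np.ones(30), tmb_b=np.ones(30))
    assert (out["genes"].freq_diff == 0).all()
    assert np.allclose(out["genes"].q, 1.0)
    assert out["tmb_wilcoxon"]["p"] == pytest.approx(1.0)


def test_compare_cohorts_detects_planted_gene_and_tmb_shift():
    rng = np.random.default_rng(5)
    genes = ["planted"] + [f"g{i}" for i in range(4)]
    a = pd.DataFrame({g: rng.random(200) < (0.30 if g == "planted" else 0.1)
                      for g in genes})
    b = pd.DataFrame({g: rng.random(200) < (0.05 if g == "planted" else 0.1)
                      for g in genes})
    tmb_a = rng.lognormal(np.log(8.1), 0.3, size=200)   # ~3x median shift
    tmb_b = rng.lognormal(np.log(2.7), 0.3, size=200)
    out = compare_cohorts(a, b, tmb_a=tmb_a, tmb_b=tmb_b)
    planted_q = out["genes"].set_index("gene").loc["planted", "q"]
    assert planted_q <= 0.05
    assert out["tmb_wilcoxon"]["p"] < 0.001


def test_compare_cohorts_validates_inputs():
    a = pd.DataFrame({"x": [True]})
    with pytest.raises(ValueError):
        compare_cohorts(a, pd.DataFrame({"y": [True]}))
    with pytest.raises(ValueError):
        compare_cohorts(a, pd.DataFrame({"x": []}))


def test_pca_cos2_sums_to_one_and_matches_svd(rng):
    m = _df(rng.random((15, 5)))
    out = pca_cos2(m)
    assert np.allclose(out["cos2"].sum(axis=1), 1.0, atol=1e-10)
    X = m.to_numpy()
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    coord = Vt.T * (s / np.sqrt(len(m) - 1))
    cos2 = coord ** 2 / (coord ** 2).sum(axis=1, keepdims=True)
    assert np.allclose(out["cos2"].to_numpy(), cos2, atol=1e-10)


def test_pca_cos2_rank_one_data_loads_first_component(rng):
    base = rng.random(5)
    rows = np.outer(rng.random(12), base) + rng.normal(0, 1e-9, size=(12, 5))
    out = pca_cos2(_df(rows))
    assert (out["cos2"]["PC1"] > 0.999).all()


def test_pca_requires_two_samples():
    with pytest.raises(ValueError):
        pca_cos2(_df(np.ones((1, 4))))
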