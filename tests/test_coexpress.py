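"""Log-relative profiles, UPGMA, Davies-Bouldin selection and cluster
activity maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from dualseq.coexpress import (
    cluster_activity,
    cut_dendrogram,
    davies_bouldin,
    log_relative_transform,
    select_cluster_count,
    upgma,
)
from dualseq.simulate import simulate_profile_matrix

from oracles import brute_davies_bouldin, brute_upgma


def df_of(X):
    return pd.DataFrame(np.asarray(X, dtype=float),
                        index=[f"g{i}" for i in range(len(X))])


# --- log-relative transform ----------------------------------------------

def test_constant_row_maps_to_zero():
    pm = log_relative_transform(df_of([[5, 5, 5, 5]]))
    assert np.allclose(pm.values.iloc[0], 0.0)


def test_hand_arithmetic_row():
    pm = log_relative_transform(df_of([[1, 2, 4, 8]]), log_base=2.0)
    expected = np.log2(np.array([1, 2, 4, 8]) / 3.75)
    assert np.allclose(pm.values.iloc[0], expected)


def test_scaling_a_zero_free_row_leaves_profile_unchanged():
    a = log_relative_transform(df_of([[1, 2, 4, 8]]))
    b = log_relative_transform(df_of([[10, 20, 40, 80]]))
    assert np.allclose(a.values.iloc[0], b.values.iloc[0])


def test_all_zero_rows_removed_and_reported():
    pm = log_relative_transform(df_of([[0, 0, 0, 0], [1, 2, 3, 4]]))
    assert pm.dropped_genes == ["g0"]
    assert pm.n_genes == 1
    with pytest.raises(ValueError, match="all-zero"):
        log_relative_transform(df_of([[0, 0, 0, 0]]))


def test_requires_two_timepoints():
    with pytest.raises(ValueError, match="two timepoints"):
        log_relative_transform(df_of([[1]]))


# --- UPGMA ---------------------------------------------------------------

def test_two_leaves_merge_at_their_distance():
    dend = upgma(df_of([[0, 0], [3, 4]]))
    a, b, h, s = dend.merges[0]
    assert (a, b, s) == (0, 1, 2) and h == pytest.approx(5.0)


def test_three_leaf_hand_recurrence():
    # d(A,B)=1, d(A,C)=4, d(B,C)=4 -> merge (A,B) at 1, then at (4+4)/2
    X = df_of([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(16 - 0.25)]])
    D = squareform(pdist(X.to_numpy()))
    assert D[0, 1] == pytest.approx(1.0) and D[0, 2] == pytest.approx(4.0)
    dend = upgma(X)
    assert dend.merges[0][2] == pytest.approx(1.0)
    assert dend.merges[1][2] == pytest.approx(4.0)
    assert tuple(dend.merges[1][:2]) == (2, 3)


def test_merge_lists_match_brute_force_average_linkage(rng):
    for _ in range(40):
        n = int(rng.integers(2, 9))
        X = rng.normal(size=(n, 3))
        dend = upgma(df_of(X))
        exp = brute_upgma(squareform(pdist(X)))
        for got, want in zip(dend.merges, exp):
            assert (int(got[0]), int(got[1]), int(got[3])) == (
                want[0], want[1], want[3]
            )
            assert got[2] == pytest.approx(want[2], abs=1e-12)


def test_merge_lists_match_scipy_average_linkage(rng):
    for _ in range(40):
        n = int(rng.integers(3, 16))
        X = rng.normal(size=(n, 4))
        ours = upgma(df_of(X)).merges
        sp = linkage(pdist(X), method="average")
        for a, b in zip(ours, sp):
            assert {int(a[0]), int(a[1])} == {int(b[0]), int(b[1])}
            assert a[2] == pytest.approx(b[2], abs=1e-9)
            assert a[3] == b[3]


def test_non_finite_profiles_rejected():
    with pytest.raises(ValueError, match="non-finite"):
        upgma(df_of([[0, np.nan], [1, 1], [2, 2]]))


def test_cut_extremes(rng):
    X = df_of(rng.normal(size=(10, 4)))
    dend = upgma(X)
    assert len(set(cut_dendrogram(dend, 10).tolist())) == 10
    assert set(cut_dendrogram(dend, 1).tolist()) == {0}


# --- Davies-Bouldin -------------------------------------------------------

def test_zero_scatter_clusters_score_zero():
    X = df_of([[0, 0], [0, 0], [5, 5], [5, 5]])
    assert davies_bouldin(np.array([0, 0, 1, 1]), X) == 0.0


def test_two_singletons_score_zero():
    X = df_of([[0, 0], [9, 3]])
    assert davies_bouldin(np.array([0, 1]), X) == 0.0


def test_db_matches_brute_force_and_sklearn(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    for _ in range(15):
        n = int(rng.integers(8, 40))
        X = rng.normal(size=(n, 4))
        labels = rng.integers(0, 3, n)
        if len(set(labels.tolist())) < 2:
            continue
        ours = davies_bouldin(labels, df_of(X))
        assert ours == pytest.approx(brute_davies_bouldin(X, labels), abs=1e-12)
        assert ours == pytest.approx(
            sklearn_metrics.davies_bouldin_score(X, labels), abs=1e-9
        )


def test_planted_labels_beat_random_permutation():
    worse = 0
    for seed in range(10):
        df, labels, _ = simulate_profile_matrix(
            80, 4, 5, noise_sd=0.25, separation=8.0, seed=seed
        )
        rng = np.random.default_rng(seed)
        perm = rng.permutation(labels)
        if davies_bouldin(labels, df) > davies_bouldin(perm, df):
            worse += 1
    assert worse == 0


# --- selection and activity ----------------------------------------------

def test_degenerate_k_range_is_trivial(rng):
    X = df_of(rng.normal(size=(12, 4)))
    dend = upgma(X)
    sel = select_cluster_count(dend, X, 4, 4)
    assert sel.chosen_k == 4 and list(sel.scores) == [4]
    with pytest.raises(ValueError, match="invalid K range"):
        select_cluster_count(dend, X, 5, 4)


def test_planted_cluster_count_recovered():
    df, labels, _ = simulate_profile_matrix(
        150, 4, 6, noise_sd=0.2, separation=10.0, seed=4
    )
    dend = upgma(df)
    sel = select_cluster_count(dend, df, 2, 40)
    assert sel.chosen_k == 6
    # chosen K attains the recorded minimum
    assert sel.scores[sel.chosen_k] == min(sel.scores.values())


def test_activity_of_singleton_and_pair_clusters():
    X = df_of([[1.0, 2.0], [3.0, 4.0], [5.0, 8.0]])
    amap = cluster_activity(X, np.array([0, 1, 1]))
    assert np.allclose(amap.activity.loc[0], [1, 2])
    assert np.allclose(amap.activity.loc[1], [4, 6])
    assert amap.sizes.tolist() == [1, 2]


def test_activity_matches_brute_group_mean_and_conserves_total(rng):
    X = df_of(rng.normal(size=(30, 4)))
    labels = rng.integers(0, 5, 30)
    amap = cluster_activity(X, labels)
    for c in np.unique(labels):
        assert np.allclose(
            amap.activity.loc[c], X.to_numpy()[labels == c].mean(axis=0)
        )
    weighted = (
        amap.activity.mul(amap.sizes, axis=0).sum() / amap.sizes.sum()
    )
    assert np.allclose(weighted, X.mean(axis=0), atol=1e-9)


def test_activity_grid_is_near_square_row_major():
    X = df_of(np.arange(20, dtype=float).reshape(10, 2))
    amap = cluster_activity(X, np.arange(10) % 7)
    assert amap.grid.loc[0].tolist() == [0, 0]
    assert amap.grid.loc[3].tolist() == [1, 0]  # ncol = ceil(sqrt(7)) = 3
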