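"""PAM clustering, K diagnostics, outcome relabeling, protocol independence."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from radclust import (ClusteringConfig, ClusterResult, GeneratorConfig,
                      generate_cohort, k_diagnostics, pam_cluster,
                      protocol_independence_check, relabel_by_outcome)


def exhaustive_kmedoids_cost(X, K):
    """Brute-force minimum cost over all medoid subsets."""
    D = squareform(pdist(X, metric="sqeuclidean"))
    return min(D[:, list(c)].min(axis=1).sum()
               for c in combinations(range(len(X)), K))


def _frame(X):
    return pd.DataFrame(np.asarray(X, dtype=float))


def test_three_separated_pairs():
    X = _frame([[0.0], [0.1], [10.0], [10.1], [20.0], [20.1]])
    res = pam_cluster(X, ClusteringConfig(K=3, n_restarts=3, seed=0))
    labels = res.labels.to_numpy()
    assert labels[0] == labels[1]
    assert labels[2] == labels[3]
    assert labels[4] == labels[5]
    assert len(set(labels)) == 3


@pytest.mark.parametrize("n,K", [(8, 2), (9, 3), (10, 2)])
def test_pam_matches_exhaustive_optimum(n, K):
    rng = np.random.default_rng(n * 10 + K)
    for _ in range(8):
        X = rng.normal(size=(n, 3))
        res = pam_cluster(_frame(X), ClusteringConfig(K=K, n_restarts=5, seed=1))
        assert res.total_cost == pytest.approx(exhaustive_kmedoids_cost(X, K))


def test_degenerate_k_equals_n():
    X = _frame(np.random.default_rng(0).normal(size=(6, 2)))
    res = pam_cluster(X, ClusteringConfig(K=6, n_restarts=1))
    assert res.total_cost == 0.0
    assert sorted(res.medoid_patient_ids) == list(range(6))


def test_k_larger_than_n_rejected():
    X = _frame(np.zeros((3, 2)))
    with pytest.raises(ValueError, match="exceeds"):
        pam_cluster(X, ClusteringConfig(K=4))


def test_local_optimality_no_improving_swap():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 4))
    res = pam_cluster(_frame(X), ClusteringConfig(K=3, n_restarts=3, seed=4))
    D = squareform(pdist(X, metric="sqeuclidean"))
    medoids = list(res.medoid_patient_ids)
    for i in range(3):
        for h in range(20):
            if h in medoids:
                continue
            trial = medoids.copy()
            trial[i] = h
            cost = D[:, trial].min(axis=1).sum()
            assert cost >= res.total_cost - 1e-9


def test_centroids_are_cluster_means(small_bundle):
    res = pam_cluster(small_bundle.feature_matrix, ClusteringConfig(K=3, seed=0))
    for k in res.centroids.index:
        members = small_bundle.feature_matrix[res.labels == k]
        assert np.allclose(res.centroids.loc[k], members.mean(), atol=1e-12)
    assert all(m in small_bundle.patient_ids for m in res.medoid_patient_ids)


def test_k_diagnostics_prefer_planted_k():
    """With strongly separated planted clusters all three criteria agree on K=3."""
    hits = 0
    for seed in range(3):
        b = generate_cohort(GeneratorConfig(
            n_patients=90, n_features=30, n_informative_features=15,
            cluster_separation=4.0, scanner_effect_fraction=0.0, seed=seed))
        z = (b.feature_matrix - b.feature_matrix.mean()) / b.feature_matrix.std()
        diag = k_diagnostics(z, k_range=range(2, 6), seed=seed)
        ok = (diag["calinski_harabasz"].idxmax() == 3
              and diag["silhouette"].idxmax() == 3
              and diag["davies_bouldin"].idxmin() == 3)
        hits += ok
    assert hits >= 2


def test_single_blob_has_flat_silhouette():
    rng = np.random.default_rng(1)
    X = _frame(rng.normal(size=(60, 10)))
    diag = k_diagnostics(X, k_range=range(2, 5), seed=1)
    assert (diag["silhouette"].abs() < 0.2).all()


def test_k1_diagnostics_rejected(small_bundle):
    with pytest.raises(ValueError, match="K < 2"):
        k_diagnostics(small_bundle.feature_matrix, k_range=range(1, 4))


def _result_with_labels(labels, index):
    labels = pd.Series(labels, index=index, name="cluster")
    centroids = pd.DataFrame(
        {"f": [float(k) for k in sorted(set(labels))]},
        index=sorted(set(labels)))
    centroids.index.name = "cluster"
    return ClusterResult(labels=labels, medoid_patient_ids=list(index[:3]),
                         total_cost=0.0, centroids=centroids, K=3)


def test_relabel_by_death_frequency():
    # raw clusters a=1, b=2, c=3 with death frequencies 0.30, 0.05, 0.20
    index = pd.Index(range(60))
    raw = np.repeat([1, 2, 3], 20)
    events = np.concatenate([
        np.r_[np.ones(6), np.zeros(14)],   # cluster 1: 0.30
        np.r_[np.ones(1), np.zeros(19)],   # cluster 2: 0.05
        np.r_[np.ones(4), np.zeros(16)],   # cluster 3: 0.20
    ])
    clinical = pd.DataFrame({"dss_event": events}, index=index)
    out = relabel_by_outcome(_result_with_labels(raw, index), clinical)
    assert out.relabel_map == {2: 1, 3: 2, 1: 3}
    freq = clinical["dss_event"].groupby(out.labels).mean()
    assert list(freq.sort_index()) == sorted(freq)
    assert freq.idxmax() == 3


def test_relabel_tie_preserves_order():
    index = pd.Index(range(30))
    raw = np.repeat([1, 2, 3], 10)
    clinical = pd.DataFrame({"dss_event": np.tile([1] + [0] * 9, 3)}, index=index)
    out = relabel_by_outcome(_result_with_labels(raw, index), clinical)
    assert out.relabel_map == {1: 1, 2: 2, 3: 3}


def test_relabel_invariant_to_raw_numbering():
    rng = np.random.default_rng(3)
    index = pd.Index(range(90))
    raw = rng.integers(1, 4, 90)
    clinical = pd.DataFrame({"dss_event": rng.integers(0, 2, 90)}, index=index)
    out1 = relabel_by_outcome(_result_with_labels(raw, index), clinical)
    perm = {1: 3, 2: 1, 3: 2}
    out2 = relabel_by_outcome(
        _result_with_labels([perm[x] for x in raw], index), clinical)
    assert (out1.labels == out2.labels).all()


def test_protocol_independence_null_and_planted(small_bundle):
    res = pam_cluster(small_bundle.feature_matrix,
                      ClusteringConfig(K=3, seed=0))
    # copy labels from field strength: that covariate must be flagged
    fs_labels = (small_bundle.protocol_table["field_strength"] == 3.0).astype(int) + 1
    planted = _result_with_labels(fs_labels.to_numpy(),
                                  small_bundle.patient_ids)
    report = protocol_independence_check(planted, small_bundle.protocol_table)
    assert report.loc["field_strength", "fdr_significant"]
    # labels independent of protocol: generated from the feature signal only
    null_report = protocol_independence_check(
        res, small_bundle.protocol_table.assign(
            repetition_time=np.random.default_rng(0).normal(
                4000, 100, len(small_bundle.patient_ids))))
    assert {"anova", "chi2"} == set(null_report["kind"].unique()) - {"skipped"}


def test_protocol_independence_skips_constant_covariate(small_bundle):
    res = pam_cluster(small_bundle.feature_matrix, ClusteringConfig(K=2, seed=0))
    proto = small_bundle.protocol_table.copy()
    proto["field_strength"] = 1.5
    report = protocol_independence_check(res, proto)
    assert report.loc["field_strength", "kind"] == "skipped"
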