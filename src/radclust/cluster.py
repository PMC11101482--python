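"""K-medoids patient stratification (PAM, squared Euclidean).

Classical partitioning-around-medoids: greedy BUILD initialization followed by
steepest-descent SWAP until no single medoid/non-medoid exchange lowers the
total cost (sum of squared Euclidean distances of patients to their assigned
medoid). K is a user decision (default 3); the Calinski-Harabasz,
Davies-Bouldin and silhouette criteria are computed as advisory diagnostics
only. Clusters are renumbered by death-by-disease frequency so that higher
cluster numbers carry higher risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)
from statsmodels.stats.multitest import multipletests

from .cohort import PROTOCOL_CATEGORICAL, PROTOCOL_CONTINUOUS

__all__ = [
    "ClusteringConfig", "ClusterResult", "pam_cluster", "k_diagnostics",
    "relabel_by_outcome", "protocol_independence_check",
]


@dataclass
class ClusteringConfig:
    K: int = 3
    n_restarts: int = 10
    seed: int = 0
    init: str = "BUILD"   # "BUILD" or "random"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init not in ("BUILD", "random"):
            raise ValueError("init must be 'BUILD' or 'random'")


@dataclass
class ClusterResult:
    labels: pd.Series                  # per patient, values 1..K
    medoid_patient_ids: list
    total_cost: float
    centroids: pd.DataFrame            # K x n_features, index = cluster label
    K: int
    relabel_map: dict | None = None    # original label -> final label

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _build_init(D: np.ndarray, K: int) -> list[int]:
    """Greedy BUILD: repeatedly add the medoid giving the largest cost drop."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dist = D[:, medoids[0]].copy()
    while len(medoids) < K:
        gains = np.maximum(dist[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -1.0
        best = int(np.argmax(gains))  # argmax takes the lowest index on ties
        medoids.append(best)
        dist = np.minimum(dist, D[:, best])
    return sorted(medoids)


def _swap_descent(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest-descent SWAP phase; ties broken by lowest (medoid, candidate)."""
    n = D.shape[0]
    medoids = sorted(medoids)
    while True:
        M = np.asarray(medoids)
        dm = D[:, M]                               # n x K
        order = np.argsort(dm, axis=1, kind="stable")
        d1 = dm[np.arange(n), order[:, 0]]          # nearest medoid distance
        nearest = order[:, 0]
        d2 = (dm[np.arange(n), order[:, 1]] if len(M) > 1
              else np.full(n, np.inf))
        cost = d1.sum()
        best_delta, best_swap = -1e-12, None
        others = np.setdiff1d(np.arange(n), M)
        for i in range(len(M)):
            # cost after removing medoid i, as a function of candidate h
            base = np.where(nearest == i, d2, d1)
            for h in others:
                new_cost = np.minimum(base, D[:, h]).sum()
                delta = cost - new_cost
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (i, int(h))
        if best_swap is None:
            return medoids, float(cost)
        i, h = best_swap
        medoids[i] = h
        medoids = sorted(medoids)


def pam_cluster(matrix: pd.DataFrame,
                config: ClusteringConfig | None = None) -> ClusterResult:
    """Cluster patients by PAM with squared Euclidean distance.

    Runs ``n_restarts`` starts (BUILD first when ``init='BUILD'``, the rest
    random) and keeps the lowest-cost solution. Deterministic given the seed;
    all ties break toward the lowest patient index.
    """
    config = config or ClusteringConfig()
    X = matrix.to_numpy(float)
    n = X.shape[0]
    if config.K > n:
        raise ValueError(f"K={config.K} exceeds number of patients ({n})")
    D = squareform(pdist(X, metric="sqeuclidean"))
    rng = np.random.default_rng(config.seed)

    starts: list[list[int]] = []
    if config.init == "BUILD":
        starts.append(_build_init(D, config.K))
    while len(starts) < config.n_restarts:
        starts.append(sorted(rng.choice(n, size=config.K, replace=False).tolist()))

    best: tuple[float, list[int]] | None = None
    for start in starts:
        medoids, cost = _swap_descent(D, start)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, medoids)
    cost, medoids = best

    # raw labels: 1..K in order of ascending medoid patient index
    assign = np.argmin(D[:, medoids], axis=1)
    labels = pd.Series(assign + 1, index=matrix.index, name="cluster")
    centroids = matrix.groupby(labels).mean()
    centroids.index.name = "cluster"
    return ClusterResult(
        labels=labels,
        medoid_patient_ids=[matrix.index[m] for m in medoids],
        total_cost=float(cost),
        centroids=centroids,
        K=config.K,
    )


def k_diagnostics(matrix: pd.DataFrame, k_range=range(2, 7),
                  seed: int = 0, n_restarts: int = 5) -> pd.DataFrame:
    """Advisory cluster-count criteria for each K in ``k_range``.

    Silhouette and Davies-Bouldin are undefined at K=1, which is rejected.
    """
    rows = {}
    X = matrix.to_numpy(float)
    for K in k_range:
        if K < 2:
            raise ValueError("cluster-count criteria are undefined for K < 2")
        res = pam_cluster(matrix, ClusteringConfig(K=K, seed=seed,
                                                   n_restarts=n_restarts))
        lab = res.labels.to_numpy()
        rows[K] = {
            "calinski_harabasz": calinski_harabasz_score(X, lab),
            "davies_bouldin": davies_bouldin_score(X, lab),
            "silhouette": silhouette_score(X, lab),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("K")


def relabel_by_outcome(result: ClusterResult,
                       clinical_table: pd.DataFrame) -> ClusterResult:
    """Renumber clusters by ascending death-by-disease frequency.

    After relabeling, cluster 1 has the lowest event fraction and cluster K
    the highest; ties keep the original label order.
    """
    events = clinical_table.loc[result.labels.index, "dss_event"]
    freq = events.groupby(result.labels).mean()
    order = sorted(freq.index, key=lambda lab: (freq[lab], lab))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    labels = result.labels.map(mapping).rename("cluster")
    centroids = result.centroids.rename(index=mapping).sort_index()
    medoids = [result.medoid_patient_ids[old - 1] for old in order]
    return ClusterResult(
        labels=labels,
        medoid_patient_ids=medoids,
        total_cost=result.total_cost,
        centroids=centroids,
        K=result.K,
        relabel_map=mapping,
    )


def protocol_independence_check(result: ClusterResult,
                                protocol_table: pd.DataFrame,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Re-test clusters against acquisition covariates.

    Chi-square for categorical covariates, one-way ANOVA for continuous ones,
    BH-FDR across covariates. The clustering passes if no covariate stays
    significant. Constant covariates are skipped with a note.
    """
    labels = result.labels
    continuous = list(PROTOCOL_CONTINUOUS) + ["n_b_values"]
    categorical = list(PROTOCOL_CATEGORICAL) + ["highest_b_value"]
    rows = []
    for cov in continuous + categorical:
        if cov not in protocol_table.columns:
            continue
        x = protocol_table.loc[labels.index, cov]
        if x.nunique() < 2:
            rows.append({"covariate": cov, "kind": "skipped",
                         "statistic": np.nan, "pvalue": np.nan,
                         "note": "constant across cohort"})
            continue
        if cov in continuous:
            groups = [x[labels == k].to_numpy(float) for k in sorted(labels.unique())]
            stat, p = stats.f_oneway(*groups)
            kind = "anova"
        else:
            table = pd.crosstab(x, labels)
            stat, p, _, _ = stats.chi2_contingency(table)
            kind = "chi2"
        rows.append({"covariate": cov, "kind": kind, "statistic": float(stat),
                     "pvalue": float(p), "note": ""})
    report = pd.DataFrame(rows).set_index("covariate")
    tested = report["pvalue"].notna()
    qvals = pd.Series(np.nan, index=report.index)
    reject = pd.Series(False, index=report.index)
    if tested.any():
        rej, q, _, _ = multipletests(report.loc[tested, "pvalue"], alpha=alpha,
                                     method="fdr_bh")
        qvals[tested] = q
        reject[tested] = rej
    report["qvalue"] = qvals
    report["fdr_significant"] = reject
    report.attrs["passed"] = bool(~reject.any())
    report.attrs["min_pvalue"] = float(report.loc[tested, "pvalue"].min()) if tested.any() else np.nan
    return report
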