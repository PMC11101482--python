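"""Centroid-distance feature ranking (FR).

For each z-normalized feature k the ranking statistic is the Euclidean
distance among the K cluster centroids:

    FR_k = sqrt( sum_{i<j} ( mu_k(C_i) - mu_k(C_j) )^2 )

High FR marks features whose centroids are far apart, i.e. the features
driving the patient clustering; the statistic is meaningful only on
z-normalized features. Features are sorted by descending FR and the top of
the ranking is partitioned into interval I (FR > 1.85) and interval II
(1.50 < FR < 1.85); both inequalities are strict, so FR exactly at a
threshold falls outside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import FeatureCatalog, TUMOR_VOLUME_FEATURE

__all__ = ["RankingConfig", "compute_fr", "rank_and_summarize",
           "volume_confound_analysis"]


@dataclass
class RankingConfig:
    interval_1_threshold: float = 1.85
    interval_2_lower: float = 1.50
    #: alternative reading of the statistic: |sum of signed pair differences|
    signed_sum: bool = False

    def __post_init__(self) -> None:
        if not self.interval_2_lower < self.interval_1_threshold:
            raise ValueError("interval_2_lower must be below interval_1_threshold")


def compute_fr(centroids: pd.DataFrame,
               config: RankingConfig | None = None) -> pd.Series:
    """FR per feature from a K x n_features centroid matrix.

    Default is the root of the sum of squared pairwise centroid differences
    (a true distance, invariant to cluster numbering). ``signed_sum`` selects
    the alternative |sum of signed differences| reading for sensitivity
    analysis; it allows sign cancellation and is not a distance.
    """
    config = config or RankingConfig()
    if centroids.shape[0] < 2:
        raise ValueError("FR requires at least 2 clusters")
    C = centroids.to_numpy(float)
    pairs = list(combinations(range(C.shape[0]), 2))
    diffs = np.stack([C[i] - C[j] for i, j in pairs])
    if config.signed_sum:
        fr = np.abs(diffs.sum(axis=0))
    else:
        fr = np.sqrt((diffs ** 2).sum(axis=0))
    return pd.Series(fr, index=centroids.columns, name="FR")


def _interval(fr: float, config: RankingConfig) -> str:
    if fr > config.interval_1_threshold:
        return "I"
    if config.interval_2_lower < fr < config.interval_1_threshold:
        return "II"
    return "none"


@dataclass
class FeatureRankingSummary:
    table: pd.DataFrame            # per feature: FR, rank, interval, series, group, centroids
    interval_counts_by_series: pd.DataFrame
    interval_counts_by_group: pd.DataFrame
    group_rank_test: dict          # Kruskal-Wallis of ranks across non-shape groups


def rank_and_summarize(fr: pd.Series, catalog: FeatureCatalog | None = None,
                       config: RankingConfig | None = None,
                       centroids: pd.DataFrame | None = None) -> FeatureRankingSummary:
    """Sort FR descending (ties keep catalog/input order) and summarize.

    Attributes each feature to its MR series and feature group, counts
    interval I/II membership per series and group, and tests for rank
    differences across the six non-shape feature groups (Kruskal-Wallis on
    FR values).
    """
    config = config or RankingConfig()
    table = pd.DataFrame({"FR": fr})
    # stable sort: ties resolved by original (catalog) order
    table = table.sort_values("FR", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    table["interval"] = [_interval(v, config) for v in table["FR"]]
    if catalog is not None:
        table["series"] = [catalog.series_of(f) for f in table.index]
        table["group"] = [catalog.group_of(f) for f in table.index]
    else:
        table["series"] = "unknown"
        table["group"] = "unknown"
    if centroids is not None:
        for k in centroids.index:
            table[f"centroid_C{k}"] = centroids.loc[k, table.index].to_numpy()

    by_series = pd.crosstab(table["interval"], table["series"])
    by_group = pd.crosstab(table["interval"], table["group"])

    group_test: dict = {"statistic": np.nan, "pvalue": np.nan}
    nonshape = table[table["group"] != "shape"]
    groups = [g["FR"].to_numpy() for _, g in nonshape.groupby("group")]
    if len(groups) >= 2 and all(len(g) for g in groups):
        stat, p = stats.kruskal(*groups)
        group_test = {"statistic": float(stat), "pvalue": float(p)}
    return FeatureRankingSummary(
        table=table.rename_axis("feature"),
        interval_counts_by_series=by_series,
        interval_counts_by_group=by_group,
        group_rank_test=group_test,
    )


@dataclass
class VolumeConfoundReport:
    """Is the clustering driven by tumor volume?"""

    table: pd.DataFrame          # per feature: spearman rho, p, q, flag
    n_volume_associated: int
    fraction_str: str
    volume_fr_rank: int
    rank_difference_test: dict   # FR of volume-associated vs not (Kruskal-Wallis)
    cluster_volume_anova: dict   # per-cluster mean volume comparison


def volume_confound_analysis(matrix: pd.DataFrame, ranking: FeatureRankingSummary,
                             labels: pd.Series,
                             volume_feature: str = TUMOR_VOLUME_FEATURE,
                             alpha: float = 0.05) -> VolumeConfoundReport:
    """Screen every feature for Spearman association with tumor volume.

    Reports the FDR-flagged count, whether volume-associated features rank
    higher than the rest (Kruskal-Wallis on FR), the tumor-volume feature's
    own FR rank, and a one-way ANOVA of volume across clusters.
    """
    if volume_feature not in matrix.columns:
        raise KeyError(f"volume feature {volume_feature!r} not in matrix")
    vol = matrix[volume_feature].to_numpy(float)
    rows = {}
    for feat in matrix.columns:
        if feat == volume_feature:
            continue
        rho, p = stats.spearmanr(matrix[feat].to_numpy(float), vol)
        rows[feat] = {"spearman_rho": float(rho), "pvalue": float(p)}
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature")
    reject, qvals, _, _ = multipletests(table["pvalue"], alpha=alpha,
                                        method="fdr_bh")
    table["qvalue"] = qvals
    table["fdr_significant"] = reject
    n_sig = int(reject.sum())
    n_tot = len(table)

    rk = ranking.table
    fr_assoc = rk.loc[rk.index.intersection(table.index[table["fdr_significant"]]), "FR"]
    fr_other = rk.loc[rk.index.intersection(table.index[~table["fdr_significant"]]), "FR"]
    if len(fr_assoc) and len(fr_other):
        stat, p = stats.kruskal(fr_assoc.to_numpy(), fr_other.to_numpy())
        rank_test = {"statistic": float(stat), "pvalue": float(p)}
    else:
        rank_test = {"statistic": np.nan, "pvalue": np.nan}

    groups = [vol[(labels == k).to_numpy()] for k in sorted(labels.unique())]
    astat, ap = stats.f_oneway(*groups)

    pct = 100.0 * n_sig / n_tot
    return VolumeConfoundReport(
        table=table,
        n_volume_associated=n_sig,
        fraction_str=f"{n_sig}/{n_tot} ({pct:.1f}%)",
        volume_fr_rank=int(rk.loc[volume_feature, "rank"]),
        rank_difference_test=rank_test,
        cluster_volume_anova={"statistic": float(astat), "pvalue": float(ap)},
    )
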