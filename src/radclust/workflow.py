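"""End-to-end pipeline: harmonize -> cluster -> rank -> associate."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import FeatureCatalog, TUMOR_VOLUME_FEATURE, build_catalog
from .cluster import (ClusteringConfig, ClusterResult, pam_cluster,
                      protocol_independence_check, relabel_by_outcome)
from .cohort import CohortBundle
from .harmonize import HarmonizationConfig, association_report, harmonize
from .outcome import (clinicopathological_table, cox_model, kaplan_meier,
                      per_gene_mutation_test, pathway_aggregation)
from .ranking import (RankingConfig, compute_fr, rank_and_summarize,
                      volume_confound_analysis)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    harmonized: pd.DataFrame
    harmonization: object
    pre_report: object
    post_report: object
    clusters: ClusterResult
    protocol_check: pd.DataFrame
    ranking: object
    volume_report: object | None
    km: object
    cox_unadjusted: pd.DataFrame
    cox_adjusted: pd.DataFrame
    clinical_associations: list
    mutation_report: pd.DataFrame | None
    pathway_report: pd.DataFrame | None


def run_pipeline(bundle: CohortBundle, catalog: FeatureCatalog | None = None,
                 alpha: float = 0.05, K: int = 3, n_restarts: int = 10,
                 seed: int = 0) -> PipelineResult:
    """Run the full radiomic-profile analysis on a cohort bundle."""
    if catalog is None and bundle.feature_matrix.shape[1] == 293:
        catalog = build_catalog()
    hcfg = HarmonizationConfig(alpha=alpha)
    pre = association_report(bundle.feature_matrix, bundle.protocol_table,
                             catalog, hcfg, stage_label="before harmonization")
    harmonized, hres = harmonize(bundle.feature_matrix, bundle.protocol_table,
                                 catalog, hcfg)
    post = association_report(harmonized, bundle.protocol_table, catalog, hcfg,
                              stage_label="after harmonization")

    raw = pam_cluster(harmonized, ClusteringConfig(K=K, n_restarts=n_restarts,
                                                   seed=seed))
    clusters = relabel_by_outcome(raw, bundle.clinical_table)
    check = protocol_independence_check(clusters, bundle.protocol_table, alpha)

    fr = compute_fr(clusters.centroids)
    ranking = rank_and_summarize(fr, catalog, RankingConfig(),
                                 centroids=clusters.centroids)
    volume = None
    if TUMOR_VOLUME_FEATURE in harmonized.columns:
        volume = volume_confound_analysis(harmonized, ranking, clusters.labels,
                                          alpha=alpha)

    km = kaplan_meier(bundle.clinical_table, clusters.labels)
    cox_u = cox_model(bundle.clinical_table, clusters.labels, adjusted=False)
    cox_a = cox_model(bundle.clinical_table, clusters.labels, adjusted=True)
    clin = clinicopathological_table(bundle.clinical_table, clusters.labels,
                                     seed=seed)
    mut = pw = None
    if bundle.mutation_matrix is not None:
        mut = per_gene_mutation_test(bundle.mutation_matrix, clusters.labels,
                                     alpha=alpha)
        pw = pathway_aggregation(bundle.mutation_matrix, clusters.labels)
    return PipelineResult(
        harmonized=harmonized, harmonization=hres, pre_report=pre,
        post_report=post, clusters=clusters, protocol_check=check,
        ranking=ranking, volume_report=volume, km=km, cox_unadjusted=cox_u,
        cox_adjusted=cox_a, clinical_associations=clin, mutation_report=mut,
        pathway_report=pw,
    )
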