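# radclust

Unsupervised radiomic profiling of tumor MRI cohorts: harmonize radiomic
features against acquisition settings, stratify patients by K-medoids
clustering, rank the cluster-driving features, and associate the clusters
with survival, clinicopathological and mutation data.

## The problem

Quantitative MRI descriptors ("radiomic features" — intensity, texture and
shape statistics computed inside a tumor segmentation) carry prognostic
information, but they are also strongly driven by how the images were
acquired: voxel size, repetition/echo time, flip angle, field strength,
diffusion weighting. Any clustering run on raw features tends to group
patients by scanner rather than by biology. `radclust` implements the
analysis pipeline for this setting, built around cervical-cancer MRI
cohorts with 293 features (14 shape features from T2-weighted imaging and
93 intensity/texture features for each of T2WI, high-b-value DWI, and the
ADC map), disease-specific survival (DSS), FIGO stage, and optional
exome-derived mutation calls.

Patient-level imaging data of this kind are generally not redistributable,
so the package ships a fully specified synthetic cohort generator (planted
cluster signal, linear scanner confounding, exponential survival with
administrative censoring, cluster-enriched mutations) that makes every
stage of the pipeline testable against known ground truth.

## Method

1. **Harmonization** — each feature is an OLS outcome on the acquisition
   covariates (plus the highest b-value and number of b-values for
   diffusion-derived features). Features whose overall F-test survives
   Benjamini–Hochberg FDR at α = 0.05 are residualized (observed minus
   linear prediction); all features are then z-normalized. After this step,
   re-screening finds zero protocol-associated features by construction.
2. **Clustering** — PAM (BUILD + SWAP) K-medoids with squared Euclidean
   distance; K is user-set (default 3) with Calinski–Harabasz,
   Davies–Bouldin and silhouette diagnostics as advisory output. Clusters
   are renumbered by death-by-disease frequency (cluster 1 = lowest risk)
   and re-tested for association with every acquisition covariate.
3. **Feature ranking** — per feature, the Euclidean distance among cluster
   centroids of the z-normalized feature,

   FR_k = √( Σ_{i<j} ( μ_k(C_i) − μ_k(C_j) )² ),

   sorted descending; interval I (FR > 1.85) and interval II
   (1.50 < FR < 1.85) mark the cluster-driving features, and a dedicated
   screen checks whether the clustering is secretly driven by tumor volume.
4. **Outcome association** — Kaplan–Meier / log-rank survival comparisons;
   Cox models unadjusted and adjusted for FIGO stage (III/IV vs I/II) and
   age; χ²/Fisher and Mann–Whitney/Kruskal–Wallis clinicopathological
   tables; per-gene cluster-vs-rest Fisher tests with FDR and an
   oncogenic-pathway aggregation.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
from radclust import GeneratorConfig, generate_cohort, run_pipeline

bundle = generate_cohort(GeneratorConfig(seed=7))      # 132-patient template
result = run_pipeline(bundle, K=3, seed=7)

print("protocol-associated features before:", result.pre_report.fraction_str)
print("protocol-associated features after: ", result.post_report.fraction_str)
print("cluster sizes:", result.clusters.sizes().to_dict())
```

prints

```
protocol-associated features before: 250/293 (85.3%)
protocol-associated features after:  0/293 (0.0%)
cluster sizes: {1: 56, 2: 43, 3: 33}
```

i.e. 85.3% of the raw features are significantly explained by acquisition
settings, none remain so after harmonization, and PAM splits the 132
patients into three clusters ordered by death frequency. Continuing,

```python
hr = result.cox_adjusted.loc["cluster_23_vs_1"]
print(f"adjusted HR cluster 2/3 vs 1: {hr['HR']:.2f} "
      f"(95% CI {hr['ci_lower']:.2f}-{hr['ci_upper']:.2f}, p={hr['pvalue']:.3f})")
```

```
adjusted HR cluster 2/3 vs 1: 2.16 (95% CI 0.78-6.00, p=0.141)
```

the age- and stage-adjusted hazard ratio for belonging to the higher-risk
clusters — at 132 patients a single synthetic cohort estimates the planted
hazard ratio (~3) with a wide confidence interval, which is exactly what
the repeated-cohort coverage checks in the test suite quantify.

The same stages are available as a command-line tool:

```bash
radclust simulate --out bundle/ --seed 5
radclust harmonize --features bundle/feature_matrix.csv --protocol bundle/protocol.csv --out harm/
radclust cluster --features harm/harmonized_matrix.csv --clinical bundle/clinical.csv \
                 --protocol bundle/protocol.csv --k 3 --seed 5 --out clusters/
radclust rank --centroids clusters/centroids.csv --out ranking/
radclust associate --clinical bundle/clinical.csv --labels clusters/labels.csv \
                   --mutations bundle/mutations.csv --out assoc/
```

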