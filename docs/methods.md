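# Methods

## Problem and model

`radclust` implements an unsupervised radiomic-profiling analysis for tumor
MRI cohorts, designed around cervical-cancer imaging: a patient × feature
matrix of 293 radiomic descriptors (14 shape features from T2-weighted
imaging plus 93 intensity/texture features for each of T2WI, high-b-value
DWI and ADC), an acquisition-protocol table, a clinical table with
disease-specific survival (DSS), and an optional binary mutation matrix.
The pipeline has four stages:

1. **Harmonization.** Radiomic features are sensitive to acquisition
   settings, so each feature is regressed (OLS) on the protocol covariates:
   voxel volume (mm³), voxel anisotropy, repetition time (ms), echo time
   (ms), flip angle (°), number of averages, field strength (1.5 T vs 3 T),
   echo train length, and phase-encoding direction; DWI- and ADC-derived
   features additionally get the highest b-value (s/mm²) and the number of
   b-values. The overall-model F-test p-value is the gate statistic;
   Benjamini–Hochberg FDR at α = 0.05 across the 293 features decides which
   features are residualized (observed minus the full linear prediction,
   intercept included — immaterial because of the final z-normalization).
   Every feature is then z-normalized (sample SD, ddof = 1).
2. **Clustering.** Patients are partitioned by K-medoids with squared
   Euclidean distance using classical PAM: greedy BUILD initialization, then
   steepest-descent SWAP until no single medoid/non-medoid exchange lowers
   the cost; best of `n_restarts` starts (BUILD first, the rest random).
   K is a user decision (default 3); Calinski–Harabasz, Davies–Bouldin and
   silhouette scores over K = 2..6 are advisory output only. Clusters are
   renumbered by ascending death-by-disease frequency, so cluster K is the
   highest-risk group, and re-tested against every protocol covariate
   (χ² for categorical, one-way ANOVA for continuous, FDR-adjusted).
3. **Feature ranking.** For each z-normalized feature k the ranking
   statistic is the Euclidean distance among the K cluster centroids,
   FR_k = sqrt( Σ_{i<j} (μ_k(C_i) − μ_k(C_j))² ). Features are sorted by
   descending FR; interval I is FR > 1.85 and interval II is
   1.50 < FR < 1.85, both strict, so FR exactly at a threshold falls in
   neither interval. A tumor-volume confound screen computes per-feature
   Spearman correlation with the volume feature (FDR-flagged), compares FR
   between volume-associated and non-associated features (Kruskal–Wallis),
   and compares mean volume across clusters (ANOVA).
4. **Outcome association.** Kaplan–Meier curves with overall and pairwise
   Mantel–Cox log-rank tests; Cox proportional-hazards models, unadjusted
   and adjusted, with covariates coded as cluster 2/3 vs 1, FIGO stage
   III/IV vs I/II, and age in years; clinicopathological tables using χ²,
   Fisher's exact (2×2 with an expected count < 5), a seeded Monte-Carlo χ²
   (larger tables with small expecteds), Mann–Whitney (two groups) or
   Kruskal–Wallis (three or more); per-gene cluster-vs-rest Fisher tests
   with FDR across tests, and an oncogenic-pathway aggregation (proportion
   of patients with ≥ 1 mutated gene per pathway, χ² across clusters).

## The FR statistic and its ambiguity

"Euclidean distance between centroids" admits two algebraic readings:
the root of the **sum of squared** pairwise differences (a true distance,
invariant to cluster relabeling), or the absolute **signed sum** of pairwise
differences, which allows sign cancellation. The first is the default; the
second is available as `RankingConfig(signed_sum=True)` for sensitivity
analysis only.

## Synthetic cohort generator

No patient-level data are distributable, so a generator produces cohorts
with the statistical structure the analysis assumes; it is first-class,
tested code, and its defaults define the study conditions used everywhere:

- **Size**: 132 patients in three clusters with proportions 52/46/34
  (largest-remainder apportionment, shuffled).
- **Features**: 293 catalog-named columns. 30 informative features (never
  the tumor-volume feature, so cluster signal is orthogonal to volume by
  construction) receive cluster means at offsets (−1, 0, +1) ×
  `cluster_separation` × `noise_sd` in a random per-feature cluster order;
  `cluster_separation` (default 2.0) is therefore the shift between
  adjacent cluster means in within-cluster SD units. Residual noise is
  i.i.d. Gaussian (`noise_sd` = 1).
- **Scanner confounding**: 85% of features receive linear protocol effects
  with coefficients ~ N(0, 0.5²) per standardized covariate (b-value
  covariates only for DWI/ADC features). This makes protocol effects
  comparable to or larger than the biological variance, which matches how
  strongly acquisition settings drive raw radiomic features, and yields a
  pre-harmonization protocol-association fraction around 85%.
- **Protocol**: four discrete scanner profiles with alternating field
  strength, phase-encoding direction and highest b-value (deterministic
  patterns keep the purely profile-level design columns linearly
  independent), per-patient multiplicative jitter (~5%) on the continuous
  fields, and per-examination draws for averages, echo train length and
  number of b-values. At least four profiles are required.
- **Survival**: exponential event times with per-cluster hazards (defaults
  5.0e-5, 1.55e-4, 2.5e-4 per day, i.e. a cluster-2/3-vs-1 hazard ratio
  near 3) and independent uniform administrative censoring over a 10-year
  horizon (`censoring_rate` is the reciprocal horizon in 1/days).
- **Clinical covariates**: cluster-dependent categorical and continuous
  distributions (FIGO rows IB/II/III/IV, histology SCC/AC/other, age,
  maximum tumor diameter) loosely patterned on a cervical-cancer cohort,
  not fitted to any particular one.
- **Mutations**: 20 recurrently mutated cervical-cancer genes at 8%
  baseline prevalence, with cluster-specific odds multipliers applied on
  the logit scale (defaults enrich chromatin/RAS genes in cluster 2 and
  PI3K/ERBB2 genes in cluster 3).

Everything is drawn from one `numpy` Generator seeded by `config.seed`, so
bundles are bit-reproducible and write/read round-trips through plain CSV
preserve them up to float representation.

### What the generator does not emulate

Real radiomic features are strongly inter-correlated (shared image content
across texture families); the generator uses independent noise because
low-rank correlated noise creates spurious cluster structure that PAM
latches onto, which would conflate two failure modes in tests. Scanner
effects are exactly linear in the encoded covariates — the best case for
the linear harmonization model; non-linear or interaction effects are not
represented. Survival depends on cluster only (proportional hazards holds
exactly), there are no competing risks, and clinical covariates are
conditionally independent given the cluster. Passing tests therefore
demonstrate correctness of the pipeline under its own model assumptions,
not robustness to their violation.

## Study conditions used in simulations

Simulation-based checks use: harmonization screens and recovery at n = 150
over 20 seeds; K-diagnostics at separation 3–4 SD; survival coverage with a
planted log-HR of 1.20 over 200 replicates and log-rank power at HR 3 over
50 cohorts. The survival experiments use a baseline hazard of 2e-4/day
(≈ 70 expected events at n = 150 over the 10-year horizon), chosen by an
a-priori power argument: the analytic log-rank power at HR 3 with ~70
events exceeds 95%, whereas the cohort-template default hazards leave too
few events for any high-power claim at this sample size. Oracle-equivalence
suites use 50 random PAM instances (n ≤ 10, K ≤ 3) against exhaustive
medoid search, 1000 random centroid triples against pair enumeration, all
10 625 2×2 tables with n ≤ 20 against hypergeometric enumeration, and 50
random p-vectors against the direct BH step-up inequality.

## Numerical and design choices

- **Gate statistic**: overall F-test of the per-feature OLS model;
  a perfectly fitted feature (zero residual) is treated as p = 0, a
  constant feature as p = 1 and never residualized. Residualizing cannot
  create new FDR hits: residualized features refit to p ≈ 1, and
  BH-adjusted p-values of untouched features can only grow when other
  p-values rise, which forces the post-harmonization screen to zero — and
  makes harmonization idempotent to < 1e-8.
- **Encodings**: field strength as a 3 T indicator; phase-encoding
  direction one-hot with the first observed level as reference. A
  rank-deficient design is an error naming the collinear columns; missing
  covariates are refused by default, with an explicit row-drop mode that
  logs the excluded patients.
- **PAM determinism**: all ties (assignment, BUILD, SWAP, restarts) break
  toward the lowest patient index; restarts are controlled by the seed.
  Duplicated patients are allowed.
- **K-medoids vs mean-based clustering**: each medoid carries its own
  noise vector of magnitude ~√p, so at weak planted signal in high
  dimensions the k-medoids optimum recovers the planted partition less
  reliably than centroid-based methods — the recovery figures reported by
  the acceptance script quantify this on the default conditions. This is a
  property of the estimator, not of the implementation: on a shared cohort
  our PAM and R's `cluster::pam` (squared-Euclidean dissimilarity) return
  identical costs and identical partitions, and on small instances PAM
  matches exhaustive search exactly.
- **Relabeling ties**: equal death frequencies keep the original label
  order.
- **Cox ties**: Efron's partial-likelihood approximation (the `lifelines`
  estimator); synthetic survival times are continuous, so ties have
  measure zero.
- **Fisher switching**: Fisher's exact test replaces χ² only for 2×2
  tables with an expected count below 5; larger sparse tables use a seeded
  permutation null for the χ² statistic (2000 draws, add-one p-value).
- **Interval boundaries**: FR = 1.85 and FR = 1.50 fall in no interval
  (strict inequalities).

## Limitations

The feature catalog records names, series and groups only; no image-level
extraction is performed, and extraction settings (bin width, Laplacian of
Gaussian sigmas) are documentation, not executed code. K selection is
deliberately manual. The per-gene test (cluster vs rest, best cluster
reported) does not adjust for selecting the best of K clusters beyond the
FDR across tests. The pipeline reports pairwise log-rank p-values without
multiplicity adjustment by default (`adjust_pairwise=True` applies a
Bonferroni correction over the pairs).
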