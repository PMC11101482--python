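"""Synthetic cervical-cancer radiomics cohort generator.

Emulates the statistical structure the downstream pipeline assumes: a planted
K-cluster signal in a subset of radiomic features, low-rank linear scanner/
protocol confounding shared across features, cluster-dependent disease-specific
survival with administrative censoring, cluster-dependent clinicopathological
covariates, and a sparse binary mutation matrix with cluster-enriched genes.

Defaults mirror the study template this package targets: 132 patients split
52/46/34 across three clusters, 293 catalog features, scanner effects planted
on 85% of features, and exponential hazards whose cluster-2/3-vs-1 log hazard
ratio is about log 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import TUMOR_VOLUME_FEATURE, build_catalog
from .cohort import CohortBundle, SyntheticTruth

__all__ = ["MutationConfig", "GeneratorConfig", "generate_cohort"]

# Recurrently mutated cervical-cancer genes used as default mutation panel.
_DEFAULT_GENES = (
    "PIK3CA", "KMT2D", "KRAS", "EP300", "FBXW7", "ERBB2", "TP53", "MAPK1",
    "HLA-B", "NFE2L2", "ARID1A", "PTEN", "STK11", "CREBBP", "DDX3X", "CASP8",
    "SHKBP1", "TGFBR2", "RB1", "SMAD4",
)

_PHASE_DIRECTIONS = ("ROW", "COL")


@dataclass
class MutationConfig:
    """Sparse binary mutation matrix parameters."""

    genes: tuple[str, ...] = _DEFAULT_GENES
    baseline_rate: float = 0.08
    #: cluster label -> {gene: odds multiplier} applied on the logit scale
    enrichment: dict = field(default_factory=lambda: {
        2: {"KMT2D": 6.0, "KRAS": 6.0, "EP300": 4.0},
        3: {"PIK3CA": 6.0, "ERBB2": 5.0, "DDX3X": 4.0, "CREBBP": 4.0},
    })

    def validate(self) -> None:
        if not 0.0 < self.baseline_rate < 1.0:
            raise ValueError("baseline mutation rate must be in (0, 1)")
        for genes in self.enrichment.values():
            for g, odds in genes.items():
                if g not in self.genes:
                    raise ValueError(f"enriched gene {g!r} not in gene panel")
                if odds <= 0:
                    raise ValueError("enrichment odds must be positive")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    cluster_separation is the shift between adjacent cluster means of an
    informative feature, in within-cluster SD units. scanner_effect_scale is
    the SD of planted protocol coefficients relative to the residual SD.
    censoring_rate is the reciprocal of the administrative follow-up horizon
    (per day); censoring times are uniform on (0, 1/censoring_rate).
    """

    n_patients: int = 132
    n_features: int = 293
    n_clusters: int = 3
    cluster_proportions: tuple[float, ...] = (52 / 132, 46 / 132, 34 / 132)
    n_informative_features: int = 30
    cluster_separation: float = 2.0
    scanner_effect_fraction: float = 0.85
    scanner_effect_scale: float = 0.5
    noise_sd: float = 1.0
    n_scanner_profiles: int = 4
    #: exponential event rates per cluster, per day
    hazard_per_cluster: tuple[float, ...] = (5.0e-5, 1.55e-4, 2.5e-4)
    censoring_rate: float = 1.0 / 3650.0
    mutations: MutationConfig | None = field(default_factory=MutationConfig)
    #: features never carrying cluster signal (cluster signal orthogonal to volume)
    exclude_from_informative: tuple[str, ...] = (TUMOR_VOLUME_FEATURE,)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_features, self.n_clusters) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_scanner_profiles < 4:
            raise ValueError("need at least 4 scanner profiles for an "
                             "identifiable protocol design")
        if len(self.cluster_proportions) != self.n_clusters:
            raise ValueError("cluster_proportions length must equal n_clusters")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must sum to 1")
        if min(self.cluster_proportions) <= 0:
            raise ValueError("degenerate cluster proportions")
        if not 0 <= self.n_informative_features <= self.n_features:
            raise ValueError("n_informative_features exceeds n_features")
        if not 0.0 <= self.scanner_effect_fraction <= 1.0:
            raise ValueError("scanner_effect_fraction must be in [0, 1]")
        if len(self.hazard_per_cluster) != self.n_clusters:
            raise ValueError("hazard_per_cluster length must equal n_clusters")
        if min(self.hazard_per_cluster) <= 0:
            raise ValueError("hazard parameters must be strictly positive")
        if self.censoring_rate <= 0 or self.noise_sd <= 0:
            raise ValueError("censoring_rate and noise_sd must be positive")
        if self.mutations is not None:
            self.mutations.validate()


def _cluster_counts(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of n patients to clusters."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    counts[order[: n - counts.sum()]] += 1
    return counts


def _feature_names(config: GeneratorConfig) -> list[str]:
    if config.n_features == 293:
        return build_catalog().names
    return [f"feature_{i:04d}" for i in range(config.n_features)]


def _sample_protocol(config: GeneratorConfig, rng: np.random.Generator,
                     index: pd.Index) -> pd.DataFrame:
    """Draw discrete scanner profiles, assign patients, jitter per-patient fields.

    Field strength, phase-encoding direction and highest b-value follow
    deterministic alternating patterns across profiles so that the purely
    profile-level covariates stay linearly independent; acquisition settings
    that realistically vary per examination (averages, echo train length,
    number of b-values, and all continuous fields) vary per patient.
    """
    m = config.n_scanner_profiles
    i = np.arange(m)
    profiles = pd.DataFrame({
        "slice_thickness": rng.uniform(3.0, 5.0, m),
        "pixel_size": rng.uniform(0.5, 1.0, m),
        "repetition_time": rng.uniform(3000.0, 6500.0, m),
        "echo_time": rng.uniform(80.0, 120.0, m),
        "flip_angle": rng.uniform(90.0, 160.0, m),
        "field_strength": np.where(i % 2 == 0, 1.5, 3.0),
        "echo_train_length": rng.integers(16, 33, m),
        "phase_encoding_direction": np.where((i // 2) % 2 == 0,
                                             *_PHASE_DIRECTIONS),
        "highest_b_value": np.where(((i + 1) // 2) % 2 == 0, 800, 1000),
    })
    assignment = rng.integers(0, m, config.n_patients)
    table = profiles.iloc[assignment].reset_index(drop=True)
    jitter_cols = ["slice_thickness", "pixel_size", "repetition_time",
                   "echo_time", "flip_angle"]
    jitter = rng.normal(1.0, 0.05, (config.n_patients, len(jitter_cols)))
    table[jitter_cols] = table[jitter_cols].to_numpy() * np.clip(jitter, 0.7, 1.3)
    table["voxel_volume"] = table["slice_thickness"] * table["pixel_size"] ** 2
    table["voxel_anisotropy"] = table["slice_thickness"] / table["pixel_size"]
    table = table.drop(columns=["slice_thickness", "pixel_size"])
    table["n_averages"] = rng.integers(1, 4, config.n_patients)
    table["echo_train_length"] = np.clip(
        table["echo_train_length"].to_numpy() + rng.integers(-2, 3, config.n_patients),
        8, 40)
    table["n_b_values"] = rng.integers(2, 5, config.n_patients)
    table.index = index
    cols = ["voxel_volume", "voxel_anisotropy", "repetition_time", "echo_time",
            "flip_angle", "n_averages", "field_strength", "echo_train_length",
            "phase_encoding_direction", "highest_b_value", "n_b_values"]
    return table[cols]


def _planting_design(protocol: pd.DataFrame) -> pd.DataFrame:
    """Standardized covariate encoding used to plant scanner effects."""
    design = pd.DataFrame(index=protocol.index)
    for col in ("voxel_volume", "voxel_anisotropy", "repetition_time",
                "echo_time", "flip_angle", "n_averages", "echo_train_length",
                "highest_b_value", "n_b_values"):
        x = protocol[col].astype(float)
        sd = x.std(ddof=0)
        design[col] = (x - x.mean()) / sd if sd > 0 else 0.0
    design["field_strength_3T"] = (protocol["field_strength"] == 3.0).astype(float)
    design["phase_encoding_COL"] = (
        protocol["phase_encoding_direction"] == "COL"
    ).astype(float)
    return design


# columns of the planting design applied only to DWI/ADC-derived features
_DWI_ONLY = ("highest_b_value", "n_b_values")


def _sample_clinical(config: GeneratorConfig, rng: np.random.Generator,
                     labels: np.ndarray, index: pd.Index) -> pd.DataFrame:
    """Cluster-dependent clinical covariates and disease-specific survival."""
    K = config.n_clusters
    # per-cluster parameters, recycled beyond three clusters
    age_mu = [48.0, 41.0, 55.0]
    figo_p = [(0.44, 0.25, 0.27, 0.04),
              (0.30, 0.22, 0.39, 0.09),
              (0.12, 0.21, 0.41, 0.26)]
    hist_p = [(0.73, 0.15, 0.12), (0.72, 0.26, 0.02), (0.94, 0.03, 0.03)]
    diam_median = [3.2, 4.5, 6.0]

    n = config.n_patients
    age = np.empty(n)
    figo = np.empty(n, dtype=object)
    hist = np.empty(n, dtype=object)
    diam = np.empty(n)
    time = np.empty(n)
    event = np.empty(n, dtype=int)
    horizon = 1.0 / config.censoring_rate
    for i, lab in enumerate(labels):
        k = (lab - 1) % 3
        age[i] = np.clip(rng.normal(age_mu[k], 13.0), 23.0, 95.0)
        figo[i] = rng.choice(["IB", "II", "III", "IV"], p=figo_p[k])
        hist[i] = rng.choice(["SCC", "AC", "Other"], p=hist_p[k])
        diam[i] = np.clip(rng.lognormal(np.log(diam_median[k]), 0.4), 0.5, 15.0)
        t_event = rng.exponential(1.0 / config.hazard_per_cluster[lab - 1])
        t_censor = rng.uniform(0.0, horizon)
        time[i] = max(min(t_event, t_censor), 1.0)
        event[i] = int(t_event <= t_censor)
    return pd.DataFrame({
        "dss_time": np.round(time, 1),
        "dss_event": event,
        "figo_stage": figo,
        "age": np.round(age, 1),
        "histology": hist,
        "max_tumor_diameter": np.round(diam, 2),
    }, index=index)


def _sample_mutations(config: GeneratorConfig, rng: np.random.Generator,
                      labels: np.ndarray, index: pd.Index) -> pd.DataFrame:
    mc = config.mutations
    base_logit = np.log(mc.baseline_rate / (1.0 - mc.baseline_rate))
    probs = np.full((config.n_patients, len(mc.genes)), mc.baseline_rate)
    for j, gene in enumerate(mc.genes):
        for k, enriched in mc.enrichment.items():
            if gene in enriched:
                logit = base_logit + np.log(enriched[gene])
                probs[labels == k, j] = 1.0 / (1.0 + np.exp(-logit))
    calls = (rng.uniform(size=probs.shape) < probs).astype(int)
    return pd.DataFrame(calls, index=index, columns=list(mc.genes))


def generate_cohort(config: GeneratorConfig | None = None) -> CohortBundle:
    """Generate one synthetic cohort; deterministic given ``config.seed``.

    Feature value for patient i, feature j:
    ``cluster_mean(label_i, j) + sum_c beta_jc * x_ic + eps``, with
    ``eps ~ Normal(0, noise_sd)``.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    index = pd.Index([f"P{i + 1:03d}" for i in range(config.n_patients)],
                     name="patient_id")
    names = _feature_names(config)

    counts = _cluster_counts(config.n_patients, config.cluster_proportions)
    labels = rng.permutation(np.repeat(np.arange(1, config.n_clusters + 1), counts))

    protocol = _sample_protocol(config, rng, index)
    design = _planting_design(protocol)

    # planted cluster signal
    eligible = [n for n in names if n not in config.exclude_from_informative]
    informative = sorted(
        rng.choice(eligible, size=min(config.n_informative_features, len(eligible)),
                   replace=False).tolist()
    )
    centered = np.arange(config.n_clusters) - (config.n_clusters - 1) / 2.0
    values = rng.normal(0.0, config.noise_sd,
                        (config.n_patients, config.n_features))
    name_pos = {n: j for j, n in enumerate(names)}
    for feat in informative:
        offsets = rng.permutation(centered) * config.cluster_separation * config.noise_sd
        values[:, name_pos[feat]] += offsets[labels - 1]

    # planted scanner effects
    n_confounded = int(round(config.scanner_effect_fraction * config.n_features))
    confounded = rng.choice(names, size=n_confounded, replace=False)
    coef = pd.DataFrame(0.0, index=names, columns=design.columns)
    catalog = build_catalog() if config.n_features == 293 else None
    beta_sd = config.scanner_effect_scale * config.noise_sd
    for feat in confounded:
        beta = rng.normal(0.0, beta_sd, design.shape[1])
        if catalog is not None and not catalog.is_diffusion_derived(feat):
            beta[[design.columns.get_loc(c) for c in _DWI_ONLY]] = 0.0
        coef.loc[feat] = beta
    values += design.to_numpy() @ coef.to_numpy().T

    features = pd.DataFrame(values, index=index, columns=names)
    clinical = _sample_clinical(config, rng, labels, index)
    mutations = (_sample_mutations(config, rng, labels, index)
                 if config.mutations is not None else None)

    h = np.asarray(config.hazard_per_cluster)
    truth = SyntheticTruth(
        true_cluster_label=pd.Series(labels, index=index, name="true_cluster_label"),
        informative_feature_ids=informative,
        planted_protocol_coefficients=coef,
        planted_log_hazard_ratios=list(np.log(h / h[0])),
    )
    return CohortBundle(features, protocol, clinical, mutations, truth)
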