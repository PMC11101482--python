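"""Protocol harmonization of radiomic features.

Each radiomic feature is regressed on the MRI acquisition covariates (ordinary
least squares). The overall-model F-test p-value says whether acquisition
settings explain the feature; Benjamini-Hochberg FDR across the features gates
which ones are residualized (observed value minus the full linear prediction).
Every feature is finally z-normalized. Features from diffusion-derived series
(high-b DWI, ADC) additionally get the highest b-value and the number of
b-values as explanatory variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .catalog import FeatureCatalog
from .cohort import PROTOCOL_CONTINUOUS

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationConfig", "FeatureModel", "HarmonizationResult",
    "build_design", "fit_protocol_models", "fdr_gate", "residualize_and_znorm",
    "association_report", "harmonize",
]

_DWI_EXTRA = ("highest_b_value", "n_b_values")


@dataclass
class HarmonizationConfig:
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"   # Benjamini-Hochberg step-up

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FeatureModel:
    """Fitted per-feature protocol model and normalization record."""

    feature: str
    design_kind: str                 # "base" or "dwi"
    params: pd.Series                # coefficient per design column
    pvalue: float                    # overall F-test
    resid_sd: float
    flagged: bool = False            # FDR decision; True => residualized
    qvalue: float = float("nan")
    znorm_mean: float = float("nan")
    znorm_sd: float = float("nan")


@dataclass
class HarmonizationResult:
    models: dict[str, FeatureModel]
    designs: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: HarmonizationConfig = field(default_factory=HarmonizationConfig)

    @property
    def n_flagged(self) -> int:
        return sum(m.flagged for m in self.models.values())

    def pvalues(self) -> pd.Series:
        return pd.Series({f: m.pvalue for f, m in self.models.items()})

    def coefficient_table(self) -> pd.DataFrame:
        """Feature x design-column coefficients with p, q and FDR flag."""
        rows = {}
        for f, m in self.models.items():
            row = m.params.to_dict()
            row.update(pvalue=m.pvalue, qvalue=m.qvalue, fdr_significant=m.flagged)
            rows[f] = row
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature")


def build_design(protocol_table: pd.DataFrame, dwi: bool = False) -> pd.DataFrame:
    """Encode acquisition covariates as a full-rank OLS design with intercept.

    Continuous covariates enter as-is; field strength becomes a 3T indicator;
    phase-encoding direction is one-hot with the first observed level dropped.
    With ``dwi=True`` the two b-value covariates are appended.
    """
    if protocol_table.isna().any().any():
        bad = protocol_table.columns[protocol_table.isna().any()].tolist()
        raise ValueError(f"protocol table has missing values in: {', '.join(bad)}")
    design = pd.DataFrame(index=protocol_table.index)
    design["intercept"] = 1.0
    for col in PROTOCOL_CONTINUOUS:
        design[col] = protocol_table[col].astype(float)
    design["field_strength_3T"] = (
        protocol_table["field_strength"].astype(float) == 3.0
    ).astype(float)
    levels = pd.unique(protocol_table["phase_encoding_direction"])
    for level in levels[1:]:  # first observed level is the reference
        design[f"phase_encoding_{level}"] = (
            protocol_table["phase_encoding_direction"] == level
        ).astype(float)
    if dwi:
        for col in _DWI_EXTRA:
            design[col] = protocol_table[col].astype(float)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns with (near) zero pivots in the QR factorization
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = design.columns[r < 1e-8 * max(r.max(), 1.0)].tolist()
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {', '.join(bad) or 'undetermined'}"
        )


def fit_protocol_models(
    matrix: pd.DataFrame,
    protocol_table: pd.DataFrame,
    catalog: FeatureCatalog | None = None,
    config: HarmonizationConfig | None = None,
    drop_missing: bool = False,
) -> HarmonizationResult:
    """Fit one OLS protocol model per feature.

    Rows with missing covariates are refused unless ``drop_missing`` is set,
    in which case they are dropped with a logged warning. A constant feature
    gets p-value 1 and is never residualized.
    """
    config = config or HarmonizationConfig()
    if not matrix.index.equals(protocol_table.index):
        raise ValueError("feature matrix and protocol table indices differ")
    if protocol_table.isna().any().any():
        if not drop_missing:
            raise ValueError(
                "protocol table has missing covariates; pass drop_missing=True "
                "to drop those patients"
            )
        keep = protocol_table.dropna().index
        dropped = protocol_table.index.difference(keep).tolist()
        logger.warning("dropping %d patients with missing covariates: %s",
                       len(dropped), dropped)
        protocol_table = protocol_table.loc[keep]
        matrix = matrix.loc[keep]

    designs = {"base": build_design(protocol_table, dwi=False),
               "dwi": build_design(protocol_table, dwi=True)}
    models: dict[str, FeatureModel] = {}
    for feat in matrix.columns:
        kind = ("dwi" if catalog is not None and catalog.is_diffusion_derived(feat)
                else "base")
        X = designs[kind]
        y = matrix[feat].to_numpy(float)
        if np.ptp(y) == 0.0:
            logger.info("feature %s is constant; protocol model skipped", feat)
            models[feat] = FeatureModel(
                feature=feat, design_kind=kind,
                params=pd.Series(0.0, index=X.columns),
                pvalue=1.0, resid_sd=0.0,
            )
            continue
        fit = sm.OLS(y, X).fit()
        pval = float(fit.f_pvalue)
        if not np.isfinite(pval):  # perfect fit: zero residual variance
            pval = 0.0
        models[feat] = FeatureModel(
            feature=feat, design_kind=kind,
            params=pd.Series(fit.params.to_numpy(), index=X.columns),
            pvalue=pval,
            resid_sd=float(np.sqrt(max(fit.mse_resid, 0.0)))
            if np.isfinite(fit.mse_resid) else 0.0,
        )
    return HarmonizationResult(models=models, designs=designs, config=config)


def fdr_gate(result: HarmonizationResult,
             config: HarmonizationConfig | None = None) -> HarmonizationResult:
    """Set FDR flags: a feature is residualized iff its BH-adjusted p <= alpha."""
    config = config or result.config
    feats = list(result.models)
    pvals = np.array([result.models[f].pvalue for f in feats])
    reject, qvals, _, _ = multipletests(pvals, alpha=config.alpha,
                                        method=config.fdr_method)
    for f, rej, q in zip(feats, reject, qvals):
        m = result.models[f]
        m.flagged = bool(rej)
        m.qvalue = float(q)
        # constant features stay untouched regardless of nominal p
        if m.resid_sd == 0.0 and m.pvalue == 1.0:
            m.flagged = False
    result.config = config
    return result


def residualize_and_znorm(matrix: pd.DataFrame,
                          result: HarmonizationResult) -> pd.DataFrame:
    """Subtract the fitted protocol prediction for flagged features, z-normalize all.

    Output columns have sample mean 0 and SD 1 (ddof=1). A zero-variance
    residual is an error naming the feature.
    """
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for feat in matrix.columns:
        m = result.models[feat]
        y = matrix[feat].to_numpy(float)
        if m.flagged:
            X = result.designs[m.design_kind]
            y = y - X.to_numpy(float) @ m.params.to_numpy()
        mu, sd = float(np.mean(y)), float(np.std(y, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance residual for feature {feat!r}")
        m.znorm_mean, m.znorm_sd = mu, sd
        out[feat] = (y - mu) / sd
    return out


@dataclass
class AssociationReport:
    """Protocol-association screen of a feature matrix at a pipeline stage."""

    stage: str
    n_significant: int
    n_features: int
    significant_features: tuple[str, ...]
    table: pd.DataFrame    # feature, pvalue, qvalue, fdr_significant

    @property
    def fraction_str(self) -> str:
        pct = 100.0 * self.n_significant / self.n_features
        return f"{self.n_significant}/{self.n_features} ({pct:.1f}%)"


def association_report(
    matrix: pd.DataFrame,
    protocol_table: pd.DataFrame,
    catalog: FeatureCatalog | None = None,
    config: HarmonizationConfig | None = None,
    stage_label: str = "",
) -> AssociationReport:
    """Count features with an FDR-significant protocol model at this stage."""
    config = config or HarmonizationConfig()
    result = fdr_gate(fit_protocol_models(matrix, protocol_table, catalog, config),
                      config)
    sig = tuple(f for f, m in result.models.items() if m.flagged)
    table = pd.DataFrame({
        "feature": list(result.models),
        "pvalue": [m.pvalue for m in result.models.values()],
        "qvalue": [m.qvalue for m in result.models.values()],
        "fdr_significant": [m.flagged for m in result.models.values()],
    }).set_index("feature")
    return AssociationReport(stage=stage_label, n_significant=len(sig),
                             n_features=matrix.shape[1],
                             significant_features=sig, table=table)


def harmonize(
    matrix: pd.DataFrame,
    protocol_table: pd.DataFrame,
    catalog: FeatureCatalog | None = None,
    config: HarmonizationConfig | None = None,
    drop_missing: bool = False,
) -> tuple[pd.DataFrame, HarmonizationResult]:
    """Fit, gate and residualize in one call; returns (harmonized, result)."""
    config = config or HarmonizationConfig()
    result = fdr_gate(
        fit_protocol_models(matrix, protocol_table, catalog, config, drop_missing),
        config,
    )
    if drop_missing:
        matrix = matrix.loc[result.designs["base"].index]
    return residualize_and_znorm(matrix, result), result
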