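"""Radiomic feature catalog: the 293-feature schema.

Features follow pyradiomics naming conventions. Fourteen shape descriptors are
computed from the T2-weighted series only; the remaining 93 intensity/texture
descriptors (first-order plus five texture families) are computed once per MR
series (T2WI, high b-value DWI, ADC), giving 14 + 3 x 93 = 293 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "FeatureDescriptor",
    "FeatureCatalog",
    "build_catalog",
    "validate_matrix",
    "SERIES",
    "GROUPS",
    "TUMOR_VOLUME_FEATURE",
]

#: MR series a feature can originate from.
SERIES = ("shape(T2WI)", "T2WI", "high-b DWI", "ADC")

#: Radiomic feature groups (pyradiomics feature classes).
GROUPS = ("shape", "firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm")

# Default-enabled pyradiomics v3 feature names per class.
_SHAPE = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)
_FIRSTORDER = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
_GLCM = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MCC", "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
_GLDM = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
_GLRLM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
_GLSZM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
_NGTDM = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

_PER_SERIES_GROUPS = (
    ("firstorder", _FIRSTORDER),
    ("glcm", _GLCM),
    ("gldm", _GLDM),
    ("glrlm", _GLRLM),
    ("glszm", _GLSZM),
    ("ngtdm", _NGTDM),
)

_SERIES_PREFIX = {"T2WI": "T2WI", "high-b DWI": "DWI", "ADC": "ADC"}

#: Column name of the tumor-volume shape feature.
TUMOR_VOLUME_FEATURE = "T2WI_shape_MeshVolume"


@dataclass(frozen=True)
class FeatureDescriptor:
    """One radiomic feature: its column name, source MR series and group."""

    name: str
    series: str
    group: str

    def __post_init__(self) -> None:
        if self.series not in SERIES:
            raise ValueError(f"unknown series {self.series!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if (self.group == "shape") != (self.series == "shape(T2WI)"):
            raise ValueError("shape group and shape(T2WI) series must coincide")


class FeatureCatalog:
    """Ordered collection of :class:`FeatureDescriptor` with lookup helpers."""

    version = "1.0"

    def __init__(self, descriptors: Iterable[FeatureDescriptor]):
        self.descriptors = tuple(descriptors)
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalog")
        self._by_name = {d.name: d for d in self.descriptors}

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def descriptor(self, name: str) -> FeatureDescriptor:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"feature {name!r} not in catalog") from None

    def series_of(self, name: str) -> str:
        return self.descriptor(name).series

    def group_of(self, name: str) -> str:
        return self.descriptor(name).group

    def is_diffusion_derived(self, name: str) -> bool:
        """True for features from DWI or ADC series (extra b-value covariates)."""
        return self.descriptor(name).series in ("high-b DWI", "ADC")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names,
             "series": [d.series for d in self.descriptors],
             "group": [d.group for d in self.descriptors]}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_catalog() -> FeatureCatalog:
    """Build the canonical 293-feature catalog.

    Order is deterministic: the 14 shape features first, then for each of the
    three intensity series (T2WI, high-b DWI, ADC) the 93 features grouped by
    feature class.
    """
    descriptors: list[FeatureDescriptor] = [
        FeatureDescriptor(f"T2WI_shape_{n}", "shape(T2WI)", "shape") for n in _SHAPE
    ]
    for series in ("T2WI", "high-b DWI", "ADC"):
        prefix = _SERIES_PREFIX[series]
        for group, names in _PER_SERIES_GROUPS:
            descriptors.extend(
                FeatureDescriptor(f"{prefix}_{group}_{n}", series, group)
                for n in names
            )
    return FeatureCatalog(descriptors)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a feature matrix against a catalog."""

    n_expected: int
    n_found: int
    missing: tuple[str, ...]
    extra: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.missing and not self.extra

    def __str__(self) -> str:
        if self.passed:
            return f"OK: {self.n_found} columns match catalog"
        parts = [f"FAIL: {self.n_found} columns vs {self.n_expected} expected"]
        if self.missing:
            parts.append("missing: " + ", ".join(self.missing))
        if self.extra:
            parts.append("extra: " + ", ".join(self.extra))
        return "; ".join(parts)


def validate_matrix(matrix: pd.DataFrame, catalog: FeatureCatalog) -> ValidationReport:
    """Check that matrix columns equal the catalog names (order-insensitive)."""
    cols = set(matrix.columns)
    expected = set(catalog.names)
    return ValidationReport(
        n_expected=len(catalog),
        n_found=len(matrix.columns),
        missing=tuple(sorted(expected - cols)),
        extra=tuple(sorted(cols - expected)),
    )
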