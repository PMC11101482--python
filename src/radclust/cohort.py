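"""Cohort bundle: aligned feature / protocol / clinical / mutation tables.

All tables share one ``patient_id`` index in identical order. On disk a bundle
is a directory of plain CSV files (UTF-8, '.' decimal) plus an optional
``truth.json`` carrying the simulation ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticTruth", "CohortBundle", "SchemaError", "write_bundle", "read_bundle"]

#: Acquisition-protocol covariates, by type.
PROTOCOL_CONTINUOUS = (
    "voxel_volume", "voxel_anisotropy", "repetition_time", "echo_time",
    "flip_angle", "n_averages", "echo_train_length",
)
PROTOCOL_CATEGORICAL = ("field_strength", "phase_encoding_direction")
PROTOCOL_DWI = ("highest_b_value", "n_b_values")
PROTOCOL_COLUMNS = PROTOCOL_CONTINUOUS + PROTOCOL_CATEGORICAL + PROTOCOL_DWI

CLINICAL_COLUMNS = (
    "dss_time", "dss_event", "figo_stage", "age", "histology",
    "max_tumor_diameter",
)


class SchemaError(ValueError):
    """A bundle table is missing columns or patient IDs are misaligned."""


@dataclass
class SyntheticTruth:
    """Ground truth planted by the cohort generator."""

    true_cluster_label: pd.Series          # per patient, values 1..K
    informative_feature_ids: list[str]
    planted_protocol_coefficients: pd.DataFrame  # feature x design-covariate
    planted_log_hazard_ratios: list[float]       # per cluster, vs cluster 1

    def to_dict(self) -> dict:
        return {
            "true_cluster_label": {str(k): int(v) for k, v in self.true_cluster_label.items()},
            "informative_feature_ids": list(self.informative_feature_ids),
            "planted_protocol_coefficients": {
                "index": list(self.planted_protocol_coefficients.index),
                "columns": list(self.planted_protocol_coefficients.columns),
                "data": self.planted_protocol_coefficients.to_numpy().tolist(),
            },
            "planted_log_hazard_ratios": [float(x) for x in self.planted_log_hazard_ratios],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        coef = d["planted_protocol_coefficients"]
        return cls(
            true_cluster_label=pd.Series(
                {k: int(v) for k, v in d["true_cluster_label"].items()},
                name="true_cluster_label",
            ).rename_axis("patient_id"),
            informative_feature_ids=list(d["informative_feature_ids"]),
            planted_protocol_coefficients=pd.DataFrame(
                coef["data"], index=coef["index"], columns=coef["columns"]
            ),
            planted_log_hazard_ratios=[float(x) for x in d["planted_log_hazard_ratios"]],
        )


@dataclass
class CohortBundle:
    """Aligned patient-level tables for one cohort."""

    feature_matrix: pd.DataFrame
    protocol_table: pd.DataFrame
    clinical_table: pd.DataFrame
    mutation_matrix: pd.DataFrame | None = None
    truth: SyntheticTruth | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def patient_ids(self) -> pd.Index:
        return self.feature_matrix.index

    @property
    def n_patients(self) -> int:
        return len(self.feature_matrix)

    def validate(self) -> None:
        idx = self.feature_matrix.index
        for label, table in (("protocol", self.protocol_table),
                             ("clinical", self.clinical_table)):
            if not table.index.equals(idx):
                raise SchemaError(f"{label} table patient_id index misaligned with features")
        if self.mutation_matrix is not None and not self.mutation_matrix.index.equals(idx):
            raise SchemaError("mutation matrix patient_id index misaligned with features")
        missing = [c for c in PROTOCOL_COLUMNS if c not in self.protocol_table.columns]
        if missing:
            raise SchemaError(f"protocol table missing columns: {', '.join(missing)}")
        missing = [c for c in CLINICAL_COLUMNS if c not in self.clinical_table.columns]
        if missing:
            raise SchemaError(f"clinical table missing columns: {', '.join(missing)}")
        if (self.clinical_table["dss_time"] <= 0).any():
            raise SchemaError("dss_time must be positive")
        if not self.clinical_table["dss_event"].isin([0, 1]).all():
            raise SchemaError("dss_event must be binary 0/1")

    def equals(self, other: "CohortBundle", rtol: float = 1e-12) -> bool:
        """Equality up to float representation (for round-trip checks)."""
        if not self.feature_matrix.index.equals(other.feature_matrix.index):
            return False
        if not np.allclose(self.feature_matrix.to_numpy(),
                           other.feature_matrix.to_numpy(), rtol=rtol):
            return False
        for a, b in ((self.protocol_table, other.protocol_table),
                     (self.clinical_table, other.clinical_table)):
            try:
                pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=rtol)
            except AssertionError:
                return False
        if (self.mutation_matrix is None) != (other.mutation_matrix is None):
            return False
        if self.mutation_matrix is not None:
            if not self.mutation_matrix.equals(other.mutation_matrix):
                return False
        return True


def write_bundle(bundle: CohortBundle, directory) -> list[Path]:
    """Write a bundle as CSV files (+ truth.json); returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = directory / name
        df.rename_axis("patient_id").to_csv(path, index=True)
        written.append(path)

    _write(bundle.feature_matrix, "feature_matrix.csv")
    _write(bundle.protocol_table, "protocol.csv")
    _write(bundle.clinical_table, "clinical.csv")
    if bundle.mutation_matrix is not None:
        _write(bundle.mutation_matrix, "mutations.csv")
    if bundle.truth is not None:
        path = directory / "truth.json"
        path.write_text(json.dumps(bundle.truth.to_dict(), indent=1))
        written.append(path)
    return written


def read_bundle(directory) -> CohortBundle:
    """Read a bundle written by :func:`write_bundle`; validates the schema."""
    directory = Path(directory)

    def _read(name: str, **kw) -> pd.DataFrame:
        path = directory / name
        if not path.exists():
            raise SchemaError(f"bundle file missing: {name}")
        df = pd.read_csv(path, **kw)
        if "patient_id" not in df.columns:
            raise SchemaError(f"{name}: missing patient_id column")
        return df.set_index("patient_id")

    features = _read("feature_matrix.csv")
    protocol = _read("protocol.csv")
    clinical = _read("clinical.csv")
    mutations = None
    if (directory / "mutations.csv").exists():
        mutations = _read("mutations.csv")
    truth = None
    if (directory / "truth.json").exists():
        truth = SyntheticTruth.from_dict(json.loads((directory / "truth.json").read_text()))
        # patient ids round-trip as strings; realign to the feature index dtype
        truth.true_cluster_label.index = truth.true_cluster_label.index.map(
            dict(zip(map(str, features.index), features.index))
        )
    return CohortBundle(features, protocol, clinical, mutations, truth)
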