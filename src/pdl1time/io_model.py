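"""Domain model and tabular I/O for spatially profiled MIBC cohorts.

The pipeline consumes three flat tables, all UTF-8 comma-separated CSV with a
mandatory header row and ``.`` decimal separator:

``densities.csv``
    One row per (patient, TMA core, immune marker): positive-cell density in
    cells per mm² for CD3, CD8, FOXP3, CD56, CD68, CTLA-4, LAG3, PD-1 and
    Granzyme B, annotated with the core's region (invasion front or tumor
    center) and a pathologist QC flag.
``assays.csv``
    One row per (patient, PD-L1 companion diagnostic assay): immune-cell area
    percentage (IC%), tumor-cell percentage (TC%) and combined positive score
    (CPS) for SP142, SP263, 22C3 and 28-8.
``annotations.csv``
    One row per patient: sTILs percentage, disease-specific and disease-free
    survival (months, event flags) and the clinical adjustment covariates.

Readers validate every row and report row-level diagnostics; writers produce
files that round-trip bit-stably through :func:`read_cohort`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import pydantic
from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "Marker",
    "Assay",
    "MarkerDensityRecord",
    "PDL1AssayReadout",
    "PatientAnnotation",
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "filter_qc",
    "DENSITY_COLUMNS",
    "ASSAY_COLUMNS",
    "ANNOTATION_COLUMNS",
    "COVARIATE_KEYS",
]


class Region(str, enum.Enum):
    """TMA sampling region within the tumor."""

    INVASION_FRONT = "invasion_front"
    TUMOR_CENTER = "tumor_center"


class Marker(str, enum.Enum):
    """Immune-cell markers quantified per mm² on the TMA cores."""

    CD3 = "CD3"
    CD8 = "CD8"
    FOXP3 = "FOXP3"
    CD56 = "CD56"
    CD68 = "CD68"
    CTLA4 = "CTLA4"
    LAG3 = "LAG3"
    PD1 = "PD1"
    GZMB = "GZMB"


class Assay(str, enum.Enum):
    """PD-L1 companion diagnostic assays."""

    SP142 = "SP142"
    SP263 = "SP263"
    C22C3 = "22C3"
    C28_8 = "28-8"


# accepted input spellings, canonicalized on read
_MARKER_ALIASES = {
    "ctla-4": Marker.CTLA4,
    "ctla_4": Marker.CTLA4,
    "pd-1": Marker.PD1,
    "pd_1": Marker.PD1,
    "granzymeb": Marker.GZMB,
}
_ASSAY_ALIASES = {
    "22c3": Assay.C22C3,
    "c22c3": Assay.C22C3,
    "28-8": Assay.C28_8,
    "28_8": Assay.C28_8,
    "c28_8": Assay.C28_8,
}


def parse_marker(value: Union[str, Marker]) -> Marker:
    if isinstance(value, Marker):
        return value
    key = str(value).strip()
    try:
        return Marker(key.upper())
    except ValueError:
        pass
    alias = _MARKER_ALIASES.get(key.lower())
    if alias is None:
        raise ValueError(f"unknown marker {value!r}")
    return alias


def parse_assay(value: Union[str, Assay]) -> Assay:
    if isinstance(value, Assay):
        return value
    key = str(value).strip()
    try:
        return Assay(key.upper())
    except ValueError:
        pass
    alias = _ASSAY_ALIASES.get(key.lower())
    if alias is None:
        raise ValueError(f"unknown assay {value!r}")
    return alias


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; message lists row indices."""

    def __init__(self, table: str, problems: Sequence[str]):
        self.table = table
        self.problems = list(problems)
        super().__init__(
            f"{table}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
        )


class MarkerDensityRecord(BaseModel):
    """One marker's positive-cell density on one TMA core."""

    model_config = pydantic.ConfigDict(frozen=True)

    patient_id: str
    core_id: str
    region: Region
    marker: Marker
    density: float = Field(ge=0, description="positive cells per mm²")
    qc_pass: bool = True

    @field_validator("marker", mode="before")
    @classmethod
    def _marker(cls, v):
        return parse_marker(v)

    @field_validator("region", mode="before")
    @classmethod
    def _region(cls, v):
        return Region(str(v).strip().lower()) if not isinstance(v, Region) else v


class PDL1AssayReadout(BaseModel):
    """One assay's patient-level PD-L1 readouts (IC%, TC%, CPS)."""

    model_config = pydantic.ConfigDict(frozen=True)

    patient_id: str
    assay: Assay
    ic_percent: float = Field(ge=0, le=100)
    tc_percent: float = Field(ge=0, le=100)
    cps: float = Field(ge=0, le=100)

    @field_validator("assay", mode="before")
    @classmethod
    def _assay(cls, v):
        return parse_assay(v)


class PatientAnnotation(BaseModel):
    """Per-patient sTILs, survival endpoints and adjustment covariates."""

    model_config = pydantic.ConfigDict(frozen=True)

    patient_id: str
    stils_percent: float = Field(ge=0, le=100)
    dss_time: float = Field(ge=0, description="months")
    dss_event: bool
    dfs_time: float = Field(ge=0, description="months")
    dfs_event: bool
    covariates: Mapping[str, object] = Field(default_factory=dict)


# CSV column layouts (External Interfaces)
DENSITY_COLUMNS = ["patient_id", "core_id", "region", "marker", "density", "qc_pass"]
ASSAY_COLUMNS = ["patient_id", "assay", "ic_percent", "tc_percent", "cps"]
_COVARIATE_COLUMNS = ["pT", "pN", "L", "age", "gender", "margin", "adj_chemo", "grade"]
ANNOTATION_COLUMNS = [
    "patient_id",
    "stils_percent",
    "dss_time",
    "dss_event",
    "dfs_time",
    "dfs_event",
    *_COVARIATE_COLUMNS,
]
# canonical covariate keys used throughout the survival module
COVARIATE_KEYS = {
    "pT": "pT_stage",
    "pN": "pN_stage",
    "L": "lymphovascular_invasion",
    "age": "age",
    "gender": "gender",
    "margin": "margin_status",
    "adj_chemo": "adjuvant_chemo",
    "grade": "grade",
}


@dataclass
class Cohort:
    """A validated cohort: density records, assay readouts and annotations."""

    density_records: list[MarkerDensityRecord] = field(default_factory=list)
    assay_readouts: list[PDL1AssayReadout] = field(default_factory=list)
    annotations: list[PatientAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for r in self.density_records:
            key = (r.patient_id, r.core_id, r.marker)
            if key in seen:
                raise CohortValidationError(
                    "densities", [f"duplicate (patient, core, marker): {key}"]
                )
            seen.add(key)
        seen = set()
        for r in self.assay_readouts:
            key = (r.patient_id, r.assay)
            if key in seen:
                raise CohortValidationError(
                    "assays", [f"duplicate (patient, assay): {key}"]
                )
            seen.add(key)
        seen = set()
        for a in self.annotations:
            if a.patient_id in seen:
                raise CohortValidationError(
                    "annotations", [f"duplicate patient_id: {a.patient_id}"]
                )
            seen.add(a.patient_id)

    def patient_ids(self) -> list[str]:
        """All patient ids, in first-appearance order across the three tables."""
        out: list[str] = []
        seen = set()
        for pid in (
            [r.patient_id for r in self.density_records]
            + [r.patient_id for r in self.assay_readouts]
            + [a.patient_id for a in self.annotations]
        ):
            if pid not in seen:
                seen.add(pid)
                out.append(pid)
        return out

    # -- frame views -------------------------------------------------------
    def densities_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "core_id": r.core_id,
                    "region": r.region.value,
                    "marker": r.marker.value,
                    "density": r.density,
                    "qc_pass": r.qc_pass,
                }
                for r in self.density_records
            ],
            columns=DENSITY_COLUMNS,
        )

    def assays_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "assay": r.assay.value,
                    "ic_percent": r.ic_percent,
                    "tc_percent": r.tc_percent,
                    "cps": r.cps,
                }
                for r in self.assay_readouts
            ],
            columns=ASSAY_COLUMNS,
        )

    def annotations_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.annotations:
            row = {
                "patient_id": a.patient_id,
                "stils_percent": a.stils_percent,
                "dss_time": a.dss_time,
                "dss_event": a.dss_event,
                "dfs_time": a.dfs_time,
                "dfs_event": a.dfs_event,
            }
            for col, key in COVARIATE_KEYS.items():
                row[col] = a.covariates.get(key, "")
            rows.append(row)
        return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s): {', '.join(missing)}")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "1.0", "yes"}:
        return True
    if s in {"false", "0", "0.0", "no"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def read_cohort(
    density_path: Union[str, Path],
    assay_path: Union[str, Path],
    annotation_path: Union[str, Path],
) -> Cohort:
    """Read and validate the three cohort tables.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`CohortValidationError` (listing row indices) when any row fails
    validation.
    """
    dens = pd.read_csv(density_path, dtype=str, keep_default_na=False)
    _require_columns(dens, DENSITY_COLUMNS, "densities")
    ass = pd.read_csv(assay_path, dtype=str, keep_default_na=False)
    _require_columns(ass, ASSAY_COLUMNS, "assays")
    ann = pd.read_csv(annotation_path, dtype=str, keep_default_na=False)
    _require_columns(ann, ["patient_id", "stils_percent", "dss_time", "dss_event",
                           "dfs_time", "dfs_event"], "annotations")

    density_records, problems = [], []
    for idx, row in dens.iterrows():
        try:
            density_records.append(
                MarkerDensityRecord(
                    patient_id=row["patient_id"],
                    core_id=row["core_id"],
                    region=row["region"],
                    marker=row["marker"],
                    density=float(row["density"]),
                    qc_pass=_parse_bool(row["qc_pass"]),
                )
            )
        except (pydantic.ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise CohortValidationError("densities", problems)

    assay_readouts, problems = [], []
    for idx, row in ass.iterrows():
        try:
            assay_readouts.append(
                PDL1AssayReadout(
                    patient_id=row["patient_id"],
                    assay=row["assay"],
                    ic_percent=float(row["ic_percent"]),
                    tc_percent=float(row["tc_percent"]),
                    cps=float(row["cps"]),
                )
            )
        except (pydantic.ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise CohortValidationError("assays", problems)

    annotations, problems = [], []
    for idx, row in ann.iterrows():
        try:
            covariates = {}
            for col, key in COVARIATE_KEYS.items():
                if col not in ann.columns:
                    continue
                raw = row[col]
                if key == "age" and raw != "":
                    covariates[key] = float(raw)
                else:
                    covariates[key] = raw
            annotations.append(
                PatientAnnotation(
                    patient_id=row["patient_id"],
                    stils_percent=float(row["stils_percent"]),
                    dss_time=float(row["dss_time"]),
                    dss_event=_parse_bool(row["dss_event"]),
                    dfs_time=float(row["dfs_time"]),
                    dfs_event=_parse_bool(row["dfs_event"]),
                    covariates=covariates,
                )
            )
        except (pydantic.ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise CohortValidationError("annotations", problems)

    return Cohort(density_records, assay_readouts, annotations)


def write_cohort(cohort: Cohort, directory: Union[str, Path]) -> dict[str, Path]:
    """Write ``densities.csv``, ``assays.csv`` and ``annotations.csv``.

    Floats are written with ``repr`` precision so numeric fields round-trip
    bit-stably through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "densities": directory / "densities.csv",
        "assays": directory / "assays.csv",
        "annotations": directory / "annotations.csv",
    }
    cohort.densities_frame().to_csv(paths["densities"], index=False)
    cohort.assays_frame().to_csv(paths["assays"], index=False)
    cohort.annotations_frame().to_csv(paths["annotations"], index=False)
    return paths


def filter_qc(cohort: Cohort) -> Cohort:
    """Drop cores that failed pathologist QC.

    Core exclusion mirrors the QC policy for TMA analysis: cores without
    representative tumor tissue or with staining artifacts are removed, the
    patient is kept as long as at least one core survives. Patients losing
    every core are dropped from the cohort entirely (they can no longer be
    density-phenotyped) and logged. Idempotent.
    """
    kept = [r for r in cohort.density_records if r.qc_pass]
    patients_before = {r.patient_id for r in cohort.density_records}
    patients_after = {r.patient_id for r in kept}
    dropped = sorted(patients_before - patients_after)
    if dropped:
        logger.warning(
            "filter_qc: dropping %d patient(s) with no QC-passing core: %s",
            len(dropped), ", ".join(dropped),
        )
    return Cohort(
        density_records=kept,
        assay_readouts=[r for r in cohort.assay_readouts if r.patient_id not in dropped],
        annotations=[a for a in cohort.annotations if a.patient_id not in dropped],
    )
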