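"""Patient-level cohort tables: typed records, CSV round-trip, eligibility filtering.

The cohort model targets elderly fragility hip fracture patients followed for
one-year vital status.  Records carry the union of the covariates required by
the seven mortality risk scores (demographics, residence and mobility,
ASA physical status, labs, comorbidity flags, fracture characteristics) plus
the outcome fields (death within one year, follow-up in months, censoring).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "Sex",
    "Residence",
    "Mobility",
    "MentalStatus",
    "FractureType",
    "Malignancy",
    "PatientRecord",
    "Cohort",
    "EligibilityConfig",
    "SchemaError",
    "RowParseError",
    "read_cohort",
    "write_cohort",
    "filter_eligible",
    "default_schema",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Residence(str, enum.Enum):
    OWN_HOME = "own_home"
    SHELTERED_OR_ASSISTED = "sheltered_or_assisted"
    LONG_TERM_CARE = "long_term_care"
    REHABILITATION = "rehabilitation"
    ACUTE_WARD = "acute_ward"


class Mobility(str, enum.Enum):
    NO_AIDS = "no_aids"
    ONE_AID = "one_aid"
    TWO_AIDS_OR_FRAME = "two_aids_or_frame"
    REQUIRES_ACCOMPANIMENT = "requires_accompaniment"
    UNABLE_TO_WALK = "unable_to_walk"


class MentalStatus(str, enum.Enum):
    ALERT = "alert"
    SLIGHT_CONFUSION = "slight_confusion"


class FractureType(str, enum.Enum):
    FEMORAL_NECK = "femoral_neck"          # intracapsular
    PERTROCHANTERIC = "pertrochanteric"    # extracapsular
    SUBTROCHANTERIC = "subtrochanteric"
    PATHOLOGICAL = "pathological"


class Malignancy(str, enum.Enum):
    NONE = "none"
    SKIN = "skin"
    OTHER = "other"
    METASTATIC = "metastatic"


_ENUM_FIELDS = {
    "sex": Sex,
    "residence": Residence,
    "mobility": Mobility,
    "mental_status": MentalStatus,
    "fracture_type": FractureType,
    "malignancy": Malignancy,
}

_BOOL_FIELDS = (
    "cognitive_impairment",
    "in_hospital_fracture",
    "nursing_care_certification",
    "copd",
    "pneumonia",
    "ischemic_heart_disease",
    "prior_mi",
    "arrhythmia",
    "chf",
    "malnutrition",
    "electrolyte_disorder",
    "renal_disease",
    "liver_disease_moderate_severe",
    "deficiency_anemia",
    "chronic_pulmonary_disease",
    "periprosthetic",
    "treated_surgically",
    "lost_to_followup",
)


class SchemaError(ValueError):
    """A required column is absent or the schema file is malformed."""


class RowParseError(ValueError):
    """A cell could not be coerced to its declared type; carries the row index."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column {column!r}: {message}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, fracture traits, and one-year outcome.

    ``dead_1y`` is ``None`` exactly when the patient was lost to follow-up;
    ``followup_months`` is time from surgery to death or last contact.
    """

    patient_id: str
    age: int
    sex: Sex
    residence: Residence
    mobility: Mobility
    mental_status: MentalStatus
    cognitive_impairment: bool
    asa_grade: int
    hemoglobin: Optional[float]
    serum_urea: Optional[float]
    cci: int
    n_comorbidities: int
    fracture_type: FractureType
    in_hospital_fracture: bool
    nursing_care_certification: bool
    copd: bool
    pneumonia: bool
    ischemic_heart_disease: bool
    prior_mi: bool
    arrhythmia: bool
    chf: bool
    malnutrition: bool
    electrolyte_disorder: bool
    renal_disease: bool
    liver_disease_moderate_severe: bool
    deficiency_anemia: bool
    chronic_pulmonary_disease: bool
    malignancy: Malignancy
    dxa_t_score: Optional[float]
    treated_surgically: bool
    admission_date: date
    dead_1y: Optional[bool]
    followup_months: float
    lost_to_followup: bool = False
    periprosthetic: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.asa_grade not in (1, 2, 3, 4, 5):
            raise ValueError(f"asa_grade must be in 1..5, got {self.asa_grade}")
        if self.hemoglobin is not None and self.hemoglobin <= 0:
            raise ValueError("hemoglobin must be > 0 when present")
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if self.cci < 0 or self.n_comorbidities < 0:
            raise ValueError("cci and n_comorbidities must be >= 0")
        if (self.dead_1y is None) != self.lost_to_followup:
            raise ValueError("dead_1y must be missing iff lost_to_followup is true")


@dataclass
class Cohort:
    """Ordered collection of patient records with a free-text provenance tag."""

    records: list[PatientRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {}
            for f in fields(PatientRecord):
                v = getattr(r, f.name)
                if isinstance(v, enum.Enum):
                    v = v.value
                elif isinstance(v, date):
                    v = v.isoformat()
                row[f.name] = v
            rows.append(row)
        return pd.DataFrame(rows, columns=[f.name for f in fields(PatientRecord)])


def default_schema() -> dict:
    """The packaged column/enum schema for cohort CSVs."""
    with resources.files("fragscore.data").joinpath("cohort_schema.json").open() as fh:
        return json.load(fh)


_REQUIRED = [f.name for f in fields(PatientRecord)
             if f.name not in ("lost_to_followup", "periprosthetic")]
_OPTIONAL_NUMERIC = ("hemoglobin", "serum_urea", "dxa_t_score")

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(raw: str, row: int, col: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RowParseError(row, col, f"cannot interpret {raw!r} as boolean")


def read_cohort(path: str | Path, schema: dict | None = None) -> Cohort:
    """Read a cohort CSV into typed, validated records.

    ``schema`` maps package field names to source column names
    (``"columns"``) and source categorical spellings to canonical enum
    values (``"values"``); omitted entries fall back to identity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or {}
    colmap: dict = schema.get("columns", {})
    valmap: dict = schema.get("values", {})

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [f for f in _REQUIRED if colmap.get(f, f) not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")

    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        kw: dict = {}
        for f in fields(PatientRecord):
            col = colmap.get(f.name, f.name)
            if col not in df.columns:
                # optional fields may be absent entirely
                continue
            cell = raw[col].strip()
            try:
                if f.name in _ENUM_FIELDS:
                    mapped = valmap.get(f.name, {}).get(cell, cell)
                    kw[f.name] = _ENUM_FIELDS[f.name](mapped)
                elif f.name == "dead_1y":
                    kw[f.name] = None if cell == "" else _parse_bool(cell, i, col)
                elif f.name in _BOOL_FIELDS:
                    kw[f.name] = _parse_bool(cell, i, col)
                elif f.name in ("age", "asa_grade", "cci", "n_comorbidities"):
                    kw[f.name] = int(float(cell))
                elif f.name in _OPTIONAL_NUMERIC:
                    kw[f.name] = None if cell == "" else float(cell)
                elif f.name == "followup_months":
                    kw[f.name] = float(cell)
                elif f.name == "admission_date":
                    kw[f.name] = date.fromisoformat(cell)
                else:
                    kw[f.name] = cell
            except RowParseError:
                raise
            except (ValueError, KeyError) as exc:
                raise RowParseError(i, col, str(exc)) from exc
        try:
            records.append(PatientRecord(**kw))
        except (TypeError, ValueError) as exc:
            raise RowParseError(i, "<record>", str(exc)) from exc
    return Cohort(records=records, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV; lossless round-trip with :func:`read_cohort`."""
    df = cohort.to_frame()
    df.to_csv(path, index=False)


@dataclass
class EligibilityConfig:
    """Study eligibility rules.

    Defaults mirror the fragility-hip-fracture inclusion criteria: age 60+,
    osteoporosis by DXA (T-score <= -2.5; missing T-scores are not excluded),
    surgically treated, no pathological or periprosthetic fractures, first
    admission per patient, complete one-year follow-up.
    """

    min_age: int = 60
    max_t_score: Optional[float] = -2.5   # None disables the DXA rule
    require_surgery: bool = True
    exclude_fracture_types: tuple[FractureType, ...] = (FractureType.PATHOLOGICAL,)
    exclude_periprosthetic: bool = True
    drop_lost_to_followup: bool = True
    keep_first_admission: bool = True


def filter_eligible(
    cohort: Cohort, rules: EligibilityConfig | None = None
) -> tuple[Cohort, dict[str, int]]:
    """Apply eligibility rules; return the eligible cohort and a per-rule count log.

    Rules are applied in a fixed order and each excluded record is counted
    against exactly one rule, so the log totals plus the eligible count equal
    the input count.  Duplicate ``patient_id``s keep the earliest admission.
    """
    rules = rules or EligibilityConfig()
    log = {
        "under_min_age": 0,
        "dxa_t_above_threshold": 0,
        "not_surgical": 0,
        "excluded_fracture_type": 0,
        "periprosthetic": 0,
        "lost_to_followup": 0,
        "repeat_admission": 0,
    }

    kept: list[PatientRecord] = []
    for r in cohort.records:
        if r.age < rules.min_age:
            log["under_min_age"] += 1
        elif (
            rules.max_t_score is not None
            and r.dxa_t_score is not None
            and r.dxa_t_score > rules.max_t_score
        ):
            log["dxa_t_above_threshold"] += 1
        elif rules.require_surgery and not r.treated_surgically:
            log["not_surgical"] += 1
        elif r.fracture_type in rules.exclude_fracture_types:
            log["excluded_fracture_type"] += 1
        elif rules.exclude_periprosthetic and r.periprosthetic:
            log["periprosthetic"] += 1
        elif rules.drop_lost_to_followup and r.lost_to_followup:
            log["lost_to_followup"] += 1
        else:
            kept.append(r)

    if rules.keep_first_admission:
        first: dict[str, PatientRecord] = {}
        order: list[str] = []
        for r in kept:
            prev = first.get(r.patient_id)
            if prev is None:
                first[r.patient_id] = r
                order.append(r.patient_id)
                continue
            log["repeat_admission"] += 1
            if r.admission_date < prev.admission_date:
                first[r.patient_id] = r
        kept = [first[pid] for pid in order]

    log = {k: v for k, v in log.items() if v}
    return Cohort(records=kept, provenance=cohort.provenance), log
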