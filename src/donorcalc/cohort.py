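"""Reading, validation and eligibility filtering of transplant cohort tables.

A cohort is one row per first allogeneic HSCT: patient covariates at day 0,
donor type and age, follow-up in days and a death indicator.  Overall survival
is the only endpoint carried; GvHD, relapse and cause-of-death variables are
out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

DONOR_TYPES = ("SIB", "MUD", "HAPLO")
COMORBIDITY_CLASSES = ("0", "1", "2plus")
DIAGNOSIS_GROUPS = (1, 2, 3)

#: Disease entities grouped by shared biologic behaviour: acute leukemias and
#: precursor lymphoid neoplasms (1); chronic myeloid, myelodysplastic and
#: myeloproliferative entities (2); lymphomas, CLL and plasma-cell disorders (3).
DIAGNOSIS_GROUP_MAP: dict[str, int] = {
    # group 1 -- acute leukemias & precursor lymphoid neoplasms
    "acute undifferentiated leukemia": 1,
    "acute myeloid leukemia and related precursor neoplasms": 1,
    "mixed phenotype acute leukemia": 1,
    "mixed phenotype b/myeloid": 1,
    "secondary acute leukemia": 1,
    "precursor lymphoid neoplasms": 1,
    # group 2 -- chronic myeloid / MDS / MPN entities
    "chronic leukemia": 2,
    "chronic myeloid leukemia": 2,
    "myeloproliferative neoplasia": 2,
    "myelodysplastic syndrome or myeloproliferative syndrome": 2,
    "myelodysplastic syndrome": 2,
    "myelodysplastic and myeloproliferative syndromes": 2,
    # group 3 -- lymphomas, CLL, plasma-cell disorders
    "hodgkin's lymphoma": 3,
    "chronic lymphocytic leukemia": 3,
    "non-hodgkin's lymphoma": 3,
    "lymphoma (not otherwise specified)": 3,
    "prolymphocytic leukemia": 3,
    "multiple myeloma": 3,
    "plasma cell leukemia": 3,
}

#: Fields the default survival model needs; records missing any of these are
#: removed by the eligibility filter (last stage) and counted in the report.
DEFAULT_REQUIRED_FIELDS = (
    "patient_age",
    "diagnosis_group",
    "comorbidity_class",
    "donor_type",
    "donor_age",
    "followup_days",
    "death_event",
)


class SchemaError(ValueError):
    """A required column is absent from the input table."""


class RecordValidationError(ValueError):
    """A record violates a field-level invariant (e.g. negative follow-up)."""


class DiagnosisMappingError(KeyError):
    """A diagnosis label is not one of the known disease entities."""


@dataclass
class CohortRecord:
    """One transplant record.

    ``followup_days`` is days from transplant to death (if ``death_event``)
    or to last contact.  Optional fields use ``None`` for missing.
    """

    record_id: str
    patient_age: Optional[float]
    patient_sex: Optional[str]
    diagnosis_label: Optional[str]
    diagnosis_group: Optional[int]
    comorbidity_class: Optional[str]
    donor_type: Optional[str]
    donor_age: Optional[float]
    followup_days: Optional[int]
    death_event: Optional[bool]
    disease_status: Optional[str] = None
    karnofsky: Optional[int] = None
    patient_cmv: Optional[str] = None
    donor_sex: Optional[str] = None
    donor_cmv: Optional[str] = None
    first_hsct: bool = True
    multiple_donor: bool = False
    planned_multigraft: bool = False

    def is_missing(self, fields: Iterable[str]) -> list[str]:
        """Names among ``fields`` whose value is missing on this record."""
        out = []
        for f in fields:
            v = getattr(self, f)
            if v is None or (isinstance(v, float) and pd.isna(v)):
                out.append(f)
        return out


@dataclass
class FilterReport:
    """Stage-by-stage accounting of the eligibility filter.

    Counts always reconcile: ``n_output`` equals ``n_input`` minus the sum of
    all removal counts.  A record failing several criteria is counted at the
    first failing stage only.
    """

    n_input: int = 0
    n_removed_not_first: int = 0
    n_removed_multiple_donor: int = 0
    n_removed_multigraft: int = 0
    n_removed_donor_type: int = 0
    n_removed_missing: int = 0
    n_output: int = 0

    @property
    def n_removed_total(self) -> int:
        return (
            self.n_removed_not_first
            + self.n_removed_multiple_donor
            + self.n_removed_multigraft
            + self.n_removed_donor_type
            + self.n_removed_missing
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def map_diagnosis_to_group(diagnosis_label: str) -> int:
    """Map a free-text diagnosis to its group 1, 2 or 3.

    Matching is case- and whitespace-insensitive; typographic apostrophes are
    normalised.  Unknown labels raise :class:`DiagnosisMappingError` listing
    the known entities — there is no silent default group.
    """
    key = " ".join(str(diagnosis_label).split()).lower().replace("’", "'")
    try:
        return DIAGNOSIS_GROUP_MAP[key]
    except KeyError:
        known = ", ".join(sorted(DIAGNOSIS_GROUP_MAP))
        raise DiagnosisMappingError(
            f"unknown diagnosis label {diagnosis_label!r}; known labels: {known}"
        ) from None


_BOOL_TRUE = {"1", "true", "yes", "y", "t"}
_BOOL_FALSE = {"0", "false", "no", "n", "f"}


def _parse_bool(value, default=None):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s == "":
        return default
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise RecordValidationError(f"cannot parse boolean value {value!r}")


def _parse_float(value):
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if pd.isna(v) else v


def _parse_category(value, allowed=None):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "na"):
        return None
    if allowed is not None and s not in allowed:
        return None
    return s


DEFAULT_SCHEMA = {name: name for name in (
    "record_id", "patient_age", "patient_sex", "diagnosis_label",
    "diagnosis_group", "disease_status", "comorbidity_class", "karnofsky",
    "patient_cmv", "donor_type", "donor_age", "donor_sex", "donor_cmv",
    "followup_days", "death_event", "first_hsct", "multiple_donor",
    "planned_multigraft",
)}

#: Columns that must exist in any input table (others are optional).
_MANDATORY_COLUMNS = ("record_id", "followup_days", "death_event")


def read_cohort(path, schema: Optional[dict] = None) -> list[CohortRecord]:
    """Read a cohort CSV into typed records.

    ``schema`` maps record field names to column names in the file; fields
    not mapped fall back to same-named columns.  Unparseable optional fields
    become missing values rather than dropping the row; a negative follow-up
    raises :class:`RecordValidationError` naming the record.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for f in _MANDATORY_COLUMNS:
        if schema[f] not in df.columns:
            raise SchemaError(f"required column {schema[f]!r} (field {f!r}) not in {path}")

    def col(row, f):
        c = schema.get(f)
        return row[c] if c in df.columns else None

    records = []
    for _, row in df.iterrows():
        rid = str(col(row, "record_id"))
        fup = _parse_float(col(row, "followup_days"))
        if fup is not None:
            if fup < 0:
                raise RecordValidationError(f"record {rid!r}: negative follow-up {fup}")
            fup = int(round(fup))
        group = _parse_float(col(row, "diagnosis_group"))
        label = _parse_category(col(row, "diagnosis_label"))
        if group is None and label is not None:
            group = map_diagnosis_to_group(label)
        records.append(CohortRecord(
            record_id=rid,
            patient_age=_parse_float(col(row, "patient_age")),
            patient_sex=_parse_category(col(row, "patient_sex"), ("M", "F")),
            diagnosis_label=label,
            diagnosis_group=int(group) if group is not None else None,
            disease_status=_parse_category(col(row, "disease_status")),
            comorbidity_class=_parse_category(col(row, "comorbidity_class"), COMORBIDITY_CLASSES),
            karnofsky=(lambda v: int(v) if v is not None else None)(_parse_float(col(row, "karnofsky"))),
            patient_cmv=_parse_category(col(row, "patient_cmv"), ("pos", "neg")),
            donor_type=_parse_category(col(row, "donor_type")),
            donor_age=_parse_float(col(row, "donor_age")),
            donor_sex=_parse_category(col(row, "donor_sex"), ("M", "F")),
            donor_cmv=_parse_category(col(row, "donor_cmv"), ("pos", "neg")),
            followup_days=fup,
            death_event=_parse_bool(col(row, "death_event")),
            first_hsct=_parse_bool(col(row, "first_hsct"), default=True),
            multiple_donor=_parse_bool(col(row, "multiple_donor"), default=False),
            planned_multigraft=_parse_bool(col(row, "planned_multigraft"), default=False),
        ))
    return records


def write_cohort(records: Sequence[CohortRecord], path) -> None:
    """Write records to CSV such that :func:`read_cohort` round-trips them."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for k, v in d.items():
            if v is None:
                d[k] = ""
            elif isinstance(v, bool):
                d[k] = "1" if v else "0"
        rows.append(d)
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA)).to_csv(path, index=False)


def apply_eligibility_filters(
    records: Sequence[CohortRecord],
    required_fields: Sequence[str] = DEFAULT_REQUIRED_FIELDS,
) -> tuple[list[CohortRecord], FilterReport]:
    """Apply the study eligibility filters in fixed order.

    Removal stages: (1) non-first transplants; (2) multiple-donor
    transplants; (3) planned multigraft protocols; (4) donor types outside
    SIB/MUD/HAPLO (mismatched unrelated donors and cord blood); (5) records
    missing any required model field.  Each record is counted once, at its
    first failing stage.
    """
    report = FilterReport(n_input=len(records))
    kept = []
    for r in records:
        if not r.first_hsct:
            report.n_removed_not_first += 1
        elif r.multiple_donor:
            report.n_removed_multiple_donor += 1
        elif r.planned_multigraft:
            report.n_removed_multigraft += 1
        elif r.donor_type is not None and r.donor_type not in DONOR_TYPES:
            # ineligible graft source (e.g. cord blood, mismatched unrelated);
            # a *missing* donor type is counted at the missing-field stage
            report.n_removed_donor_type += 1
        elif r.is_missing(required_fields):
            report.n_removed_missing += 1
        else:
            kept.append(r)
    report.n_output = len(kept)
    assert report.n_output == report.n_input - report.n_removed_total
    return kept, report
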