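"""Declarative model specification and numeric design-matrix construction.

Categorical predictors are dummy-coded against a reference level; pairwise
interactions are elementwise products of the parent columns.  The default
specification is the published two-center model: diagnosis group (ref 1),
donor type "HLA" (ref SIB), optional comorbidity class (ref 0), patient and
donor age entered raw (no centering), and the four age interactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import CohortRecord

DONOR_TYPE_TO_HLA = {"SIB": "1", "MUD": "2", "HAPLO": "3"}


class EncodingError(ValueError):
    """A profile value cannot be encoded under the model specification."""


@dataclass(frozen=True)
class Factor:
    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if self.reference not in self.levels:
            raise ValueError(f"reference {self.reference!r} not a level of {self.name!r}")

    @property
    def dummy_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class ModelSpec:
    """Factors, continuous covariates and pairwise interactions."""

    factors: tuple[Factor, ...]
    continuous: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = {f.name for f in self.factors} | set(self.continuous)
        for a, b in self.interactions:
            for t in (a, b):
                if t not in names:
                    raise ValueError(f"interaction references undeclared term {t!r}")

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def _term_columns(self, term: str) -> list[str]:
        """Column names contributed by a main-effect term."""
        if term in self.continuous:
            return [term]
        f = self.factor(term)
        return [f"{f.name}_{l}" for l in f.dummy_levels]

    @property
    def column_names(self) -> list[str]:
        """Deterministic column order: intercept, factor dummies in
        declaration order, continuous terms, then interactions in spec order
        (dummy levels in level order)."""
        cols = ["Intercept"]
        for f in self.factors:
            cols.extend(self._term_columns(f.name))
        cols.extend(self.continuous)
        for a, b in self.interactions:
            for ca in self._term_columns(a):
                for cb in self._term_columns(b):
                    cols.append(f"{ca}:{cb}")
        return cols

    @property
    def term_names(self) -> list[str]:
        return [f.name for f in self.factors] + list(self.continuous) + [
            f"{a}:{b}" for a, b in self.interactions
        ]

    def term_column_map(self) -> dict[str, list[str]]:
        """Model term -> list of design columns it owns (for joint tests)."""
        out: dict[str, list[str]] = {}
        for f in self.factors:
            out[f.name] = self._term_columns(f.name)
        for c in self.continuous:
            out[c] = [c]
        for a, b in self.interactions:
            out[f"{a}:{b}"] = [
                f"{ca}:{cb}" for ca in self._term_columns(a) for cb in self._term_columns(b)
            ]
        return out

    def to_json(self) -> str:
        return json.dumps({
            "factors": [
                {"name": f.name, "levels": list(f.levels), "reference": f.reference}
                for f in self.factors
            ],
            "continuous": list(self.continuous),
            "interactions": [list(i) for i in self.interactions],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            factors=tuple(Factor(f["name"], tuple(f["levels"]), f["reference"])
                          for f in d["factors"]),
            continuous=tuple(d["continuous"]),
            interactions=tuple((a, b) for a, b in d["interactions"]),
        )


def default_spec(include_comorbidity: bool = False,
                 include_disease_status: bool = False) -> ModelSpec:
    """The published model specification.

    Without comorbidity this yields 15 design columns (intercept + 14
    predictors).  ``include_comorbidity`` adds the two comorbidity dummies
    (17 columns); ``include_disease_status`` adds a remission-status main
    effect for sensitivity analyses.
    """
    factors = [Factor("Diagnosis", ("1", "2", "3"), "1"),
               Factor("HLA", ("1", "2", "3"), "1")]
    if include_comorbidity:
        factors.append(Factor("Comorbidity", ("0", "1", "2plus"), "0"))
    if include_disease_status:
        factors.append(Factor("DiseaseStatus", ("CR", "not_CR"), "CR"))
    return ModelSpec(
        factors=tuple(factors),
        continuous=("AgePatient", "AgeDonor"),
        interactions=(("AgePatient", "Diagnosis"), ("HLA", "AgePatient"),
                      ("HLA", "AgeDonor"), ("Diagnosis", "AgeDonor")),
    )


def profile_from_record(record: CohortRecord) -> dict[str, object]:
    """Model-term values for one cohort record."""
    prof: dict[str, object] = {}
    if record.diagnosis_group is not None:
        prof["Diagnosis"] = str(record.diagnosis_group)
    if record.donor_type is not None:
        prof["HLA"] = DONOR_TYPE_TO_HLA.get(record.donor_type, record.donor_type)
    if record.comorbidity_class is not None:
        prof["Comorbidity"] = record.comorbidity_class
    if record.disease_status is not None:
        prof["DiseaseStatus"] = "CR" if str(record.disease_status).upper().startswith("CR") else "not_CR"
    if record.patient_age is not None:
        prof["AgePatient"] = float(record.patient_age)
    if record.donor_age is not None:
        prof["AgeDonor"] = float(record.donor_age)
    return prof


def encode_profile(profile: Mapping[str, object], spec: ModelSpec) -> np.ndarray:
    """Encode one covariate assignment as a numeric design row.

    ``profile`` maps term names (``Diagnosis``, ``HLA``, ``AgePatient``, ...)
    to values.  All spec terms must be present; an unknown factor level
    raises :class:`EncodingError`.
    """
    values: dict[str, float] = {"Intercept": 1.0}
    for f in spec.factors:
        if f.name not in profile:
            raise EncodingError(f"profile is missing factor {f.name!r}")
        level = str(profile[f.name])
        if level not in f.levels:
            raise EncodingError(
                f"unknown level {level!r} for factor {f.name!r}; levels: {f.levels}")
        for l in f.dummy_levels:
            values[f"{f.name}_{l}"] = 1.0 if level == l else 0.0
    for c in spec.continuous:
        if c not in profile:
            raise EncodingError(f"profile is missing continuous term {c!r}")
        values[c] = float(profile[c])  # type: ignore[arg-type]
    for a, b in spec.interactions:
        for ca in spec._term_columns(a):
            for cb in spec._term_columns(b):
                values[f"{ca}:{cb}"] = values[ca] * values[cb]
    return np.array([values[c] for c in spec.column_names], dtype=float)


@dataclass
class DesignMatrix:
    """Numeric covariate matrix with survival times and event indicators."""

    column_names: list[str]
    X: np.ndarray        # (n, p)
    times: np.ndarray    # days, (n,)
    events: np.ndarray   # bool, (n,)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


def build_design_matrix(records: Sequence[CohortRecord], spec: ModelSpec) -> DesignMatrix:
    """Encode filtered cohort records into a :class:`DesignMatrix`.

    Records must have no missing model fields (run the eligibility filter
    first); a missing field raises :class:`EncodingError` naming the record.
    """
    cols = spec.column_names
    X = np.empty((len(records), len(cols)))
    times = np.empty(len(records))
    events = np.empty(len(records), dtype=bool)
    for i, r in enumerate(records):
        try:
            X[i] = encode_profile(profile_from_record(r), spec)
        except EncodingError as e:
            raise EncodingError(f"record {r.record_id!r}: {e}") from None
        if r.followup_days is None or r.death_event is None:
            raise EncodingError(f"record {r.record_id!r}: missing follow-up or event")
        times[i] = float(r.followup_days)
        events[i] = bool(r.death_event)
    return DesignMatrix(column_names=cols, X=X, times=times, events=events)
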