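"""The donor-selection calculator: ranked per-donor survival comparison.

Given one patient and several candidate donors, produce the ranked 2-year
overall-survival table with confidence intervals, hazard ratios against a
reference donor, and groups of donors whose survival CIs mutually overlap
(donors inside one group are statistically comparable options).  The tool
ranks and annotates; it never auto-selects a donor.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .aft import AFTParameters, FittedAFT, NoCovarianceError
from .design import ModelSpec
from .predict import (DonorOption, PatientProfile, PredictionResult,
                      TWO_YEARS, hazard_ratio, predict_survival)


@dataclass
class ComparisonRow:
    donor: DonorOption
    prediction: PredictionResult
    hazard_ratio: float
    hr_ci: Optional[tuple[float, float]]


@dataclass
class ComparisonReport:
    """Ranked donor comparison for one patient.

    Rows are sorted by point-estimate survival, descending.  ``reference``
    is the donor the hazard ratios are computed against (HR = 1 for it;
    HR > 1 = higher hazard than the reference).  ``overlap_groups`` are
    maximal runs of donors whose survival CIs mutually intersect; absent
    when the model carries no covariance.
    """

    patient: PatientProfile
    horizon: float
    rows: list[ComparisonRow]
    reference: str
    overlap_groups: list[list[str]]

    def to_dict(self) -> dict:
        return {
            "patient": dataclasses.asdict(self.patient),
            "horizon_days": self.horizon,
            "reference": self.reference,
            "rows": [{
                "donor": dataclasses.asdict(r.donor),
                "mu": r.prediction.mu,
                "survival": r.prediction.survival,
                "ci": list(r.prediction.ci) if r.prediction.ci else None,
                "hazard_ratio": r.hazard_ratio,
                "hr_ci": list(r.hr_ci) if r.hr_ci else None,
            } for r in self.rows],
            "overlap_groups": self.overlap_groups,
        }


def _overlap_groups(rows: Sequence[ComparisonRow]) -> list[list[str]]:
    """Maximal sets of donors with pairwise-intersecting survival CIs.

    Computed on the survival-sorted rows: a group extends while every pair
    inside it still overlaps.  Any shared boundary counts as overlap.
    """
    if any(r.prediction.ci is None for r in rows):
        return []
    groups: list[list[int]] = []
    for i in range(len(rows)):
        placed = False
        for g in groups:
            if all(_ci_overlap(rows[i].prediction.ci, rows[j].prediction.ci)
                   for j in g):
                g.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])
    return [[rows[i].donor.label for i in g] for g in groups]


def _ci_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_donor_options(model, patient: PatientProfile,
                          donors: Sequence[DonorOption], spec: ModelSpec,
                          horizon: float = TWO_YEARS,
                          reference: Optional[str] = None,
                          level: float = 0.95) -> ComparisonReport:
    """Predict survival under each donor option and rank them.

    ``model`` is a :class:`FittedAFT` (CIs included) or bare
    :class:`AFTParameters` / covariance-free fixture (point estimates and
    HRs only; CI fields are None, never fabricated).  The hazard-ratio
    reference defaults to the first listed donor.
    """
    if not donors:
        raise ValueError("at least one donor option is required")
    labels = [d.label for d in donors]
    if len(set(labels)) != len(labels):
        raise ValueError("donor labels must be unique")
    ref_label = reference if reference is not None else donors[0].label
    ref = next((d for d in donors if d.label == ref_label), None)
    if ref is None:
        raise ValueError(f"reference donor {ref_label!r} not among the options")

    rows = []
    for d in donors:
        pred = predict_survival(model, patient, d, spec, horizon, level)
        hr, hr_ci = hazard_ratio(model, patient, d, ref, spec, level)
        rows.append(ComparisonRow(donor=d, prediction=pred,
                                  hazard_ratio=hr, hr_ci=hr_ci))
    rows.sort(key=lambda r: (-r.prediction.survival, r.donor.label))
    return ComparisonReport(patient=patient, horizon=float(horizon), rows=rows,
                            reference=ref_label,
                            overlap_groups=_overlap_groups(rows))


def report_from_dict(d: dict) -> ComparisonReport:
    """Rebuild a report from its JSON form (inverse of ``render_report``)."""
    rows = [ComparisonRow(
        donor=DonorOption(**r["donor"]),
        prediction=PredictionResult(
            mu=r["mu"], survival=r["survival"],
            ci=tuple(r["ci"]) if r["ci"] else None,
            horizon=d["horizon_days"]),
        hazard_ratio=r["hazard_ratio"],
        hr_ci=tuple(r["hr_ci"]) if r["hr_ci"] else None,
    ) for r in d["rows"]]
    return ComparisonReport(
        patient=PatientProfile(**d["patient"]), horizon=d["horizon_days"],
        rows=rows, reference=d["reference"],
        overlap_groups=[list(g) for g in d["overlap_groups"]])


def render_report(report: ComparisonReport, format: str = "text") -> str:
    """Serialize a comparison report as ``json``, ``text`` or ``csv``."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format == "csv":
        import pandas as pd
        rows = []
        for r in report.rows:
            rows.append({
                "donor_label": r.donor.label,
                "donor_type": r.donor.donor_type,
                "donor_age": repr(r.donor.donor_age),
                "survival": repr(r.prediction.survival),
                "ci_low": "" if r.prediction.ci is None else repr(r.prediction.ci[0]),
                "ci_high": "" if r.prediction.ci is None else repr(r.prediction.ci[1]),
                "hazard_ratio": repr(r.hazard_ratio),
                "hr_ci_low": "" if r.hr_ci is None else repr(r.hr_ci[0]),
                "hr_ci_high": "" if r.hr_ci is None else repr(r.hr_ci[1]),
            })
        buf = io.StringIO()
        pd.DataFrame(rows).to_csv(buf, index=False)
        return buf.getvalue()
    if format == "text":
        p = report.patient
        lines = [
            f"Patient: age {p.patient_age:g}, diagnosis group {p.diagnosis_group}, "
            f"comorbidity {p.comorbidity_class}",
            f"Horizon: {report.horizon:g} days | HR reference: {report.reference}",
            f"{'Donor':<24}{'Type':>6}{'Age':>5}{'OS':>8}{'95% CI':>18}{'HR':>7}",
        ]
        for r in report.rows:
            ci = ("--" if r.prediction.ci is None
                  else f"({r.prediction.ci[0]:.3f}, {r.prediction.ci[1]:.3f})")
            lines.append(f"{r.donor.label:<24}{r.donor.donor_type:>6}"
                         f"{r.donor.donor_age:>5.0f}{r.prediction.survival:>8.3f}"
                         f"{ci:>18}{r.hazard_ratio:>7.3f}")
        if report.overlap_groups:
            comparable = [g for g in report.overlap_groups if len(g) > 1]
            if comparable:
                lines.append("Comparable options (overlapping CIs): "
                             + "; ".join(" ~ ".join(g) for g in comparable))
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}; expected json, text or csv")
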