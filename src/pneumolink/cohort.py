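"""Cohort eligibility, follow-up windows, and flow accounting.

Eligibility for the validation cohort requires a COPD diagnosis at age 35 or
older, registration at a practice overlapping the study period, and linkage
eligibility between the primary-care and hospital data. Event ascertainment
for an eligible patient is confined to a follow-up window that starts at the
latest of the study start, one year after COPD diagnosis, and practice
registration, and ends at the earliest of the study end, death, transfer-out,
and the practice's last data-collection date.

The exclusion stages are applied in a fixed order so that the flow counts
emitted for a run are deterministic and monotonically non-increasing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .ehr_model import LinkedDataset, PatientRecord

__all__ = [
    "STUDY_START",
    "STUDY_END",
    "FollowUpWindow",
    "FlowCounts",
    "CohortResult",
    "add_years",
    "age_at",
    "eligible",
    "build_followup_window",
    "apply_cohort",
]

STUDY_START = dt.date(2015, 1, 1)
STUDY_END = dt.date(2019, 12, 31)

#: Fixed order of exclusion stages for flow accounting.
STAGES = (
    "all_patients",
    "copd_diagnosis",
    "age_35_plus_at_diagnosis",
    "registered_during_study",
    "linkage_eligible",
    "followup_time_available",
)


def add_years(date: dt.date, years: int) -> dt.date:
    """Calendar-year shift: same month/day; Feb 29 maps to Mar 1."""
    try:
        return date.replace(year=date.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return dt.date(date.year + years, 3, 1)


def age_at(birth_date: dt.date, on: dt.date) -> int:
    """Age in completed years on a given date."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


@dataclass(frozen=True)
class FollowUpWindow:
    patient_id: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.patient_id}: window start after end")

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


@dataclass(frozen=True)
class FlowCounts:
    """Ordered (stage label, patients remaining) pairs; non-increasing."""

    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("flow counts must be non-increasing")

    @property
    def final_count(self) -> int:
        return self.stages[-1][1] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "patients_remaining"])


def eligible(
    patient: PatientRecord,
    study_start: dt.date = STUDY_START,
    study_end: dt.date = STUDY_END,
) -> tuple[bool, str]:
    """Check the inclusion criteria; the reason names the first failure.

    Registration is required to overlap *any part* of the study period
    (a registration ending before study start, or starting after study end,
    fails). A missing registration end means the patient never transferred
    out.
    """
    if patient.copd_diagnosis_date is None:
        return False, "no_copd_diagnosis"
    if age_at(patient.birth_date, patient.copd_diagnosis_date) < 35:
        return False, "age_under_35_at_diagnosis"
    reg_end = patient.registration_end or dt.date.max
    if patient.registration_start > study_end or reg_end < study_start:
        return False, "not_registered_during_study"
    if not patient.linkage_eligible:
        return False, "not_linkage_eligible"
    return True, "eligible"


def build_followup_window(
    patient: PatientRecord,
    study_start: dt.date = STUDY_START,
    study_end: dt.date = STUDY_END,
) -> FollowUpWindow | None:
    """Follow-up window for an eligible patient, or None when it is empty.

    start = max(study_start, COPD diagnosis + 1 year, registration start);
    end = min(study_end, death, transfer-out, last collection), with absent
    dates ignored. Both ends are inclusive.
    """
    if patient.copd_diagnosis_date is None:
        return None
    start = max(
        study_start,
        add_years(patient.copd_diagnosis_date, 1),
        patient.registration_start,
    )
    end_candidates = [study_end, patient.last_collection_date]
    if patient.death_date is not None:
        end_candidates.append(patient.death_date)
    if patient.registration_end is not None:
        end_candidates.append(patient.registration_end)
    end = min(end_candidates)
    if start > end:
        return None
    return FollowUpWindow(patient.patient_id, start, end)


@dataclass
class CohortResult:
    dataset: LinkedDataset
    windows: pd.DataFrame  # patient_id, start, end (datetime64)
    flow: FlowCounts

    def window_map(self) -> dict[str, FollowUpWindow]:
        return {
            r.patient_id: FollowUpWindow(r.patient_id, r.start.date(), r.end.date())
            for r in self.windows.itertuples(index=False)
        }


def apply_cohort(
    dataset: LinkedDataset,
    study_start: dt.date = STUDY_START,
    study_end: dt.date = STUDY_END,
) -> CohortResult:
    """Apply the eligibility stages in fixed order and derive windows.

    Returns the dataset restricted to cohort patients (all tables filtered),
    their follow-up windows, and the stage-by-stage flow counts.
    """
    records = dataset.patient_records()
    remaining = list(records)
    stage_counts: list[tuple[str, int]] = [("all_patients", len(remaining))]

    stage_predicates = [
        ("copd_diagnosis", lambda p: p.copd_diagnosis_date is not None),
        (
            "age_35_plus_at_diagnosis",
            lambda p: age_at(p.birth_date, p.copd_diagnosis_date) >= 35,
        ),
        (
            "registered_during_study",
            lambda p: p.registration_start <= study_end
            and (p.registration_end or dt.date.max) >= study_start,
        ),
        ("linkage_eligible", lambda p: p.linkage_eligible),
    ]
    for label, predicate in stage_predicates:
        remaining = [p for p in remaining if predicate(p)]
        stage_counts.append((label, len(remaining)))

    windows = [
        w
        for p in remaining
        if (w := build_followup_window(p, study_start, study_end)) is not None
    ]
    stage_counts.append(("followup_time_available", len(windows)))

    keep = {w.patient_id for w in windows}
    windows_frame = pd.DataFrame(
        {
            "patient_id": [w.patient_id for w in windows],
            "start": pd.to_datetime([w.start for w in windows]),
            "end": pd.to_datetime([w.end for w in windows]),
        }
    )
    filtered = LinkedDataset(
        patients=dataset.patients[dataset.patients["patient_id"].isin(keep)].reset_index(drop=True),
        observations=dataset.observations[
            dataset.observations["patient_id"].isin(keep)
        ].reset_index(drop=True),
        prescriptions=dataset.prescriptions[
            dataset.prescriptions["patient_id"].isin(keep)
        ].reset_index(drop=True),
        spells=[s for s in dataset.spells if s.patient_id in keep],
    )
    return CohortResult(
        dataset=filtered,
        windows=windows_frame,
        flow=FlowCounts(tuple(stage_counts)),
    )
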