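"""The two validation stages of pneumonia coding against the hospital record.

Stage 1 — PPV of primary-care coding. Qualifying primary-care events
(prospectively coded, community onset) are linked to the earliest hospital
admission within a closed 7-day horizon of the index date. The linked spell's
gold standard is the primary (position-1) diagnosis of its *last* episode;
a sensitivity analysis instead counts a pneumonia code in *any* position of
the last episode. PPV = confirmed pneumonia / linked events, with an exact
binomial interval. A further sensitivity analysis restricts the denominator
to same-day admissions.

Stage 2 — sensitivity of primary-care recording. Hospital pneumonia events
(primary last-episode diagnosis J12-J18, admitted inside the patient's
follow-up window; community/hospital onset not distinguished here) are
checked for a primary-care pneumonia code within a closed 42-day horizon of
the *admission* date — either any pneumonia code, or a pneumonia code paired
with a generic/respiratory hospitalisation code on the same observation date.
No same-day-entry restriction applies in this stage.

Counts of 1-4 are censored only when rendering; machine-readable reports
retain exact counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .algorithm_engine import (
    AlgorithmSpec,
    apply_algorithm,
    enumerate_algorithms,
)
from .codelists import CATEGORIES, CategoryMap, CodelistBundle
from .ehr_model import HospitalSpell, last_episode
from .stats import ProportionEstimate, censor_count

__all__ = [
    "GOLD_MODES",
    "RECORDING_MODES",
    "AdmissionOutcome",
    "AlgorithmResult",
    "ValidationReport",
    "build_gold_table",
    "classify_gold",
    "link_admissions",
    "compute_ppv",
    "breakdown_nonpneumonia",
    "find_hospital_pneumonia_events",
    "check_gp_recording",
    "compute_sensitivity",
    "validate_ppv",
]

GOLD_MODES = ("primary_last_episode", "any_position_last_episode")
RECORDING_MODES = ("code_only", "code_plus_hosp")


@dataclass(frozen=True)
class AdmissionOutcome:
    """One linked event: the spell it linked to and its gold classification."""

    event_id: int
    spell_id: str
    days_to_admission: int
    gold_category: str
    gold_mode: str

    def __post_init__(self) -> None:
        if self.days_to_admission < 0:
            raise ValueError("days_to_admission must be >= 0")
        if self.gold_mode not in GOLD_MODES:
            raise ValueError(f"unknown gold mode {self.gold_mode!r}")


def classify_gold(
    spell: HospitalSpell,
    category_map: CategoryMap | None = None,
    mode: str = "primary_last_episode",
) -> str:
    """Gold-standard category of one spell under the chosen mode.

    ``any_position_last_episode`` classifies the spell as pneumonia when any
    diagnosis of the last episode is J12-J18 and otherwise falls back to the
    primary code's category.
    """
    cmap = category_map or CategoryMap()
    if mode not in GOLD_MODES:
        raise ValueError(f"unknown gold mode {mode!r}")
    episode = last_episode(spell)
    if mode == "any_position_last_episode" and any(
        cmap.is_pneumonia(code) for code in episode.diagnoses
    ):
        return "pneumonia"
    return cmap.category(episode.primary_diagnosis)


def build_gold_table(
    spells: list[HospitalSpell], category_map: CategoryMap | None = None
) -> pd.DataFrame:
    """One row per spell with its last-episode gold classification.

    Columns: spell_id, patient_id, admission_date, discharge_date,
    primary_code, primary_category, any_position_pneumonia.
    """
    cmap = category_map or CategoryMap()
    rows = []
    for s in spells:
        episode = last_episode(s)
        rows.append(
            (
                s.spell_id,
                s.patient_id,
                s.admission_date,
                s.discharge_date,
                episode.primary_diagnosis,
                cmap.category(episode.primary_diagnosis),
                any(cmap.is_pneumonia(c) for c in episode.diagnoses),
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "spell_id",
            "patient_id",
            "admission_date",
            "discharge_date",
            "primary_code",
            "primary_category",
            "any_position_pneumonia",
        ],
    )
    frame["admission_date"] = pd.to_datetime(frame["admission_date"])
    frame["discharge_date"] = pd.to_datetime(frame["discharge_date"])
    return frame


def link_admissions(
    events: pd.DataFrame,
    gold_table: pd.DataFrame,
    horizon_days: int = 7,
) -> pd.DataFrame:
    """Link each event to the earliest admission within the closed horizon.

    An admission on the index date itself (day 0) is allowed. Ties on the
    admission date are broken by spell_id so linkage is deterministic.
    Returns one row per *linked* event with the spell's gold columns and
    ``days_to_admission``.
    """
    if events.empty or gold_table.empty:
        return pd.DataFrame(
            columns=[
                "event_id",
                "patient_id",
                "index_date",
                "spell_id",
                "admission_date",
                "days_to_admission",
                "primary_category",
                "any_position_pneumonia",
            ]
        )
    merged = events[["event_id", "patient_id", "index_date"]].merge(
        gold_table, on="patient_id", how="inner"
    )
    delta = (merged["admission_date"] - merged["index_date"]).dt.days
    merged = merged[(delta >= 0) & (delta <= horizon_days)].copy()
    merged["days_to_admission"] = (
        (merged["admission_date"] - merged["index_date"]).dt.days.astype(int)
    )
    merged = merged.sort_values(
        ["event_id", "admission_date", "spell_id"], kind="stable"
    )
    linked = merged.groupby("event_id", as_index=False).first()
    return linked[
        [
            "event_id",
            "patient_id",
            "index_date",
            "spell_id",
            "admission_date",
            "days_to_admission",
            "primary_category",
            "any_position_pneumonia",
        ]
    ].reset_index(drop=True)


def _gold_is_pneumonia(linked: pd.DataFrame, mode: str) -> pd.Series:
    if mode == "primary_last_episode":
        return linked["primary_category"] == "pneumonia"
    if mode == "any_position_last_episode":
        return (linked["primary_category"] == "pneumonia") | linked[
            "any_position_pneumonia"
        ].astype(bool)
    raise ValueError(f"unknown gold mode {mode!r}")


@dataclass(frozen=True)
class AlgorithmResult:
    """One algorithm grid row: event/admission/confirmation counts and PPV."""

    algorithm_id: int
    label: str
    gold_mode: str
    same_day_only: bool
    events: int
    admitted: int
    confirmed: int
    estimate: ProportionEstimate | None  # None when no event was admitted

    def __post_init__(self) -> None:
        if not self.confirmed <= self.admitted <= self.events:
            raise ValueError("counts must satisfy confirmed <= admitted <= events")

    def render_row(self, threshold: int = 5) -> dict[str, str]:
        admitted_pct = (
            f"{100 * self.admitted / self.events:.1f}%" if self.events else "-"
        )
        return {
            "algorithm_id": str(self.algorithm_id),
            "label": self.label,
            "gold_mode": self.gold_mode,
            "same_day_only": str(self.same_day_only).lower(),
            "events": censor_count(self.events, threshold),
            "admitted": f"{censor_count(self.admitted, threshold)} ({admitted_pct})",
            "confirmed": censor_count(self.confirmed, threshold),
            "ppv": self.estimate.render(threshold) if self.estimate else "-",
        }


def compute_ppv(
    qualifying_events: pd.DataFrame,
    linked: pd.DataFrame,
    spec: AlgorithmSpec,
    gold_mode: str = "primary_last_episode",
    same_day_only: bool = False,
    ci_method: str = "clopper_pearson",
) -> AlgorithmResult:
    """PPV of one algorithm: confirmed pneumonia among its linked events."""
    linked = linked[linked["event_id"].isin(qualifying_events["event_id"])]
    if same_day_only:
        linked = linked[linked["days_to_admission"] == 0]
    n = len(linked)
    k = int(_gold_is_pneumonia(linked, gold_mode).sum())
    estimate = (
        ProportionEstimate.from_counts(k, n, method=ci_method) if n > 0 else None
    )
    return AlgorithmResult(
        algorithm_id=spec.id,
        label=spec.label,
        gold_mode=gold_mode,
        same_day_only=same_day_only,
        events=len(qualifying_events),
        admitted=n,
        confirmed=k,
        estimate=estimate,
    )


def breakdown_nonpneumonia(
    linked: pd.DataFrame, ci_method: str = "clopper_pearson"
) -> dict[str, ProportionEstimate]:
    """Category shares among linked events not confirmed as pneumonia.

    Uses the primary-mode classification; the denominator is the number of
    non-pneumonia linked events, so the shares sum to 100%.
    """
    non = linked[linked["primary_category"] != "pneumonia"]
    denominator = len(non)
    if denominator == 0:
        return {}
    out: dict[str, ProportionEstimate] = {}
    for category in CATEGORIES:
        if category == "pneumonia":
            continue
        k = int((non["primary_category"] == category).sum())
        out[category] = ProportionEstimate.from_counts(k, denominator, method=ci_method)
    return out


def find_hospital_pneumonia_events(
    gold_table: pd.DataFrame,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Hospital pneumonia events eligible for the recording analysis.

    Spells with a primary last-episode diagnosis of pneumonia and an
    admission date inside the patient's follow-up window. No
    hospital-acquired exclusion applies: every hospitalised pneumonia should
    reach the GP record regardless of onset.
    """
    pneu = gold_table[gold_table["primary_category"] == "pneumonia"]
    if pneu.empty or windows.empty:
        return pneu.iloc[0:0]
    merged = pneu.merge(windows, on="patient_id", how="inner")
    inside = (merged["admission_date"] >= merged["start"]) & (
        merged["admission_date"] <= merged["end"]
    )
    return (
        merged[inside]
        .drop(columns=["start", "end"])
        .sort_values(["patient_id", "admission_date", "spell_id"], kind="stable")
        .reset_index(drop=True)
    )


def check_gp_recording(
    hospital_events: pd.DataFrame,
    observations: pd.DataFrame,
    bundle: CodelistBundle,
    mode: str = "code_only",
    horizon_days: int = 42,
) -> pd.Series:
    """Whether each hospital event was recorded in primary care in time.

    ``code_only``: any pneumonia code with observation date in the closed
    interval [admission, admission + horizon]. ``code_plus_hosp``: that
    pneumonia code must be accompanied by a generic or respiratory
    hospitalisation code on the *same observation date*. Entry dates are
    ignored here: retrospective recording still counts as recording.
    """
    if mode not in RECORDING_MODES:
        raise ValueError(f"unknown recording mode {mode!r}")
    if hospital_events.empty:
        return pd.Series(dtype=bool)
    from .algorithm_engine import _matching_mask  # shared code-matching helper

    pneu_obs = observations.loc[
        _matching_mask(observations["code"], bundle.pneumonia),
        ["patient_id", "observation_date"],
    ]
    if mode == "code_plus_hosp":
        hosp_obs = observations.loc[
            _matching_mask(observations["code"], bundle.hospitalisation),
            ["patient_id", "observation_date"],
        ].drop_duplicates()
        pneu_obs = pneu_obs.merge(
            hosp_obs, on=["patient_id", "observation_date"], how="inner"
        )
    merged = hospital_events[["spell_id", "patient_id", "admission_date"]].merge(
        pneu_obs, on="patient_id", how="left"
    )
    delta = (merged["observation_date"] - merged["admission_date"]).dt.days
    merged["hit"] = (delta >= 0) & (delta <= horizon_days)
    by_spell = merged.groupby("spell_id")["hit"].any()
    return (
        hospital_events["spell_id"].map(by_spell).fillna(False).astype(bool)
    )


def compute_sensitivity(
    hospital_events: pd.DataFrame,
    recorded: pd.Series,
    ci_method: str = "clopper_pearson",
) -> ProportionEstimate | None:
    """Share of hospital pneumonia events recorded in primary care in time."""
    n = len(hospital_events)
    if n == 0:
        return None
    return ProportionEstimate.from_counts(int(recorded.sum()), n, method=ci_method)


@dataclass
class ValidationReport:
    """Full PPV-stage output: the algorithm grid plus the category breakdown."""

    rows: list[AlgorithmResult]
    breakdown: dict[str, ProportionEstimate] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "algorithm_id": r.algorithm_id,
                    "label": r.label,
                    "gold_mode": r.gold_mode,
                    "same_day_only": r.same_day_only,
                    "events": r.events,
                    "admitted": r.admitted,
                    "confirmed": r.confirmed,
                    "ppv_percent": r.estimate.percent if r.estimate else None,
                    "ci_low": r.estimate.ci_low if r.estimate else None,
                    "ci_high": r.estimate.ci_high if r.estimate else None,
                }
            )
        return pd.DataFrame(records)

    def render_frame(self, threshold: int = 5) -> pd.DataFrame:
        return pd.DataFrame([r.render_row(threshold) for r in self.rows])


def validate_ppv(
    events_with_components: pd.DataFrame,
    gold_table: pd.DataFrame,
    specs: list[AlgorithmSpec] | None = None,
    gold_modes: tuple[str, ...] = GOLD_MODES,
    same_day_variants: tuple[bool, ...] = (False, True),
    horizon_days: int = 7,
    ci_method: str = "clopper_pearson",
) -> ValidationReport:
    """Run the full algorithm grid over every gold mode and same-day variant.

    ``events_with_components`` must already be filtered to same-day-entry,
    non-hospital-acquired events with component columns evaluated.
    """
    specs = specs or enumerate_algorithms()
    linked = link_admissions(events_with_components, gold_table, horizon_days)
    rows = []
    for spec in specs:
        qualifying = apply_algorithm(spec, events_with_components)
        for mode in gold_modes:
            for same_day in same_day_variants:
                rows.append(
                    compute_ppv(
                        qualifying,
                        linked,
                        spec,
                        gold_mode=mode,
                        same_day_only=same_day,
                        ci_method=ci_method,
                    )
                )
    return ValidationReport(rows=rows, breakdown=breakdown_nonpneumonia(linked, ci_method))
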