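"""Candidate pneumonia events in primary care and the 19 component algorithms.

A *candidate event* is a cluster of primary-care pneumonia codes for one
patient: codes separated by at most ``dedup_gap_days`` (chained) collapse to
a single event indexed at the earliest code. Candidate events are then
filtered to prospectively coded ones (observation date equal to data-entry
date) and to community onset (not during, or shortly after, a hospital stay).

The 19 identification algorithms combine the index pneumonia code with
supporting components recorded within a symmetric ``component_window_days``
window around the index date:

* symptoms — codes from at least two distinct symptom categories out of
  new cough, sputum, breathlessness, fever, lethargy, tachycardia;
* referral for chest X-ray;
* antibiotics — any prescription issue, or one lasting 5-14 days;
* sputum/blood culture sent, and culture positive result.

Events are held in a DataFrame (one row per event) with boolean component
columns; :class:`CandidateEvent` is the record-level view of one row.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codelists import Codelist, CodelistBundle, normalize_code
from .ehr_model import HospitalSpell

__all__ = [
    "AlgorithmSpec",
    "CandidateEvent",
    "EVENT_COLUMNS",
    "enumerate_algorithms",
    "find_index_events",
    "require_same_day_entry",
    "flag_hospital_acquired",
    "evaluate_components",
    "apply_algorithm",
]

EVENT_COLUMNS = ["event_id", "patient_id", "index_date", "entry_date", "same_day_entry"]
COMPONENT_COLUMNS = [
    "symptoms",
    "cxr",
    "culture_sent",
    "culture_positive",
    "abx_any",
    "abx_5_14",
]


@dataclass(frozen=True)
class AlgorithmSpec:
    """One row of the algorithm grid: which components the event must carry."""

    id: int
    label: str
    requires_symptoms: bool = False
    requires_cxr: bool = False
    antibiotics_mode: str = "none"  # none | any_duration | duration_5_14
    requires_culture_sent: bool = False
    requires_culture_positive: bool = False
    component_window_days: int = 7

    def __post_init__(self) -> None:
        if self.antibiotics_mode not in ("none", "any_duration", "duration_5_14"):
            raise ValueError(f"unknown antibiotics_mode {self.antibiotics_mode!r}")

    def required_columns(self) -> list[str]:
        cols = []
        if self.requires_symptoms:
            cols.append("symptoms")
        if self.requires_cxr:
            cols.append("cxr")
        if self.antibiotics_mode == "any_duration":
            cols.append("abx_any")
        elif self.antibiotics_mode == "duration_5_14":
            cols.append("abx_5_14")
        if self.requires_culture_sent:
            cols.append("culture_sent")
        if self.requires_culture_positive:
            cols.append("culture_positive")
        return cols


@dataclass(frozen=True)
class CandidateEvent:
    """Record-level view of one candidate-event row."""

    event_id: int
    patient_id: str
    index_date: dt.date
    entry_date: dt.date
    same_day_entry: bool
    hospital_acquired: bool = False

    @classmethod
    def from_row(cls, row: pd.Series) -> "CandidateEvent":
        return cls(
            event_id=int(row["event_id"]),
            patient_id=row["patient_id"],
            index_date=row["index_date"].date(),
            entry_date=row["entry_date"].date(),
            same_day_entry=bool(row["same_day_entry"]),
            hospital_acquired=bool(row.get("hospital_acquired", False)),
        )


def enumerate_algorithms(component_window_days: int = 7) -> list[AlgorithmSpec]:
    """The 19 predefined algorithms, from code-only to the full combination."""

    def spec(i, label, symptoms=False, cxr=False, abx="none", sent=False, pos=False):
        return AlgorithmSpec(
            id=i,
            label=label,
            requires_symptoms=symptoms,
            requires_cxr=cxr,
            antibiotics_mode=abx,
            requires_culture_sent=sent,
            requires_culture_positive=pos,
            component_window_days=component_window_days,
        )

    return [
        spec(1, "pneumonia code only"),
        spec(2, "code + symptoms (>=2 categories)", symptoms=True),
        spec(3, "code + chest X-ray referral", cxr=True),
        spec(4, "code + culture sent", sent=True),
        spec(5, "code + culture positive", pos=True),
        spec(6, "code + symptoms + chest X-ray", symptoms=True, cxr=True),
        spec(7, "code + antibiotics 5-14 days", abx="duration_5_14"),
        spec(8, "code + antibiotics any duration", abx="any_duration"),
        spec(9, "code + symptoms + antibiotics", symptoms=True, abx="any_duration"),
        spec(10, "code + chest X-ray + antibiotics", cxr=True, abx="any_duration"),
        spec(11, "code + antibiotics + culture sent", abx="any_duration", sent=True),
        spec(12, "code + antibiotics + culture positive", abx="any_duration", pos=True),
        spec(13, "code + chest X-ray + culture sent", cxr=True, sent=True),
        spec(14, "code + chest X-ray + culture positive", cxr=True, pos=True),
        spec(15, "code + symptoms + culture sent", symptoms=True, sent=True),
        spec(16, "code + symptoms + culture positive", symptoms=True, pos=True),
        spec(
            17,
            "code + chest X-ray + symptoms + antibiotics",
            symptoms=True,
            cxr=True,
            abx="any_duration",
        ),
        spec(
            18,
            "code + chest X-ray + symptoms + antibiotics + culture sent",
            symptoms=True,
            cxr=True,
            abx="any_duration",
            sent=True,
        ),
        spec(
            19,
            "code + chest X-ray + symptoms + antibiotics + culture positive",
            symptoms=True,
            cxr=True,
            abx="any_duration",
            pos=True,
        ),
    ]


def algorithm_by_id(algorithm_id: int, component_window_days: int = 7) -> AlgorithmSpec:
    """Look up one of the 19 algorithms by its grid id."""
    for spec in enumerate_algorithms(component_window_days):
        if spec.id == algorithm_id:
            return spec
    raise ValueError(f"unknown algorithm id {algorithm_id}; valid ids are 1-19")


def _matching_mask(codes: pd.Series, codelist: Codelist) -> pd.Series:
    normed = codes.map(normalize_code)
    if codelist.match_mode == "exact":
        return normed.isin(codelist.codes)
    return normed.str.startswith(tuple(codelist.codes))


def find_index_events(
    observations: pd.DataFrame,
    pneumonia_codelist: Codelist,
    windows: pd.DataFrame,
    dedup_gap_days: int = 14,
) -> pd.DataFrame:
    """Cluster pneumonia codes into candidate events inside follow-up windows.

    Consecutive pneumonia codes of a patient at most ``dedup_gap_days`` apart
    chain into one event, indexed at the earliest code of the chain. The
    event's entry date is the earliest entry date among index-day codes, and
    ``same_day_entry`` is true when any index-day code was entered on the
    index date. Events whose index date falls outside the patient's follow-up
    window are dropped. Order-independent and idempotent.
    """
    obs = observations[_matching_mask(observations["code"], pneumonia_codelist)]
    if obs.empty or windows.empty:
        return _empty_events()
    obs = obs.sort_values(
        ["patient_id", "observation_date", "entry_date"], kind="stable"
    ).reset_index(drop=True)
    gap = obs.groupby("patient_id")["observation_date"].diff()
    new_cluster = gap.isna() | (gap > pd.Timedelta(days=dedup_gap_days))
    obs["cluster"] = new_cluster.cumsum()

    first = obs.groupby("cluster").agg(
        patient_id=("patient_id", "first"),
        index_date=("observation_date", "min"),
    )
    index_day = obs.merge(first, left_on="cluster", right_index=True, suffixes=("", "_c"))
    index_day = index_day[index_day["observation_date"] == index_day["index_date"]].copy()
    index_day["same_day"] = index_day["entry_date"] == index_day["observation_date"]
    entry = index_day.groupby("cluster").agg(
        entry_date=("entry_date", "min"),
        same_day_entry=("same_day", "any"),
    )
    events = first.join(entry).reset_index(drop=True)

    events = events.merge(windows, on="patient_id", how="inner")
    events = events[
        (events["index_date"] >= events["start"]) & (events["index_date"] <= events["end"])
    ]
    events = events.drop(columns=["start", "end"]).reset_index(drop=True)
    events = events.sort_values(["patient_id", "index_date"], kind="stable").reset_index(
        drop=True
    )
    events.insert(0, "event_id", np.arange(len(events)))
    return events[EVENT_COLUMNS]


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": pd.Series(dtype=int),
            "patient_id": pd.Series(dtype=str),
            "index_date": pd.Series(dtype="datetime64[ns]"),
            "entry_date": pd.Series(dtype="datetime64[ns]"),
            "same_day_entry": pd.Series(dtype=bool),
        }
    )


def require_same_day_entry(events: pd.DataFrame) -> pd.DataFrame:
    """Keep prospectively coded events (entered on the observation day)."""
    return events[events["same_day_entry"]].reset_index(drop=True)


def flag_hospital_acquired(
    events: pd.DataFrame,
    spells: list[HospitalSpell],
    post_discharge_days: int = 14,
) -> pd.DataFrame:
    """Add a ``hospital_acquired`` flag for events arising around a prior stay.

    An event is flagged when its index date lies inside a spell that *began
    before* the index date, or within ``post_discharge_days`` after any such
    spell's discharge. A spell admitted on or after the index date does not
    flag the event: an admission that follows a primary-care diagnosis is its
    consequence, not its source.
    """
    events = events.copy()
    if events.empty or not spells:
        events["hospital_acquired"] = pd.Series(dtype=bool) if events.empty else False
        return events
    spell_frame = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in spells],
            "admission": pd.to_datetime([s.admission_date for s in spells]),
            "discharge": pd.to_datetime([s.discharge_date for s in spells]),
        }
    )
    merged = events[["event_id", "patient_id", "index_date"]].merge(
        spell_frame, on="patient_id", how="left"
    )
    flagged = (
        (merged["admission"] < merged["index_date"])
        & (merged["index_date"] <= merged["discharge"] + pd.Timedelta(days=post_discharge_days))
    )
    by_event = flagged.groupby(merged["event_id"]).any()
    events["hospital_acquired"] = events["event_id"].map(by_event).fillna(False).astype(bool)
    return events


def _window_flag(
    events: pd.DataFrame,
    records: pd.DataFrame,
    date_column: str,
    window_days: int,
) -> pd.Series:
    """Boolean per event: any record within +/- window_days of the index date."""
    if records.empty:
        return pd.Series(False, index=events.index)
    merged = events[["event_id", "patient_id", "index_date"]].merge(
        records, on="patient_id", how="inner"
    )
    delta = (merged[date_column] - merged["index_date"]).dt.days.abs()
    hit = merged.loc[delta <= window_days, "event_id"].unique()
    return events["event_id"].isin(hit)


def evaluate_components(
    events: pd.DataFrame,
    observations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    bundle: CodelistBundle,
    component_window_days: int = 7,
) -> pd.DataFrame:
    """Add the six boolean component columns to the event table.

    All components are sought in the closed window
    [index - w, index + w] with w = ``component_window_days``. The symptoms
    flag requires codes from at least two *distinct* symptom categories;
    repeated codes from one category do not qualify.
    """
    events = events.copy()
    if events.empty:
        for col in COMPONENT_COLUMNS:
            events[col] = pd.Series(dtype=bool)
        return events

    def obs_for(codelist: Codelist) -> pd.DataFrame:
        return observations.loc[
            _matching_mask(observations["code"], codelist),
            ["patient_id", "code", "observation_date"],
        ]

    # symptoms: distinct categories within the window
    symp = obs_for(bundle.symptoms).copy()
    if symp.empty:
        events["symptoms"] = False
    else:
        symp["category"] = symp["code"].map(
            lambda c: bundle.symptoms.category_of(c)
        )
        merged = events[["event_id", "patient_id", "index_date"]].merge(
            symp, on="patient_id", how="inner"
        )
        delta = (merged["observation_date"] - merged["index_date"]).dt.days.abs()
        merged = merged[delta <= component_window_days]
        n_cat = merged.groupby("event_id")["category"].nunique()
        events["symptoms"] = (
            events["event_id"].map(n_cat).fillna(0).astype(int) >= 2
        )

    events["cxr"] = _window_flag(
        events, obs_for(bundle.chest_xray), "observation_date", component_window_days
    )
    events["culture_sent"] = _window_flag(
        events, obs_for(bundle.culture_sent), "observation_date", component_window_days
    )
    events["culture_positive"] = _window_flag(
        events,
        obs_for(bundle.culture_positive),
        "observation_date",
        component_window_days,
    )

    abx = prescriptions.loc[
        _matching_mask(prescriptions["product_code"], bundle.antibiotics),
        ["patient_id", "issue_date", "duration_days"],
    ]
    events["abx_any"] = _window_flag(events, abx, "issue_date", component_window_days)
    abx_5_14 = abx[abx["duration_days"].between(5, 14).fillna(False).astype(bool)]
    events["abx_5_14"] = _window_flag(
        events, abx_5_14, "issue_date", component_window_days
    )
    return events


def apply_algorithm(spec: AlgorithmSpec, events: pd.DataFrame) -> pd.DataFrame:
    """Events qualifying under one algorithm (all required components true).

    The code-only algorithm passes every event unchanged, so every other
    algorithm's qualifying set is a subset of it.
    """
    required = spec.required_columns()
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise ValueError(
            f"algorithm {spec.id} needs component column(s) {missing}; "
            "run evaluate_components first"
        )
    if not required:
        return events.reset_index(drop=True)
    mask = events[required].all(axis=1)
    return events[mask].reset_index(drop=True)
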