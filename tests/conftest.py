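"""Shared fixtures and factory helpers for building tiny linked datasets."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from pneumolink.codelists import default_bundle
from pneumolink.ehr_model import HospitalEpisode, HospitalSpell, LinkedDataset


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


def patient_row(
    pid: str = "P1",
    sex: str = "male",
    birth: str = "1950-01-01",
    copd: str | None = "2010-05-01",
    reg_start: str = "2000-01-01",
    reg_end: str | None = None,
    death: str | None = None,
    collection: str = "2021-05-01",
    linkage: bool = True,
) -> dict:
    return {
        "patient_id": pid,
        "sex": sex,
        "birth_date": birth,
        "copd_diagnosis_date": copd,
        "registration_start": reg_start,
        "registration_end": reg_end,
        "death_date": death,
        "last_collection_date": collection,
        "linkage_eligible": linkage,
    }


def obs_row(pid: str, code: str, obs_date: str, entry_date: str | None = None) -> dict:
    return {
        "patient_id": pid,
        "code": code,
        "observation_date": obs_date,
        "entry_date": entry_date or obs_date,
    }


def rx_row(pid: str, code: str, issue: str, duration: int | None = None) -> dict:
    return {
        "patient_id": pid,
        "product_code": code,
        "issue_date": issue,
        "duration_days": duration,
    }


def spell(
    sid: str,
    pid: str,
    admission: str,
    discharge: str,
    episodes: list[tuple[int, str, list[str]]],
) -> HospitalSpell:
    return HospitalSpell(
        spell_id=sid,
        patient_id=pid,
        admission_date=d(admission),
        discharge_date=d(discharge),
        episodes=tuple(
            HospitalEpisode(episode_order=o, episode_start=d(s), diagnoses=tuple(dx))
            for o, s, dx in episodes
        ),
    )


def make_dataset(
    patients: list[dict],
    observations: list[dict] | None = None,
    prescriptions: list[dict] | None = None,
    spells: list[HospitalSpell] | None = None,
) -> LinkedDataset:
    columns = list(patient_row().keys())
    pat = pd.DataFrame(patients, columns=columns)
    for col in pat.columns:
        if col.endswith(("_date", "_start", "_end")):
            pat[col] = pd.to_datetime(pat[col])
    obs = pd.DataFrame(
        observations or [],
        columns=["patient_id", "code", "observation_date", "entry_date"],
    )
    obs["observation_date"] = pd.to_datetime(obs["observation_date"])
    obs["entry_date"] = pd.to_datetime(obs["entry_date"])
    rx = pd.DataFrame(
        prescriptions or [],
        columns=["patient_id", "product_code", "issue_date", "duration_days"],
    )
    rx["issue_date"] = pd.to_datetime(rx["issue_date"])
    rx["duration_days"] = pd.to_numeric(rx["duration_days"]).astype("Int64")
    return LinkedDataset(
        patients=pat, observations=obs, prescriptions=rx, spells=list(spells or [])
    )


def make_windows(entries: list[tuple[str, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p for p, _, _ in entries],
            "start": pd.to_datetime([s for _, s, _ in entries]),
            "end": pd.to_datetime([e for _, _, e in entries]),
        }
    )


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()
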