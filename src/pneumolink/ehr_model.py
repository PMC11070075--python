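"""Domain types and CSV IO for linked primary/secondary-care EHR extracts.

The data model mirrors the relational shape of UK routinely collected data:

* primary care — a patient registry, dated clinical observations (with both an
  observation date and a data-entry date, which may differ when coding is
  retrospective), and prescription issues;
* secondary care — inpatient *spells* (admissions), each made of ordered
  consultant *episodes* carrying an ordered list of ICD-10 diagnoses, where
  position 1 is the primary diagnosis.

Files are UTF-8 CSV with a mandatory header row and ISO-8601 (YYYY-MM-DD)
dates. The hospital file is long format: one row per diagnosis position per
episode. All date intervals elsewhere in this package are closed on both ends
unless an operation states otherwise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "RowParseError",
    "IntegrityError",
    "PatientRecord",
    "ClinicalObservation",
    "PrescriptionRecord",
    "HospitalEpisode",
    "HospitalSpell",
    "LinkedDataset",
    "read_primary_care",
    "read_hospital",
    "last_episode",
    "write_linked_dataset",
]


class SchemaError(ValueError):
    """A required column is missing or a file is structurally invalid."""


class RowParseError(ValueError):
    """A row holds an unparseable value; the message carries the line number."""


class IntegrityError(ValueError):
    """A cross-table invariant is violated (orphan rows, inverted dates...)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str  # male | female
    birth_date: dt.date
    copd_diagnosis_date: dt.date | None
    registration_start: dt.date
    last_collection_date: dt.date
    registration_end: dt.date | None = None
    death_date: dt.date | None = None
    linkage_eligible: bool = True

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise IntegrityError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.registration_start > self.last_collection_date:
            raise IntegrityError(
                f"{self.patient_id}: registration_start after last_collection_date"
            )
        if self.death_date is not None and self.death_date < self.birth_date:
            raise IntegrityError(f"{self.patient_id}: death before birth")
        if (
            self.copd_diagnosis_date is not None
            and self.copd_diagnosis_date < self.birth_date
        ):
            raise IntegrityError(f"{self.patient_id}: COPD diagnosis before birth")


@dataclass(frozen=True)
class ClinicalObservation:
    patient_id: str
    code: str
    observation_date: dt.date
    entry_date: dt.date  # may precede, equal or follow observation_date


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    product_code: str
    issue_date: dt.date
    duration_days: int | None = None

    def __post_init__(self) -> None:
        if self.duration_days is not None and self.duration_days < 1:
            raise IntegrityError(
                f"{self.patient_id}: duration_days must be >= 1, "
                f"got {self.duration_days}"
            )


@dataclass(frozen=True)
class HospitalEpisode:
    episode_order: int
    episode_start: dt.date
    diagnoses: tuple[str, ...]  # position 1 (index 0) = primary diagnosis

    def __post_init__(self) -> None:
        if not self.diagnoses:
            raise IntegrityError("episode has an empty diagnosis list")
        if self.episode_order < 1:
            raise IntegrityError(f"episode_order must be >= 1, got {self.episode_order}")

    @property
    def primary_diagnosis(self) -> str:
        return self.diagnoses[0]


@dataclass(frozen=True)
class HospitalSpell:
    spell_id: str
    patient_id: str
    admission_date: dt.date
    discharge_date: dt.date
    episodes: tuple[HospitalEpisode, ...]

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise IntegrityError(
                f"spell {self.spell_id}: admission after discharge"
            )
        if not self.episodes:
            raise IntegrityError(f"spell {self.spell_id}: no episodes")
        orders = [e.episode_order for e in self.episodes]
        if len(set(orders)) != len(orders):
            raise IntegrityError(f"spell {self.spell_id}: duplicate episode_order")
        if list(orders) != sorted(orders):
            raise IntegrityError(f"spell {self.spell_id}: episodes out of order")
        for e in self.episodes:
            if not self.admission_date <= e.episode_start <= self.discharge_date:
                raise IntegrityError(
                    f"spell {self.spell_id}: episode {e.episode_order} starts "
                    "outside the spell dates"
                )


def last_episode(spell: HospitalSpell) -> HospitalEpisode:
    """The episode carrying the spell's gold-standard diagnosis.

    "Last" means highest ``episode_order``; an order tie is broken by the
    latest ``episode_start``, and an unresolvable tie is an error rather than
    a silent arbitrary pick. Idempotent and independent of input row order
    because spells are stored sorted.
    """
    if not spell.episodes:
        raise IntegrityError(f"spell {spell.spell_id}: no episodes")
    best = max(spell.episodes, key=lambda e: (e.episode_order, e.episode_start))
    ties = [
        e
        for e in spell.episodes
        if (e.episode_order, e.episode_start)
        == (best.episode_order, best.episode_start)
    ]
    if len(ties) > 1:
        raise IntegrityError(
            f"spell {spell.spell_id}: ambiguous last episode "
            f"(order {best.episode_order} tied on start date)"
        )
    return best


# ---------------------------------------------------------------------------
# CSV IO

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "copd_diagnosis_date",
    "registration_start",
    "registration_end",
    "death_date",
    "last_collection_date",
    "linkage_eligible",
]
OBSERVATION_COLUMNS = ["patient_id", "code", "observation_date", "entry_date"]
PRESCRIPTION_COLUMNS = ["patient_id", "product_code", "issue_date", "duration_days"]
HOSPITAL_COLUMNS = [
    "spell_id",
    "patient_id",
    "admission_date",
    "discharge_date",
    "episode_order",
    "episode_start",
    "position",
    "icd10_code",
]

_OPTIONAL_DATE_COLUMNS = {"registration_end", "death_date", "copd_diagnosis_date"}


def _require_columns(frame: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_dates(frame: pd.DataFrame, column: str, path: str | Path) -> pd.Series:
    raw = frame[column].astype("string").str.strip()
    optional = column in _OPTIONAL_DATE_COLUMNS
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    blank = raw.isna() | (raw == "")
    bad = parsed.isna() & ~blank
    if bad.any():
        # +2: one for the header row, one for 0- vs 1-based indexing
        line = int(bad.idxmax()) + 2
        raise RowParseError(
            f"{path}, line {line}: unparseable date {raw[bad.idxmax()]!r} "
            f"in column {column!r}"
        )
    if not optional and blank.any():
        line = int(blank.idxmax()) + 2
        raise RowParseError(f"{path}, line {line}: empty date in column {column!r}")
    return parsed


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc


def read_primary_care(
    patients_path: str | Path,
    observations_path: str | Path,
    prescriptions_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three primary-care tables.

    Returns typed DataFrames (dates as datetime64, ``linkage_eligible`` as
    bool, ``duration_days`` as nullable Int64) and enforces referential
    integrity of observation and prescription patient identifiers.
    """
    patients = _read_csv(patients_path)
    _require_columns(patients, PATIENT_COLUMNS, patients_path)
    patients = patients[PATIENT_COLUMNS].copy()
    for col in PATIENT_COLUMNS:
        if col.endswith("_date") or col.endswith(("_start", "_end")):
            patients[col] = _parse_dates(patients, col, patients_path)
    patients["linkage_eligible"] = (
        patients["linkage_eligible"].astype("string").str.strip().str.lower()
        .map({"true": True, "false": False, "1": True, "0": False})
    )
    if patients["linkage_eligible"].isna().any():
        raise RowParseError(f"{patients_path}: unparseable linkage_eligible value")
    patients["linkage_eligible"] = patients["linkage_eligible"].astype(bool)
    if patients["patient_id"].duplicated().any():
        raise IntegrityError(f"{patients_path}: duplicate patient_id")

    observations = _read_csv(observations_path)
    _require_columns(observations, OBSERVATION_COLUMNS, observations_path)
    observations = observations[OBSERVATION_COLUMNS].copy()
    observations["observation_date"] = _parse_dates(
        observations, "observation_date", observations_path
    )
    observations["entry_date"] = _parse_dates(observations, "entry_date", observations_path)

    prescriptions = _read_csv(prescriptions_path)
    _require_columns(prescriptions, PRESCRIPTION_COLUMNS, prescriptions_path)
    prescriptions = prescriptions[PRESCRIPTION_COLUMNS].copy()
    prescriptions["issue_date"] = _parse_dates(prescriptions, "issue_date", prescriptions_path)
    prescriptions["duration_days"] = pd.to_numeric(
        prescriptions["duration_days"], errors="raise"
    ).astype("Int64")
    if (prescriptions["duration_days"].dropna() < 1).any():
        raise IntegrityError(f"{prescriptions_path}: duration_days < 1")

    known = set(patients["patient_id"])
    for name, frame in (("observations", observations), ("prescriptions", prescriptions)):
        orphans = set(frame["patient_id"]) - known
        if orphans:
            raise IntegrityError(
                f"{name}: patient_id(s) not present in patients table: "
                f"{sorted(orphans)[:5]}"
            )
    return patients, observations, prescriptions


def read_hospital(
    path: str | Path, patient_ids: set[str] | None = None
) -> list[HospitalSpell]:
    """Assemble spells from the long-format hospital CSV.

    Episodes are returned ordered by ``episode_order`` and diagnoses by
    ``position`` regardless of file row order. Duplicate
    (spell, episode_order, position) keys and episodes outside their spell's
    date range are errors.
    """
    frame = _read_csv(path)
    _require_columns(frame, HOSPITAL_COLUMNS, path)
    frame = frame[HOSPITAL_COLUMNS].copy()
    frame["admission_date"] = _parse_dates(frame, "admission_date", path)
    frame["discharge_date"] = _parse_dates(frame, "discharge_date", path)
    frame["episode_start"] = _parse_dates(frame, "episode_start", path)
    frame["episode_order"] = pd.to_numeric(frame["episode_order"], errors="raise").astype(int)
    frame["position"] = pd.to_numeric(frame["position"], errors="raise").astype(int)

    key = frame[["spell_id", "episode_order", "position"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate diagnosis key "
            f"(spell {dup['spell_id']}, episode {dup['episode_order']}, "
            f"position {dup['position']})"
        )
    if patient_ids is not None:
        orphans = set(frame["patient_id"]) - patient_ids
        if orphans:
            raise IntegrityError(
                f"{path}: patient_id(s) not present in patients table: "
                f"{sorted(orphans)[:5]}"
            )

    spells: list[HospitalSpell] = []
    frame = frame.sort_values(["spell_id", "episode_order", "position"], kind="stable")
    for spell_id, spell_rows in frame.groupby("spell_id", sort=True):
        if spell_rows["patient_id"].nunique() > 1 or spell_rows["admission_date"].nunique() > 1 \
                or spell_rows["discharge_date"].nunique() > 1:
            raise IntegrityError(f"{path}: inconsistent spell-level fields for {spell_id}")
        episodes = []
        for (order, start), ep_rows in spell_rows.groupby(
            ["episode_order", "episode_start"], sort=True
        ):
            episodes.append(
                HospitalEpisode(
                    episode_order=int(order),
                    episode_start=start.date(),
                    diagnoses=tuple(ep_rows.sort_values("position")["icd10_code"]),
                )
            )
        spells.append(
            HospitalSpell(
                spell_id=str(spell_id),
                patient_id=str(spell_rows["patient_id"].iloc[0]),
                admission_date=spell_rows["admission_date"].iloc[0].date(),
                discharge_date=spell_rows["discharge_date"].iloc[0].date(),
                episodes=tuple(episodes),
            )
        )
    return spells


def spells_to_frame(spells: list[HospitalSpell]) -> pd.DataFrame:
    """Long-format frame (one row per diagnosis position) for CSV export."""
    rows = []
    for s in spells:
        for e in s.episodes:
            for pos, code in enumerate(e.diagnoses, start=1):
                rows.append(
                    (
                        s.spell_id,
                        s.patient_id,
                        s.admission_date,
                        s.discharge_date,
                        e.episode_order,
                        e.episode_start,
                        pos,
                        code,
                    )
                )
    return pd.DataFrame(rows, columns=HOSPITAL_COLUMNS)


@dataclass
class LinkedDataset:
    """Primary-care tables plus assembled hospital spells for one extract."""

    patients: pd.DataFrame
    observations: pd.DataFrame
    prescriptions: pd.DataFrame
    spells: list[HospitalSpell] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.patients["patient_id"])
        for name, ids in (
            ("observations", set(self.observations["patient_id"])),
            ("prescriptions", set(self.prescriptions["patient_id"])),
            ("spells", {s.patient_id for s in self.spells}),
        ):
            orphans = ids - known
            if orphans:
                raise IntegrityError(
                    f"{name}: patient_id(s) not present in patients table: "
                    f"{sorted(orphans)[:5]}"
                )

    @classmethod
    def from_csv_dir(cls, directory: str | Path) -> "LinkedDataset":
        directory = Path(directory)
        patients, observations, prescriptions = read_primary_care(
            directory / "patients.csv",
            directory / "observations.csv",
            directory / "prescriptions.csv",
        )
        spells = read_hospital(
            directory / "hospital.csv", patient_ids=set(patients["patient_id"])
        )
        return cls(patients, observations, prescriptions, spells)

    def to_csv_dir(self, directory: str | Path) -> None:
        write_linked_dataset(self, directory)

    def patient_records(self) -> list[PatientRecord]:
        records = []
        for row in self.patients.itertuples(index=False):
            records.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    sex=row.sex,
                    birth_date=row.birth_date.date(),
                    copd_diagnosis_date=(
                        None if pd.isna(row.copd_diagnosis_date)
                        else row.copd_diagnosis_date.date()
                    ),
                    registration_start=row.registration_start.date(),
                    registration_end=(
                        None if pd.isna(row.registration_end)
                        else row.registration_end.date()
                    ),
                    death_date=(
                        None if pd.isna(row.death_date) else row.death_date.date()
                    ),
                    last_collection_date=row.last_collection_date.date(),
                    linkage_eligible=bool(row.linkage_eligible),
                )
            )
        return records


def _dates_to_iso(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out


def write_linked_dataset(dataset: LinkedDataset, directory: str | Path) -> None:
    """Write the four CSV tables; ``from_csv_dir`` round-trips them exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _dates_to_iso(dataset.patients).to_csv(directory / "patients.csv", index=False)
    _dates_to_iso(dataset.observations).to_csv(directory / "observations.csv", index=False)
    _dates_to_iso(dataset.prescriptions).to_csv(directory / "prescriptions.csv", index=False)
    _dates_to_iso(spells_to_frame(dataset.spells)).to_csv(
        directory / "hospital.csv", index=False
    )
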