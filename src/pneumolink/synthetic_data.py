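"""Synthetic linked primary/secondary-care datasets with known ground truth.

Real UK primary-care and hospital extracts are licensed, so every pipeline
stage here is exercised on simulated data that reproduces the *relational
structure* and the *coding-error structure* of the study setting:

* a COPD patient registry with registration, death, transfer-out and
  collection dates, plus configurable fractions of patients made ineligible
  (too young at diagnosis, not linkage-eligible, dead before the study) so
  that cohort flow accounting can be tested;
* true pneumonia episodes arising at a configurable annual rate inside each
  patient's follow-up window. An episode may be seen in primary care, may be
  coded as pneumonia rather than as an AECOPD/LRTI (GP miscoding — those
  codes are emitted but invisible to the pneumonia pipeline), may be entered
  the same day or retrospectively, and may lead to a hospital admission
  within 0-7 days whose last-episode primary diagnosis confirms pneumonia
  with probability ``p_hospital_confirms``;
* hospital-only pneumonia admissions that primary care never saw beforehand,
  recorded back into the GP record within 0-42 days with probability
  ``p_gp_records_admission`` (incomplete GP recording of hospitalisations),
  optionally carrying a same-day hospitalisation code.

Episodes within a patient are spaced at least ``min_event_separation_days``
apart so that every generated event maps one-to-one onto a pipeline event:
deduplication, hospital-acquired flagging and linkage cannot entangle
neighbouring episodes, and the exact recount in :func:`realized_rates` is an
equality oracle for the pipeline, not an approximation.

Default parameters emulate the study conditions: a confirmation probability
of 0.577, an admission probability of 0.277, a recording probability of
0.341, a non-pneumonia gold-category mixture of 32% COPD / 12.9% other
respiratory / 12.3% circulatory, and component emission rates giving the
observed orders of magnitude of chest X-ray referral, symptom, antibiotic
and culture coding.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .codelists import SYMPTOM_CATEGORIES, CodelistBundle, default_bundle
from .ehr_model import (
    HOSPITAL_COLUMNS,
    HospitalEpisode,
    HospitalSpell,
    LinkedDataset,
    OBSERVATION_COLUMNS,
    PATIENT_COLUMNS,
    PRESCRIPTION_COLUMNS,
)

__all__ = [
    "ComponentProbs",
    "SyntheticConfig",
    "GroundTruth",
    "RealizedRates",
    "generate",
    "realized_rates",
    "paper_like_config",
    "ppv_calibration_config",
]

# ICD-10 codes drawn for each gold-standard category
_ICD_BY_CATEGORY = {
    "pneumonia": ("J129", "J13", "J14", "J159", "J180", "J181", "J189"),
    "copd": ("J440", "J441", "J449"),
    "other_respiratory": ("J22", "J069", "J459", "J841"),
    "circulatory": ("I219", "I500", "I639"),
    "other": ("A419", "N390", "K529", "E119"),
}
_NONSPECIFIC_ICD = ("R05", "R068", "R509")


class ConfigError(ValueError):
    """An invalid generator configuration value."""


@dataclass(frozen=True)
class ComponentProbs:
    """Emission probabilities for the supporting components of a coded event.

    ``p_symptom_each`` applies independently to each of the six symptom
    categories, so the probability of the >=2-distinct-categories flag is
    roughly ``15 * p**2`` for small ``p``. Antibiotic course lengths are
    drawn from ``durations``/``duration_probs`` (days).
    """

    p_symptom_each: float = 0.05
    p_cxr: float = 0.14
    p_antibiotics: float = 0.32
    p_culture_sent: float = 0.03
    p_culture_positive_given_sent: float = 0.06
    durations: tuple[int, ...] = (3, 5, 7, 10, 14, 21)
    duration_probs: tuple[float, ...] = (0.15, 0.15, 0.40, 0.10, 0.05, 0.15)

    def __post_init__(self) -> None:
        for name in (
            "p_symptom_each",
            "p_cxr",
            "p_antibiotics",
            "p_culture_sent",
            "p_culture_positive_given_sent",
        ):
            _check_prob(name, getattr(self, name))
        if len(self.durations) != len(self.duration_probs):
            raise ConfigError("durations and duration_probs differ in length")
        if abs(sum(self.duration_probs) - 1.0) > 1e-9:
            raise ConfigError("duration_probs must sum to 1")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one simulated study population."""

    seed: int = 0
    n_patients: int = 2000
    study_start: dt.date = dt.date(2015, 1, 1)
    study_end: dt.date = dt.date(2019, 12, 31)

    # true-episode process
    annual_pneumonia_rate: float = 0.04
    annual_hospital_pneumonia_rate: float = 0.028
    min_event_separation_days: int = 70

    # primary-care seeing/coding of a true episode
    p_gp_presents: float = 0.5
    p_gp_codes_pneumonia: float = 0.33
    p_same_day_entry: float = 0.8

    # hospitalisation and gold standard
    p_admit_given_event: float = 0.277
    p_hospital_confirms: float = 0.577
    nonpneumonia_mix: tuple[tuple[str, float], ...] = (
        ("copd", 0.320),
        ("other_respiratory", 0.129),
        ("circulatory", 0.123),
        ("other", 0.428),
    )
    p_secondary_pneumonia_code: float = 0.23  # any-position reclassification

    # GP recording of hospitalised pneumonia
    p_gp_records_admission: float = 0.341
    p_hosp_code_same_day: float = 0.595

    # component emission, by latent confirmation status
    components_confirmed: ComponentProbs = field(
        default_factory=lambda: ComponentProbs(
            p_cxr=0.16, p_antibiotics=0.29, p_culture_sent=0.033
        )
    )
    components_unconfirmed: ComponentProbs = field(
        default_factory=lambda: ComponentProbs(
            p_cxr=0.11, p_antibiotics=0.37, p_culture_sent=0.026
        )
    )

    # ineligibility fractions for flow testing (mutually exclusive)
    ineligible_age_fraction: float = 0.03
    unlinked_fraction: float = 0.04
    dead_before_study_fraction: float = 0.02

    # incidental realism
    p_death_during_study: float = 0.05
    p_transfer_out: float = 0.05
    noise_codes_per_patient: float = 0.5

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name in (
            "p_gp_presents",
            "p_gp_codes_pneumonia",
            "p_same_day_entry",
            "p_admit_given_event",
            "p_hospital_confirms",
            "p_secondary_pneumonia_code",
            "p_gp_records_admission",
            "p_hosp_code_same_day",
            "ineligible_age_fraction",
            "unlinked_fraction",
            "dead_before_study_fraction",
            "p_death_during_study",
            "p_transfer_out",
        ):
            _check_prob(name, getattr(self, name))
        for name in ("annual_pneumonia_rate", "annual_hospital_pneumonia_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        mix_total = sum(w for _, w in self.nonpneumonia_mix)
        if abs(mix_total - 1.0) > 1e-9:
            raise ConfigError("nonpneumonia_mix weights must sum to 1")
        excl = (
            self.ineligible_age_fraction
            + self.unlinked_fraction
            + self.dead_before_study_fraction
        )
        if excl > 1.0:
            raise ConfigError("ineligibility fractions must sum to <= 1")

    def to_yaml(self, path) -> None:
        data = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, dt.date):
                value = value.isoformat()
            elif isinstance(value, ComponentProbs):
                value = {
                    g.name: list(v) if isinstance(v := getattr(value, g.name), tuple) else v
                    for g in fields(value)
                }
            elif f.name == "nonpneumonia_mix":
                value = {k: w for k, w in value}
            data[f.name] = value
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("study_start", "study_end"):
            if isinstance(data.get(key), str):
                data[key] = dt.date.fromisoformat(data[key])
        for key in ("components_confirmed", "components_unconfirmed"):
            if isinstance(data.get(key), dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in data[key].items()
                }
                data[key] = ComponentProbs(**sub)
        if isinstance(data.get("nonpneumonia_mix"), dict):
            data["nonpneumonia_mix"] = tuple(data["nonpneumonia_mix"].items())
        return cls(**data)


def paper_like_config(seed: int = 0, n_patients: int = 2000) -> SyntheticConfig:
    """The default study-condition preset."""
    return SyntheticConfig(seed=seed, n_patients=n_patients)


def ppv_calibration_config(
    seed: int = 0,
    n_patients: int = 2000,
    p_hospital_confirms: float = 0.58,
) -> SyntheticConfig:
    """A stripped preset yielding roughly one linked event per patient.

    Presentation, coding, same-day entry and admission are made certain and
    component/recording emission switched off, so the run isolates the
    confirmation step for parameter-recovery (CI calibration) studies.
    """
    zero = ComponentProbs(
        p_symptom_each=0.0,
        p_cxr=0.0,
        p_antibiotics=0.0,
        p_culture_sent=0.0,
        p_culture_positive_given_sent=0.0,
    )
    return SyntheticConfig(
        seed=seed,
        n_patients=n_patients,
        annual_pneumonia_rate=0.24,
        annual_hospital_pneumonia_rate=0.0,
        p_gp_presents=1.0,
        p_gp_codes_pneumonia=1.0,
        p_same_day_entry=1.0,
        p_admit_given_event=1.0,
        p_hospital_confirms=p_hospital_confirms,
        p_gp_records_admission=0.0,
        components_confirmed=zero,
        components_unconfirmed=zero,
        ineligible_age_fraction=0.0,
        unlinked_fraction=0.0,
        dead_before_study_fraction=0.0,
        p_death_during_study=0.0,
        p_transfer_out=0.0,
        noise_codes_per_patient=0.0,
    )


# ---------------------------------------------------------------------------
# helpers


def _add_years(date: dt.date, years: int) -> dt.date:
    try:
        return date.replace(year=date.year + years)
    except ValueError:
        return dt.date(date.year + years, 3, 1)


def _uniform_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    return start + dt.timedelta(days=int(rng.integers(0, (end - start).days + 1)))


@dataclass
class GroundTruth:
    """Intended outcomes of one generated dataset.

    ``gp_events`` has one row per pneumonia-*coded* primary-care event with
    its intended filters, link and gold classification; ``hospital_events``
    has one row per hospital pneumonia spell with its intended recording
    flags. Both are exact by construction (events are spaced so pipeline
    stages cannot interact), so recounting them reproduces the pipeline's
    estimates identically.
    """

    config: SyntheticConfig
    patient_status: pd.DataFrame  # patient_id, status, in_cohort
    flow: dict[str, int]
    gp_events: pd.DataFrame
    hospital_events: pd.DataFrame


@dataclass(frozen=True)
class RealizedRates:
    """Exact recount of the generator's intended outcomes."""

    n_cohort: int
    flow: dict[str, int]
    events: int  # coded, same-day-entry, community-onset events
    admitted: int
    confirmed: int
    confirmed_any_position: int
    same_day_admitted: int
    same_day_confirmed: int
    same_day_confirmed_any_position: int
    breakdown: dict[str, int]  # admitted-but-unconfirmed, by category
    sens_n: int
    sens_k_code_only: int
    sens_k_code_plus_hosp: int

    @property
    def ppv(self) -> float | None:
        return self.confirmed / self.admitted if self.admitted else None

    @property
    def sensitivity(self) -> float | None:
        return self.sens_k_code_only / self.sens_n if self.sens_n else None


def realized_rates(truth: GroundTruth) -> RealizedRates:
    """Recount the intended outcomes; the oracle for pipeline equality tests."""
    ev = truth.gp_events
    eligible = ev[ev["same_day_entry"]]
    admitted = eligible[eligible["admitted"]]
    confirmed = admitted[admitted["gold_category"] == "pneumonia"]
    any_pos = admitted[
        (admitted["gold_category"] == "pneumonia")
        | admitted["any_position_pneumonia"]
    ]
    same_day = admitted[admitted["admit_offset"] == 0]
    unconfirmed = admitted[admitted["gold_category"] != "pneumonia"]
    breakdown = unconfirmed["gold_category"].value_counts().to_dict()

    hosp = truth.hospital_events
    in_window = hosp[hosp["in_window"]]
    return RealizedRates(
        n_cohort=int(truth.patient_status["in_cohort"].sum()),
        flow=dict(truth.flow),
        events=len(eligible),
        admitted=len(admitted),
        confirmed=len(confirmed),
        confirmed_any_position=len(any_pos),
        same_day_admitted=len(same_day),
        same_day_confirmed=int(
            (same_day["gold_category"] == "pneumonia").sum()
        ),
        same_day_confirmed_any_position=int(
            (
                (same_day["gold_category"] == "pneumonia")
                | same_day["any_position_pneumonia"]
            ).sum()
        ),
        breakdown=breakdown,
        sens_n=len(in_window),
        sens_k_code_only=int(in_window["recorded_code_only"].sum()),
        sens_k_code_plus_hosp=int(in_window["recorded_code_plus_hosp"].sum()),
    )


# ---------------------------------------------------------------------------
# generation


def generate(
    config: SyntheticConfig, bundle: CodelistBundle | None = None
) -> tuple[LinkedDataset, GroundTruth]:
    """Generate one linked dataset plus its ground truth, reproducibly.

    The same configuration (including seed) always yields byte-identical
    CSV exports.
    """
    bundle = bundle or default_bundle()
    rng = np.random.default_rng(config.seed)

    pneu_codes = sorted(bundle.pneumonia.codes)
    aecopd_codes = sorted(bundle.aecopd.codes)
    cxr_codes = sorted(bundle.chest_xray.codes)
    sent_codes = sorted(bundle.culture_sent.codes)
    pos_codes = sorted(bundle.culture_positive.codes)
    abx_codes = sorted(bundle.antibiotics.codes)
    hosp_codes = sorted(bundle.hospitalisation.codes)
    symptom_codes_by_cat = {
        cat: sorted(c for c, g in (bundle.symptoms.categories or {}).items() if g == cat)
        for cat in SYMPTOM_CATEGORIES
    }

    def pick(rng_, options):
        return options[int(rng_.integers(0, len(options)))]

    # --- patients -----------------------------------------------------------
    statuses = rng.choice(
        ["ok", "young", "unlinked", "dead_pre"],
        size=config.n_patients,
        p=[
            1
            - config.ineligible_age_fraction
            - config.unlinked_fraction
            - config.dead_before_study_fraction,
            config.ineligible_age_fraction,
            config.unlinked_fraction,
            config.dead_before_study_fraction,
        ],
    )
    patient_rows = []
    status_rows = []
    windows: dict[str, tuple[dt.date, dt.date]] = {}
    for i, status in enumerate(statuses):
        pid = f"P{i:06d}"
        sex = "male" if rng.random() < 0.55 else "female"
        reg_start = _uniform_date(rng, dt.date(1995, 1, 1), dt.date(2010, 12, 31))
        if status == "dead_pre":
            copd = _uniform_date(rng, dt.date(2005, 1, 1), dt.date(2008, 12, 31))
        else:
            copd = _uniform_date(rng, dt.date(2005, 1, 1), dt.date(2017, 12, 31))
        age = int(rng.integers(20, 34)) if status == "young" else int(rng.integers(40, 85))
        birth = _add_years(copd, -age) - dt.timedelta(days=int(rng.integers(0, 330)))
        death = None
        reg_end = None
        if status == "dead_pre":
            death = _uniform_date(rng, dt.date(2010, 1, 1), dt.date(2014, 12, 31))
        else:
            if rng.random() < config.p_death_during_study:
                death = _uniform_date(rng, dt.date(2016, 1, 1), dt.date(2019, 12, 31))
            if rng.random() < config.p_transfer_out:
                reg_end = _uniform_date(rng, dt.date(2016, 1, 1), dt.date(2019, 12, 31))
        collection = dt.date(2021, 5, 1)
        linkage = status != "unlinked"
        patient_rows.append(
            (pid, sex, birth, copd, reg_start, reg_end, death, collection, linkage)
        )

        in_cohort = False
        if status not in ("young", "unlinked"):
            start = max(config.study_start, _add_years(copd, 1), reg_start)
            end_candidates = [config.study_end, collection]
            if death is not None:
                end_candidates.append(death)
            if reg_end is not None:
                end_candidates.append(reg_end)
            end = min(end_candidates)
            if start <= end:
                in_cohort = True
                windows[pid] = (start, end)
        status_rows.append((pid, status, in_cohort))

    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id",
            "sex",
            "birth_date",
            "copd_diagnosis_date",
            "registration_start",
            "registration_end",
            "death_date",
            "last_collection_date",
            "linkage_eligible",
        ],
    )[PATIENT_COLUMNS]
    for col in PATIENT_COLUMNS:
        if col not in ("patient_id", "sex", "linkage_eligible"):
            patients[col] = pd.to_datetime(patients[col])
    status_frame = pd.DataFrame(status_rows, columns=["patient_id", "status", "in_cohort"])

    # flow truth (generator's own bookkeeping, stage order fixed)
    n = config.n_patients
    n_young = int((statuses == "young").sum())
    n_unlinked = int((statuses == "unlinked").sum())
    flow = {
        "all_patients": n,
        "copd_diagnosis": n,
        "age_35_plus_at_diagnosis": n - n_young,
        "registered_during_study": n - n_young,
        "linkage_eligible": n - n_young - n_unlinked,
        "followup_time_available": len(windows),
    }

    # --- episodes -----------------------------------------------------------
    obs_rows: list[tuple] = []
    rx_rows: list[tuple] = []
    spells: list[HospitalSpell] = []
    gp_event_rows: list[dict] = []
    hosp_event_rows: list[dict] = []
    spell_counter = 0

    total_rate = config.annual_pneumonia_rate + config.annual_hospital_pneumonia_rate
    p_hosp_only = (
        config.annual_hospital_pneumonia_rate / total_rate if total_rate > 0 else 0.0
    )
    mix_labels = [c for c, _ in config.nonpneumonia_mix]
    mix_weights = np.array([w for _, w in config.nonpneumonia_mix])

    def make_spell(pid, admission, gold_code, secondary):
        nonlocal spell_counter
        sid = f"S{spell_counter:07d}"
        spell_counter += 1
        los = min(int(rng.poisson(5)), 20)
        discharge = admission + dt.timedelta(days=los)
        n_eps = int(rng.integers(1, 4))
        starts = [admission]
        if n_eps > 1:
            extra = sorted(
                int(rng.integers(0, los + 1)) for _ in range(n_eps - 1)
            )
            starts += [admission + dt.timedelta(days=d) for d in extra]
        episodes = []
        for order in range(1, n_eps):
            episodes.append(
                HospitalEpisode(
                    episode_order=order,
                    episode_start=starts[order - 1],
                    diagnoses=(pick(rng, _NONSPECIFIC_ICD),),
                )
            )
        last_diagnoses = [gold_code] + list(secondary)
        episodes.append(
            HospitalEpisode(
                episode_order=n_eps,
                episode_start=starts[n_eps - 1],
                diagnoses=tuple(last_diagnoses),
            )
        )
        spells.append(
            HospitalSpell(
                spell_id=sid,
                patient_id=pid,
                admission_date=admission,
                discharge_date=discharge,
                episodes=tuple(episodes),
            )
        )
        return sid

    def emit_components(pid, index_date, probs: ComponentProbs):
        flags = {
            "symptoms": False,
            "cxr": False,
            "culture_sent": False,
            "culture_positive": False,
            "abx_any": False,
            "abx_5_14": False,
        }
        n_cats = 0
        for cat in SYMPTOM_CATEGORIES:
            if symptom_codes_by_cat[cat] and rng.random() < probs.p_symptom_each:
                n_cats += 1
                day = index_date + dt.timedelta(days=int(rng.integers(-7, 8)))
                obs_rows.append((pid, pick(rng, symptom_codes_by_cat[cat]), day, day))
        flags["symptoms"] = n_cats >= 2
        if rng.random() < probs.p_cxr:
            day = index_date + dt.timedelta(days=int(rng.integers(-7, 8)))
            obs_rows.append((pid, pick(rng, cxr_codes), day, day))
            flags["cxr"] = True
        if rng.random() < probs.p_culture_sent:
            day = index_date + dt.timedelta(days=int(rng.integers(-7, 8)))
            obs_rows.append((pid, pick(rng, sent_codes), day, day))
            flags["culture_sent"] = True
            if rng.random() < probs.p_culture_positive_given_sent:
                day2 = index_date + dt.timedelta(days=int(rng.integers(-7, 8)))
                obs_rows.append((pid, pick(rng, pos_codes), day2, day2))
                flags["culture_positive"] = True
        if rng.random() < probs.p_antibiotics:
            day = index_date + dt.timedelta(days=int(rng.integers(-7, 8)))
            duration = int(
                rng.choice(np.array(probs.durations), p=np.array(probs.duration_probs))
            )
            rx_rows.append((pid, pick(rng, abx_codes), day, duration))
            flags["abx_any"] = True
            flags["abx_5_14"] = 5 <= duration <= 14
        return flags

    def emit_recording(pid, admission, source, admit_offset):
        """Post-admission GP recording of a hospital pneumonia spell."""
        emitted = rng.random() < config.p_gp_records_admission
        with_hosp = False
        if emitted:
            rec_day = admission + dt.timedelta(days=int(rng.integers(0, 43)))
            entry = rec_day + dt.timedelta(days=int(rng.integers(1, 11)))
            obs_rows.append((pid, pick(rng, pneu_codes), rec_day, entry))
            if rng.random() < config.p_hosp_code_same_day:
                obs_rows.append((pid, pick(rng, hosp_codes), rec_day, entry))
                with_hosp = True
        recorded_code_only = emitted or (source == "gp_arm" and admit_offset == 0)
        return recorded_code_only, emitted and with_hosp

    for pid, (win_start, win_end) in windows.items():
        span = (win_end - win_start).days
        years = (span + 1) / 365.25
        n_episodes = int(rng.poisson(total_rate * years)) if total_rate > 0 else 0
        if n_episodes == 0:
            episode_days: list[int] = []
        else:
            draws = np.sort(rng.integers(0, span + 1, size=n_episodes))
            episode_days = []
            for d in draws.tolist():
                if not episode_days or d - episode_days[-1] >= config.min_event_separation_days:
                    episode_days.append(d)
        for day in episode_days:
            episode_date = win_start + dt.timedelta(days=int(day))
            if rng.random() < p_hosp_only:
                # hospital-only pneumonia admission, unseen in primary care
                gold_code = pick(rng, _ICD_BY_CATEGORY["pneumonia"])
                sid = make_spell(pid, episode_date, gold_code, ())
                rec, rec_hosp = emit_recording(pid, episode_date, "hospital_only", None)
                hosp_event_rows.append(
                    {
                        "spell_id": sid,
                        "patient_id": pid,
                        "admission_date": episode_date,
                        "source": "hospital_only",
                        "in_window": True,
                        "recorded_code_only": rec,
                        "recorded_code_plus_hosp": rec_hosp,
                    }
                )
                continue

            # primary-care arm
            if rng.random() >= config.p_gp_presents:
                continue
            if rng.random() >= config.p_gp_codes_pneumonia:
                # GP miscodes the episode as AECOPD/LRTI; invisible to the
                # pneumonia pipeline by codelist disjointness
                obs_rows.append((pid, pick(rng, aecopd_codes), episode_date, episode_date))
                continue

            same_day = rng.random() < config.p_same_day_entry
            entry = episode_date + dt.timedelta(
                days=0 if same_day else int(rng.integers(1, 31))
            )
            obs_rows.append((pid, pick(rng, pneu_codes), episode_date, entry))

            admitted = rng.random() < config.p_admit_given_event
            confirmed = rng.random() < config.p_hospital_confirms
            if confirmed:
                gold_category = "pneumonia"
                any_pos = True
            else:
                gold_category = mix_labels[
                    int(rng.choice(len(mix_labels), p=mix_weights))
                ]
                any_pos = rng.random() < config.p_secondary_pneumonia_code

            probs = (
                config.components_confirmed if confirmed else config.components_unconfirmed
            )
            flags = emit_components(pid, episode_date, probs)

            admit_offset = None
            sid = None
            admission = None
            if admitted:
                admit_offset = int(rng.integers(0, 8))
                admission = episode_date + dt.timedelta(days=admit_offset)
                gold_code = pick(rng, _ICD_BY_CATEGORY[gold_category])
                secondary: list[str] = []
                if gold_category != "pneumonia" and any_pos:
                    secondary.append(pick(rng, _ICD_BY_CATEGORY["pneumonia"]))
                elif rng.random() < 0.3:
                    secondary.append("I10")
                sid = make_spell(pid, admission, gold_code, tuple(secondary))
                if gold_category == "pneumonia":
                    rec, rec_hosp = emit_recording(pid, admission, "gp_arm", admit_offset)
                    hosp_event_rows.append(
                        {
                            "spell_id": sid,
                            "patient_id": pid,
                            "admission_date": admission,
                            "source": "gp_arm",
                            "in_window": admission <= win_end,
                            "recorded_code_only": rec,
                            "recorded_code_plus_hosp": rec_hosp,
                        }
                    )
            gp_event_rows.append(
                {
                    "patient_id": pid,
                    "index_date": episode_date,
                    "same_day_entry": same_day,
                    "admitted": admitted,
                    "admit_offset": admit_offset,
                    "spell_id": sid,
                    "gold_category": gold_category if admitted else None,
                    "any_position_pneumonia": bool(any_pos) if admitted else False,
                    **flags,
                }
            )

        # unrelated noise codes, matching no codelist
        n_noise = int(rng.poisson(config.noise_codes_per_patient))
        for _ in range(n_noise):
            day = win_start + dt.timedelta(days=int(rng.integers(0, span + 1)))
            obs_rows.append((pid, f"MISC{int(rng.integers(0, 50)):03d}", day, day))

    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    prescriptions = pd.DataFrame(rx_rows, columns=PRESCRIPTION_COLUMNS)
    if observations.empty:
        observations = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "code": pd.Series(dtype=str),
                "observation_date": pd.Series(dtype="datetime64[ns]"),
                "entry_date": pd.Series(dtype="datetime64[ns]"),
            }
        )
    else:
        observations["observation_date"] = pd.to_datetime(observations["observation_date"])
        observations["entry_date"] = pd.to_datetime(observations["entry_date"])
    if prescriptions.empty:
        prescriptions = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "product_code": pd.Series(dtype=str),
                "issue_date": pd.Series(dtype="datetime64[ns]"),
                "duration_days": pd.Series(dtype="Int64"),
            }
        )
    else:
        prescriptions["issue_date"] = pd.to_datetime(prescriptions["issue_date"])
        prescriptions["duration_days"] = prescriptions["duration_days"].astype("Int64")

    dataset = LinkedDataset(
        patients=patients,
        observations=observations,
        prescriptions=prescriptions,
        spells=spells,
    )
    gp_events = pd.DataFrame(
        gp_event_rows,
        columns=[
            "patient_id",
            "index_date",
            "same_day_entry",
            "admitted",
            "admit_offset",
            "spell_id",
            "gold_category",
            "any_position_pneumonia",
            "symptoms",
            "cxr",
            "culture_sent",
            "culture_positive",
            "abx_any",
            "abx_5_14",
        ],
    )
    hospital_events = pd.DataFrame(
        hosp_event_rows,
        columns=[
            "spell_id",
            "patient_id",
            "admission_date",
            "source",
            "in_window",
            "recorded_code_only",
            "recorded_code_plus_hosp",
        ],
    )
    truth = GroundTruth(
        config=config,
        patient_status=status_frame,
        flow=flow,
        gp_events=gp_events,
        hospital_events=hospital_events,
    )
    return dataset, truth
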