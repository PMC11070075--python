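"""Codelists for primary-care clinical/product codes and ICD-10 diagnoses.

A codelist is a curated set of codes defining a clinical concept (pneumonia,
chest X-ray referral, antibiotic product, ...). Primary-care lists are matched
exactly; ICD-10 lists are usually matched by prefix so that a three-character
family such as J18 captures J180, J181, J189 and dotted variants (J18.1).

Hospital primary diagnoses are classified into five mutually exclusive,
exhaustive categories used by the validation stage: pneumonia (J12-J18),
COPD (configurable, default J40-J44), any other chapter-J code
(other respiratory), chapter-I (circulatory), everything else (other).

The packaged fixture codelists under ``data/codelists`` are synthetic
structural stand-ins: real UK primary-care terminologies are licensed, so the
fixtures only reproduce the shape (columns, symptom categories, disjointness
between pneumonia and AECOPD/LRTI codes) that the pipeline relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CATEGORIES",
    "SYMPTOM_CATEGORIES",
    "PNEUMONIA_ICD10_PREFIXES",
    "Codelist",
    "CategoryMap",
    "CodelistBundle",
    "normalize_code",
    "load_codelist",
    "matches",
    "icd10_category",
    "default_bundle",
]

#: Gold-standard categories for a hospital primary diagnosis.
CATEGORIES = ("pneumonia", "copd", "other_respiratory", "circulatory", "other")

#: The six symptom groups whose distinct count feeds the >=2-symptom rule.
SYMPTOM_CATEGORIES = (
    "new_cough",
    "sputum",
    "breathlessness",
    "fever",
    "lethargy",
    "tachycardia",
)

#: ICD-10 three-character families defining pneumonia.
PNEUMONIA_ICD10_PREFIXES = ("J12", "J13", "J14", "J15", "J16", "J17", "J18")

DEFAULT_COPD_PREFIXES = ("J40", "J41", "J42", "J43", "J44")


def normalize_code(code: str) -> str:
    """Uppercase, strip whitespace and embedded dots (ICD-10 J18.1 -> J181)."""
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class Codelist:
    """A named set of codes with a matching mode.

    ``categories`` optionally maps each code to a symptom category; it is only
    populated for symptom lists, where the algorithm engine needs to count
    distinct categories rather than code occurrences.
    """

    name: str
    domain: str  # clinical | prescription | icd10
    codes: frozenset[str]
    match_mode: str = "exact"  # exact | prefix
    categories: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"codelist {self.name!r} is empty")
        if self.domain not in ("clinical", "prescription", "icd10"):
            raise ValueError(f"unknown codelist domain {self.domain!r}")
        if self.match_mode not in ("exact", "prefix"):
            raise ValueError(f"unknown match mode {self.match_mode!r}")

    def matches(self, code: str) -> bool:
        norm = normalize_code(code)
        if self.match_mode == "exact":
            return norm in self.codes
        return norm.startswith(tuple(self.codes))

    def category_of(self, code: str) -> str | None:
        if self.categories is None:
            return None
        return self.categories.get(normalize_code(code))


def matches(codelist: Codelist, code: str) -> bool:
    """Functional alias for :meth:`Codelist.matches`."""
    return codelist.matches(code)


def load_codelist(
    path: str | Path,
    name: str,
    domain: str = "clinical",
    match_mode: str = "exact",
) -> Codelist:
    """Read a codelist CSV (columns ``code``, ``term``, optional ``category``).

    Codes are normalised on load; duplicates surviving normalisation are
    dropped with a warning so curation slips are visible but not fatal.
    """
    frame = pd.read_csv(path, dtype=str)
    if "code" not in frame.columns:
        raise ValueError(f"codelist file {path} lacks required column 'code'")
    if frame.empty:
        raise ValueError(f"codelist file {path} has no rows")
    normed = frame["code"].map(normalize_code)
    if normed.duplicated().any():
        dups = sorted(normed[normed.duplicated()].unique())
        warnings.warn(
            f"codelist {name!r}: duplicate codes after normalisation: {dups}",
            stacklevel=2,
        )
    categories = None
    if "category" in frame.columns:
        categories = dict(zip(normed, frame["category"].str.strip()))
    return Codelist(
        name=name,
        domain=domain,
        codes=frozenset(normed),
        match_mode=match_mode,
        categories=categories,
    )


@dataclass(frozen=True)
class CategoryMap:
    """Ordered prefix rules classifying an ICD-10 code into one category.

    The first matching rule wins: pneumonia families, then the configured COPD
    families, then any other chapter-J code, then chapter I, then ``other``.
    By construction the map is total and the categories mutually exclusive.
    """

    copd_prefixes: tuple[str, ...] = DEFAULT_COPD_PREFIXES
    pneumonia_prefixes: tuple[str, ...] = PNEUMONIA_ICD10_PREFIXES

    def category(self, code: str) -> str:
        norm = normalize_code(code)
        if norm.startswith(self.pneumonia_prefixes):
            return "pneumonia"
        if norm.startswith(self.copd_prefixes):
            return "copd"
        if norm.startswith("J"):
            return "other_respiratory"
        if norm.startswith("I"):
            return "circulatory"
        return "other"

    def is_pneumonia(self, code: str) -> bool:
        return normalize_code(code).startswith(self.pneumonia_prefixes)


def icd10_category(code: str, category_map: CategoryMap | None = None) -> str:
    """Classify an ICD-10 code under the (default) category map."""
    return (category_map or CategoryMap()).category(code)


@dataclass(frozen=True)
class CodelistBundle:
    """All codelists one validation run needs, keyed by concept."""

    pneumonia: Codelist
    symptoms: Codelist
    chest_xray: Codelist
    culture_sent: Codelist
    culture_positive: Codelist
    antibiotics: Codelist
    hospitalisation: Codelist
    aecopd: Codelist
    pneumonia_icd10: Codelist = field(
        default=Codelist(
            name="pneumonia_icd10",
            domain="icd10",
            codes=frozenset(PNEUMONIA_ICD10_PREFIXES),
            match_mode="prefix",
        )
    )


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("pneumolink").joinpath("data/codelists", filename)))


def default_bundle() -> CodelistBundle:
    """Load the packaged synthetic fixture codelists."""
    return CodelistBundle(
        pneumonia=load_codelist(
            _fixture_path("synthetic_pneumonia_clinical.csv"), "pneumonia", "clinical"
        ),
        symptoms=load_codelist(
            _fixture_path("synthetic_symptoms.csv"), "symptoms", "clinical"
        ),
        chest_xray=load_codelist(
            _fixture_path("synthetic_chest_xray.csv"), "chest_xray", "clinical"
        ),
        culture_sent=load_codelist(
            _fixture_path("synthetic_culture_sent.csv"), "culture_sent", "clinical"
        ),
        culture_positive=load_codelist(
            _fixture_path("synthetic_culture_positive.csv"),
            "culture_positive",
            "clinical",
        ),
        antibiotics=load_codelist(
            _fixture_path("synthetic_antibiotics.csv"), "antibiotics", "prescription"
        ),
        hospitalisation=load_codelist(
            _fixture_path("synthetic_hospitalisation.csv"),
            "hospitalisation",
            "clinical",
        ),
        aecopd=load_codelist(
            _fixture_path("synthetic_aecopd_lrti.csv"), "aecopd", "clinical"
        ),
    )
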