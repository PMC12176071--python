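"""Configuration models: the synthetic-population generator and the ETL rule-sets.

Two shipped ETL rule-sets are provided (``ahon_style`` and ``nivel_style``),
capturing the contrasts between a registry that takes the EHR content largely
as recorded (enrollment-date quarters, postal-code/birth-year/sex pseudonyms,
all claims codes, GP-recorded episodes) and one that processes more heavily
(capitation-derived quarters with gap imputation, national-identifier
pseudonyms, a study-specific claims code selection, 8-day prescription
deduplication including pharmacy feedback, and an episode construct).
"""

from __future__ import annotations

import datetime as dt
from importlib import resources
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: claims codes for regular consultations and home visits; identical in both
#: shipped rule-sets (12001 consult >20min, 12002 visit <20min, 12003 visit
#: >20min, 12010 consult <5min, 12011 consult 5-20min).
REGULAR_CONSULT_CODES: frozenset[str] = frozenset(
    {"12001", "12002", "12003", "12010", "12011"}
)


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return value


class IcpcRate(BaseModel):
    """Annual probability that a patient carries / presents a diagnosis.

    For chronic conditions the probability is the population prevalence of
    carrying the condition (present every year once acquired); for acute
    conditions it is the per-year probability of at least one illness episode.
    """

    model_config = ConfigDict(frozen=True)

    annual_prob: float
    chronic: bool = False

    @field_validator("annual_prob")
    @classmethod
    def _prob(cls, v: float) -> float:
        return _check_prob("annual_prob", v)


class AtcRate(BaseModel):
    """One drug prescribed for a condition, at a mean rate per episode-year."""

    model_config = ConfigDict(frozen=True)

    atc: str
    per_episode_year: float = Field(gt=0)

    @field_validator("atc")
    @classmethod
    def _atc(cls, v: str) -> str:
        if not (3 <= len(v) <= 7 and v.isalnum()):
            raise ValueError(f"ATC code must be 3-7 alphanumeric characters, got {v!r}")
        return v


def _default_icpc_prevalence() -> dict[str, IcpcRate]:
    # Chronic panel: diabetes (T90), hypertension (K86), asthma (R96).
    # Acute panel: urinary tract infection (U71), cough (R05), low back (L03).
    # T90/U71/R05 rates sit in the 5-7% band typical of Dutch general practice.
    return {
        "T90": IcpcRate(annual_prob=0.065, chronic=True),
        "K86": IcpcRate(annual_prob=0.090, chronic=True),
        "R96": IcpcRate(annual_prob=0.030, chronic=True),
        "U71": IcpcRate(annual_prob=0.065, chronic=False),
        "R05": IcpcRate(annual_prob=0.055, chronic=False),
        "L03": IcpcRate(annual_prob=0.040, chronic=False),
    }


def _default_atc_prescribing() -> dict[str, list[AtcRate]]:
    return {
        "T90": [
            AtcRate(atc="A10BA02", per_episode_year=4.0),  # metformin
            AtcRate(atc="A10AB05", per_episode_year=1.5),  # insulin aspart
        ],
        "K86": [AtcRate(atc="C09AA02", per_episode_year=3.0)],  # enalapril
        "R96": [AtcRate(atc="R03AC02", per_episode_year=2.5)],  # salbutamol
        "U71": [
            AtcRate(atc="J01XE01", per_episode_year=1.6),  # nitrofurantoin
            AtcRate(atc="J01MA02", per_episode_year=0.4),  # ciprofloxacin
        ],
        "R05": [
            AtcRate(atc="R05DA04", per_episode_year=0.5),  # codeine
            AtcRate(atc="R06AE07", per_episode_year=0.3),  # cetirizine
        ],
        "L03": [AtcRate(atc="M01AE01", per_episode_year=0.8)],  # ibuprofen
    }


def _default_claims_catalog() -> list[tuple[str, float]]:
    # Consultation/visit codes carry slightly more than half the claim volume;
    # the remainder are other invoiced GP activities (interventions, support
    # staff actions, administrative codes).
    return [
        ("12001", 0.12),
        ("12002", 0.04),
        ("12003", 0.03),
        ("12010", 0.05),
        ("12011", 0.30),
        ("13012", 0.10),
        ("13034", 0.08),
        ("12004", 0.08),
        ("13015", 0.06),
        ("12111", 0.07),
        ("13500", 0.07),
    ]


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic general-practice population and its events.

    Defaults emulate the study conditions: 8 practices of roughly 5,500-6,000
    enrolled patients, age bands 0-4 / 5-17 / 18-64 / 65+ at about
    4.7/15.5/58/22 percent, a near-even sex split, an event window covering
    the 2019 analysis year plus the two prior years, and diagnosis-group
    prevalences in the 5-7% range.
    """

    model_config = ConfigDict(frozen=True)

    n_practices: int = Field(default=8, ge=1)
    patients_per_practice_mean: float = Field(default=5750.0, gt=0)
    patients_per_practice_sd: float = Field(default=650.0, ge=0)
    age_band_weights: tuple[float, float, float, float] = (0.047, 0.155, 0.579, 0.219)
    female_fraction: float = 0.506
    window_start: dt.date = dt.date(2017, 1, 1)
    window_end: dt.date = dt.date(2019, 12, 31)
    analysis_year: int = 2019
    ssn_missing_prob: float = 0.05
    pc3_pool: int = Field(default=800, ge=1, le=800)  # 3-digit prefixes 100..899
    mid_year_enrollment_prob: float = 0.05
    capitation_gap_prob: float = 0.02
    contact_rate: float = Field(default=8.5, gt=0)  # claims events per patient-year
    icpc_prevalence: dict[str, IcpcRate] = Field(default_factory=_default_icpc_prevalence)
    atc_prescribing: dict[str, list[AtcRate]] = Field(default_factory=_default_atc_prescribing)
    pharmacy_source_fraction: float = 0.05
    near_duplicate_prob: float = 0.10
    claims_code_catalog: list[tuple[str, float]] = Field(default_factory=_default_claims_catalog)
    seed: int = 20190101

    @field_validator(
        "female_fraction",
        "ssn_missing_prob",
        "mid_year_enrollment_prob",
        "capitation_gap_prob",
        "pharmacy_source_fraction",
        "near_duplicate_prob",
    )
    @classmethod
    def _probs(cls, v: float, info) -> float:
        return _check_prob(info.field_name, v)

    @field_validator("age_band_weights")
    @classmethod
    def _weights(cls, v):
        for w in v:
            _check_prob("age_band_weights", w)
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"age_band_weights must sum to 1, got {sum(v)}")
        return v

    @field_validator("icpc_prevalence")
    @classmethod
    def _icpc(cls, v):
        for code in v:
            if not (len(code) == 3 and code[0].isalpha() and code[1:].isdigit()):
                raise ValueError(f"icpc_prevalence: ICPC code must be letter+2 digits, got {code!r}")
        return v

    @field_validator("claims_code_catalog")
    @classmethod
    def _catalog(cls, v):
        codes = {c for c, _ in v}
        missing = REGULAR_CONSULT_CODES - codes
        if missing:
            raise ValueError(f"claims_code_catalog must include consult codes {sorted(missing)}")
        for code, w in v:
            if not (len(code) == 5 and code.isdigit()):
                raise ValueError(f"claims_code_catalog: code must be 5 digits, got {code!r}")
            if w < 0:
                raise ValueError(f"claims_code_catalog: weight for {code} must be >= 0")
        if sum(w for _, w in v) <= 0:
            raise ValueError("claims_code_catalog weights must sum to > 0")
        return v

    @model_validator(mode="after")
    def _window(self):
        if self.window_end < self.window_start:
            raise ValueError("window_end before window_start")
        if self.window_start > dt.date(self.analysis_year - 2, 1, 1):
            raise ValueError("window_start must cover at least 2 years before analysis_year")
        if self.window_end < dt.date(self.analysis_year, 12, 31):
            raise ValueError("window_end must cover the full analysis_year")
        return self


CodeFilter = Union[Literal["all"], list[str]]


class PipelineConfig(BaseModel):
    """One ETL rule-set: every database-zone processing choice as a toggle."""

    model_config = ConfigDict(frozen=True)

    name: str
    quarter_rule: Literal["from_enrollment_date", "from_capitation_imputed"]
    pseudonym_scheme: Literal["pc3_birthyear_sex", "ssn"]
    claims_filter: CodeFilter = "all"
    #: claims code set applied before contact derivation; None = same as claims_filter
    contact_codes_filter: CodeFilter | None = None
    dedup_window_days: int = Field(default=0, ge=0)  # 0 = only same-day duplicates
    include_pharmacy_prescriptions: bool = False
    episode_mode: Literal["recorded", "construct"] = "recorded"
    lookback_years: int = Field(default=2, ge=0)
    contact_free_interval_days: dict[str, int] = Field(default_factory=dict)
    default_contact_free_interval_days: int = Field(default=90, gt=0)
    chronic_codes: frozenset[str] = frozenset({"T90"})
    #: collapse patients whose pseudonyms collide into one record (union of
    #: events); if False, ambiguous patients are dropped instead
    collapse_pseudonym_collisions: bool = True

    @field_validator("contact_free_interval_days")
    @classmethod
    def _intervals(cls, v):
        for code, days in v.items():
            if days <= 0:
                raise ValueError(f"contact_free_interval_days[{code}] must be > 0")
        return v

    def interval_for(self, icpc: str) -> int:
        return self.contact_free_interval_days.get(icpc, self.default_contact_free_interval_days)

    def effective_contact_filter(self) -> CodeFilter:
        return self.claims_filter if self.contact_codes_filter is None else self.contact_codes_filter

    # -- serialisation --------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        data["chronic_codes"] = sorted(self.chronic_codes)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_shipped_config(name: Literal["ahon_style", "nivel_style"]) -> PipelineConfig:
    """Load one of the two shipped ETL rule-sets from package data."""
    ref = resources.files("ehrdiv.configs").joinpath(f"{name}.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return PipelineConfig.model_validate(yaml.safe_load(fh))


def ahon_style() -> PipelineConfig:
    """Registry-style rule-set: minimal processing of the EHR content."""
    return load_shipped_config("ahon_style")


def nivel_style() -> PipelineConfig:
    """Heavily-processed rule-set: capitation quarters, claims selection,
    8-day prescription dedup with pharmacy feedback, episode construct."""
    return load_shipped_config("nivel_style")
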