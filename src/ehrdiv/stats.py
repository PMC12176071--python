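"""The three-step comparison of two processed datasets.

Step 1 — demographics of each full dataset (patients, patient years, patients
per practice, age bands, sex).  Step 2 — per-patient similarity indicators on
the concordant patients (contacts, regular consultations and visits,
prescriptions, episodes), compared with paired *t* tests and confidence
intervals of the mean difference.  Step 3 — three diagnosis groups (diabetes
T90, urinary tract infection U71, cough R05): prevalence per 1000 patient
years, prescriptions per 1000 patient years from diagnosis-specific ATC
prefix sets, and regular consultations and visits per 1000 patient years,
each compared with the two-proportion standardized difference

    SD = (p_a - p_b) / sqrt[(p_a(1-p_a) + p_b(1-p_b)) / 2]

with |SD| > 0.2 flagged as significant and |SD| of 0.2 / 0.5 / 0.8 banded as
small / medium / large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import REGULAR_CONSULT_CODES
from .containers import ProcessedDataset
from .etl import AGE_BAND_LABELS
from .linkage import ConcordantLink, restrict_to_concordant

SD_THRESHOLD = 0.2
INDICATORS = ("contacts", "regular_consults", "prescriptions", "episodes")


@dataclass(frozen=True)
class DiagnosisGroupSpec:
    """A diagnosis group: its ICPC code and the ATC prefixes of its drugs."""

    label: str
    icpc_code: str
    atc_prefixes: frozenset[str]


#: Shipped diagnosis groups: a chronic condition, an acute infection, and a
#: high-prevalence symptom, with their reference drug groups.
DEFAULT_DIAGNOSIS_GROUPS: tuple[DiagnosisGroupSpec, ...] = (
    DiagnosisGroupSpec("Diabetes mellitus", "T90", frozenset({"A10A", "A10B"})),
    DiagnosisGroupSpec(
        "Urinary tract infection",
        "U71",
        frozenset({"G03C", "J01C", "J01D", "J01E", "J01G", "J01M", "J01X"}),
    ),
    DiagnosisGroupSpec("Cough", "R05", frozenset({"R05C", "R05D", "R05X", "R06A"})),
)


def patient_years_total(ds: ProcessedDataset) -> float:
    """Total person-time: sum over patients of 0.25 x registered quarters."""
    return float(ds.patients["patient_years"].sum())


def demographics_table(ds: ProcessedDataset) -> pd.DataFrame:
    """Step-1 demographics: counts and percentages in long form."""
    p = ds.patients
    n = len(p)
    rows = [
        ("patients", "n", float(n), math.nan),
        ("patient_years", "total", patient_years_total(ds), math.nan),
        ("patient_years_per_patient", "mean", patient_years_total(ds) / n if n else math.nan, math.nan),
    ]
    per_practice = p.groupby("practice_id").size()
    rows.append(
        (
            "patients_per_practice",
            "mean (sd)",
            float(per_practice.mean()) if n else math.nan,
            float(per_practice.std(ddof=1)) if len(per_practice) > 1 else math.nan,
        )
    )
    for band in AGE_BAND_LABELS:
        cnt = int((p["age_band"] == band).sum())
        rows.append((f"age_{band}", "n (%)", float(cnt), round(100.0 * cnt / n, 1) if n else math.nan))
    for s in ("male", "female"):
        cnt = int((p["sex"] == s).sum())
        rows.append((f"sex_{s}", "n (%)", float(cnt), round(100.0 * cnt / n, 1) if n else math.nan))
    return pd.DataFrame(rows, columns=["characteristic", "statistic", "value", "value2"])


def per_patient_indicator(
    ds: ProcessedDataset,
    indicator: str,
    code_set: frozenset[str] = REGULAR_CONSULT_CODES,
) -> pd.Series:
    """One count per patient (0 for patients without events), indexed by pseudo_id.

    ``contacts``: contact rows; ``regular_consults``: distinct (patient, day)
    among claims rows whose code is in *code_set*; ``prescriptions``:
    prescription rows; ``episodes``: episodes overlapping the analysis year.
    """
    index = pd.Index(ds.patients["pseudo_id"], name="pseudo_id")
    if indicator == "contacts":
        counts = ds.contacts.groupby("pseudo_id").size()
    elif indicator == "regular_consults":
        c = ds.claims[ds.claims["claims_code"].isin(code_set)]
        counts = c.drop_duplicates(["pseudo_id", "date"]).groupby("pseudo_id").size()
    elif indicator == "prescriptions":
        counts = ds.prescriptions.groupby("pseudo_id").size()
    elif indicator == "episodes":
        counts = ds.episodes.groupby("pseudo_id").size()
    else:
        raise ValueError(f"unknown indicator {indicator!r}")
    return counts.reindex(index, fill_value=0).astype(np.int64)


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired *t* test on per-patient indicator differences (a - b)."""

    indicator: str
    n: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_diff: float
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    conf_level: float
    degenerate: bool = False  # zero-variance differences (e.g. identical inputs)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def paired_t_test(x, y, conf_level: float = 0.95, indicator: str = "") -> PairedTestResult:
    """Paired *t* test of ``d = x - y`` with a two-sided CI of the mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        # no variability in the differences: flag rather than divide by zero
        return PairedTestResult(
            indicator=indicator,
            n=n,
            mean_a=float(x.mean()),
            mean_b=float(y.mean()),
            sd_a=float(x.std(ddof=1)),
            sd_b=float(y.std(ddof=1)),
            mean_diff=mean_d,
            t_statistic=0.0 if mean_d == 0.0 else math.inf * math.copysign(1, mean_d),
            p_value=1.0 if mean_d == 0.0 else 0.0,
            ci_low=mean_d,
            ci_high=mean_d,
            conf_level=conf_level,
            degenerate=True,
        )
    se = sd_d / math.sqrt(n)
    t = mean_d / se
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    tcrit = sps.t.ppf(0.5 * (1 + conf_level), df=n - 1)
    return PairedTestResult(
        indicator=indicator,
        n=n,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        sd_a=float(x.std(ddof=1)),
        sd_b=float(y.std(ddof=1)),
        mean_diff=mean_d,
        t_statistic=float(t),
        p_value=float(p),
        ci_low=mean_d - tcrit * se,
        ci_high=mean_d + tcrit * se,
        conf_level=conf_level,
    )


def prevalence_rate(n_cases: int, patient_years: float) -> float:
    """Distinct diseased patients per 1000 patient years (max 1 case/patient)."""
    if patient_years <= 0:
        raise ValueError("patient_years must be > 0")
    return 1000.0 * n_cases / patient_years


def rate_per_1000py(n_events: int, patient_years: float) -> float:
    """Events (prescriptions, consultations, ...) per 1000 patient years."""
    if patient_years <= 0:
        raise ValueError("patient_years must be > 0")
    return 1000.0 * n_events / patient_years


@dataclass(frozen=True)
class SdResult:
    """A two-proportion standardized difference and its interpretation."""

    sd_value: float
    magnitude: str  # negligible | small | medium | large
    significant: bool

    def to_dict(self) -> dict:
        return {"sd_value": self.sd_value, "magnitude": self.magnitude, "significant": self.significant}


def standardized_difference(p_a: float, p_b: float, threshold: float = SD_THRESHOLD) -> SdResult:
    """Standardized difference of two proportions; |SD| > *threshold* is significant.

    Antisymmetric in its arguments.  Undefined (raises) when both proportions
    are degenerate (each exactly 0 or 1), since the pooled variance vanishes.
    """
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    var = (p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0
    if var == 0.0:
        if p_a == p_b:
            sd = 0.0
        else:
            raise ValueError("standardized difference undefined: both proportions degenerate")
    else:
        sd = (p_a - p_b) / math.sqrt(var)
    a = abs(sd)
    if a < 0.2:
        magnitude = "negligible"
    elif a < 0.5:
        magnitude = "small"
    elif a < 0.8:
        magnitude = "medium"
    else:
        magnitude = "large"
    return SdResult(sd_value=sd, magnitude=magnitude, significant=a > threshold)


@dataclass(frozen=True)
class GroupIndicators:
    """Step-3 indicators for one diagnosis group in one dataset."""

    label: str
    icpc_code: str
    n_cases: int
    group_patient_years: float
    patient_years_per_case: float
    prevalence_per_1000py: float
    prescriptions_per_1000py: float
    consults_per_1000py: float
    n_prescriptions: int
    n_consults: int
    denominator: str  # "total_py" | "group_py"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def diagnosis_group_report(
    ds: ProcessedDataset,
    spec: DiagnosisGroupSpec,
    consult_codes: frozenset[str] = REGULAR_CONSULT_CODES,
    denominator: str = "total_py",
) -> GroupIndicators:
    """Prevalence and utilisation indicators for one diagnosis group.

    A case is a patient with at least one claims row carrying the group's
    ICPC code in the analysis year (counted once).  Prescriptions count rows
    of case patients whose ATC code starts with any group prefix; consults
    count the case patients' regular consultations and visits.  Rates divide
    by the total population patient years (default) or the group's own.
    """
    case_ids = set(ds.claims.loc[ds.claims["icpc"] == spec.icpc_code, "pseudo_id"])
    cases = ds.patients[ds.patients["pseudo_id"].isin(case_ids)]
    n_cases = len(cases)
    group_py = float(cases["patient_years"].sum())
    total_py = patient_years_total(ds)
    denom = total_py if denominator == "total_py" else group_py

    rx = ds.prescriptions[ds.prescriptions["pseudo_id"].isin(case_ids)]
    prefixes = tuple(sorted(spec.atc_prefixes))
    n_rx = int(rx["atc"].str.startswith(prefixes).sum()) if len(rx) else 0

    claims = ds.claims[
        ds.claims["pseudo_id"].isin(case_ids) & ds.claims["claims_code"].isin(consult_codes)
    ]
    n_consults = int(len(claims.drop_duplicates(["pseudo_id", "date"])))

    return GroupIndicators(
        label=spec.label,
        icpc_code=spec.icpc_code,
        n_cases=n_cases,
        group_patient_years=group_py,
        patient_years_per_case=group_py / n_cases if n_cases else math.nan,
        prevalence_per_1000py=prevalence_rate(n_cases, total_py) if total_py > 0 else math.nan,
        prescriptions_per_1000py=rate_per_1000py(n_rx, denom) if denom > 0 else math.nan,
        consults_per_1000py=rate_per_1000py(n_consults, denom) if denom > 0 else math.nan,
        n_prescriptions=n_rx,
        n_consults=n_consults,
        denominator=denominator,
    )


@dataclass
class ComparisonReport:
    """Tables 1-3-shaped outcome of comparing two processed datasets."""

    name_a: str
    name_b: str
    analysis_year: int
    conf_level: float
    link: dict
    demographics_a: pd.DataFrame
    demographics_b: pd.DataFrame
    paired: dict[str, PairedTestResult]
    step2_skipped: str | None
    groups: list[dict]  # per group: {"a": GroupIndicators, "b": ..., "sd": {...}}
    notes: list[str] = field(default_factory=list)


def _rate_sds(a: GroupIndicators, b: GroupIndicators) -> dict[str, dict | None]:
    """Eq.-style SDs on the three group indicators, rates read as proportions
    per patient-year (rate/1000).  None where the formula is undefined."""
    out: dict[str, dict | None] = {}
    for key, ra, rb in (
        ("prevalence", a.prevalence_per_1000py, b.prevalence_per_1000py),
        ("prescriptions", a.prescriptions_per_1000py, b.prescriptions_per_1000py),
        ("consults", a.consults_per_1000py, b.consults_per_1000py),
    ):
        pa, pb = ra / 1000.0, rb / 1000.0
        if not (0.0 <= pa <= 1.0 and 0.0 <= pb <= 1.0) or math.isnan(pa) or math.isnan(pb):
            out[key] = None
            continue
        try:
            out[key] = standardized_difference(pa, pb).to_dict()
        except ValueError:
            out[key] = None
    return out


def compare_datasets(
    ds_a: ProcessedDataset,
    ds_b: ProcessedDataset,
    link: ConcordantLink,
    specs: tuple[DiagnosisGroupSpec, ...] = DEFAULT_DIAGNOSIS_GROUPS,
    conf_level: float = 0.95,
    consult_codes: frozenset[str] = REGULAR_CONSULT_CODES,
    denominator: str = "total_py",
) -> ComparisonReport:
    """Run the three comparison steps; sign convention is dataset A minus B."""
    demo_a = demographics_table(ds_a)
    demo_b = demographics_table(ds_b)

    paired: dict[str, PairedTestResult] = {}
    step2_skipped = None
    if link.n_shared == 0:
        step2_skipped = "no concordant patients: step 2 skipped"
    else:
        ca = restrict_to_concordant(ds_a, link)
        cb = restrict_to_concordant(ds_b, link)
        # align per-patient vectors on the shared platform identifier
        map_a = ca.patients.set_index("pseudo_id")["platform_id"]
        map_b = cb.patients.set_index("pseudo_id")["platform_id"]
        for ind in INDICATORS:
            va = per_patient_indicator(ca, ind, consult_codes)
            vb = per_patient_indicator(cb, ind, consult_codes)
            va = va.rename(index=map_a).sort_index()
            vb = vb.rename(index=map_b).sort_index()
            paired[ind] = paired_t_test(va.to_numpy(), vb.to_numpy(), conf_level, indicator=ind)

    groups = []
    for spec in specs:
        gi_a = diagnosis_group_report(ds_a, spec, consult_codes, denominator)
        gi_b = diagnosis_group_report(ds_b, spec, consult_codes, denominator)
        groups.append({"a": gi_a, "b": gi_b, "sd": _rate_sds(gi_a, gi_b)})

    return ComparisonReport(
        name_a=ds_a.name,
        name_b=ds_b.name,
        analysis_year=ds_a.analysis_year,
        conf_level=conf_level,
        link=link.to_dict(),
        demographics_a=demo_a,
        demographics_b=demo_b,
        paired=paired,
        step2_skipped=step2_skipped,
        groups=groups,
        notes=["sign convention: dataset A minus dataset B", "no multiple-testing correction applied"],
    )
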