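import pandas as pd
import pytest
from hypothesis import settings

import ehrdiv as ed
from ehrdiv.containers import RAW_SCHEMAS, coerce_table, empty_table

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("suite")


def make_extract(
    patients=(),
    journal_contacts=(),
    claims_events=(),
    episodes=(),
    prescriptions=(),
    capitation=(),
) -> ed.RawEhrExtract:
    """Build a raw extract from row dicts, filling schema defaults."""
    defaults = {
        "patients": {
            "ssn": "",
            "postal_code": "1234AB",
            "birth_year": 1980,
            "sex": "female",
            "practice_id": "GP01",
            "enrollment_date": "2017-01-01",
            "disenrollment_date": "",
        },
        "journal_contacts": {"episode_key": ""},
        "claims_events": {"icpc": "", "claims_code": "12011"},
        "episodes": {"end_date": "", "chronic": False},
        "prescriptions": {"source": "gp", "icpc_indication": ""},
        "capitation": {},
    }
    tables = {}
    for name, rows in (
        ("patients", patients),
        ("journal_contacts", journal_contacts),
        ("claims_events", claims_events),
        ("episodes", episodes),
        ("prescriptions", prescriptions),
        ("capitation", capitation),
    ):
        rows = [dict(defaults[name], **r) for r in rows]
        tables[name] = (
            coerce_table(pd.DataFrame(rows), RAW_SCHEMAS[name], name)
            if rows
            else empty_table(RAW_SCHEMAS[name])
        )
    return ed.RawEhrExtract(**tables)


@pytest.fixture(scope="session")
def small_cfg() -> ed.GeneratorConfig:
    return ed.GeneratorConfig(
        n_practices=2,
        patients_per_practice_mean=200,
        patients_per_practice_sd=20,
        seed=20190101,
    )


@pytest.fixture(scope="session")
def small_extract(small_cfg) -> ed.RawEhrExtract:
    return ed.generate_extract(small_cfg)


@pytest.fixture(scope="session")
def big_extract() -> ed.RawEhrExtract:
    # ~10,000 patients: large enough for 3-standard-error shape checks
    cfg = ed.GeneratorConfig(
        n_practices=2,
        patients_per_practice_mean=5000,
        patients_per_practice_sd=100,
        seed=42,
    )
    return ed.generate_extract(cfg)


@pytest.fixture(scope="session")
def processed_pair(small_extract):
    """(dataset_a, dataset_b, registry, link) from the two shipped rule-sets."""
    registry = ed.build_registry(small_extract)
    a = ed.run_pipeline(small_extract, ed.ahon_style(), 2019)
    b = ed.run_pipeline(small_extract, ed.nivel_style(), 2019)
    a = ed.attach_platform_ids(a, "pc3_birthyear_sex", registry)
    b = ed.attach_platform_ids(b, "ssn", registry)
    link = ed.concordant(a, b)
    return a, b, registry, link
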