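"""Database-zone processing rules, composable into two ETL pipelines.

Each rule is a standalone function; :func:`run_pipeline` composes them in a
fixed order driven by a :class:`~ehrdiv.config.PipelineConfig`:

1. pseudonymization (patients without the required source field are dropped;
   pseudonym collisions are collapsed into one patient, keeping the union of
   their events — or dropped, if configured);
2. registration quarters (from the enrollment date with the "full quarters
   only, mid-quarter enrollment starts next quarter" rule, or from quarterly
   capitation-fee records with gaps between first and last record imputed);
3. exclusion of patients with no registered quarter in the analysis year;
4. prescription source filtering (pharmacy feedback dropped unless included)
   and window-based deduplication of double records;
5. insurance-claims code filtering and contact derivation (at most one
   contact per patient per day);
6. episodes, either as recorded in the EHR or rebuilt with the episode
   construct over the analysis year plus a lookback window.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import CodeFilter, PipelineConfig
from .containers import PROCESSED_SCHEMAS, ProcessedDataset, RawEhrExtract, coerce_table, empty_table

log = logging.getLogger(__name__)

AGE_BAND_LABELS = ("0-4", "5-17", "18-64", "65+")


def age_band(birth_year: int, analysis_year: int) -> str:
    """Age band at the analysis year (year-of-birth granularity)."""
    age = analysis_year - birth_year
    if age <= 4:
        return AGE_BAND_LABELS[0]
    if age <= 17:
        return AGE_BAND_LABELS[1]
    if age <= 64:
        return AGE_BAND_LABELS[2]
    return AGE_BAND_LABELS[3]


def quarter_bounds(year: int, q: int) -> tuple[dt.date, dt.date]:
    start = dt.date(year, 3 * (q - 1) + 1, 1)
    end = dt.date(year + 1, 1, 1) if q == 4 else dt.date(year, 3 * q + 1, 1)
    return start, end - dt.timedelta(days=1)


def quarters_from_enrollment(
    enrollment_date: dt.date,
    disenrollment_date: dt.date | None,
    analysis_year: int,
) -> frozenset[int]:
    """Quarters of the analysis year fully covered by the enrollment span.

    A quarter counts only if enrollment is on or before its first day (a
    mid-quarter enrollment starts counting from the next quarter) and
    disenrollment, when present, is on or after its last day.
    """
    if disenrollment_date is not None and disenrollment_date < enrollment_date:
        raise ValueError("disenrollment_date before enrollment_date")
    out = set()
    for q in (1, 2, 3, 4):
        qs, qe = quarter_bounds(analysis_year, q)
        if enrollment_date <= qs and (disenrollment_date is None or disenrollment_date >= qe):
            out.add(q)
    return frozenset(out)


def quarters_from_capitation(
    capitation_quarters: Iterable[tuple[int, int]],
    analysis_year: int,
) -> frozenset[int]:
    """Analysis-year quarters between the first and last capitation record.

    Gaps between the first and last recorded quarter are imputed; there is no
    extrapolation beyond the observed span.  Empty input gives an empty set.
    """
    ts = sorted(y * 4 + (q - 1) for y, q in capitation_quarters)
    if not ts:
        return frozenset()
    lo, hi = ts[0], ts[-1]
    base = analysis_year * 4
    return frozenset(
        q for q in (1, 2, 3, 4) if lo <= base + (q - 1) <= hi
    )


_PSEUDO_KEYS = {"pc3_birthyear_sex": b"ehrdiv-pc3", "ssn": b"ehrdiv-ssn"}


def _keyed_hash(material: str, scheme: str) -> str:
    h = hashlib.blake2b(material.encode("utf-8"), key=_PSEUDO_KEYS[scheme], digest_size=8)
    return h.hexdigest()


def pseudonymize(patient: Mapping, scheme: str) -> str | None:
    """Deterministic keyed pseudonym, or ``None`` when the source is missing.

    ``pc3_birthyear_sex`` hashes (first 3 postal digits, birth year, sex)
    within one practice upload — distinct patients of a practice sharing that
    triple collide by construction; ``ssn`` hashes the social security number
    and is absent when the SSN is missing.
    """
    if scheme == "pc3_birthyear_sex":
        material = (
            f"{patient['practice_id']}|{str(patient['postal_code'])[:3]}"
            f"|{patient['birth_year']}|{patient['sex']}"
        )
        return _keyed_hash(material, scheme)
    if scheme == "ssn":
        ssn = patient.get("ssn", "") if hasattr(patient, "get") else patient["ssn"]
        if ssn is None or str(ssn) == "":
            return None
        return _keyed_hash(str(ssn), scheme)
    raise ValueError(f"unknown pseudonym scheme {scheme!r}")


def pseudonymize_frame(patients: pd.DataFrame, scheme: str) -> pd.Series:
    """Vectorised :func:`pseudonymize` over a patients table (None = absent)."""
    if scheme == "pc3_birthyear_sex":
        material = (
            patients["practice_id"]
            + "|"
            + patients["postal_code"].str[:3]
            + "|"
            + patients["birth_year"].astype(str)
            + "|"
            + patients["sex"]
        )
        return material.map(lambda m: _keyed_hash(m, scheme))
    if scheme == "ssn":
        return patients["ssn"].map(lambda s: None if s == "" else _keyed_hash(s, scheme))
    raise ValueError(f"unknown pseudonym scheme {scheme!r}")


def filter_claims(claims: pd.DataFrame, code_filter: CodeFilter) -> pd.DataFrame:
    """Retain claims rows whose code is in the filter; ``"all"`` keeps everything."""
    if code_filter == "all":
        return claims.reset_index(drop=True)
    codes = set(code_filter)
    if not codes:
        log.warning("empty explicit claims filter: result will be empty")
    return claims[claims["claims_code"].isin(codes)].reset_index(drop=True)


def derive_contacts(claims: pd.DataFrame) -> pd.DataFrame:
    """One contact per distinct (patient, date): max one contact per day."""
    out = (
        claims[["pseudo_id", "date"]]
        .drop_duplicates()
        .sort_values(["pseudo_id", "date"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def dedupe_prescriptions(prescriptions: pd.DataFrame, window_days: int) -> pd.DataFrame:
    """Drop double records of the same drug within ``window_days``.

    Within each (patient, ATC) group, records are scanned in date order; a
    record is dropped iff it falls no more than ``window_days`` after the last
    *kept* record of the group (boundary inclusive).  Window 0 collapses only
    exact same-day duplicates.  Idempotent; never increases the row count.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    if prescriptions.empty:
        return prescriptions.reset_index(drop=True)
    df = prescriptions.sort_values(["pseudo_id", "atc", "date"], kind="stable").reset_index(drop=True)
    pid = df["pseudo_id"].to_numpy()
    atc = df["atc"].to_numpy()
    day = df["date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    keep = np.ones(len(df), dtype=bool)
    last_kept = 0
    for i in range(len(df)):
        if i == 0 or pid[i] != pid[last_kept] or atc[i] != atc[last_kept]:
            last_kept = i
            continue
        if day[i] - day[last_kept] <= window_days:
            keep[i] = False
        else:
            last_kept = i
    return df[keep].reset_index(drop=True)


def episodes_recorded(episode_records: pd.DataFrame, analysis_year: int) -> pd.DataFrame:
    """Recorded episodes of care whose interval overlaps the analysis year."""
    y0 = pd.Timestamp(dt.date(analysis_year, 1, 1))
    y1 = pd.Timestamp(dt.date(analysis_year, 12, 31))
    e = episode_records
    overlap = (e["start_date"] <= y1) & (e["end_date"].isna() | (e["end_date"] >= y0))
    out = e.loc[overlap, ["pseudo_id", "icpc", "start_date", "end_date"]]
    return out.sort_values(["pseudo_id", "icpc", "start_date"], kind="stable").reset_index(drop=True)


def apply_symptom_overrule(
    journal_contacts: pd.DataFrame, episode_records: pd.DataFrame
) -> pd.DataFrame:
    """Relabel symptom contacts filed under an episode with a different code.

    A contact whose episode link points at an episode carrying another ICPC
    code takes the episode's code (e.g. a cough contact recorded under an
    asthma episode becomes an asthma encounter).  Unlinked contacts and
    contacts with dangling episode keys are left unchanged.
    """
    if journal_contacts.empty or episode_records.empty:
        return journal_contacts.reset_index(drop=True)
    key_to_icpc = episode_records.set_index("episode_key")["icpc"]
    key_to_icpc = key_to_icpc[~key_to_icpc.index.duplicated()]
    out = journal_contacts.copy().reset_index(drop=True)
    linked = out["episode_key"] != ""
    mapped = out.loc[linked, "episode_key"].map(key_to_icpc)
    dangling = mapped.isna()
    if dangling.any():
        log.warning("%d contacts reference unknown episode keys; left unchanged", int(dangling.sum()))
    replace = linked.copy()
    replace.loc[linked] = ~dangling
    out.loc[replace, "icpc"] = mapped[~dangling]
    return out


def episodes_construct(
    journal_contacts: pd.DataFrame,
    prescriptions: pd.DataFrame,
    episode_records: pd.DataFrame,
    analysis_year: int,
    lookback_years: int,
    interval_map: Mapping[str, int],
    default_interval: int = 90,
    chronic_codes: frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Rebuild episodes of illness from coded encounters (the episode construct).

    Per (patient, ICPC code), encounter dates are pooled from journal contacts
    with that code, prescriptions whose indication is that code, and the start
    dates of recorded episode records, restricted to the analysis year plus
    ``lookback_years`` prior years.  Encounters are sorted; a new episode
    starts whenever the gap to the previous encounter exceeds the code's
    contact-free interval L.  Each episode spans first encounter to last
    encounter + L/2 (rounded down to whole days).  Chronic codes yield one
    never-closing episode from the first encounter.  Only episodes overlapping
    the analysis year are returned.
    """
    w0 = pd.Timestamp(dt.date(analysis_year - lookback_years, 1, 1))
    w1 = pd.Timestamp(dt.date(analysis_year, 12, 31))
    y0 = pd.Timestamp(dt.date(analysis_year, 1, 1))

    pools = []
    if len(journal_contacts):
        pools.append(journal_contacts[["pseudo_id", "date", "icpc"]])
    if len(prescriptions) and "icpc_indication" in prescriptions.columns:
        p = prescriptions[prescriptions["icpc_indication"] != ""]
        if len(p):
            pools.append(
                p[["pseudo_id", "date", "icpc_indication"]].rename(columns={"icpc_indication": "icpc"})
            )
    if len(episode_records):
        pools.append(
            episode_records[["pseudo_id", "start_date", "icpc"]].rename(columns={"start_date": "date"})
        )
    if not pools:
        return empty_table(PROCESSED_SCHEMAS["episodes"])

    enc = pd.concat(pools, ignore_index=True)
    enc = enc[(enc["date"] >= w0) & (enc["date"] <= w1)]
    enc = enc.drop_duplicates().sort_values(["pseudo_id", "icpc", "date"], kind="stable")
    if enc.empty:
        return empty_table(PROCESSED_SCHEMAS["episodes"])

    unknown = sorted(set(enc["icpc"]) - set(interval_map) - set(chronic_codes))
    for code in unknown:
        log.info("no contact-free interval configured for %s; using default %d days", code, default_interval)

    pid = enc["pseudo_id"].to_numpy()
    icpc = enc["icpc"].to_numpy()
    day = enc["date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    L = np.array([interval_map.get(c, default_interval) for c in icpc], dtype=np.int64)
    chronic = np.isin(icpc, sorted(chronic_codes)) if chronic_codes else np.zeros(len(enc), dtype=bool)

    new_group = np.ones(len(enc), dtype=bool)
    new_group[1:] = (pid[1:] != pid[:-1]) | (icpc[1:] != icpc[:-1])
    gap = np.empty(len(enc), dtype=np.int64)
    gap[0] = 0
    gap[1:] = day[1:] - day[:-1]
    # chronic: one episode per (patient, code); otherwise split on gap > L
    new_episode = new_group | (~chronic & (gap > L))
    ep_id = np.cumsum(new_episode) - 1

    starts = np.full(ep_id[-1] + 1, np.iinfo(np.int64).max, dtype=np.int64)
    ends = np.full(ep_id[-1] + 1, np.iinfo(np.int64).min, dtype=np.int64)
    np.minimum.at(starts, ep_id, day)
    np.maximum.at(ends, ep_id, day)
    first_rows = np.flatnonzero(new_episode)
    ep_pid = pid[first_rows]
    ep_icpc = icpc[first_rows]
    ep_chronic = chronic[first_rows]
    ep_L = L[first_rows]
    ep_end = ends + ep_L // 2

    start_ts = pd.to_datetime(starts.astype("datetime64[D]"))
    end_ts = pd.Series(pd.to_datetime(ep_end.astype("datetime64[D]")))
    end_ts[ep_chronic] = pd.NaT

    out = pd.DataFrame(
        {"pseudo_id": ep_pid, "icpc": ep_icpc, "start_date": start_ts, "end_date": end_ts.values}
    )
    overlap = (out["start_date"] <= w1) & (out["end_date"].isna() | (out["end_date"] >= y0))
    out = out[overlap]
    out = coerce_table(out, PROCESSED_SCHEMAS["episodes"], "episodes")
    return out.sort_values(["pseudo_id", "icpc", "start_date"], kind="stable").reset_index(drop=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _restrict_year(df: pd.DataFrame, analysis_year: int, col: str = "date") -> pd.DataFrame:
    y0 = pd.Timestamp(dt.date(analysis_year, 1, 1))
    y1 = pd.Timestamp(dt.date(analysis_year, 12, 31))
    return df[(df[col] >= y0) & (df[col] <= y1)].reset_index(drop=True)


def run_pipeline(
    extract: RawEhrExtract, config: PipelineConfig, analysis_year: int | None = None
) -> ProcessedDataset:
    """Apply one ETL rule-set to a raw extract, yielding a research dataset.

    Event tables of the result are restricted to the analysis year (episodes:
    to episodes overlapping it); the episode construct additionally consumes
    the configured lookback years of raw history.
    """
    if analysis_year is None:
        analysis_year = dt.datetime.now().year
    pats = extract.patients

    # -- pseudonymization ------------------------------------------------
    try:
        pseudo = pseudonymize_frame(pats, config.pseudonym_scheme)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("pseudonymize", exc) from exc
    kept = pats.assign(pseudo_id=pseudo).dropna(subset=["pseudo_id"]).reset_index(drop=True)

    counts = kept["pseudo_id"].value_counts()
    if not config.collapse_pseudonym_collisions:
        ambiguous = set(counts[counts > 1].index)
        if ambiguous:
            log.info("dropping %d patients with colliding pseudonyms", int(counts[counts > 1].sum()))
        kept = kept[~kept["pseudo_id"].isin(ambiguous)].reset_index(drop=True)

    # -- registration quarters per raw patient (vectorised), as a 4-bit mask
    qmask = np.zeros(len(kept), dtype=np.int64)
    if config.quarter_rule == "from_enrollment_date":
        enroll = kept["enrollment_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        disen_raw = kept["disenrollment_date"]
        open_end = disen_raw.isna().to_numpy()
        disen = disen_raw.fillna(pd.Timestamp("2262-01-01")).to_numpy().astype("datetime64[D]").astype(np.int64)
        bad = (~open_end) & (disen < enroll)
        if bad.any():
            raise PipelineError("quarters", ValueError("disenrollment_date before enrollment_date"))
        for q in (1, 2, 3, 4):
            qs, qe = quarter_bounds(analysis_year, q)
            qs_d = np.datetime64(qs, "D").astype(int)
            qe_d = np.datetime64(qe, "D").astype(int)
            qmask |= ((enroll <= qs_d) & (open_end | (disen >= qe_d))) << (q - 1)
    else:
        cap = extract.capitation
        t = cap["year"].to_numpy() * 4 + cap["quarter"].to_numpy() - 1
        span = pd.DataFrame({"true_id": cap["true_id"], "t": t}).groupby("true_id")["t"].agg(["min", "max"])
        lo = kept["true_id"].map(span["min"]).to_numpy()
        hi = kept["true_id"].map(span["max"]).to_numpy()
        base = analysis_year * 4
        has_cap = ~pd.isna(lo)
        for q in (1, 2, 3, 4):
            tq = base + (q - 1)
            with np.errstate(invalid="ignore"):
                inside = has_cap & (lo <= tq) & (tq <= hi)
            qmask |= np.where(inside, 1 << (q - 1), 0)

    # -- collapse collisions: union of quarters and events, demographics of
    # the first contributing patient (by true_id order)
    kept = kept.assign(_qmask=qmask).sort_values("true_id", kind="stable").reset_index(drop=True)
    codes, uniques = pd.factorize(kept["pseudo_id"], sort=True)
    union_mask = np.zeros(len(uniques), dtype=np.int64)
    np.bitwise_or.at(union_mask, codes, kept["_qmask"].to_numpy())
    reps = kept.drop_duplicates("pseudo_id", keep="first").set_index("pseudo_id").loc[uniques]

    _QSTR = ["".join(str(q) for q in (1, 2, 3, 4) if m >> (q - 1) & 1) for m in range(16)]
    nq = np.array([bin(m).count("1") for m in range(16)])[union_mask]
    keep_pseudo = nq > 0  # no full registered quarter in the analysis year: excluded
    bands = np.array(AGE_BAND_LABELS, dtype=object)
    ages = analysis_year - reps["birth_year"].to_numpy()
    band_idx = np.digitize(ages, [5, 18, 65])
    patients_out = pd.DataFrame(
        {
            "pseudo_id": np.asarray(uniques, dtype=object)[keep_pseudo],
            "platform_id": "",
            "practice_id": reps["practice_id"].to_numpy()[keep_pseudo],
            "age_band": bands[band_idx][keep_pseudo],
            "sex": reps["sex"].to_numpy()[keep_pseudo],
            "quarters": np.array(_QSTR, dtype=object)[union_mask][keep_pseudo],
            "patient_years": 0.25 * nq[keep_pseudo],
        }
    )
    patients_out = (
        coerce_table(patients_out, PROCESSED_SCHEMAS["patients"], "patients")
        if len(patients_out)
        else empty_table(PROCESSED_SCHEMAS["patients"])
    )
    patients_out = patients_out.sort_values("pseudo_id", kind="stable").reset_index(drop=True)

    pseudo_kept = set(patients_out["pseudo_id"])
    id_map = pd.Series(kept["pseudo_id"].to_numpy(), index=kept["true_id"])
    id_map = id_map[id_map.isin(pseudo_kept)]

    def _mapped(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out["pseudo_id"] = out["true_id"].map(id_map)
        return out.dropna(subset=["pseudo_id"]).drop(columns=["true_id"]).reset_index(drop=True)

    # -- prescriptions: source filter, dedup, analysis-year restriction --
    try:
        rx = extract.prescriptions
        if not config.include_pharmacy_prescriptions:
            rx = rx[rx["source"] == "gp"]
        rx = _mapped(rx)
        rx = dedupe_prescriptions(rx, config.dedup_window_days)
    except Exception as exc:
        raise PipelineError("prescriptions", exc) from exc
    rx_full = rx  # multi-year, deduped: feeds the episode construct
    rx_year = coerce_table(
        _restrict_year(rx, analysis_year)[["pseudo_id", "date", "atc"]],
        PROCESSED_SCHEMAS["prescriptions"],
        "prescriptions",
    ).sort_values(["pseudo_id", "date", "atc"], kind="stable").reset_index(drop=True)

    # -- claims filtering and contact derivation -------------------------
    try:
        claims_all = _mapped(extract.claims_events)
        claims_year = _restrict_year(claims_all, analysis_year)
        claims_tbl = coerce_table(
            filter_claims(claims_year, config.claims_filter),
            PROCESSED_SCHEMAS["claims"],
            "claims",
        ).sort_values(["pseudo_id", "date", "claims_code", "icpc"], kind="stable").reset_index(drop=True)
        contacts_tbl = coerce_table(
            derive_contacts(filter_claims(claims_year, config.effective_contact_filter())),
            PROCESSED_SCHEMAS["contacts"],
            "contacts",
        )
    except Exception as exc:
        raise PipelineError("claims", exc) from exc

    # -- episodes ---------------------------------------------------------
    try:
        ep_records = _mapped(extract.episodes)
        if config.episode_mode == "recorded":
            episodes_tbl = coerce_table(
                episodes_recorded(ep_records, analysis_year), PROCESSED_SCHEMAS["episodes"], "episodes"
            )
        else:
            journal = _mapped(extract.journal_contacts)
            journal = apply_symptom_overrule(journal, ep_records)
            episodes_tbl = episodes_construct(
                journal,
                rx_full,
                ep_records,
                analysis_year,
                config.lookback_years,
                config.contact_free_interval_days,
                config.default_contact_free_interval_days,
                config.chronic_codes,
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("episodes", exc) from exc

    ds = ProcessedDataset(
        name=config.name,
        analysis_year=analysis_year,
        patients=patients_out,
        contacts=contacts_tbl,
        claims=claims_tbl,
        prescriptions=rx_year,
        episodes=episodes_tbl,
    )
    ds.validate()
    return ds
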