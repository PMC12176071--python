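"""Seeded synthetic general-practice EHR extracts.

The generator produces the raw "care zone" event tables that the two ETL
rule-sets consume: enrolled patients with demographics and (sometimes missing)
social-security numbers, quarterly capitation-fee records with occasional
gaps, ICPC-1 coded journal contacts and GP-recorded episodes of care,
insurance-claims events (consultations, visits and other invoiced
activities), and ATC-coded prescriptions from both the GP and pharmacy
feedback, including near-duplicate double records.

Everything is driven by a single :class:`~ehrdiv.config.GeneratorConfig` and a
single integer seed; identical inputs give byte-identical extracts.

Population model, in brief
--------------------------
* Practice sizes are normal around a configured mean; each patient gets an
  age band, sex, postal code, and an enrollment span (most span the whole
  window; a configurable fraction enrolls late or disenrolls during the
  analysis year).
* Capitation-fee records exist for every quarter fully covered by the
  enrollment span, each independently dropped with ``capitation_gap_prob``.
* Chronic conditions are carried with their configured prevalence and
  generate 1 + Poisson(2) coded contacts per year from onset; acute
  conditions strike in a given year with their configured probability and
  generate a short burst of contacts.
* Every coded contact produces a same-day insurance-claims event
  (consultation-type codes with high probability); additional uncoded claims
  events are added so the total claims rate matches ``contact_rate`` per
  patient-year.
* Prescriptions arise from conditions (per ``atc_prescribing``) and from a
  fraction of background claims; a configurable fraction carry a
  near-duplicate record 0-8 days later from the other source (GP vs
  pharmacy), mimicking double registration.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .config import GeneratorConfig, REGULAR_CONSULT_CODES
from .containers import RAW_SCHEMAS, RawEhrExtract, coerce_table, empty_table

# GP recording-habit constants (not part of the config surface; see docs).
CHRONIC_EPISODE_RECORD_PROB = 0.90  # chronic conditions usually get an episode record
ACUTE_EPISODE_RECORD_PROB = 0.50  # acute illnesses often go unrecorded as episodes
ACUTE_EPISODE_CLOSE_PROB = 0.70  # recorded acute episodes get an end date this often
ACUTE_EPISODE_CLOSE_LAG_DAYS = 28
SYMPTOM_UNDER_EPISODE_PROB = 0.20  # cough contact filed under an asthma episode
BACKGROUND_RX_PER_CLAIM = 0.55  # prescriptions per non-diagnosis claims event
CONSULT_CODE_PROB_FOR_DIAGNOSIS = 0.95  # diagnosis contacts are billed as consults
CHRONIC_CONTACTS_PER_YEAR_EXTRA = 2.0  # contacts/year = 1 + Poisson(this)
ACUTE_CONTACTS_EXTRA = 0.7  # contacts/episode = 1 + Poisson(this)
ONSET_HORIZON_DAYS = 5 * 365  # chronic onset up to 5 years before the window

#: ATC codes for prescriptions not tied to a modelled condition; deliberately
#: outside the diagnosis-group prefix sets (A10*, G03C/J01*, R05C/D/X, R06A).
BACKGROUND_ATC = ("N02BE01", "A02BC01", "C10AA01", "D01AC02", "N05BA04", "B01AC06")

_OPEN = np.iinfo(np.int64).max  # sentinel day number for "still enrolled"


def _day(d: dt.date) -> int:
    return np.datetime64(d, "D").astype(int)


def _to_ts(day_ints: np.ndarray) -> pd.Series:
    return pd.Series(pd.to_datetime(np.asarray(day_ints, dtype="int64").astype("datetime64[D]")))


def _quarter_bounds_days(year: int, q: int) -> tuple[int, int]:
    start = dt.date(year, 3 * (q - 1) + 1, 1)
    end_excl = dt.date(year + 1, 1, 1) if q == 4 else dt.date(year, 3 * q + 1, 1)
    return _day(start), _day(end_excl) - 1


def empty_raw_extract() -> RawEhrExtract:
    """An extract with zero patients and empty, schema-correct tables."""
    return RawEhrExtract(**{name: empty_table(RAW_SCHEMAS[name]) for name in RAW_SCHEMAS})


class _Rows:
    """Column-wise row accumulator (lists of numpy arrays)."""

    def __init__(self, *cols: str) -> None:
        self.cols = cols
        self.parts: list[tuple[np.ndarray, ...]] = []

    def add(self, *arrays: np.ndarray) -> None:
        arrays = tuple(np.asarray(a) for a in arrays)
        if len(arrays[0]):
            self.parts.append(arrays)

    def col(self, name: str) -> np.ndarray:
        i = self.cols.index(name)
        if not self.parts:
            return np.array([], dtype=object if name not in ("date", "day") else np.int64)
        return np.concatenate([p[i] for p in self.parts])


def generate_extract(config: GeneratorConfig | dict) -> RawEhrExtract:
    """Generate a raw EHR extract; deterministic given ``config`` (incl. seed)."""
    if not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.model_validate(config)
    rng = np.random.default_rng(config.seed)

    ws, we = _day(config.window_start), _day(config.window_end)
    year0, year1 = config.window_start.year, config.window_end.year
    years = list(range(year0, year1 + 1))

    # ------------------------------------------------------------------
    # Patients
    # ------------------------------------------------------------------
    sizes = np.maximum(
        1,
        np.rint(
            rng.normal(config.patients_per_practice_mean, config.patients_per_practice_sd, config.n_practices)
        ),
    ).astype(np.int64)
    n = int(sizes.sum())
    practice = np.repeat(np.array([f"GP{i + 1:02d}" for i in range(config.n_practices)], dtype=object), sizes)
    true_id = np.array([f"PT{i:07d}" for i in range(n)], dtype=object)

    band = rng.choice(4, size=n, p=np.asarray(config.age_band_weights, dtype=float))
    band_lo = np.array([0, 5, 18, 65])[band]
    band_span = np.array([5, 13, 47, 30])[band]
    age = band_lo + (rng.random(n) * band_span).astype(np.int64)
    birth_year = config.analysis_year - age
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male").astype(object)

    ssn = np.array([f"S{100000000 + i}" for i in range(n)], dtype=object)
    ssn[rng.random(n) < config.ssn_missing_prob] = ""

    pc3 = (100 + rng.integers(0, config.pc3_pool, n)).astype(str)
    digit = rng.integers(0, 10, n).astype(str)
    letters = rng.integers(0, 26, (n, 2))
    postal = np.array(
        [f"{p}{d}{chr(65 + a)}{chr(65 + b)}" for p, d, (a, b) in zip(pc3, digit, letters)],
        dtype=object,
    )

    # Enrollment spans: most patients cover the whole window; "churners"
    # either enroll at a uniform date inside the window or disenroll at a
    # uniform date inside the analysis year.
    enroll = np.full(n, ws, dtype=np.int64)
    disen = np.full(n, _OPEN, dtype=np.int64)
    churn = rng.random(n) < config.mid_year_enrollment_prob
    late = churn & (rng.random(n) < 0.5)
    early = churn & ~late
    enroll[late] = ws + (rng.random(late.sum()) * (we - ws + 1)).astype(np.int64)
    ay0, ay1 = _day(dt.date(config.analysis_year, 1, 1)), _day(dt.date(config.analysis_year, 12, 31))
    disen[early] = ay0 + (rng.random(early.sum()) * (ay1 - ay0 + 1)).astype(np.int64)

    # ------------------------------------------------------------------
    # Capitation-fee records: quarters fully covered by the enrollment span,
    # each independently dropped with capitation_gap_prob.
    # ------------------------------------------------------------------
    cap = _Rows("idx", "year", "quarter")
    for y in years:
        for q in (1, 2, 3, 4):
            qs, qe = _quarter_bounds_days(y, q)
            if qs < ws or qe > we:
                continue
            covered = (enroll <= qs) & (disen >= qe)
            keep = covered & (rng.random(n) >= config.capitation_gap_prob)
            idx = np.flatnonzero(keep)
            cap.add(idx, np.full(len(idx), y), np.full(len(idx), q))

    # ------------------------------------------------------------------
    # Conditions -> journal contacts, episode records, prescriptions
    # ------------------------------------------------------------------
    contacts = _Rows("idx", "day", "icpc", "epkey")
    episodes = _Rows("key", "idx", "icpc", "start", "end", "chronic")
    rx = _Rows("idx", "day", "atc", "indication")
    ep_counter = 0

    def _new_keys(k: int) -> np.ndarray:
        nonlocal ep_counter
        keys = np.array([f"EP{ep_counter + i:08d}" for i in range(k)], dtype=object)
        ep_counter += k
        return keys

    def _uniform_days(lo: np.ndarray, hi: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-row uniform day draws: returns (repeated row index, day)."""
        rep = np.repeat(np.arange(len(counts)), counts)
        u = rng.random(rep.size)
        days = lo[rep] + (u * (hi[rep] - lo[rep] + 1)).astype(np.int64)
        return rep, days

    hi_all = np.minimum(disen, we)

    for code in sorted(config.icpc_prevalence):
        spec = config.icpc_prevalence[code]
        drugs = config.atc_prescribing.get(code, [])
        if spec.chronic:
            has = rng.random(n) < spec.annual_prob
            idx = np.flatnonzero(has)
            k = len(idx)
            onset = we - rng.integers(0, we - ws + ONSET_HORIZON_DAYS + 1, k)
            eff = np.maximum(np.maximum(onset, enroll[idx]), ws)
            recorded = rng.random(k) < CHRONIC_EPISODE_RECORD_PROB
            keys = np.full(k, "", dtype=object)
            keys[recorded] = _new_keys(int(recorded.sum()))
            valid_any = eff <= hi_all[idx]
            ridx = idx[recorded & valid_any]
            episodes.add(
                keys[recorded & valid_any],
                ridx,
                np.full(len(ridx), code, dtype=object),
                eff[recorded & valid_any],
                np.full(len(ridx), _OPEN),
                np.ones(len(ridx), dtype=bool),
            )
            for y in years:
                y0, y1 = _day(dt.date(y, 1, 1)), _day(dt.date(y, 12, 31))
                lo = np.maximum(eff, y0)
                hi = np.minimum(hi_all[idx], y1)
                valid = lo <= hi
                vi, vlo, vhi = idx[valid], lo[valid], hi[valid]
                vkeys = keys[valid]
                cnt = 1 + rng.poisson(CHRONIC_CONTACTS_PER_YEAR_EXTRA, len(vi))
                rep, days = _uniform_days(vlo, vhi, cnt)
                contacts.add(vi[rep], days, np.full(rep.size, code, dtype=object), vkeys[rep])
                frac = (vhi - vlo + 1) / 365.0
                for drug in drugs:
                    m = rng.poisson(drug.per_episode_year * frac)
                    rrep, rdays = _uniform_days(vlo, vhi, m)
                    rx.add(
                        vi[rrep],
                        rdays,
                        np.full(rrep.size, drug.atc, dtype=object),
                        np.full(rrep.size, code, dtype=object),
                    )
        else:
            for y in years:
                y0, y1 = _day(dt.date(y, 1, 1)), _day(dt.date(y, 12, 31))
                active = rng.random(n) < spec.annual_prob
                idx = np.flatnonzero(active)
                lo = np.maximum(enroll[idx], y0)
                hi = np.minimum(hi_all[idx], y1)
                valid = lo <= hi
                vi, vlo, vhi = idx[valid], lo[valid], hi[valid]
                k = len(vi)
                start = vlo + (rng.random(k) * (vhi - vlo + 1)).astype(np.int64)
                extra = rng.poisson(ACUTE_CONTACTS_EXTRA, k)
                rep, edays = _uniform_days(start + 1, np.minimum(start + 21, vhi) + 0, extra)
                edays = np.minimum(edays, vhi[rep])
                # last contact date per episode (for recorded end dates)
                last = start.copy()
                if rep.size:
                    np.maximum.at(last, rep, edays)
                recorded = rng.random(k) < ACUTE_EPISODE_RECORD_PROB
                keys = np.full(k, "", dtype=object)
                keys[recorded] = _new_keys(int(recorded.sum()))
                closing = recorded & (rng.random(k) < ACUTE_EPISODE_CLOSE_PROB)
                end = np.full(k, _OPEN, dtype=np.int64)
                end[closing] = np.minimum(last[closing] + ACUTE_EPISODE_CLOSE_LAG_DAYS, we)
                ri = np.flatnonzero(recorded)
                episodes.add(
                    keys[ri],
                    vi[ri],
                    np.full(len(ri), code, dtype=object),
                    start[ri],
                    end[ri],
                    np.zeros(len(ri), dtype=bool),
                )
                contacts.add(vi, start, np.full(k, code, dtype=object), keys)
                if rep.size:
                    contacts.add(vi[rep], edays, np.full(rep.size, code, dtype=object), keys[rep])
                for drug in drugs:
                    m = rng.poisson(drug.per_episode_year, k)
                    rrep = np.repeat(np.arange(k), m)
                    rdays = start[rrep] + rng.integers(0, 15, rrep.size)
                    rdays = np.minimum(rdays, vhi[rrep])
                    rx.add(
                        vi[rrep],
                        rdays,
                        np.full(rrep.size, drug.atc, dtype=object),
                        np.full(rrep.size, code, dtype=object),
                    )

    c_idx = contacts.col("idx").astype(np.int64) if contacts.parts else np.array([], dtype=np.int64)
    c_day = contacts.col("day").astype(np.int64) if contacts.parts else np.array([], dtype=np.int64)
    c_icpc = contacts.col("icpc")
    c_key = contacts.col("epkey")

    # Cough contacts occasionally filed under an existing asthma episode:
    # exercised later by the construct's symptom-overrule step.
    ep_key_arr = episodes.col("key")
    ep_idx_arr = episodes.col("idx").astype(np.int64) if episodes.parts else np.array([], dtype=np.int64)
    ep_icpc_arr = episodes.col("icpc")
    r96_mask = ep_icpc_arr == "R96"
    if r96_mask.any() and len(c_idx):
        r96_key_by_patient: dict[int, str] = {}
        for i, key in zip(ep_idx_arr[r96_mask], ep_key_arr[r96_mask]):
            r96_key_by_patient.setdefault(int(i), key)
        cand = np.flatnonzero(
            (c_icpc == "R05") & np.isin(c_idx, np.fromiter(r96_key_by_patient, dtype=np.int64, count=len(r96_key_by_patient)))
        )
        chosen = cand[rng.random(len(cand)) < SYMPTOM_UNDER_EPISODE_PROB]
        for j in chosen:
            c_key[j] = r96_key_by_patient[int(c_idx[j])]

    # ------------------------------------------------------------------
    # Claims events: one per diagnosis contact (consult-heavy code mix) plus
    # background events topping total volume up to `contact_rate`/patient-year.
    # ------------------------------------------------------------------
    catalog_codes = np.array([c for c, _ in config.claims_code_catalog], dtype=object)
    catalog_w = np.array([w for _, w in config.claims_code_catalog], dtype=float)
    catalog_p = catalog_w / catalog_w.sum()
    consult_mask = np.isin(catalog_codes, sorted(REGULAR_CONSULT_CODES))
    consult_codes, consult_p = catalog_codes[consult_mask], catalog_p[consult_mask] / catalog_p[consult_mask].sum()
    other_codes = catalog_codes[~consult_mask]
    other_p = (
        catalog_p[~consult_mask] / catalog_p[~consult_mask].sum() if (~consult_mask).any() else None
    )

    m = len(c_idx)
    diag_codes = np.empty(m, dtype=object)
    as_consult = rng.random(m) < CONSULT_CODE_PROB_FOR_DIAGNOSIS
    diag_codes[as_consult] = rng.choice(consult_codes, size=int(as_consult.sum()), p=consult_p)
    rest = ~as_consult
    if other_p is not None:
        diag_codes[rest] = rng.choice(other_codes, size=int(rest.sum()), p=other_p)
    else:
        diag_codes[rest] = rng.choice(consult_codes, size=int(rest.sum()), p=consult_p)

    claims = _Rows("idx", "day", "code", "icpc")
    claims.add(c_idx, c_day, diag_codes, c_icpc.copy())

    bg_rx = _Rows("idx", "day", "atc", "indication")
    for y in years:
        y0, y1 = _day(dt.date(y, 1, 1)), _day(dt.date(y, 12, 31))
        lo = np.maximum(enroll, y0)
        hi = np.minimum(hi_all, y1)
        valid = lo <= hi
        in_year = (c_day >= y0) & (c_day <= y1)
        diag_count = np.bincount(c_idx[in_year], minlength=n).astype(float)
        frac = np.where(valid, (hi - lo + 1) / 365.0, 0.0)
        lam = np.maximum(0.0, config.contact_rate * frac - diag_count)
        cnt = rng.poisson(lam)
        rep, days = _uniform_days(np.where(valid, lo, 0), np.where(valid, hi, 0), cnt)
        codes = rng.choice(catalog_codes, size=rep.size, p=catalog_p)
        claims.add(rep, days, codes, np.full(rep.size, "", dtype=object))
        with_rx = rng.random(rep.size) < BACKGROUND_RX_PER_CLAIM
        bg_atc = rng.choice(np.array(BACKGROUND_ATC, dtype=object), size=int(with_rx.sum()))
        bg_rx.add(rep[with_rx], days[with_rx], bg_atc, np.full(int(with_rx.sum()), "", dtype=object))

    # ------------------------------------------------------------------
    # Prescriptions: source attribution and near-duplicate double records.
    # ------------------------------------------------------------------
    rx_idx = np.concatenate([rx.col("idx").astype(np.int64), bg_rx.col("idx").astype(np.int64)])
    rx_day = np.concatenate([rx.col("day").astype(np.int64), bg_rx.col("day").astype(np.int64)])
    rx_atc = np.concatenate([rx.col("atc"), bg_rx.col("atc")])
    rx_ind = np.concatenate([rx.col("indication"), bg_rx.col("indication")])
    nrx = len(rx_idx)
    rx_src = np.where(rng.random(nrx) < config.pharmacy_source_fraction, "pharmacy", "gp").astype(object)

    dup = rng.random(nrx) < config.near_duplicate_prob
    d_idx = rx_idx[dup]
    d_day = np.minimum(rx_day[dup] + rng.integers(0, 9, int(dup.sum())), we)
    d_atc = rx_atc[dup]
    d_ind = rx_ind[dup]
    d_src = np.where(rx_src[dup] == "gp", "pharmacy", "gp").astype(object)

    rx_idx = np.concatenate([rx_idx, d_idx])
    rx_day = np.concatenate([rx_day, d_day])
    rx_atc = np.concatenate([rx_atc, d_atc])
    rx_ind = np.concatenate([rx_ind, d_ind])
    rx_src = np.concatenate([rx_src, d_src])

    # ------------------------------------------------------------------
    # Assemble tables (deterministic order).
    # ------------------------------------------------------------------
    patients = pd.DataFrame(
        {
            "true_id": true_id,
            "practice_id": practice,
            "ssn": ssn,
            "postal_code": postal,
            "birth_year": birth_year,
            "sex": sex,
            "enrollment_date": _to_ts(enroll).values,
            "disenrollment_date": _to_ts(np.where(disen == _OPEN, 0, disen)).where(disen != _OPEN, pd.NaT).values,
        }
    )

    def _finish(df: pd.DataFrame, name: str, sort_cols: list[str]) -> pd.DataFrame:
        df = coerce_table(df, RAW_SCHEMAS[name], name)
        return df.sort_values(sort_cols, kind="stable").reset_index(drop=True)

    journal = pd.DataFrame(
        {
            "true_id": true_id[c_idx] if len(c_idx) else np.array([], dtype=object),
            "date": _to_ts(c_day).values,
            "icpc": c_icpc,
            "episode_key": c_key,
        }
    )
    claims_df = pd.DataFrame(
        {
            "true_id": true_id[claims.col("idx").astype(np.int64)] if claims.parts else np.array([], dtype=object),
            "date": _to_ts(claims.col("day").astype(np.int64)).values,
            "claims_code": claims.col("code"),
            "icpc": claims.col("icpc"),
        }
    )
    ep_start = episodes.col("start").astype(np.int64) if episodes.parts else np.array([], dtype=np.int64)
    ep_end = episodes.col("end").astype(np.int64) if episodes.parts else np.array([], dtype=np.int64)
    episodes_df = pd.DataFrame(
        {
            "episode_key": ep_key_arr,
            "true_id": true_id[ep_idx_arr] if len(ep_idx_arr) else np.array([], dtype=object),
            "icpc": ep_icpc_arr,
            "start_date": _to_ts(ep_start).values,
            "end_date": _to_ts(np.where(ep_end == _OPEN, 0, ep_end)).where(pd.Series(ep_end) != _OPEN, pd.NaT).values
            if len(ep_end)
            else pd.Series([], dtype="datetime64[ns]").values,
            "chronic": episodes.col("chronic").astype(bool) if episodes.parts else np.array([], dtype=bool),
        }
    )
    rx_df = pd.DataFrame(
        {
            "true_id": true_id[rx_idx] if nrx or len(rx_idx) else np.array([], dtype=object),
            "date": _to_ts(rx_day).values,
            "atc": rx_atc,
            "source": rx_src,
            "icpc_indication": rx_ind,
        }
    )
    cap_df = pd.DataFrame(
        {
            "true_id": true_id[cap.col("idx").astype(np.int64)] if cap.parts else np.array([], dtype=object),
            "year": cap.col("year").astype(np.int64) if cap.parts else np.array([], dtype=np.int64),
            "quarter": cap.col("quarter").astype(np.int64) if cap.parts else np.array([], dtype=np.int64),
        }
    )

    extract = RawEhrExtract(
        patients=coerce_table(patients, RAW_SCHEMAS["patients"], "patients"),
        journal_contacts=_finish(journal, "journal_contacts", ["true_id", "date", "icpc", "episode_key"]),
        claims_events=_finish(claims_df, "claims_events", ["true_id", "date", "claims_code", "icpc"]),
        episodes=_finish(episodes_df, "episodes", ["episode_key"]),
        prescriptions=_finish(rx_df, "prescriptions", ["true_id", "date", "atc", "source", "icpc_indication"]),
        capitation=_finish(cap_df, "capitation", ["true_id", "year", "quarter"]),
    )
    extract.validate()
    return extract
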