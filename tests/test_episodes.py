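"""Recorded episodes, the episode construct, and the symptom overrule."""

import numpy as np
import pandas as pd
import pytest

import ehrdiv as ed


def _contacts(rows):
    return pd.DataFrame(
        [
            {"pseudo_id": p, "date": pd.Timestamp(d), "icpc": c, "episode_key": k}
            for p, d, c, k in rows
        ]
    )


def _records(rows):
    return pd.DataFrame(
        [
            {
                "pseudo_id": p,
                "episode_key": k,
                "icpc": c,
                "start_date": pd.Timestamp(s),
                "end_date": pd.Timestamp(e) if e else pd.NaT,
                "chronic": ch,
            }
            for p, k, c, s, e, ch in rows
        ]
    )


_EMPTY_RX = pd.DataFrame(
    {
        "pseudo_id": pd.Series([], dtype=object),
        "date": pd.Series([], dtype="datetime64[ns]"),
        "atc": pd.Series([], dtype=object),
        "icpc_indication": pd.Series([], dtype=object),
    }
)
def construct(contacts, rx=None, records=None, intervals=None, chronic=frozenset(), lookback=2):
    return ed.episodes_construct(
        contacts,
        rx if rx is not None else _EMPTY_RX,
        records if records is not None else _records([]).reindex(
            columns=["pseudo_id", "episode_key", "icpc", "start_date", "end_date", "chronic"]
        ),
        2019,
        lookback,
        intervals or {},
        90,
        chronic,
    )


class TestRecordedEpisodes:
    def test_open_episode_from_prior_year_overlaps(self):
        recs = _records([("p", "E1", "K86", "2018-06-01", None, True)])
        assert len(ed.episodes_recorded(recs, 2019)) == 1

    def test_closed_episode_before_the_year_is_excluded(self):
        recs = _records([("p", "E1", "R05", "2017-01-01", "2017-12-31", False)])
        assert ed.episodes_recorded(recs, 2019).empty

    def test_no_end_date_synthesis(self):
        recs = _records([("p", "E1", "R05", "2019-02-01", None, False)])
        out = ed.episodes_recorded(recs, 2019)
        assert out["end_date"].isna().all()

    def test_inclusion_matches_interval_overlap_oracle(self):
        rng = np.random.default_rng(13)
        base = pd.Timestamp("2017-01-01")
        rows = []
        for i in range(300):
            start = base + pd.Timedelta(days=int(rng.integers(0, 1000)))
            if rng.random() < 0.3:
                end = None
            else:
                end = start + pd.Timedelta(days=int(rng.integers(0, 400)))
            rows.append(("p", f"E{i}", "R05", start, end, False))
        recs = _records([(p, k, c, s, e.strftime("%Y-%m-%d") if e is not None else None, ch) for p, k, c, s, e, ch in rows])
        got = len(ed.episodes_recorded(recs, 2019))
        y0, y1 = pd.Timestamp("2019-01-01"), pd.Timestamp("2019-12-31")
        expected = sum(1 for _, _, _, s, e, _ in rows if s <= y1 and (e is None or e >= y0))
        assert got == expected


def partition_oracle(days: list[int], L: int) -> list[tuple[int, int]]:
    """Brute-force oracle: enumerate every partition of the sorted encounter
    dates into contiguous runs; keep the unique partition whose within-run
    gaps are all <= L and whose between-run boundary gaps are all > L.
    Episodes span first encounter to last encounter + L//2."""
    days = sorted(set(days))
    n = len(days)
    valid = []
    for cuts in range(1 << max(0, n - 1)):
        runs, cur = [], [days[0]]
        ok = True
        for i in range(1, n):
            if cuts >> (i - 1) & 1:  # cut between i-1 and i
                if days[i] - days[i - 1] <= L:
                    ok = False
                    break
                runs.append(cur)
                cur = [days[i]]
            else:
                if days[i] - days[i - 1] > L:
                    ok = False
                    break
                cur.append(days[i])
        if ok:
            runs.append(cur)
            valid.append(runs)
    assert len(valid) == 1, (days, L, valid)
    return [(r[0], r[-1] + L // 2) for r in valid[0]]


class TestEpisodeConstruct:
    def test_two_contacts_within_interval_form_one_episode(self):
        out = construct(
            _contacts([("p", "2019-01-10", "R05", ""), ("p", "2019-02-10", "R05", "")]),
            intervals={"R05": 90},
        )
        assert len(out) == 1
        assert out.loc[0, "start_date"] == pd.Timestamp("2019-01-10")
        assert out.loc[0, "end_date"] == pd.Timestamp("2019-03-27")  # Feb 10 + 45 days

    def test_single_encounter_episode_ends_at_half_interval(self):
        out = construct(_contacts([("p", "2019-05-01", "U71", "")]), intervals={"U71": 28})
        assert len(out) == 1
        assert out.loc[0, "end_date"] == pd.Timestamp("2019-05-15")

    def test_gap_beyond_interval_splits_episodes(self):
        out = construct(
            _contacts([("p", "2019-01-01", "R05", ""), ("p", "2019-07-20", "R05", "")]),
            intervals={"R05": 90},
        )
        assert len(out) == 2

    def test_chronic_code_yields_single_open_episode_from_lookback(self):
        out = construct(
            _contacts([("p", "2017-03-05", "T90", ""), ("p", "2018-11-01", "T90", "")]),
            chronic=frozenset({"T90"}),
        )
        assert len(out) == 1
        assert out["end_date"].isna().all()
        assert out.loc[0, "start_date"] == pd.Timestamp("2017-03-05")

    def test_prescription_indications_count_as_encounters(self):
        rx = pd.DataFrame(
            {
                "pseudo_id": ["p"],
                "date": [pd.Timestamp("2019-06-01")],
                "atc": ["J01XE01"],
                "icpc_indication": ["U71"],
            }
        )
        out = construct(_contacts([]), rx=rx, intervals={"U71": 28})
        assert len(out) == 1
        assert out.loc[0, "icpc"] == "U71"

    def test_recorded_episode_start_dates_seed_encounters(self):
        recs = _records([("p", "E1", "R05", "2019-04-01", None, False)])
        out = construct(_contacts([]), records=recs, intervals={"R05": 90})
        assert len(out) == 1
        assert out.loc[0, "start_date"] == pd.Timestamp("2019-04-01")

    def test_encounters_before_lookback_window_are_ignored(self):
        out = construct(
            _contacts([("p", "2016-06-01", "R05", ""), ("p", "2019-06-01", "R05", "")]),
            intervals={"R05": 90},
            lookback=2,
        )
        assert len(out) == 1
        assert out.loc[0, "start_date"] == pd.Timestamp("2019-06-01")

    def test_episodes_not_overlapping_analysis_year_are_dropped(self):
        out = construct(_contacts([("p", "2017-02-01", "R05", "")]), intervals={"R05": 90})
        assert out.empty

    def test_agreement_with_partition_oracle_on_random_patients(self):
        rng = np.random.default_rng(77)
        base = pd.Timestamp("2019-01-01")
        for _ in range(400):
            k = int(rng.integers(1, 11))
            days = sorted(int(d) for d in rng.integers(0, 330, k))
            L = int(rng.integers(5, 120))
            out = construct(
                _contacts([("p", base + pd.Timedelta(days=d), "R05", "") for d in days]),
                intervals={"R05": L},
            )
            expected = partition_oracle(days, L)
            got = sorted(
                ((s - base).days, (e - base).days)
                for s, e in zip(out["start_date"], out["end_date"])
            )
            assert got == sorted(expected)


class TestSymptomOverrule:
    def test_symptom_contact_takes_the_episode_code(self):
        contacts = _contacts([("p", "2019-02-01", "R05", "E1")])
        recs = _records([("p", "E1", "R96", "2018-01-01", None, True)])
        out = ed.apply_symptom_overrule(contacts, recs)
        assert list(out["icpc"]) == ["R96"]

    def test_matching_code_unchanged(self):
        contacts = _contacts([("p", "2019-02-01", "R05", "E1")])
        recs = _records([("p", "E1", "R05", "2019-01-01", None, False)])
        out = ed.apply_symptom_overrule(contacts, recs)
        assert list(out["icpc"]) == ["R05"]

    def test_unlinked_contact_unchanged(self):
        contacts = _contacts([("p", "2019-02-01", "R05", "")])
        recs = _records([("p", "E1", "R96", "2018-01-01", None, True)])
        out = ed.apply_symptom_overrule(contacts, recs)
        assert list(out["icpc"]) == ["R05"]

    def test_dangling_episode_key_unchanged_with_warning(self, caplog):
        contacts = _contacts([("p", "2019-02-01", "R05", "GONE")])
        recs = _records([("p", "E1", "R96", "2018-01-01", None, True)])
        with caplog.at_level("WARNING", logger="ehrdiv.etl"):
            out = ed.apply_symptom_overrule(contacts, recs)
        assert list(out["icpc"]) == ["R05"]
        assert any("unknown episode" in r.message for r in caplog.records)
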