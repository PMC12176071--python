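"""Comparison statistics: person-time, demographics, indicators, paired t,
rates and the standardized difference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import ehrdiv as ed
from ehrdiv.report import report_from_json, report_to_dict, report_to_json, table1, table2, table3


def _patients(rows):
    df = pd.DataFrame(
        [
            {
                "pseudo_id": p,
                "platform_id": p,
                "practice_id": pr,
                "age_band": band,
                "sex": sex,
                "quarters": q,
                "patient_years": 0.25 * len(q),
            }
            for p, pr, band, sex, q in rows
        ]
    )
    return df


def _dataset(patients, contacts=None, claims=None, prescriptions=None, episodes=None):
    empty_date = pd.Series([], dtype="datetime64[ns]")
    return ed.ProcessedDataset(
        name="t",
        analysis_year=2019,
        patients=patients,
        contacts=contacts
        if contacts is not None
        else pd.DataFrame({"pseudo_id": pd.Series([], dtype=object), "date": empty_date}),
        claims=claims
        if claims is not None
        else pd.DataFrame(
            {
                "pseudo_id": pd.Series([], dtype=object),
                "date": empty_date,
                "claims_code": pd.Series([], dtype=object),
                "icpc": pd.Series([], dtype=object),
            }
        ),
        prescriptions=prescriptions
        if prescriptions is not None
        else pd.DataFrame(
            {
                "pseudo_id": pd.Series([], dtype=object),
                "date": empty_date,
                "atc": pd.Series([], dtype=object),
            }
        ),
        episodes=episodes
        if episodes is not None
        else pd.DataFrame(
            {
                "pseudo_id": pd.Series([], dtype=object),
                "icpc": pd.Series([], dtype=object),
                "start_date": empty_date,
                "end_date": empty_date,
            }
        ),
    )


class TestPatientYears:
    def test_four_full_year_patients(self):
        ds = _dataset(_patients([(f"p{i}", "GP01", "18-64", "female", "1234") for i in range(4)]))
        assert ed.patient_years_total(ds) == 4.0

    def test_single_quarter_patient_contributes_quarter_year(self):
        ds = _dataset(_patients([("p", "GP01", "18-64", "male", "3")]))
        assert ed.patient_years_total(ds) == 0.25


class TestDemographics:
    def test_band_counts_match_brute_force_group_by(self, processed_pair):
        a, _, _, _ = processed_pair
        table = ed.demographics_table(a).set_index("characteristic")
        by_hand = a.patients["age_band"].value_counts()
        for band in ("0-4", "5-17", "18-64", "65+"):
            assert table.loc[f"age_{band}", "value"] == by_hand.get(band, 0)
        assert table.loc["patients", "value"] == len(a.patients)
        assert (
            table.loc["patients_per_practice", "value"]
            == len(a.patients) / a.patients["practice_id"].nunique()
        )

    def test_single_band_population_shows_100_percent(self):
        ds = _dataset(_patients([(f"p{i}", "GP01", "65+", "female", "1234") for i in range(5)]))
        t = ed.demographics_table(ds).set_index("characteristic")
        assert t.loc["age_65+", "value2"] == 100.0
        assert t.loc["age_0-4", "value2"] == 0.0

    def test_band_counts_sum_to_total(self, processed_pair):
        _, b, _, _ = processed_pair
        t = ed.demographics_table(b).set_index("characteristic")
        total = sum(t.loc[f"age_{band}", "value"] for band in ("0-4", "5-17", "18-64", "65+"))
        assert total == t.loc["patients", "value"]


class TestPerPatientIndicator:
    def test_patient_without_events_scores_zero_everywhere(self):
        ds = _dataset(_patients([("p", "GP01", "18-64", "male", "1234")]))
        for ind in ("contacts", "regular_consults", "prescriptions", "episodes"):
            assert ed.per_patient_indicator(ds, ind).tolist() == [0]

    def test_regular_consults_apply_code_set_and_distinct_dates(self):
        claims = pd.DataFrame(
            {
                "pseudo_id": ["p", "p", "p"],
                "date": pd.to_datetime(["2019-01-01", "2019-01-01", "2019-01-02"]),
                "claims_code": ["12010", "13012", "12001"],
                "icpc": ["", "", ""],
            }
        )
        ds = _dataset(_patients([("p", "GP01", "18-64", "male", "1234")]), claims=claims)
        assert ed.per_patient_indicator(ds, "regular_consults").tolist() == [2]

    def test_unknown_indicator_rejected(self):
        ds = _dataset(_patients([("p", "GP01", "18-64", "male", "1234")]))
        with pytest.raises(ValueError):
            ed.per_patient_indicator(ds, "admissions")

    def test_counts_match_brute_force_on_generated_data(self, processed_pair):
        a, _, _, _ = processed_pair
        got = ed.per_patient_indicator(a, "prescriptions")
        for pid in a.patients["pseudo_id"].sample(20, random_state=2):
            assert got[pid] == (a.prescriptions["pseudo_id"] == pid).sum()


class TestPairedT:
    def test_identical_vectors_are_a_degenerate_zero(self):
        r = ed.paired_t_test([1, 2, 3], [1, 2, 3])
        assert r.mean_diff == 0.0 and r.t_statistic == 0.0 and r.p_value == 1.0
        assert r.ci_low <= 0.0 <= r.ci_high
        assert r.degenerate

    def test_closed_form_example(self):
        r = ed.paired_t_test([1, 2, 3], [0, 0, 0], conf_level=0.95)
        assert r.mean_diff == 2.0
        assert r.t_statistic == pytest.approx(2 * math.sqrt(3), abs=1e-12)
        assert r.ci_low == pytest.approx(-0.4841, abs=5e-5)
        assert r.ci_high == pytest.approx(4.4841, abs=5e-5)

    def test_matches_scipy_ttest_rel_on_random_data(self):
        rng = np.random.default_rng(8)
        x = rng.normal(1.0, 2.0, 50)
        y = rng.normal(0.5, 1.5, 50)
        r = ed.paired_t_test(x, y)
        ref = sps.ttest_rel(x, y)
        assert r.t_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)
        lo, hi = ref.confidence_interval(0.95)
        assert r.ci_low == pytest.approx(lo, rel=1e-9)
        assert r.ci_high == pytest.approx(hi, rel=1e-9)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ed.paired_t_test([1], [2])


class TestRates:
    def test_printed_prevalence_examples(self):
        assert round(ed.prevalence_rate(2979, 46400), 1) == 64.2
        assert round(ed.prevalence_rate(2718, 43100), 1) == 63.1

    def test_zero_cases_give_zero(self):
        assert ed.prevalence_rate(0, 100.0) == 0.0
        assert ed.rate_per_1000py(0, 100.0) == 0.0

    def test_event_rate_arithmetic(self):
        assert ed.rate_per_1000py(100, 50.0) == 2000.0

    def test_nonpositive_person_time_rejected(self):
        for fn in (ed.prevalence_rate, ed.rate_per_1000py):
            with pytest.raises(ValueError):
                fn(5, 0.0)


class TestStandardizedDifference:
    def test_equal_proportions_give_zero(self):
        r = ed.standardized_difference(0.3, 0.3)
        assert r.sd_value == 0.0 and not r.significant and r.magnitude == "negligible"

    def test_worked_example(self):
        r = ed.standardized_difference(0.3, 0.2)
        assert r.sd_value == pytest.approx(0.1 / math.sqrt(0.185), rel=1e-12)
        assert r.significant and r.magnitude == "small"

    @given(
        p_a=st.floats(0.0, 1.0, allow_nan=False),
        p_b=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_antisymmetry(self, p_a, p_b):
        degenerate = p_a in (0.0, 1.0) and p_b in (0.0, 1.0) and p_a != p_b
        if degenerate:
            with pytest.raises(ValueError):
                ed.standardized_difference(p_a, p_b)
        else:
            assert ed.standardized_difference(p_a, p_b).sd_value == pytest.approx(
                -ed.standardized_difference(p_b, p_a).sd_value, abs=1e-12
            )

    def test_magnitude_banding(self):
        assert ed.standardized_difference(0.5, 0.45).magnitude == "negligible"
        assert ed.standardized_difference(0.5, 0.45).significant is False
        assert ed.standardized_difference(0.5, 0.3).magnitude == "small"
        assert ed.standardized_difference(0.8, 0.5).magnitude == "medium"
        assert ed.standardized_difference(0.9, 0.3).magnitude == "large"

    def test_out_of_range_proportions_rejected(self):
        with pytest.raises(ValueError):
            ed.standardized_difference(1.2, 0.3)


class TestDiagnosisGroups:
    def test_shipped_group_definitions(self):
        by_code = {g.icpc_code: g for g in ed.DEFAULT_DIAGNOSIS_GROUPS}
        assert by_code["T90"].atc_prefixes == {"A10A", "A10B"}
        assert by_code["U71"].atc_prefixes == {"G03C", "J01C", "J01D", "J01E", "J01G", "J01M", "J01X"}
        assert by_code["R05"].atc_prefixes == {"R05C", "R05D", "R05X", "R06A"}

    def test_no_records_give_zero_cases_and_zero_prevalence(self):
        ds = _dataset(_patients([("p", "GP01", "18-64", "male", "1234")]))
        gi = ed.diagnosis_group_report(ds, ed.DEFAULT_DIAGNOSIS_GROUPS[0])
        assert gi.n_cases == 0 and gi.prevalence_per_1000py == 0.0

    def test_atc_prefix_semantics(self):
        pats = _patients([("p", "GP01", "18-64", "male", "1234")])
        claims = pd.DataFrame(
            {
                "pseudo_id": ["p"],
                "date": pd.to_datetime(["2019-03-01"]),
                "claims_code": ["12010"],
                "icpc": ["T90"],
            }
        )
        rx = pd.DataFrame(
            {
                "pseudo_id": ["p", "p"],
                "date": pd.to_datetime(["2019-03-01", "2019-04-01"]),
                "atc": ["A10AB01", "C09AA02"],
            }
        )
        gi = ed.diagnosis_group_report(_dataset(pats, claims=claims, prescriptions=rx), ed.DEFAULT_DIAGNOSIS_GROUPS[0])
        assert gi.n_cases == 1
        assert gi.n_prescriptions == 1  # A10AB01 matches prefix A10A; C09AA02 does not

    def test_all_five_numbers_match_brute_force(self, processed_pair):
        a, _, _, _ = processed_pair
        spec = ed.DEFAULT_DIAGNOSIS_GROUPS[1]  # U71
        gi = ed.diagnosis_group_report(a, spec)
        cases = {
            pid
            for pid, icpc in zip(a.claims["pseudo_id"], a.claims["icpc"])
            if icpc == spec.icpc_code
        }
        assert gi.n_cases == len(cases)
        py = sum(
            y for pid, y in zip(a.patients["pseudo_id"], a.patients["patient_years"]) if pid in cases
        )
        assert gi.group_patient_years == pytest.approx(py)
        n_rx = sum(
            1
            for pid, atc in zip(a.prescriptions["pseudo_id"], a.prescriptions["atc"])
            if pid in cases and any(atc.startswith(pref) for pref in spec.atc_prefixes)
        )
        assert gi.n_prescriptions == n_rx
        consults = {
            (pid, d)
            for pid, d, c in zip(a.claims["pseudo_id"], a.claims["date"], a.claims["claims_code"])
            if pid in cases and c in ed.REGULAR_CONSULT_CODES
        }
        assert gi.n_consults == len(consults)
        total_py = ed.patient_years_total(a)
        assert gi.prevalence_per_1000py == pytest.approx(1000 * len(cases) / total_py)
        assert gi.prescriptions_per_1000py == pytest.approx(1000 * n_rx / total_py)


class TestCompareAndReport:
    def test_identity_comparison_is_all_zero(self, processed_pair):
        a, _, _, _ = processed_pair
        link = ed.concordant(a, a)
        rep = ed.compare_datasets(a, a, link)
        for r in rep.paired.values():
            assert r.mean_diff == 0.0 and r.degenerate
        for g in rep.groups:
            for sd in g["sd"].values():
                assert sd is None or sd["sd_value"] == 0.0

    def test_report_round_trips_through_json(self, processed_pair, tmp_path):
        a, b, _, link = processed_pair
        rep = ed.compare_datasets(a, b, link)
        report_to_json(rep, tmp_path / "r.json")
        again = report_from_json(tmp_path / "r.json")
        assert report_to_dict(rep) == report_to_dict(again)

    def test_empty_concordant_set_skips_step_two_with_diagnostic(self, processed_pair):
        a, _, _, _ = processed_pair
        empty_link = ed.ConcordantLink.from_id_sets(set(), set())
        rep = ed.compare_datasets(a, a, empty_link)
        assert rep.paired == {}
        assert "skipped" in rep.step2_skipped

    def test_rendered_tables_have_expected_shape(self, processed_pair, tmp_path):
        a, b, _, link = processed_pair
        rep = ed.compare_datasets(a, b, link)
        t1, t2, t3 = table1(rep), table2(rep), table3(rep)
        assert len(t2) == 4  # one row per similarity indicator
        assert len(t3) == 6 * len(ed.DEFAULT_DIAGNOSIS_GROUPS)
        assert {"characteristic", a.name, b.name} <= set(t1.columns)
        paths = ed.write_tables(rep, tmp_path)
        assert all(p.exists() for p in paths)
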