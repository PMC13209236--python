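"""FAERS-dialect parsing, deduplication, PS filtering and summaries."""

import pytest
from hypothesis import given, settings, strategies as st

import pvsignal as pv
from pvsignal.errors import SchemaError
from pvsignal.faers import parse_faers_date

from conftest import make_report, write_faers_files


class TestReadTables:
    def test_identity_parse_of_three_row_demo(self, tmp_path):
        paths = write_faers_files(tmp_path, [
            "101$1$20230101$M$64$YR$70$KG$MD$US",
            "102$2$20230215$F$55$YR$$$$JP",
            "103$3$20230301$$$$$$CN$US",
        ])
        tables = pv.read_faers_tables(paths)
        assert len(tables["demo"]) == 3
        reports, warnings = pv.build_store(tables)
        assert [r.primaryid for r in reports] == ["101", "102", "103"]
        assert reports[0].gender == "M" and reports[0].age_years == 64
        assert reports[1].weight_kg is None
        assert reports[2].gender == "UNK" and reports[2].reporter == "consumer"
        assert sum(warnings.values()) == 0

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        paths = write_faers_files(
            tmp_path, ["101$1$M$64$YR$70$KG$MD$US"],
            demo_header="primaryid$caseid$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country")
        with pytest.raises(SchemaError, match="fda_dt"):
            pv.read_faers_tables(paths)

    def test_unparseable_age_kept_with_warning(self, tmp_path):
        paths = write_faers_files(tmp_path, [
            "101$1$20230101$M$ERR$YR$70$KG$MD$US",
        ])
        reports, warnings = pv.build_store(pv.read_faers_tables(paths))
        assert len(reports) == 1
        assert reports[0].age_years is None
        assert warnings["age_unparseable"] == 1

    def test_age_and_weight_unit_conversion(self, tmp_path):
        paths = write_faers_files(tmp_path, [
            "101$1$20230101$M$24$MON$154$LBS$MD$US",
        ])
        reports, _ = pv.build_store(pv.read_faers_tables(paths))
        assert reports[0].age_years == pytest.approx(2.0)
        assert reports[0].weight_kg == pytest.approx(154 * 0.453592)


class TestDates:
    @pytest.mark.parametrize("raw,complete,year", [
        ("20230415", True, 2023),
        ("202304", False, 2023),
        ("2023", False, 2023),
        ("20231301", False, None),   # impossible month
        ("garbage", False, None),
        ("", False, None),
    ])
    def test_partial_and_invalid_dates(self, raw, complete, year):
        d = parse_faers_date(raw)
        assert d.complete is complete
        assert d.year == year


class TestDeduplicate:
    def test_most_recent_fda_dt_wins(self):
        older = make_report("100", caseid="7", fda="20230101")
        newer = make_report("99", caseid="7", fda="20230301")
        assert pv.deduplicate([older, newer]) == [newer]

    def test_fda_dt_tie_broken_by_largest_primaryid(self):
        a = make_report("100", caseid="7", fda="20230101")
        b = make_report("250", caseid="7", fda="20230101")
        assert pv.deduplicate([a, b]) == [b]

    def test_numeric_primaryid_comparison(self):
        # lexicographically "9" > "250" but numerically 250 > 9
        a = make_report("9", caseid="7", fda="20230101")
        b = make_report("250", caseid="7", fda="20230101")
        assert pv.deduplicate([a, b]) == [b]

    def test_unique_caseids_pass_through(self):
        reports = [make_report(str(i), caseid=str(i)) for i in range(5)]
        assert pv.deduplicate(reports) == sorted(reports, key=lambda r: r.caseid)

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 30),
                              st.integers(1, 999)), max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_dedup_idempotent_and_sized_by_distinct_caseids(self, triples):
        reports = [
            make_report(str(pid), caseid=str(case),
                        fda=f"2023{1 + day // 28:02d}{1 + day % 28:02d}")
            for case, day, pid in triples]
        out = pv.deduplicate(reports)
        assert len(out) == len({r.caseid for r in reports})
        assert pv.deduplicate(out) == out
        assert [r.caseid for r in out] == sorted(r.caseid for r in out)


class TestPrimarySuspect:
    def test_ps_role_included_concomitant_excluded(self):
        ps = make_report("1", drugs=[("drugx", "PS")])
        conc = make_report("2", drugs=[("drugx", "C")])
        ss = make_report("3", drugs=[("drugx", "SS")])
        assert pv.select_primary_suspect([ps, conc, ss], ["drugx"]) == [ps]

    def test_report_with_ps_and_other_concomitant_included_once(self):
        r = make_report("1", drugs=[("drugx", "PS"), ("drugy", "C")])
        assert pv.select_primary_suspect([r], ["drugx"]) == [r]

    def test_name_normalization_matches(self):
        r = make_report("1", drugs=[("  Drug   X ", "PS")])
        assert pv.select_primary_suspect([r], ["drug x"]) == [r]

    def test_empty_drug_names_rejected(self):
        with pytest.raises(ValueError):
            pv.select_primary_suspect([], [])

    def test_subset_of_store(self):
        store = [make_report(str(i), drugs=[("drugx", "PS" if i % 2 else "C")])
                 for i in range(10)]
        subset = pv.select_primary_suspect(store, ["drugx"])
        assert set(r.primaryid for r in subset) <= set(r.primaryid for r in store)


class TestDemographics:
    def test_percentages_match_hand_tally(self):
        reports = ([make_report(str(i), gender="M") for i in range(3)]
                   + [make_report("9", gender="F")])
        df = pv.summarize_demographics(reports)
        gender = df[df.section == "Gender"].set_index("category")
        assert gender.loc["Male", "count"] == 3
        assert gender.loc["Male", "percent"] == 75.0
        assert gender.loc["Female", "percent"] == 25.0

    def test_all_missing_weight_marked_unknown_and_mean_undefined(self):
        reports = [make_report(str(i)) for i in range(4)]
        df = pv.summarize_demographics(reports)
        wt = df[df.section == "Weight"].set_index("category")
        assert wt.loc["Unknown", "percent"] == 100.0
        assert df.attrs["weight_mean"] is None
        assert df.attrs["weight_sd"] is None

    def test_outcome_precedence_most_severe_wins(self):
        r = make_report("1", outcomes={"HO", "DE", "OT"})
        df = pv.summarize_demographics([r])
        out = df[df.section == "Outcome"].set_index("category")
        assert out.loc["Death", "count"] == 1
        assert out.loc["Hospitalization", "count"] == 0

    def test_category_partitions_sum_to_100(self):
        import numpy as np
        rng = np.random.default_rng(5)
        reports = [make_report(str(i), gender=rng.choice(["M", "F", "UNK"]),
                               age=float(rng.integers(1, 95)) if rng.random() < 0.7 else None,
                               outcomes={str(rng.choice(["DE", "HO", "OT"]))}
                               if rng.random() < 0.5 else ())
                   for i in range(137)]
        df = pv.summarize_demographics(reports)
        for _, section in df.groupby("section"):
            assert abs(section["percent"].sum() - 100.0) <= 0.05

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            pv.summarize_demographics([])


class TestAnnualCounts:
    def test_zero_filled_interior_years(self):
        reports = [make_report("1", fda="20200101"),
                   make_report("2", fda="20200601"),
                   make_report("3", fda="20201201"),
                   make_report("4", fda="20220301")]
        assert pv.annual_counts(reports) == {2020: 3, 2021: 0, 2022: 1}

    def test_empty_store_empty_map(self):
        assert pv.annual_counts([]) == {}

    def test_partial_dates_still_counted_by_year(self):
        reports = [make_report("1", fda="202006"), make_report("2", fda="2021")]
        assert pv.annual_counts(reports) == {2020: 1, 2021: 1}


class TestMeddraDict:
    def test_lookup_and_unmapped_error(self, tmp_path):
        p = tmp_path / "dict.tsv"
        p.write_text("pt\tsoc\nNausea\tGastrointestinal disorders\n")
        d = pv.MeddraDict.from_tsv(p)
        assert d.soc_of("NAUSEA") == "Gastrointestinal disorders"
        from pvsignal.errors import MeddraLookupError
        with pytest.raises(MeddraLookupError):
            d.soc_of("Vertigo")
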