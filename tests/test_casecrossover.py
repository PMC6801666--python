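"""Line-list validation, ICD-10 grouping, and referent selection."""

import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import heatcross as hc
from heatcross.casecrossover import diagnostic_group_flags


class TestLoadPresentations:
    CSV = (
        "presentation_id,date,region_id,age,gender,seifa_decile,icd10\n"
        "p1,2010-01-05,hobart,34,F,4,J45.9\n"
        "p2,2010-01-06,hobart,2,male,9,\n"
        "p3,not-a-date,hobart,50,M,5,I20\n"
        "p4,2010-01-07,launceston,61,x,2,T67\n"
        "p5,2010-01-08,hobart,-3,F,5,I20\n"
        "p6,2010-01-09,hobart,70,F,11,I20\n"
        "p7,2010-01-10,hobart,8,F,,N17\n"
    )

    def test_valid_and_rejected_counts(self):
        records, rejects = hc.load_presentations(io.StringIO(self.CSV))
        assert len(records) == 4
        assert len(rejects) == 3
        reasons = " | ".join(r for _, r in rejects)
        assert "date" in reasons and "age" in reasons and "seifa" in reasons

    def test_reject_line_numbers_count_header(self):
        _, rejects = hc.load_presentations(io.StringIO(self.CSV))
        assert [line for line, _ in rejects] == [4, 6, 7]

    def test_unknown_gender_retained(self):
        records, _ = hc.load_presentations(io.StringIO(self.CSV))
        assert records.set_index("presentation_id").loc["p4", "gender"] == "unknown"

    def test_blank_seifa_and_icd_become_missing(self):
        records, _ = hc.load_presentations(io.StringIO(self.CSV))
        row = records.set_index("presentation_id").loc["p7"]
        assert pd.isna(row["seifa_decile"])
        row2 = records.set_index("presentation_id").loc["p2"]
        assert pd.isna(row2["icd10"])

    def test_empty_file(self):
        header = "presentation_id,date,region_id,age,gender,seifa_decile,icd10\n"
        records, rejects = hc.load_presentations(io.StringIO(header))
        assert records.empty and rejects == []


class TestDiagnosticGroups:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("J45.9", {"All respiratory", "Asthma"}),
            ("T67", {"Heat and light disorders"}),
            ("X30", {"Heat and light disorders"}),
            (
                "F02",
                {"All mental disorders", "Dementia", "Organic mental disorders"},
            ),
            ("I48", {"All cardiovascular", "Atrial fibrillation"}),
            ("G45", {"All cardiovascular"}),
            ("J67", {"All respiratory", "COPD"}),
            ("E12", set()),  # between the two diabetes ranges
            ("Z00", set()),
        ],
    )
    def test_range_membership(self, code, expected):
        assert hc.map_diagnostic_groups(code) == expected

    def test_unknown_code_empty(self):
        assert hc.map_diagnostic_groups(None) == set()
        assert hc.map_diagnostic_groups("") == set()

    def test_vectorized_flags_agree_with_scalar(self):
        codes = pd.Series(["J45.9", "T67", "F02", "Z00", None, "I10"])
        flags = diagnostic_group_flags(codes)
        for i, code in enumerate(codes):
            expected = hc.map_diagnostic_groups(code)
            got = set(flags.columns[flags.iloc[i]])
            assert got == expected


class TestReferentSelection:
    def test_mid_month_wednesday(self):
        assert hc.select_referents("2009-01-14") == [
            dt.date(2009, 1, 7),
            dt.date(2009, 1, 21),
            dt.date(2009, 1, 28),
        ]

    def test_first_wednesday(self):
        assert hc.select_referents("2009-01-07") == [
            dt.date(2009, 1, 14),
            dt.date(2009, 1, 21),
            dt.date(2009, 1, 28),
        ]

    @given(
        st.dates(min_value=dt.date(2008, 1, 1), max_value=dt.date(2016, 12, 31))
    )
    @settings(max_examples=200, derandomize=True)
    def test_referent_invariants(self, day):
        refs = hc.select_referents(day)
        assert day not in refs
        assert len(refs) in (3, 4)
        for r in refs:
            assert r.weekday() == day.weekday()
            assert (r.year, r.month) == (day.year, day.month)
        assert refs == sorted(refs)

    @given(
        st.dates(min_value=dt.date(2008, 1, 1), max_value=dt.date(2016, 12, 31))
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetry(self, day):
        for r in hc.select_referents(day):
            assert day in hc.select_referents(r)

    def test_stratum_size_matches_weekday_count(self):
        """Months with five occurrences of the weekday give 4 referents."""
        for day in pd.date_range("2012-01-01", "2012-12-31", freq="D"):
            n_same = sum(
                1
                for d in pd.date_range(
                    day.replace(day=1), day.replace(day=day.days_in_month)
                )
                if d.weekday() == day.weekday()
            )
            assert len(hc.select_referents(day)) == n_same - 1


class TestSeifa:
    @pytest.mark.parametrize(
        "decile,band",
        [(1, "low"), (3, "low"), (4, "middle"), (7, "middle"), (8, "high"), (10, "high")],
    )
    def test_bands(self, decile, band):
        assert hc.condense_seifa(decile) == band

    def test_unknown(self):
        assert hc.condense_seifa(None) == "unknown"
        assert hc.condense_seifa(np.nan) == "unknown"
        assert hc.condense_seifa(0) == "unknown"


class TestBuildDataset:
    def _exposure(self, dates, region="hobart", exposed_dates=()):
        exposed_set = {pd.Timestamp(d) for d in exposed_dates}
        return pd.DataFrame(
            {
                "region_id": region,
                "date": pd.to_datetime(list(dates)),
                "exposed": [pd.Timestamp(d) in exposed_set for d in dates],
                "pm25": 5.0,
                "holiday": False,
            }
        )

    def _presentations(self, rows):
        return pd.DataFrame(
            rows,
            columns=["presentation_id", "date", "region_id", "age", "gender", "seifa_decile", "icd10"],
        )

    def test_single_presentation_stratum(self):
        pres = self._presentations([("p1", "2010-06-09", "hobart", 30, "female", 5, "J45")])
        expo = self._exposure(pd.date_range("2010-06-01", "2010-06-30"))
        ds = hc.build_analysis_dataset(pres, expo)
        assert ds.n_strata == 1
        assert len(ds.data) in (4, 5)
        assert ds.data["is_case"].sum() == 1
        # all member days share weekday/month/year
        dates = pd.to_datetime(ds.data["date"])
        assert dates.dt.weekday.nunique() == 1
        assert dates.dt.month.nunique() == 1 and dates.dt.year.nunique() == 1

    def test_subgroup_filter(self):
        pres = self._presentations(
            [
                ("p1", "2010-06-09", "hobart", 3, "female", 5, ""),
                ("p2", "2010-06-09", "hobart", 40, "male", 5, ""),
            ]
        )
        expo = self._exposure(pd.date_range("2010-06-01", "2010-06-30"))
        ds = hc.build_analysis_dataset(pres, expo, lambda df: df["age"] <= 5)
        assert ds.n_strata == 1
        assert set(ds.data["stratum_id"]) == {"p1"}

    def test_constant_exposure_not_informative(self):
        pres = self._presentations([("p1", "2010-06-09", "hobart", 30, "female", 5, "")])
        expo = self._exposure(pd.date_range("2010-06-01", "2010-06-30"))
        ds = hc.build_analysis_dataset(pres, expo)
        assert ds.n_informative == 0

    def test_varying_exposure_informative(self):
        pres = self._presentations([("p1", "2010-06-09", "hobart", 30, "female", 5, "")])
        expo = self._exposure(
            pd.date_range("2010-06-01", "2010-06-30"), exposed_dates=["2010-06-09"]
        )
        ds = hc.build_analysis_dataset(pres, expo)
        assert ds.n_informative == 1
        case_row = ds.data[ds.data["is_case"] == 1]
        assert case_row["exposed"].iloc[0] == 1

    def test_missing_exposure_day_reported(self):
        pres = self._presentations([("p1", "2010-06-09", "hobart", 30, "female", 5, "")])
        expo = self._exposure(pd.date_range("2010-06-01", "2010-06-15"))
        with pytest.raises(ValueError, match="missing"):
            hc.build_analysis_dataset(pres, expo)

    def test_row_conservation(self, small_study, small_exposure):
        _, study = small_study
        pres = study["presentations"].head(500)
        ds = hc.build_analysis_dataset(pres, small_exposure)
        assert ds.n_strata == len(pres)
        sizes = ds.data.groupby("stratum_id").size()
        assert set(sizes.unique()) <= {4, 5}
        assert (ds.data.groupby("stratum_id")["is_case"].sum() == 1).all()

    def test_empty_filter_gives_empty_dataset(self):
        pres = self._presentations([("p1", "2010-06-09", "hobart", 30, "female", 5, "")])
        expo = self._exposure(pd.date_range("2010-06-01", "2010-06-30"))
        ds = hc.build_analysis_dataset(pres, expo, lambda df: df["age"] > 99)
        assert ds.n_strata == 0 and ds.data.empty
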