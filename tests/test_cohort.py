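"""Cohort rules: loading, eligibility quota, index/age computation, condition selection."""

import numpy as np
import pandas as pd
import pytest

import multimorbnet as mm
from multimorbnet.cohort import DAYS_PER_YEAR, SchemaError, age_stratum


def _events(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "visit_date", "visit_type", "icd10_code"])
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    return df


def _patients(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "sex", "birth_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


def _catalog(rows):
    return mm.ConditionCatalog(
        pd.DataFrame(rows, columns=["code", "chapter", "chronic_flag", "is_t2dm_index"])
    )


BASIC_CATALOG = _catalog(
    [
        ("E11", 4, True, True),
        ("I10", 9, True, False),
        ("J06", 10, False, False),
        ("K29", 11, True, False),
    ]
)


class TestLoadRecords:
    def test_round_trip_toy_csv(self, tmp_path):
        ev = _events([(f"P{i}", "2015-03-01", "outpatient", "E11") for i in range(5)])
        pat = _patients([(f"P{i}", "male", "1960-01-01") for i in range(5)])
        ev.to_csv(tmp_path / "e.csv", index=False)
        pat.to_csv(tmp_path / "p.csv", index=False)
        BASIC_CATALOG.df.to_csv(tmp_path / "c.csv", index=False)
        events, patients, catalog = mm.load_records(
            tmp_path / "e.csv", tmp_path / "p.csv", tmp_path / "c.csv"
        )
        assert len(patients) == 5 and len(events) == 5
        assert catalog.t2dm_codes == {"E11"}

    def test_unknown_visit_type_is_schema_error(self, tmp_path):
        ev = _events([("P1", "2015-03-01", "ER", "E11")])
        ev.to_csv(tmp_path / "e.csv", index=False)
        _patients([("P1", "male", "1960-01-01")]).to_csv(tmp_path / "p.csv", index=False)
        BASIC_CATALOG.df.to_csv(tmp_path / "c.csv", index=False)
        with pytest.raises(SchemaError, match="outpatient"):
            mm.load_records(tmp_path / "e.csv", tmp_path / "p.csv", tmp_path / "c.csv")

    def test_missing_column_is_schema_error(self, tmp_path):
        _events([("P1", "2015-03-01", "outpatient", "E11")]).drop(columns=["visit_type"]).to_csv(
            tmp_path / "e.csv", index=False
        )
        _patients([("P1", "male", "1960-01-01")]).to_csv(tmp_path / "p.csv", index=False)
        BASIC_CATALOG.df.to_csv(tmp_path / "c.csv", index=False)
        with pytest.raises(SchemaError, match="visit_type"):
            mm.load_records(tmp_path / "e.csv", tmp_path / "p.csv", tmp_path / "c.csv")

    def test_empty_events_file(self, tmp_path):
        pd.DataFrame(columns=["patient_id", "visit_date", "visit_type", "icd10_code"]).to_csv(
            tmp_path / "e.csv", index=False
        )
        _patients([("P1", "male", "1960-01-01")]).to_csv(tmp_path / "p.csv", index=False)
        BASIC_CATALOG.df.to_csv(tmp_path / "c.csv", index=False)
        events, patients, _ = mm.load_records(tmp_path / "e.csv", tmp_path / "p.csv", tmp_path / "c.csv")
        assert events.empty and len(patients) == 1


class TestEligibility:
    PAT = _patients([("P1", "male", "1960-01-01")])

    def _eligible(self, events, patients=None):
        eligible, excl = mm.apply_eligibility(events, patients if patients is not None else self.PAT)
        return set(eligible["patient_id"]), excl

    def test_three_outpatient_per_year_qualifies(self):
        rows = [
            ("P1", f"{y}-0{m}-15", "outpatient", "E11")
            for y in (2014, 2015, 2016)
            for m in (2, 5, 8)
        ]
        ids, _ = self._eligible(_events(rows))
        assert ids == {"P1"}

    def test_hospitalization_clause_rescues_short_year(self):
        rows = [("P1", f"2014-0{m}-01", "outpatient", "E11") for m in (1, 4, 7)]
        rows += [
            ("P1", "2015-02-01", "outpatient", "E11"),
            ("P1", "2015-03-01", "outpatient", "E11"),
            ("P1", "2015-06-01", "inpatient", "E11"),
        ]
        rows += [("P1", f"2016-0{m}-01", "outpatient", "E11") for m in (2, 5, 9)]
        ids, _ = self._eligible(_events(rows))
        assert ids == {"P1"}

    def test_gap_year_disqualifies(self):
        rows = [("P1", f"2014-0{m}-01", "outpatient", "E11") for m in (1, 4, 7)]
        rows += [("P1", f"2016-0{m}-01", "outpatient", "E11") for m in (2, 5, 9)]
        ids, excl = self._eligible(_events(rows))
        assert ids == set()
        assert excl["reason"].tolist() == ["insufficient_visits"]

    def test_conflicting_sex_excluded(self):
        pats = _patients([("P1", "male", "1960-01-01"), ("P1", "female", "1960-01-01")])
        rows = [("P1", f"2014-0{m}-01", "outpatient", "E11") for m in (1, 4, 7)]
        ids, excl = self._eligible(_events(rows), pats)
        assert ids == set()
        assert excl["reason"].tolist() == ["conflicting_sex"]

    def test_missing_sex_excluded(self):
        pats = _patients([("P1", None, "1960-01-01")])
        rows = [("P1", f"2014-0{m}-01", "outpatient", "E11") for m in (1, 4, 7)]
        ids, excl = self._eligible(_events(rows), pats)
        assert ids == set()
        assert excl["reason"].tolist() == ["missing_age_or_sex"]

    def test_adding_outpatient_visits_is_monotone(self):
        # adding visits within the existing span can never disqualify
        base = [
            ("P1", f"{y}-0{m}-15", "outpatient", "E11")
            for y in (2014, 2015)
            for m in (2, 5, 8)
        ]
        ids, _ = self._eligible(_events(base))
        assert ids == {"P1"}
        rng = np.random.default_rng(0)
        extra = [
            ("P1", f"{rng.choice([2014, 2015])}-0{rng.integers(1, 10)}-{rng.integers(10, 28)}",
             "outpatient", "I10")
            for _ in range(10)
        ]
        ids2, _ = self._eligible(_events(base + extra))
        assert ids2 == {"P1"}


class TestIndexAndAge:
    def test_mean_age_is_midpoint_of_index_and_last_visit(self):
        index_date = pd.Timestamp("2014-06-01")
        birth = index_date - pd.to_timedelta(round(50.0 * DAYS_PER_YEAR), unit="D")
        rows = [
            ("P1", "2014-06-01", "outpatient", "E11"),
            ("P1", "2020-06-01", "outpatient", "I10"),
        ]
        pats = _patients([("P1", "male", birth)])
        cohort, excl = mm.compute_index_and_age(_events(rows), pats, ("E11",))
        assert excl.empty
        row = cohort.iloc[0]
        assert row["index_date"] == index_date
        assert row["mean_age"] == pytest.approx(53.0, abs=0.01)
        assert row["age_stratum"] == "50-59"

    def test_index_equals_last_visit(self):
        birth = pd.Timestamp("2015-03-01") - pd.to_timedelta(round(40.0 * DAYS_PER_YEAR), unit="D")
        cohort, _ = mm.compute_index_and_age(
            _events([("P1", "2015-03-01", "outpatient", "E11")]),
            _patients([("P1", "male", birth)]),
            ("E11",),
        )
        assert cohort.iloc[0]["mean_age"] == pytest.approx(40.0, abs=0.01)
        assert cohort.iloc[0]["age_stratum"] == "40-49"

    def test_index_is_earliest_t2dm_code_not_earliest_visit(self):
        rows = [
            ("P1", "2014-01-01", "outpatient", "I10"),
            ("P1", "2015-06-01", "outpatient", "E11"),
            ("P1", "2016-01-01", "outpatient", "E11"),
        ]
        cohort, _ = mm.compute_index_and_age(
            _events(rows), _patients([("P1", "male", "1960-01-01")]), ("E11",)
        )
        assert cohort.iloc[0]["index_date"] == pd.Timestamp("2015-06-01")

    def test_no_t2dm_code_excluded_with_reason(self):
        cohort, excl = mm.compute_index_and_age(
            _events([("P1", "2015-01-01", "outpatient", "I10")]),
            _patients([("P1", "male", "1960-01-01")]),
            ("E11",),
        )
        assert cohort.empty
        assert excl["reason"].tolist() == ["no_t2dm_code"]

    @pytest.mark.parametrize(
        "age, band",
        [(18, "<40"), (39.99, "<40"), (40.0, "40-49"), (49.999, "40-49"),
         (59.2, "50-59"), (69.9, "60-69"), (79.0, "70-79"), (80.0, ">=80"), (101.0, ">=80")],
    )
    def test_age_bands_partition(self, age, band):
        assert age_stratum(age) == band


class TestSelectConditions:
    def _cohort_one(self, index="2014-01-01"):
        return pd.DataFrame(
            {
                "patient_id": ["P1"],
                "sex": ["male"],
                "index_date": [pd.Timestamp(index)],
                "mean_age": [55.0],
                "age_stratum": ["50-59"],
            }
        )

    def test_low_prevalence_code_excluded(self):
        # I10 in 100% of patients, K29 in one of many -> below 2% threshold
        rows = []
        pats = []
        for i in range(60):
            rows.append((f"P{i}", "2015-01-01", "outpatient", "I10"))
            pats.append(f"P{i}")
        rows.append(("P0", "2015-02-01", "outpatient", "K29"))
        cohort = pd.DataFrame(
            {
                "patient_id": pats,
                "sex": "male",
                "index_date": pd.Timestamp("2014-01-01"),
                "mean_age": 55.0,
                "age_stratum": "50-59",
            }
        )
        sel = mm.select_conditions(_events(rows), cohort, BASIC_CATALOG, min_prevalence=0.02)
        assert "I10" in sel.universe and "K29" not in sel.universe

    def test_chapter_above_14_excluded(self):
        catalog = _catalog(
            [("E11", 4, True, True), ("O80", 15, False, False), ("I10", 9, True, False)]
        )
        rows = [("P1", "2015-01-01", "outpatient", "O80"), ("P1", "2015-01-01", "outpatient", "I10")]
        sel = mm.select_conditions(_events(rows), self._cohort_one(), catalog)
        assert sel.universe == ["I10"]

    def test_pre_index_diagnoses_do_not_count(self):
        rows = [
            ("P1", "2013-06-01", "outpatient", "I10"),  # before index
            ("P1", "2015-01-01", "outpatient", "K29"),
        ]
        sel = mm.select_conditions(_events(rows), self._cohort_one("2014-01-01"), BASIC_CATALOG)
        assert sel.universe == ["K29"]
        assert sel.condition_sets["code"].tolist() == ["K29"]

    def test_granularity_rule_drops_mixed_stem(self):
        # K29 has both an acute (K29.0) and a chronic (K29.5) subcode: the bare
        # stem is dropped and the subcodes analyzed separately. J06 has no
        # subdivision and is kept as a three-character code.
        catalog = _catalog(
            [
                ("E11", 4, True, True),
                ("K29", 11, True, False),
                ("K29.0", 11, False, False),
                ("K29.5", 11, True, False),
                ("J06", 10, False, False),
            ]
        )
        assert catalog.analyzable_codes() == {"K29.0", "K29.5", "J06"}

    def test_t2dm_index_code_excluded_but_subcodes_analyzable(self):
        catalog = _catalog(
            [
                ("E11", 4, True, True),
                ("E11.2", 4, True, False),
                ("I10", 9, True, False),
            ]
        )
        rows = [
            ("P1", "2015-01-01", "outpatient", "E11"),
            ("P1", "2015-02-01", "outpatient", "E11.2"),
            ("P1", "2015-03-01", "outpatient", "I10"),
        ]
        sel = mm.select_conditions(_events(rows), self._cohort_one(), catalog)
        assert sel.universe == ["E11.2", "I10"]

    def test_unknown_code_warn_then_error_mode(self):
        rows = [("P1", "2015-01-01", "outpatient", "Z99"), ("P1", "2015-01-01", "outpatient", "I10")]
        sel = mm.select_conditions(_events(rows), self._cohort_one(), BASIC_CATALOG)
        assert sel.dropped_unknown == ["Z99"]
        with pytest.raises(KeyError):
            mm.select_conditions(
                _events(rows), self._cohort_one(), BASIC_CATALOG, on_missing="error"
            )

    def test_pair_eligibility_requires_chronic_anchor(self):
        # P1: chronic I10 + acute J06 -> pair-eligible; P2: acute J06 only in
        # duplicate -> single condition; P3: two acute codes, no chronic anchor
        catalog = _catalog(
            [
                ("E11", 4, True, True),
                ("I10", 9, True, False),
                ("J06", 10, False, False),
                ("L02", 12, False, False),
            ]
        )
        rows = [
            ("P1", "2015-01-01", "outpatient", "I10"),
            ("P1", "2015-02-01", "outpatient", "J06"),
            ("P2", "2015-01-01", "outpatient", "J06"),
            ("P3", "2015-01-01", "outpatient", "J06"),
            ("P3", "2015-02-01", "outpatient", "L02"),
        ]
        cohort = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3"],
                "sex": "male",
                "index_date": pd.Timestamp("2014-01-01"),
                "mean_age": 55.0,
                "age_stratum": "50-59",
            }
        )
        sel = mm.select_conditions(_events(rows), cohort, catalog, min_prevalence=0.01)
        assert sel.pair_eligible == {"P1"}
        relaxed = mm.select_conditions(
            _events(rows), cohort, catalog, min_prevalence=0.01, require_chronic_anchor=False
        )
        assert relaxed.pair_eligible == {"P1", "P3"}

    def test_selection_idempotent(self, small_cohort):
        events, cohort, catalog, selection, _ = small_cohort
        again = mm.select_conditions(events, cohort, catalog)
        assert again.universe == selection.universe
        pd.testing.assert_frame_equal(again.condition_sets, selection.condition_sets)
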