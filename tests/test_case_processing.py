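"""Deduplication, case assembly, age normalization, target screening."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.case_processing import (
    AGE_GROUPS,
    age_group,
    age_to_years,
    assemble_cases,
    case_matches_target,
    deduplicate,
    partition_by_target,
)
from pvsignal.faers_io import (
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    ReacRecord,
    RecordStore,
    TherRecord,
)
from tests.conftest import make_case


def demo(pid, caseid, ymd):
    return DemoRecord(pid, caseid, PartialDate(*ymd))


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        decisions = deduplicate(
            [demo("10", "C1", (2021, 1, 1)), demo("11", "C1", (2021, 3, 1))]
        )
        assert decisions[0].kept_primaryid == "11"
        assert decisions[0].discarded_primaryids == ("10",)

    def test_tie_broken_by_higher_primaryid(self):
        decisions = deduplicate(
            [demo("21", "C2", (2021, 1, 1)), demo("20", "C2", (2021, 1, 1))]
        )
        assert decisions[0].kept_primaryid == "21"

    def test_single_version_kept(self):
        decisions = deduplicate([demo("30", "C3", (2021, 1, 1))])
        assert decisions[0].kept_primaryid == "30"
        assert decisions[0].discarded_primaryids == ()

    def test_idempotent(self):
        records = [demo(str(100 + i), f"C{i}", (2021, 1, 1 + i)) for i in range(20)]
        first = deduplicate(records)
        kept = {d.kept_primaryid for d in first}
        again = deduplicate([r for r in records if r.primaryid in kept])
        assert {d.kept_primaryid for d in again} == kept

    def test_matches_bruteforce_group_max(self):
        """Random versioned cases agree with a sort-each-group-take-last oracle."""
        rng = random.Random(42)
        records = []
        for case_i in range(120):
            for version in range(rng.randint(1, 4)):
                records.append(
                    demo(
                        str(rng.randrange(10**6)),
                        f"C{case_i}",
                        (2021, rng.randint(1, 12), rng.randint(1, 28)),
                    )
                )
        rng.shuffle(records)
        expected = {}
        groups: dict[str, list[DemoRecord]] = {}
        for r in records:
            groups.setdefault(r.caseid, []).append(r)
        for caseid, grp in groups.items():
            expected[caseid] = sorted(
                grp, key=lambda r: (r.fda_dt.sort_key(), int(r.primaryid))
            )[-1].primaryid
        got = {d.caseid: d.kept_primaryid for d in deduplicate(records)}
        assert got == expected

    def test_non_numeric_primaryid_uses_padded_strings(self):
        decisions = deduplicate(
            [demo("A9", "C1", (2021, 1, 1)), demo("B10", "C1", (2021, 1, 1))]
        )
        # zero-padded: "0A9" < "B10"
        assert decisions[0].kept_primaryid == "B10"


class TestAgeToYears:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (6, "MON", 0.5),
            (2, "DEC", 20.0),
            (36, "YR", 36.0),
            (52.14, "WK", 1.0),
            (365.25, "DY", 1.0),
            (8766, "HR", 1.0),
            (None, "YR", None),
            (-5, "YR", None),
            (200, "YR", None),  # implausible
            (15, None, 15.0),  # missing unit treated as years
        ],
    )
    def test_conversions(self, value, unit, expected):
        got = age_to_years(value, unit)
        assert got == pytest.approx(expected) if expected is not None else got is None

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=100, allow_nan=False),
        st.floats(min_value=0, max_value=100, allow_nan=False),
        st.sampled_from(["DEC", "YR", "MON", "WK", "DY", "HR"]),
    )
    def test_monotone_in_value(self, v1, v2, unit):
        lo, hi = sorted([v1, v2])
        y_lo, y_hi = age_to_years(lo, unit), age_to_years(hi, unit)
        if y_lo is not None and y_hi is not None:
            assert y_lo <= y_hi

    def test_age_group_boundaries_half_open(self):
        assert age_group(17.99) == AGE_GROUPS[0]
        assert age_group(18.0) == AGE_GROUPS[1]
        assert age_group(44.99) == AGE_GROUPS[1]
        assert age_group(45.0) == AGE_GROUPS[2]
        assert age_group(65.0) == AGE_GROUPS[3]
        assert age_group(None) is None


class TestAssemble:
    def _store(self):
        store = RecordStore()
        store.demo = [demo("101", "C1", (2021, 5, 1))]
        store.drug = [DrugRecord("101", 1, "EVRYSDI", "RISDIPLAM", "PS")]
        store.reac = [
            ReacRecord("101", "Pyrexia"),
            ReacRecord("101", "Pyrexia"),
            ReacRecord("101", "Diarrhoea"),
        ]
        store.ther = [TherRecord("101", 1, PartialDate(2021, 1, 1))]
        return store

    def test_within_report_pt_collapse(self):
        store = self._store()
        cases = assemble_cases(store, deduplicate(store.demo))
        assert sorted(cases[0].events) == ["Diarrhoea", "Pyrexia"]

    def test_serious_iff_any_outcome(self):
        store = self._store()
        cases = assemble_cases(store, deduplicate(store.demo))
        assert not cases[0].serious
        store.outc = [OutcRecord("101", "HO")]
        cases = assemble_cases(store, deduplicate(store.demo))
        assert cases[0].serious

    def test_report_year_from_fda_dt(self):
        store = self._store()
        cases = assemble_cases(store, deduplicate(store.demo))
        assert cases[0].report_year == 2021

    def test_only_kept_version_joined(self):
        store = self._store()
        store.demo.append(demo("102", "C1", (2021, 8, 1)))
        store.reac.append(ReacRecord("102", "Asthenia"))
        cases = assemble_cases(store, deduplicate(store.demo))
        assert len(cases) == 1
        assert cases[0].primaryid == "102"
        assert cases[0].events == ("Asthenia",)


class TestScreening:
    def test_ps_role_required(self):
        sel = make_case(drugs=(DrugRecord("1", 1, "EVRYSDI", "RISDIPLAM", "PS"),))
        conc = make_case(drugs=(DrugRecord("2", 1, "EVRYSDI", "Risdiplam", "C"),))
        assert case_matches_target(sel, "risdiplam")
        assert not case_matches_target(conc, "risdiplam")

    def test_drugname_fallback_when_prod_ai_missing(self):
        case = make_case(
            drugs=(DrugRecord("3", 1, "EVRYSDI (RISDIPLAM)", None, "PS"),)
        )
        assert case_matches_target(case, "risdiplam")

    def test_whitespace_and_case_insensitive(self):
        case = make_case(drugs=(DrugRecord("4", 1, "x", "  RISDIPLAM   salt ", "PS"),))
        assert case_matches_target(case, "risdiplam salt")

    def test_partition_is_exact(self):
        cases = [
            make_case("1"),
            make_case("2", drugs=(DrugRecord("2", 1, "OTHER", "OTHER", "PS"),)),
            make_case("3"),
        ]
        target, background = partition_by_target(cases, "risdiplam")
        assert {c.primaryid for c in target} == {"1", "3"}
        assert {c.primaryid for c in background} == {"2"}
        assert len(target) + len(background) == len(cases)

    def test_empty_keyword_rejected(self):
        with pytest.raises(ValueError):
            partition_by_target([make_case()], "  ")
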