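"""Shared fixtures: tiny in-memory cases, toy dictionary, small file sets."""

from __future__ import annotations

import pytest

from pvsignal.case_processing import CaseReport
from pvsignal.faers_io import DrugRecord, PartialDate
from pvsignal.meddra import MeddraTable


def make_case(
    primaryid: str = "1001",
    caseid: str | None = None,
    events: tuple[str, ...] = (),
    sex: str = "UNK",
    age_years: float | None = None,
    country: str | None = None,
    outcomes: frozenset[str] = frozenset(),
    drugs: tuple[DrugRecord, ...] | None = None,
    fda_dt: PartialDate = PartialDate(2021, 6, 1),
    event_dt: PartialDate | None = None,
    reporter_type: str = "missing",
    therapy_starts: tuple[tuple[int, PartialDate], ...] = (),
) -> CaseReport:
    """A CaseReport with sensible defaults for unit tests."""
    if drugs is None:
        drugs = (DrugRecord(primaryid, 1, "EVRYSDI", "RISDIPLAM", "PS"),)
    return CaseReport(
        primaryid=primaryid,
        caseid=caseid or primaryid,
        fda_dt=fda_dt,
        event_dt=event_dt,
        sex=sex,
        age_years=age_years,
        reporter_type=reporter_type,
        country=country,
        drugs=drugs,
        events=events,
        outcomes=outcomes,
        therapy_starts=therapy_starts,
    )


@pytest.fixture
def case_factory():
    return make_case


@pytest.fixture
def toy_meddra() -> MeddraTable:
    return MeddraTable(
        pt_to_soc={
            "Pyrexia": "General disorders and administration site conditions",
            "Diarrhoea": "Gastrointestinal disorders",
            "Cardiac arrest": "Cardiac disorders",
            "Nephrolithiasis": "Renal and urinary disorders",
            "Asthenia": "General disorders and administration site conditions",
        },
        synonym_to_pt={"Renal calculus": "Nephrolithiasis"},
        version_label="test",
    )
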