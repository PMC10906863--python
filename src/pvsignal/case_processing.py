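"""Case deduplication, assembly, age normalization and target-drug screening.

A FAERS case (CASEID) can appear several times across quarterly releases
as follow-up versions with distinct report identifiers (PRIMARYID).  The
FDA-recommended rule keeps, per case, the version with the most recent
FDA receipt date (FDA_DT), breaking ties by the higher PRIMARYID.  After
deduplication, the surviving reports are joined across tables into one
:class:`CaseReport` each, ages are normalized to years, seriousness is
derived from the presence of outcome codes, and the target-drug screen
partitions cases into the study set and the comparator background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._utils import norm_text
from .faers_io import DemoRecord, DrugRecord, PartialDate, RecordStore

log = logging.getLogger(__name__)

#: Conversion divisors from FAERS age units to years.  DEC (decades) is a
#: multiplier; week/day/hour divisors use calendar-accurate values.
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 120.0

AGE_GROUPS = ("< 18", "≥ 18 and < 45", "≥ 45 and < 65", "≥ 65")


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report with all tables joined."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate
    event_dt: PartialDate | None
    sex: str
    age_years: float | None
    reporter_type: str
    country: str | None
    drugs: tuple[DrugRecord, ...]
    events: tuple[str, ...]  # unique PTs, first-occurrence order collapsed, sorted
    outcomes: frozenset[str]
    therapy_starts: tuple[tuple[int, PartialDate], ...]  # (drug_seq, start)

    @property
    def serious(self) -> bool:
        return bool(self.outcomes)

    @property
    def report_year(self) -> int:
        return self.fda_dt.year

    def therapy_start_for(self, drug_seq: int) -> PartialDate | None:
        for seq, start in self.therapy_starts:
            if seq == drug_seq:
                return start
        return None


@dataclass(frozen=True)
class DedupDecision:
    caseid: str
    kept_primaryid: str
    discarded_primaryids: tuple[str, ...]


def _primaryid_keys(pids: list[str]) -> dict[str, tuple]:
    """Tie-break keys for PRIMARYID: numeric when possible, else zero-padded."""
    if all(p.isdigit() for p in pids):
        return {p: (int(p),) for p in pids}
    width = max(len(p) for p in pids)
    log.warning(
        "non-numeric primaryid among %s; tie-break uses zero-padded strings", pids
    )
    return {p: (p.rjust(width, "0"),) for p in pids}


def deduplicate(demo: list[DemoRecord]) -> list[DedupDecision]:
    """Apply the FDA duplicate rule: latest FDA_DT, then higher PRIMARYID.

    Returns one decision per distinct CASEID, sorted by CASEID, so the
    output is deterministic regardless of input order.  Idempotent: on
    already-unique input every record is kept.
    """
    groups: dict[str, list[DemoRecord]] = {}
    for rec in demo:
        groups.setdefault(rec.caseid, []).append(rec)

    decisions = []
    for caseid in sorted(groups):
        versions = groups[caseid]
        pid_keys = _primaryid_keys([v.primaryid for v in versions])
        kept = max(versions, key=lambda v: (v.fda_dt.sort_key(), pid_keys[v.primaryid]))
        discarded = tuple(
            sorted(v.primaryid for v in versions if v.primaryid != kept.primaryid)
        )
        decisions.append(DedupDecision(caseid, kept.primaryid, discarded))
    return decisions


def age_to_years(age_value: float | None, age_unit: str | None) -> float | None:
    """Convert a FAERS (age, unit) pair to years.

    Negative or implausible (> 120 y) results are treated as missing; a
    present value with a missing unit is taken as years, with a warning.
    Monotone in ``age_value`` for a fixed unit.
    """
    if age_value is None:
        return None
    if age_value < 0:
        log.warning("negative age %s discarded", age_value)
        return None
    if age_unit is None:
        log.warning("age %s has no unit; assuming years", age_value)
        factor = 1.0
    else:
        try:
            factor = _AGE_FACTORS[age_unit]
        except KeyError:
            log.warning("unknown age unit %r; treating age as missing", age_unit)
            return None
    years = age_value * factor
    if years > MAX_PLAUSIBLE_AGE:
        log.warning("implausible age %.1f years discarded", years)
        return None
    return years


def age_group(age_years: float | None) -> str | None:
    """Half-open age strata: [0,18), [18,45), [45,65), [65, inf)."""
    if age_years is None:
        return None
    if age_years < 18:
        return AGE_GROUPS[0]
    if age_years < 45:
        return AGE_GROUPS[1]
    if age_years < 65:
        return AGE_GROUPS[2]
    return AGE_GROUPS[3]


def assemble_cases(
    store: RecordStore, decisions: list[DedupDecision]
) -> list[CaseReport]:
    """Join DRUG/REAC/OUTC/THER onto the kept DEMO version of each case.

    Within-report duplicate PTs collapse to one event (the analysis unit
    downstream is the report x PT pair).  A kept report with no drug or no
    event rows is retained here — the screening stage excludes it — so the
    flow accounting stays conservative.
    """
    kept_ids = {d.kept_primaryid for d in decisions}
    demo_by_pid: dict[str, DemoRecord] = {}
    for rec in store.demo:
        if rec.primaryid in kept_ids:
            # Duplicate DEMO rows for one primaryid: first wins (logged).
            if rec.primaryid in demo_by_pid:
                log.warning("duplicate DEMO row for primaryid %s", rec.primaryid)
                continue
            demo_by_pid[rec.primaryid] = rec

    drugs: dict[str, list[DrugRecord]] = {}
    for d in store.drug:
        if d.primaryid in kept_ids:
            drugs.setdefault(d.primaryid, []).append(d)
    events: dict[str, list[str]] = {}
    seen_events: dict[str, set[str]] = {}
    for r in store.reac:
        if r.primaryid in kept_ids:
            key = norm_text(r.pt)
            if key not in seen_events.setdefault(r.primaryid, set()):
                seen_events[r.primaryid].add(key)
                events.setdefault(r.primaryid, []).append(r.pt)
    outcomes: dict[str, set[str]] = {}
    for o in store.outc:
        if o.primaryid in kept_ids:
            outcomes.setdefault(o.primaryid, set()).add(o.outcome)
    starts: dict[str, dict[int, PartialDate]] = {}
    for t in store.ther:
        if t.primaryid in kept_ids and t.start_dt is not None:
            seqs = starts.setdefault(t.primaryid, {})
            # Earliest start per drug_seq when THER repeats a sequence.
            if t.drug_seq not in seqs or t.start_dt.sort_key() < seqs[
                t.drug_seq
            ].sort_key():
                seqs[t.drug_seq] = t.start_dt

    cases = []
    for decision in decisions:
        pid = decision.kept_primaryid
        demo = demo_by_pid.get(pid)
        if demo is None:
            log.warning("kept primaryid %s has no DEMO row; skipped", pid)
            continue
        case_drugs = tuple(
            sorted(drugs.get(pid, []), key=lambda d: (d.drug_seq, d.drugname))
        )
        if not case_drugs or pid not in events:
            log.info("case %s has empty DRUG or REAC; retained for screening", pid)
        cases.append(
            CaseReport(
                primaryid=pid,
                caseid=demo.caseid,
                fda_dt=demo.fda_dt,
                event_dt=demo.event_dt,
                sex=demo.sex,
                age_years=age_to_years(demo.age_value, demo.age_unit),
                reporter_type=demo.reporter_type,
                country=demo.country,
                drugs=case_drugs,
                events=tuple(events.get(pid, [])),
                outcomes=frozenset(outcomes.get(pid, set())),
                therapy_starts=tuple(sorted(starts.get(pid, {}).items())),
            )
        )
    return cases


def _drug_matches(drug: DrugRecord, keyword_key: str, require_role: str | None) -> bool:
    if require_role is not None and drug.role != require_role:
        return False
    name = drug.prod_ai if drug.prod_ai else drug.drugname
    return keyword_key in norm_text(name)


def case_matches_target(
    case: CaseReport, keyword: str, require_role: str | None = "PS"
) -> bool:
    """True if the case lists the target active ingredient in the given role.

    Matching is a case-insensitive substring test on PROD_AI, falling back
    to DRUGNAME when PROD_AI is blank.
    """
    key = norm_text(keyword)
    return any(_drug_matches(d, key, require_role) for d in case.drugs)


def select_target_reports(
    cases: list[CaseReport], keyword: str, require_role: str | None = "PS"
) -> list[CaseReport]:
    """Cases whose target drug matches ``keyword`` with the required role."""
    if not keyword.strip():
        raise ValueError("target keyword must be non-empty")
    selected = [c for c in cases if case_matches_target(c, keyword, require_role)]
    if not selected:
        log.warning("target screen matched zero cases for keyword %r", keyword)
    return selected


def partition_by_target(
    cases: list[CaseReport], keyword: str, require_role: str | None = "PS"
) -> tuple[list[CaseReport], list[CaseReport]]:
    """Split cases into (target, background); a strict partition."""
    target = select_target_reports(cases, keyword, require_role)
    target_ids = {c.primaryid for c in target}
    background = [c for c in cases if c.primaryid not in target_ids]
    return target, background


def target_drug_seqs(case: CaseReport, keyword: str) -> list[int]:
    """Drug sequence numbers of entries matching the target keyword (any role)."""
    key = norm_text(keyword)
    return [d.drug_seq for d in case.drugs if _drug_matches(d, key, None)]
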