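"""Demographic, outcome and organ-class summary tables for the target cases.

All percentages are exact integer divisions rounded half-up to two
decimals.  Dimensions that are exhaustive (sex, age strata with a Missing
row, reporting year, reporter type, seriousness) conserve their counts:
rows sum to the denominator.  The outcome table is deliberately
non-exclusive — one report can carry several outcome codes — so its rows
need not sum to the report count and the table is labelled accordingly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._utils import pct
from .case_processing import AGE_GROUPS, CaseReport, age_group
from .disproportionality import mapped_events
from .meddra import MeddraTable

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization-Initial or Prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention to Prevent Permanent Impairment/Damage",
    "OT": "Other serious and important medical events",
}

REPORTER_LABELS = {
    "consumer": "Consumer",
    "physician": "Physician",
    "pharmacist": "Pharmacist",
    "other": "Other health professional",
    "missing": "Missing",
}


@dataclass
class SummaryTable:
    dimension: str
    rows: list[tuple[str, int, float]]  # (label, count, percent)
    denominator: int
    denominator_rule: str  # all_reports | known_only | all_AEs
    exhaustive: bool = True

    def count(self, label: str) -> int:
        for lab, n, _ in self.rows:
            if lab == label:
                return n
        raise KeyError(label)

    def percent(self, label: str) -> float:
        for lab, _, p in self.rows:
            if lab == label:
                return p
        raise KeyError(label)


def _table(dimension, pairs, denom, rule, exhaustive=True) -> SummaryTable:
    rows = [(label, n, pct(n, denom)) for label, n in pairs]
    return SummaryTable(dimension, rows, denom, rule, exhaustive)


def demographics_table(
    target_cases: list[CaseReport], top_k_countries: int = 5
) -> dict[str, SummaryTable]:
    """Sex / age / year / reporter / country / seriousness / outcome tables.

    All use the report count as denominator.  The country table keeps the
    top-k countries only (non-exhaustive); the outcome table counts each
    report once per outcome code it carries (non-exclusive).
    """
    if not target_cases:
        raise ValueError("no target cases: nothing to summarize")
    denom = len(target_cases)

    sex_counts = Counter(c.sex for c in target_cases)
    sex = _table(
        "sex",
        [
            ("Female", sex_counts.get("F", 0)),
            ("Male", sex_counts.get("M", 0)),
            ("Unknown", sex_counts.get("UNK", 0)),
        ],
        denom,
        "all_reports",
    )

    age_counts = Counter(age_group(c.age_years) for c in target_cases)
    age = _table(
        "age_group",
        [(g, age_counts.get(g, 0)) for g in AGE_GROUPS]
        + [("Missing", age_counts.get(None, 0))],
        denom,
        "all_reports",
    )

    year_counts = Counter(c.report_year for c in target_cases)
    year = _table(
        "reporting_year",
        [(str(y), year_counts[y]) for y in sorted(year_counts)],
        denom,
        "all_reports",
    )

    rep_counts = Counter(c.reporter_type for c in target_cases)
    reporter = _table(
        "reporter_type",
        [
            (label, rep_counts.get(key, 0))
            for key, label in REPORTER_LABELS.items()
        ],
        denom,
        "all_reports",
    )

    country_counts = Counter(c.country for c in target_cases if c.country)
    top = country_counts.most_common()
    top.sort(key=lambda kv: (-kv[1], kv[0]))
    country = _table(
        "country",
        top[:top_k_countries],
        denom,
        "all_reports",
        exhaustive=False,
    )

    serious_n = sum(c.serious for c in target_cases)
    seriousness = _table(
        "report_type",
        [("Non-serious", denom - serious_n), ("Serious", serious_n)],
        denom,
        "all_reports",
    )

    outc_counts = Counter()
    for c in target_cases:
        for code in c.outcomes:
            outc_counts[code] += 1
    outcome = _table(
        "outcome",
        [(label, outc_counts.get(code, 0)) for code, label in OUTCOME_LABELS.items()],
        denom,
        "all_reports",
        exhaustive=False,  # non-exclusive categorization
    )

    return {
        "sex": sex,
        "age_group": age,
        "reporting_year": year,
        "reporter_type": reporter,
        "country": country,
        "report_type": seriousness,
        "outcome": outcome,
    }


def age_summary(target_cases: list[CaseReport]) -> dict[str, float | None]:
    """Mean/SD/median/quartiles over cases with a known age (years)."""
    ages = np.asarray(
        [c.age_years for c in target_cases if c.age_years is not None], dtype=float
    )
    if ages.size == 0:
        return {"n": 0, "mean": None, "sd": None, "median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(ages, [25, 50, 75])
    return {
        "n": int(ages.size),
        "mean": float(ages.mean()),
        "sd": float(ages.std(ddof=1)) if ages.size >= 2 else None,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def soc_distribution(
    target_cases: list[CaseReport], meddra: MeddraTable
) -> SummaryTable:
    """Report x PT pairs grouped by SOC, sorted descending by count.

    The denominator is the total number of mapped pairs; unmapped terms
    are excluded here (they stay in PT-level statistics).
    """
    counts: Counter[str] = Counter()
    for case in target_cases:
        for pt, soc in mapped_events(case, meddra).items():
            if soc is not None:
                counts[soc] += 1
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [(soc, n, pct(n, total) if total else 0.0) for soc, n in ordered]
    return SummaryTable("soc", rows, total, "all_AEs")
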