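"""Reporting odds ratio disproportionality and the signal criterion.

For each adverse-event preferred term the analysis frame is the 2x2 table
of report x PT pairs::

                        target AE    other AEs
        target drug        a            b
        other drugs        c            d

ROR = (a/b) / (c/d) = ad / bc, with the 95% Wald interval on the log scale

    CI = exp( ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) ).

No continuity correction is applied: a table with any zero cell has an
undefined ROR and can never be a signal.  The signal criterion is the
classical imbalance rule: lower 95% bound above 1 supported by at least
``min_count`` reports (default 3).  Subgroup scans restrict both the
target and the comparator background to the stratum by default, so a
stratum's ROR is computed entirely inside that stratum.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace

from .case_processing import CaseReport, age_group
from .meddra import MeddraTable

log = logging.getLogger(__name__)

#: 95% normal quantile, fixed by convention rather than recomputed.
Z_95 = 1.96

STRATUM_DIMENSIONS = ("sex", "age_group", "country")

_SEX_LABELS = {"F": "Female", "M": "Male"}


class EmptyTargetError(Exception):
    """The screen produced no target cases; disproportionality refuses to run."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # target drug, target AE
    b: int  # target drug, other AEs
    c: int  # other drugs, target AE
    d: int  # other drugs, other AEs

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer: {v}")

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class SignalEstimate:
    """Per-PT disproportionality result within one stratum."""

    pt: str
    soc: str | None  # None for terms the dictionary cannot map
    stratum: str  # "overall" or "<dimension>:<label>"
    n: int  # = a, reports of the target drug with this PT
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    is_signal: bool
    is_new: bool | None = None  # None = not assessed
    table: ContingencyTable | None = None


def compute_ror(t: ContingencyTable) -> RorEstimate | None:
    """ROR with 95% Wald CI; ``None`` (undefined) when any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    log_ror = math.log(t.a) + math.log(t.d) - math.log(t.b) - math.log(t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RorEstimate(
        ror=math.exp(log_ror),
        ci_low=math.exp(log_ror - Z_95 * se),
        ci_high=math.exp(log_ror + Z_95 * se),
    )


def detect_signal(
    estimate: RorEstimate | None, n: int, min_count: int = 3
) -> bool:
    """The imbalance rule: CI lower bound > 1 and at least ``min_count`` reports."""
    return estimate is not None and estimate.ci_low > 1.0 and n >= min_count


# ---------------------------------------------------------------------------
# Event normalization and table building
# ---------------------------------------------------------------------------


def mapped_events(case: CaseReport, meddra: MeddraTable) -> dict[str, str | None]:
    """Normalize a case's events; returns {canonical or raw PT: SOC or None}.

    Unmapped raw terms are retained under their raw name with SOC ``None``
    so PT-level statistics keep them while SOC-level tables exclude them.
    """
    out: dict[str, str | None] = {}
    for raw in case.events:
        hit = meddra.normalize(raw)
        if hit is None:
            out.setdefault(raw, None)
        else:
            out.setdefault(hit[0], hit[1])
    return out


def _event_index(
    cases: list[CaseReport], meddra: MeddraTable
) -> tuple[list[set[str]], dict[str, str | None], int]:
    """Per-case normalized event sets, PT->SOC map, and total pair count."""
    sets: list[set[str]] = []
    soc_of: dict[str, str | None] = {}
    total = 0
    for case in cases:
        ev = mapped_events(case, meddra)
        sets.append(set(ev))
        total += len(ev)
        for pt, soc in ev.items():
            soc_of.setdefault(pt, soc)
    return sets, soc_of, total


def build_contingency(
    target_cases: list[CaseReport],
    background_cases: list[CaseReport],
    pt: str,
    meddra: MeddraTable,
) -> ContingencyTable:
    """The 2x2 table for one PT; counting unit is the report x PT pair."""
    t_sets, _, t_total = _event_index(target_cases, meddra)
    b_sets, _, b_total = _event_index(background_cases, meddra)
    a = sum(pt in s for s in t_sets)
    c = sum(pt in s for s in b_sets)
    return ContingencyTable(a, t_total - a, c, b_total - c)


def run_signal_scan(
    target_cases: list[CaseReport],
    background_cases: list[CaseReport],
    meddra: MeddraTable,
    min_count: int = 3,
    stratum: str = "overall",
) -> list[SignalEstimate]:
    """Scan every PT occurring in the target set; one estimate per PT.

    Results are sorted by PT name for determinism.  Raises
    :class:`EmptyTargetError` on an empty target set.
    """
    if not target_cases:
        raise EmptyTargetError("no target cases; cannot run disproportionality")
    t_sets, soc_of, t_total = _event_index(target_cases, meddra)
    b_sets, b_soc_of, b_total = _event_index(background_cases, meddra)
    for pt, soc in b_soc_of.items():
        soc_of.setdefault(pt, soc)

    a_counts: Counter[str] = Counter()
    for s in t_sets:
        a_counts.update(s)
    c_counts: Counter[str] = Counter()
    for s in b_sets:
        c_counts.update(s)

    estimates = []
    for pt in sorted(a_counts):
        a = a_counts[pt]
        c = c_counts.get(pt, 0)
        table = ContingencyTable(a, t_total - a, c, b_total - c)
        est = compute_ror(table)
        estimates.append(
            SignalEstimate(
                pt=pt,
                soc=soc_of.get(pt),
                stratum=stratum,
                n=a,
                ror=est.ror if est else None,
                ci_low=est.ci_low if est else None,
                ci_high=est.ci_high if est else None,
                is_signal=detect_signal(est, a, min_count),
                table=table,
            )
        )
    return estimates


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------


def stratum_label(case: CaseReport, dimension: str) -> str | None:
    """The case's label on a stratification dimension, or None if missing."""
    if dimension == "sex":
        return _SEX_LABELS.get(case.sex)
    if dimension == "age_group":
        return age_group(case.age_years)
    if dimension == "country":
        return case.country
    raise ValueError(f"unknown stratum dimension: {dimension}")


def stratified_scan(
    target_cases: list[CaseReport],
    background_cases: list[CaseReport],
    meddra: MeddraTable,
    dimension: str,
    min_count: int = 3,
    comparator: str = "within",
    labels: list[str] | None = None,
) -> dict[str, list[SignalEstimate]]:
    """Run the scan inside each stratum of one dimension.

    ``comparator="within"`` restricts the background to the stratum before
    building tables (each stratum is a self-contained analysis frame);
    ``"global"`` keeps the whole background as comparator.  Cases missing
    the dimension's label are excluded from that dimension.  ``labels``
    restricts and orders the strata (e.g. the top-5 reporting countries);
    by default all labels observed in the target set are scanned.
    """
    if comparator not in ("within", "global"):
        raise ValueError(f"unknown comparator: {comparator}")
    if labels is None:
        seen = []
        for case in target_cases:
            lab = stratum_label(case, dimension)
            if lab is not None and lab not in seen:
                seen.append(lab)
        labels = sorted(seen)

    results: dict[str, list[SignalEstimate]] = {}
    for label in labels:
        t_sub = [c for c in target_cases if stratum_label(c, dimension) == label]
        if not t_sub:
            log.info("stratum %s=%s has no target cases", dimension, label)
            results[label] = []
            continue
        if comparator == "within":
            b_sub = [
                c for c in background_cases if stratum_label(c, dimension) == label
            ]
        else:
            b_sub = background_cases
        results[label] = run_signal_scan(
            t_sub, b_sub, meddra, min_count, stratum=f"{dimension}:{label}"
        )
    return results


# ---------------------------------------------------------------------------
# Ranking and labelled-AE comparison
# ---------------------------------------------------------------------------


def rank_signals(
    estimates: list[SignalEstimate], by: str = "ror", k: int = 5
) -> list[SignalEstimate]:
    """Top-k positive signals by ROR or by report count.

    Ties on the chosen key break by the other key (descending), then by PT
    name ascending.  Only estimates with ``is_signal`` are ranked.
    """
    if by not in ("ror", "count"):
        raise ValueError(f"unknown ranking key: {by}")
    signals = [e for e in estimates if e.is_signal]

    def key(e: SignalEstimate):
        primary = e.ror if by == "ror" else e.n
        secondary = e.n if by == "ror" else e.ror
        return (-(primary or 0), -(secondary or 0), e.pt)

    return sorted(signals, key=key)[: max(k, 0)]


def flag_new_signals(
    estimates: list[SignalEstimate], labelled_pts: set[str]
) -> list[SignalEstimate]:
    """Mark each positive signal as new when its PT is absent from the label.

    ``labelled_pts`` are compared case-insensitively.  An empty label list
    flags every signal as new (with a warning): nothing is on the label.
    """
    from ._utils import norm_text

    if not labelled_pts:
        log.warning("empty labelled-PT list: every signal will be flagged new")
    keys = {norm_text(p) for p in labelled_pts}
    out = []
    for e in estimates:
        is_new = e.is_signal and norm_text(e.pt) not in keys
        out.append(replace(e, is_new=is_new if e.is_signal else False))
    return out


def new_signal_table(
    estimates: list[SignalEstimate], min_n: int = 10
) -> list[SignalEstimate]:
    """The label-comparison view: new signals reported at least ``min_n`` times."""
    rows = [e for e in estimates if e.is_new and e.n >= min_n]
    return sorted(rows, key=lambda e: (-e.n, e.pt))


def soc_signal_counts(estimates: list[SignalEstimate]) -> dict[str, int]:
    """Positive-signal count per SOC (PT-level signals grouped by SOC)."""
    counts: Counter[str] = Counter()
    for e in estimates:
        if e.is_signal and e.soc is not None:
            counts[e.soc] += 1
    return dict(counts)
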