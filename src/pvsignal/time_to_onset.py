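"""Time from therapy start to adverse-event onset.

Onset is the calendar-day difference between the event date and the
earliest therapy start among the case's target-drug entries.  It is only
computed when both dates are full (year, month and day): month- or
year-precision dates cannot support a day difference, and an event dated
before the therapy start is treated as a data-entry error, so both cases
yield "unknown".  Known onsets are summarized into the conventional
pharmacovigilance bins (first month, monthly to half a year, half a year
to a year, beyond a year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._utils import round_half_up
from .case_processing import CaseReport, target_drug_seqs
from .faers_io import PartialDate

log = logging.getLogger(__name__)

#: Closed onset bins in days; the last bin is open-ended.
ONSET_BINS: tuple[tuple[str, int, int | None], ...] = (
    ("0-30", 0, 30),
    ("31-60", 31, 60),
    ("61-90", 61, 90),
    ("91-120", 91, 120),
    ("121-150", 121, 150),
    ("151-180", 151, 180),
    ("181-360", 181, 360),
    (">360", 361, None),
)

BIN_LABELS = tuple(label for label, _, _ in ONSET_BINS)


@dataclass(frozen=True)
class OnsetObservation:
    primaryid: str
    days: int
    bin: str


def compute_onset_days(
    start: PartialDate | None, event: PartialDate | None
) -> int | None:
    """Calendar days from ``start`` to ``event``; ``None`` when unknowable.

    Requires two full dates with ``event >= start``.
    """
    if start is None or event is None:
        return None
    if not (start.is_full and event.is_full):
        return None
    delta = (event.to_date() - start.to_date()).days
    if delta < 0:
        log.info("event precedes therapy start (%s before %s)", event, start)
        return None
    return delta


def bin_onset(days: int) -> str:
    """The unique onset bin containing ``days`` (non-negative)."""
    if days < 0:
        raise ValueError(f"onset days must be non-negative: {days}")
    for label, lo, hi in ONSET_BINS:
        if days >= lo and (hi is None or days <= hi):
            return label
    raise AssertionError("unreachable: bins cover [0, inf)")


def case_onset(case: CaseReport, keyword: str) -> OnsetObservation | None:
    """Onset observation for one target case, or None when unknown.

    Anchored to the earliest full therapy-start date among the case's
    drug entries matching the target keyword.
    """
    seqs = set(target_drug_seqs(case, keyword))
    starts = [
        start
        for seq, start in case.therapy_starts
        if seq in seqs and start.is_full
    ]
    if not starts:
        return None
    earliest = min(starts, key=lambda s: s.sort_key())
    days = compute_onset_days(earliest, case.event_dt)
    if days is None:
        return None
    return OnsetObservation(case.primaryid, days, bin_onset(days))


@dataclass
class OnsetSummary:
    n_known: int
    n_unknown: int
    mean: float | None
    sd: float | None
    median: float | None
    q1: float | None
    q3: float | None
    #: (bin label, count, percent of known)
    bins: list[tuple[str, int, float]]


def summarize_onset(days: list[int], n_unknown: int = 0) -> OnsetSummary:
    """Summary statistics and bin percentages over known onsets.

    Percentages use the number of known onsets as denominator (rounded
    half-up to 2 decimals); quartiles use linear interpolation between
    order statistics; the standard deviation is the sample (n-1) form and
    undefined for fewer than two observations.
    """
    n = len(days)
    counts = {label: 0 for label in BIN_LABELS}
    for d in days:
        counts[bin_onset(d)] += 1
    if n == 0:
        return OnsetSummary(
            0, n_unknown, None, None, None, None, None,
            [(label, 0, 0.0) for label in BIN_LABELS],
        )
    arr = np.asarray(days, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return OnsetSummary(
        n_known=n,
        n_unknown=n_unknown,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n >= 2 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        bins=[
            (label, counts[label], round_half_up(100.0 * counts[label] / n))
            for label in BIN_LABELS
        ],
    )
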