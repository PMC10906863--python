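"""Synthetic FAERS-dialect data with known ground truth.

The generator emulates the statistical structure of a spontaneous
reporting database at desk scale: many drugs and many preferred terms per
report, duplicate case versions exercising both branches of the FDA
deduplication rule, partial and missing dates, missing age and sex, a
configurable serious-outcome rate, and — most importantly — planted
drug-event associations with a known strength, so that signal detection
can be validated against ground truth instead of against a database
download.

Event sampling: each PT of the catalogue enters a report independently
with its baseline probability (comparator reports) or with that
probability scaled by ``exp(theta)`` for planted PTs (target-drug
reports), conditioned on at least one event per report by redrawing.  The
redraw factor cancels within each drug arm, so with a single planted PT
the population report x PT reporting odds ratio equals ``exp(theta)``
exactly; :func:`expected_ror` evaluates the exact closed form in general
(simultaneously planted PTs deflate each other's pair-level ROR slightly
because they enlarge the comparator event column).

Defaults mirror the marginal structure of a real spontaneous-reporting
study of a newly approved drug: ~5% target-drug reports, roughly half the
ages missing, three quarters of onset dates unusable, a ~44% serious
fraction, and a strongly right-skewed onset distribution (median around
two months, heavy tail beyond a year).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .faers_io import (
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    ReacRecord,
    RecordStore,
    TherRecord,
    write_faers_table,
)

STUDY_START = date(2020, 7, 1)
STUDY_END = date(2023, 6, 30)

TARGET_DRUGNAME = "EVRYSDI"
TARGET_PROD_AI = "RISDIPLAM"

#: (PT, SOC, baseline per-report probability).  Roughly 1.6 expected raw
#: event draws per report before conditioning on >= 1.
DEFAULT_PT_CATALOGUE: tuple[tuple[str, str, float], ...] = (
    ("Asthenia", "General disorders and administration site conditions", 0.12),
    ("Fatigue", "General disorders and administration site conditions", 0.10),
    ("Pyrexia", "General disorders and administration site conditions", 0.08),
    ("Death", "General disorders and administration site conditions", 0.06),
    ("Diarrhoea", "Gastrointestinal disorders", 0.12),
    ("Nausea", "Gastrointestinal disorders", 0.10),
    ("Vomiting", "Gastrointestinal disorders", 0.08),
    ("Constipation", "Gastrointestinal disorders", 0.05),
    ("Pneumonia", "Infections and infestations", 0.07),
    ("COVID-19", "Infections and infestations", 0.06),
    ("Urinary tract infection", "Infections and infestations", 0.05),
    ("Fall", "Injury, poisoning and procedural complications", 0.05),
    ("Product container issue", "Injury, poisoning and procedural complications", 0.03),
    ("Headache", "Nervous system disorders", 0.09),
    ("Seizure", "Nervous system disorders", 0.03),
    ("Muscular weakness", "Musculoskeletal and connective tissue disorders", 0.06),
    ("Myalgia", "Musculoskeletal and connective tissue disorders", 0.04),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.07),
    ("Respiratory failure", "Respiratory, thoracic and mediastinal disorders", 0.03),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.06),
    ("Hypokalaemia", "Metabolism and nutrition disorders", 0.03),
    ("Nephrolithiasis", "Renal and urinary disorders", 0.02),
    ("Tachycardia", "Cardiac disorders", 0.03),
    ("Cardiac arrest", "Cardiac disorders", 0.015),
    ("Insomnia", "Psychiatric disorders", 0.05),
    ("Weight decreased", "Investigations", 0.04),
    ("Hepatic enzyme increased", "Investigations", 0.02),
)

#: Variant spellings the toy dictionary resolves to canonical PTs.
DEFAULT_SYNONYMS: dict[str, str] = {
    "Renal calculus": "Nephrolithiasis",
    "Pyrexia NOS": "Pyrexia",
}

#: PTs considered on-label for the target drug (known from its trials).
DEFAULT_LABELLED_PTS: tuple[str, ...] = (
    "Diarrhoea",
    "Pyrexia",
    "Rash",
    "Nausea",
    "Vomiting",
    "Constipation",
    "Urinary tract infection",
    "Headache",
    "Fatigue",
    "Fall",
)


class InfeasibleSignalError(ValueError):
    """A planted log-ROR would require an event probability above 1."""


@dataclass
class SimulationConfig:
    """Knobs of the generator; the seed fully determines the output."""

    n_reports: int = 20_000
    target_drug_fraction: float = 0.05
    background_drugs: int = 20
    pt_catalogue: tuple[tuple[str, str, float], ...] = DEFAULT_PT_CATALOGUE
    #: (PT, true log reporting odds ratio theta)
    planted_signals: tuple[tuple[str, float], ...] = (
        ("Nephrolithiasis", math.log(8.0)),
    )
    duplicate_rate: float = 0.10
    missing_age_rate: float = 0.52
    missing_sex_rate: float = 0.177
    partial_date_rate: float = 0.75
    #: log-normal onset in days (mu, sigma of log-days)
    onset_lognormal: tuple[float, float] = (math.log(64.0), 2.45)
    outcome_rate: float = 0.4427
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "target_drug_fraction",
            "duplicate_rate",
            "missing_age_rate",
            "missing_sex_rate",
            "partial_date_rate",
            "outcome_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability: {v}")
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        catalogue = {pt: p for pt, _, p in self.pt_catalogue}
        for pt, theta in self.planted_signals:
            if pt not in catalogue:
                raise ValueError(f"planted PT {pt!r} not in catalogue")
            if catalogue[pt] * math.exp(theta) > 1.0:
                max_theta = math.log(1.0 / catalogue[pt])
                raise InfeasibleSignalError(
                    f"theta={theta:.3f} infeasible for PT {pt!r} "
                    f"(baseline {catalogue[pt]}); maximum feasible theta is "
                    f"{max_theta:.3f}"
                )
        expected_pairs = sum(catalogue.values())
        if not 0.05 <= expected_pairs <= 10.0:
            raise ValueError(
                f"catalogue implies {expected_pairs:.2f} expected raw events "
                "per report; keep it within [0.05, 10]"
            )

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "target_drug_fraction": self.target_drug_fraction,
            "background_drugs": self.background_drugs,
            "pt_catalogue": [list(row) for row in self.pt_catalogue],
            "planted_signals": [list(row) for row in self.planted_signals],
            "duplicate_rate": self.duplicate_rate,
            "missing_age_rate": self.missing_age_rate,
            "missing_sex_rate": self.missing_sex_rate,
            "partial_date_rate": self.partial_date_rate,
            "onset_lognormal": list(self.onset_lognormal),
            "outcome_rate": self.outcome_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        if "pt_catalogue" in kwargs:
            kwargs["pt_catalogue"] = tuple(
                (str(pt), str(soc), float(p)) for pt, soc, p in kwargs["pt_catalogue"]
            )
        if "planted_signals" in kwargs:
            kwargs["planted_signals"] = tuple(
                (str(pt), float(th)) for pt, th in kwargs["planted_signals"]
            )
        if "onset_lognormal" in kwargs:
            kwargs["onset_lognormal"] = tuple(kwargs["onset_lognormal"])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    config: dict
    #: caseid -> {"versions": [...], "keeper": primaryid}
    duplicates: dict[str, dict]
    #: PT -> true pair-level reporting odds ratio
    true_ror: dict[str, float]
    #: PT -> expected {a, b, c, d} (expectations, not integers)
    expected_tables: dict[str, dict[str, float]]
    #: primaryid (kept version) -> true onset days
    onset_days: dict[str, int]
    #: quarter -> {table kind -> written row count}
    row_counts: dict[str, dict[str, int]]
    n_target_reports: int
    n_background_reports: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "duplicates": self.duplicates,
                    "true_ror": self.true_ror,
                    "expected_tables": self.expected_tables,
                    "onset_days": self.onset_days,
                    "row_counts": self.row_counts,
                    "n_target_reports": self.n_target_reports,
                    "n_background_reports": self.n_background_reports,
                },
                indent=1,
                sort_keys=True,
            )
        )


# ---------------------------------------------------------------------------
# Closed-form ground truth
# ---------------------------------------------------------------------------


def _probability_vectors(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pts = [pt for pt, _, _ in config.pt_catalogue]
    p_bg = np.array([p for _, _, p in config.pt_catalogue], dtype=float)
    p_tg = p_bg.copy()
    planted = dict(config.planted_signals)
    for i, pt in enumerate(pts):
        if pt in planted:
            p_tg[i] = p_bg[i] * math.exp(planted[pt])
    return p_bg, p_tg, pts


def expected_ror(config: SimulationConfig, pt: str) -> float:
    """Exact population report x PT reporting odds ratio for one PT.

    With probabilities ``p`` (comparator) and ``p'`` (target) and catalogue
    sums ``S`` and ``S'``, the pair-level ROR the pipeline estimates is

        ROR = [p' (S - p)] / [p (S' - p')].

    For a single planted PT this reduces to ``exp(theta)`` exactly, and to
    1 for every PT when nothing is planted.
    """
    p_bg, p_tg, pts = _probability_vectors(config)
    if pt not in pts:
        raise ValueError(f"PT {pt!r} not in catalogue")
    i = pts.index(pt)
    s_bg = float(p_bg.sum())
    s_tg = float(p_tg.sum())
    return (p_tg[i] * (s_bg - p_bg[i])) / (p_bg[i] * (s_tg - p_tg[i]))


def _expected_tables(config: SimulationConfig) -> dict[str, dict[str, float]]:
    p_bg, p_tg, pts = _probability_vectors(config)
    n_t = config.n_reports * config.target_drug_fraction
    n_b = config.n_reports - n_t
    cond_t = 1.0 - float(np.prod(1.0 - p_tg))
    cond_b = 1.0 - float(np.prod(1.0 - p_bg))
    total_t = n_t * float(p_tg.sum()) / cond_t
    total_b = n_b * float(p_bg.sum()) / cond_b
    out = {}
    for i, pt in enumerate(pts):
        a = n_t * p_tg[i] / cond_t
        c = n_b * p_bg[i] / cond_b
        out[pt] = {"a": a, "b": total_t - a, "c": c, "d": total_b - c}
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _quarter_of(d: date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def _full_pd(d: date) -> PartialDate:
    return PartialDate(d.year, d.month, d.day)


def generate_records(
    config: SimulationConfig,
) -> tuple[RecordStore, GroundTruth]:
    """Generate the record store in memory (no files) plus its ground truth.

    Deterministic: identical config (including seed) gives identical
    records.  The store contains duplicate case versions exactly as a
    multi-quarter FAERS load would.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    p_bg, p_tg, pts = _probability_vectors(config)
    n_pt = len(pts)

    is_target = rng.random(n) < config.target_drug_fraction
    prob = np.where(is_target[:, None], p_tg[None, :], p_bg[None, :])

    events = rng.random((n, n_pt)) < prob
    # Condition on >= 1 event per report by redrawing empty reports.
    empty = ~events.any(axis=1)
    while empty.any():
        idx = np.where(empty)[0]
        events[idx] = rng.random((idx.size, n_pt)) < prob[idx]
        empty[idx] = ~events[idx].any(axis=1)

    # Demographics ---------------------------------------------------------
    sex_known = rng.random(n) >= config.missing_sex_rate
    sex_female = rng.random(n) < 0.58
    age_known = rng.random(n) >= config.missing_age_rate
    # Gamma(1.552, 14.92): mean 23.2 y, SD 18.6 y, median ~18 y — the
    # child-heavy age profile of a paediatric-onset disease drug.
    ages = np.minimum(rng.gamma(1.552, 14.92, n), 100.0)
    reporter = rng.choice(
        np.array(["CN", "MD", "PH", ""]), size=n, p=[0.63, 0.25, 0.11, 0.01]
    )
    countries = rng.choice(
        np.array(["US", "GB", "NL", "IN", "DE", "FR", "CA", "JP", "AU", "BR"]),
        size=n,
        p=[0.70, 0.05, 0.04, 0.03, 0.03, 0.04, 0.03, 0.03, 0.025, 0.025],
    )

    serious = rng.random(n) < config.outcome_rate
    outcome1 = rng.choice(
        np.array(["HO", "OT", "DE", "LT", "DS", "CA"]),
        size=n,
        p=[0.40, 0.38, 0.15, 0.04, 0.025, 0.005],
    )
    outcome2 = rng.choice(
        np.array(["HO", "OT", "DE", "LT", "DS", "CA"]),
        size=n,
        p=[0.40, 0.38, 0.15, 0.04, 0.025, 0.005],
    )
    has_second_outcome = rng.random(n) < 0.25

    # Dates ----------------------------------------------------------------
    start_ord, end_ord = STUDY_START.toordinal(), STUDY_END.toordinal()
    fda_ord = rng.integers(start_ord, end_ord + 1, size=n)
    report_delay = rng.integers(0, 61, size=n)
    mu, sigma = config.onset_lognormal
    onset_days = np.minimum(
        np.round(rng.lognormal(mu, sigma, size=n)), 2000.0
    ).astype(int)

    date_partial = rng.random(n) < config.partial_date_rate
    partial_mode = rng.random(n)  # <0.4 drop event_dt, <0.7 month start, else drop start

    # Drugs ----------------------------------------------------------------
    bg_drug_idx = rng.integers(0, config.background_drugs, size=n)
    concomitant = rng.random(n) < 0.5
    conc_drug_idx = rng.integers(0, config.background_drugs, size=n)
    target_as_conc = rng.random(n) < 0.05  # target appears as concomitant only
    blank_prod_ai = rng.random(n) < 0.05  # exercises the DRUGNAME fallback

    # Quirks ---------------------------------------------------------------
    use_synonym = rng.random((n, n_pt)) < 0.10
    uppercase_pt = rng.random((n, n_pt)) < 0.15
    repeat_reac = rng.random(n) < 0.03  # duplicate PT row within a report

    # Duplicate case versions ---------------------------------------------
    duplicated = rng.random(n) < config.duplicate_rate
    dup_tie = rng.random(n) < 0.5  # equal FDA_DT, higher primaryid wins
    dup_advance = rng.integers(1, 91, size=n)

    store = RecordStore()
    truth_duplicates: dict[str, dict] = {}
    truth_onset: dict[str, int] = {}

    def emit_child_rows(pid: str, i: int, drugname: str, prod_ai: str | None,
                        start_pd: PartialDate | None) -> None:
        # Primary (suspect) drug.
        store.drug.append(DrugRecord(pid, 1, drugname, prod_ai, "PS"))
        if not is_target[i] and target_as_conc[i]:
            # Target drug present but only as concomitant: must NOT screen in.
            store.drug.append(
                DrugRecord(pid, 3, TARGET_DRUGNAME, TARGET_PROD_AI, "C")
            )
        if concomitant[i]:
            name = f"BRAND-{conc_drug_idx[i]:02d}"
            store.drug.append(
                DrugRecord(pid, 2, name, f"INGREDIENT-{conc_drug_idx[i]:02d}", "C")
            )
        ev_idx = np.where(events[i])[0]
        first = True
        for j in ev_idx:
            text = pts[j]
            if use_synonym[i, j]:
                for syn, canon in DEFAULT_SYNONYMS.items():
                    if canon == text:
                        text = syn
                        break
            if uppercase_pt[i, j]:
                text = text.upper()
            store.reac.append(ReacRecord(pid, text))
            if first and repeat_reac[i]:
                store.reac.append(ReacRecord(pid, text))
            first = False
        if serious[i]:
            store.outc.append(OutcRecord(pid, str(outcome1[i])))
            if has_second_outcome[i] and outcome2[i] != outcome1[i]:
                store.outc.append(OutcRecord(pid, str(outcome2[i])))
        if start_pd is not None:
            store.ther.append(TherRecord(pid, 1, start_pd))

    for i in range(n):
        caseid = str(1_000_000 + i)
        pid1 = caseid + "1"
        fda1 = date.fromordinal(int(fda_ord[i]))
        event_date = fda1 - timedelta(days=int(report_delay[i]))
        start_date = event_date - timedelta(days=int(onset_days[i]))

        event_pd: PartialDate | None = _full_pd(event_date)
        start_pd: PartialDate | None = _full_pd(start_date)
        if date_partial[i]:
            if partial_mode[i] < 0.4:
                event_pd = None
            elif partial_mode[i] < 0.7:
                start_pd = PartialDate(start_date.year, start_date.month)
            else:
                start_pd = None

        if is_target[i]:
            if blank_prod_ai[i]:
                drugname, prod_ai = f"{TARGET_DRUGNAME} ({TARGET_PROD_AI})", None
            else:
                drugname, prod_ai = TARGET_DRUGNAME, TARGET_PROD_AI
        else:
            drugname = f"BRAND-{bg_drug_idx[i]:02d}"
            prod_ai = f"INGREDIENT-{bg_drug_idx[i]:02d}"

        age_value: float | None = None
        age_unit: str | None = None
        if age_known[i]:
            years = float(ages[i])
            if years < 2.0:
                age_value, age_unit = round(years * 12.0, 1), "MON"
            elif i % 50 == 0:
                age_value, age_unit = round(years / 10.0, 1), "DEC"
            else:
                age_value, age_unit = float(int(years)), "YR"

        sex = ("F" if sex_female[i] else "M") if sex_known[i] else "UNK"
        rep = {"CN": "consumer", "MD": "physician", "PH": "pharmacist", "": "missing"}[
            str(reporter[i])
        ]

        def demo_record(pid: str, fda: date) -> DemoRecord:
            return DemoRecord(
                primaryid=pid,
                caseid=caseid,
                fda_dt=_full_pd(fda),
                event_dt=event_pd,
                sex=sex,
                age_value=age_value,
                age_unit=age_unit,
                reporter_type=rep,
                country=str(countries[i]),
            )

        store.demo.append(demo_record(pid1, fda1))
        emit_child_rows(pid1, i, drugname, prod_ai, start_pd)

        keeper = pid1
        if duplicated[i]:
            pid2 = caseid + "2"
            fda2 = fda1 if dup_tie[i] else min(
                fda1 + timedelta(days=int(dup_advance[i])), STUDY_END
            )
            store.demo.append(demo_record(pid2, fda2))
            emit_child_rows(pid2, i, drugname, prod_ai, start_pd)
            keeper = pid2  # later date, or equal date with higher primaryid
            truth_duplicates[caseid] = {"versions": [pid1, pid2], "keeper": pid2}
        else:
            truth_duplicates[caseid] = {"versions": [pid1], "keeper": pid1}

        if (
            is_target[i]
            and event_pd is not None
            and start_pd is not None
            and start_pd.is_full
        ):
            truth_onset[keeper] = int(onset_days[i])

    truth = GroundTruth(
        config=config.to_dict(),
        duplicates=truth_duplicates,
        true_ror={pt: expected_ror(config, pt) for pt in pts},
        expected_tables=_expected_tables(config),
        onset_days=truth_onset,
        row_counts={},  # filled by generate_dataset when files are written
        n_target_reports=int(is_target.sum()),
        n_background_reports=int(n - is_target.sum()),
    )
    # Provenance for in-memory stores: a single pseudo-quarter per actual
    # quarter is only materialized when files are written.
    store.provenance["in-memory"] = {}
    return store, truth


def build_meddra_table(config: SimulationConfig):
    """Toy dictionary matching the catalogue, as a MeddraTable."""
    from .meddra import MeddraTable

    pt_to_soc = {pt: soc for pt, soc, _ in config.pt_catalogue}
    synonyms = {
        syn: canon for syn, canon in DEFAULT_SYNONYMS.items() if canon in pt_to_soc
    }
    return MeddraTable(
        pt_to_soc=pt_to_soc, synonym_to_pt=synonyms, version_label="toy-dictionary"
    )


def write_meddra_tsv(config: SimulationConfig, path: str | Path) -> None:
    lines = ["pt\tsoc\tsynonym"]
    syn_of: dict[str, list[str]] = {}
    for syn, canon in DEFAULT_SYNONYMS.items():
        syn_of.setdefault(canon, []).append(syn)
    for pt, soc, _ in config.pt_catalogue:
        synonyms = syn_of.get(pt, [""])
        for syn in synonyms:
            lines.append(f"{pt}\t{soc}\t{syn}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_label_list(path: str | Path, pts=DEFAULT_LABELLED_PTS) -> None:
    Path(path).write_text("\n".join(pts) + "\n", encoding="utf-8")


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> GroundTruth:
    """Write quarterly ASCII files, toy dictionary, label list and manifest.

    Files are named ``DEMO2021Q1.txt`` etc.; every quarter that received at
    least one DEMO row gets all five table files (possibly header-only), so
    the loader's per-quarter requirements always hold.  Byte-identical
    output for identical config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store, truth = generate_records(config)

    demo_by_q: dict[str, list[DemoRecord]] = {}
    for rec in store.demo:
        demo_by_q.setdefault(_quarter_label_of(rec.fda_dt), []).append(rec)
    pid_quarter = {
        rec.primaryid: _quarter_label_of(rec.fda_dt) for rec in store.demo
    }

    tables = {"DEMO": store.demo, "DRUG": store.drug, "REAC": store.reac,
              "OUTC": store.outc, "THER": store.ther}
    by_quarter: dict[str, dict[str, list]] = {
        q: {k: [] for k in tables} for q in demo_by_q
    }
    for kind, records in tables.items():
        for rec in records:
            by_quarter[pid_quarter[rec.primaryid]][kind].append(rec)

    row_counts: dict[str, dict[str, int]] = {}
    for quarter in sorted(by_quarter):
        row_counts[quarter] = {}
        for kind, records in by_quarter[quarter].items():
            write_faers_table(records, out / f"{kind}{quarter}.txt", kind)
            row_counts[quarter][kind] = len(records)
    truth.row_counts = row_counts

    write_meddra_tsv(config, out / "meddra.tsv")
    write_label_list(out / "labelled_pts.txt")
    truth.to_json(out / "manifest.json")
    return truth


def _quarter_label_of(pd_: PartialDate) -> str:
    return f"{pd_.year}Q{((pd_.month or 1) - 1) // 3 + 1}"
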