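"""End-to-end orchestration: load -> dedup -> assemble -> screen -> map ->
scan -> onset -> descriptives -> report files.

The pipeline itself is deterministic and seed-free; all randomness in the
toolchain lives in :mod:`pvsignal.synthetic_data`.  Every stage appends a
machine-readable entry (stage name, input/output counts, exclusions with
reasons) to a flow log, the analogue of a study-selection flowchart, and
identical inputs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import case_processing, descriptives, disproportionality, time_to_onset
from ._utils import round_half_up
from .case_processing import CaseReport
from .disproportionality import (
    EmptyTargetError,
    SignalEstimate,
    flag_new_signals,
    new_signal_table,
    rank_signals,
    run_signal_scan,
    soc_signal_counts,
    stratified_scan,
)
from .faers_io import FaersFormatError, discover_quarters, load_quarters
from .meddra import MeddraTable, load_meddra_table, unmapped_report

log = logging.getLogger(__name__)


class StageRefusal(Exception):
    """A stage's precondition failed; the run aborts with the stage named."""


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    target_keyword: str = "risdiplam"
    meddra_path: str | None = None  # default: <input_dir>/meddra.tsv
    label_path: str | None = None  # default: <input_dir>/labelled_pts.txt
    min_count: int = 3
    new_signal_min_n: int = 10
    stratified_comparator: str = "within"  # within | global
    top_k: int = 5
    country_column: str = "auto"  # auto | occr_country | reporter_country
    require_role: str = "PS"

    def resolve_paths(self) -> None:
        if self.meddra_path is None:
            self.meddra_path = str(Path(self.input_dir) / "meddra.tsv")
        if self.label_path is None:
            candidate = Path(self.input_dir) / "labelled_pts.txt"
            self.label_path = str(candidate) if candidate.exists() else None

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise ValueError(f"input directory does not exist: {self.input_dir}")
        if self.meddra_path and not Path(self.meddra_path).exists():
            raise ValueError(f"dictionary file does not exist: {self.meddra_path}")
        if self.label_path and not Path(self.label_path).exists():
            raise ValueError(f"label file does not exist: {self.label_path}")
        if self.stratified_comparator not in ("within", "global"):
            raise ValueError("stratified_comparator must be 'within' or 'global'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FlowLog:
    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        entry = {"stage": stage, "in": n_in, "out": n_out, "excluded": n_in - n_out}
        entry.update(extra)
        self.entries.append(entry)
        log.info("stage %s: %d -> %d", stage, n_in, n_out)

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for entry in self.entries:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")


def load_labelled_pts(path: str | Path) -> set[str]:
    """One PT per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.split("#", 1)[0].strip()
        if term:
            out.add(term)
    return out


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------


def _fmt2(x: float | None) -> str:
    return "" if x is None else f"{round_half_up(x, 2):.2f}"


_SIGNAL_COLUMNS = [
    "pt", "soc", "stratum", "n", "ror", "ci_low", "ci_high", "is_signal",
    "is_new", "unmapped", "ror_full", "ci_low_full", "ci_high_full",
]


def signals_frame(estimates: list[SignalEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "pt": e.pt,
                "soc": e.soc or "",
                "stratum": e.stratum,
                "n": e.n,
                "ror": _fmt2(e.ror),
                "ci_low": _fmt2(e.ci_low),
                "ci_high": _fmt2(e.ci_high),
                "is_signal": e.is_signal,
                "is_new": "" if e.is_new is None else e.is_new,
                "unmapped": e.soc is None,
                "ror_full": "" if e.ror is None else repr(e.ror),
                "ci_low_full": "" if e.ci_low is None else repr(e.ci_low),
                "ci_high_full": "" if e.ci_high is None else repr(e.ci_high),
            }
        )
    return pd.DataFrame(rows, columns=_SIGNAL_COLUMNS)


def summary_frame(table: descriptives.SummaryTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dimension": table.dimension,
                "label": label,
                "count": n,
                "percent": f"{p:.2f}",
                "denominator": table.denominator,
                "denominator_rule": table.denominator_rule,
            }
            for label, n, p in table.rows
        ]
    )


@dataclass
class PipelineResult:
    config: RunConfig
    cases: list[CaseReport]
    target_cases: list[CaseReport]
    background_cases: list[CaseReport]
    overall: list[SignalEstimate]
    stratified: dict[str, dict[str, list[SignalEstimate]]]
    onset_summary: time_to_onset.OnsetSummary
    flow: FlowLog


def analyze_store(
    store,
    meddra: MeddraTable,
    keyword: str,
    min_count: int = 3,
    require_role: str = "PS",
):
    """Dedup, assemble and screen an in-memory store, then scan overall.

    The file-free core of :func:`run_pipeline`, also used by simulation
    studies that never touch disk.  Returns (target, background, estimates).
    """
    decisions = case_processing.deduplicate(store.demo)
    cases = case_processing.assemble_cases(store, decisions)
    target, background = case_processing.partition_by_target(
        cases, keyword, require_role
    )
    if not target:
        raise EmptyTargetError(f"no cases matched keyword {keyword!r}")
    estimates = run_signal_scan(target, background, meddra, min_count)
    return target, background, estimates


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write the output bundle.

    Outputs under ``config.output_dir``: ``signals.tsv`` (all strata),
    ``soc_summary.tsv``, ``top_ror.tsv`` / ``top_count.tsv`` (top-k per
    stratum), ``new_signals.tsv``, ``demographics.tsv``, ``onset.tsv`` /
    ``onset_summary.tsv``, ``unmapped_terms.tsv``, ``dedup_audit.tsv``,
    ``flow.jsonl`` and the verbatim ``run_config.json``.
    """
    config.resolve_paths()
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    flow = FlowLog()

    # --- load -------------------------------------------------------------
    try:
        quarters = discover_quarters(config.input_dir)
        if not quarters:
            raise StageRefusal(f"load: no quarterly tables in {config.input_dir}")
        store = load_quarters(quarters, country_column=config.country_column)
    except FaersFormatError as exc:
        raise StageRefusal(f"load: {exc}") from exc
    n_rows = sum(len(store.table(k)) for k in ("DEMO",))
    flow.add(
        "load",
        n_rows,
        n_rows,
        tables=store.counts(),
        rejected_rows=sum(r.rows_rejected for r in store.reports),
        quarters=sorted(quarters),
    )

    # --- dedup ------------------------------------------------------------
    decisions = case_processing.deduplicate(store.demo)
    flow.add(
        "deduplicate",
        len(store.demo),
        len(decisions),
        reasons={"duplicate_case_versions": len(store.demo) - len(decisions)},
    )

    # --- assemble ---------------------------------------------------------
    cases = case_processing.assemble_cases(store, decisions)
    flow.add("assemble", len(decisions), len(cases))

    # --- screen -----------------------------------------------------------
    target, background = case_processing.partition_by_target(
        cases, config.target_keyword, config.require_role
    )
    if not target:
        raise StageRefusal(
            f"screen: no cases matched keyword {config.target_keyword!r}"
        )
    flow.add(
        "screen",
        len(cases),
        len(target),
        reasons={"background_cases": len(background)},
    )

    # --- map --------------------------------------------------------------
    meddra = load_meddra_table(config.meddra_path)
    raw_terms = [pt for c in target for pt in c.events]
    unmapped = unmapped_report(raw_terms, meddra)
    target_pairs = sum(
        len(disproportionality.mapped_events(c, meddra)) for c in target
    )
    if target_pairs == 0:
        raise StageRefusal("scan: target cases carry no adverse events")
    flow.add(
        "map",
        len(raw_terms),
        target_pairs,
        reasons={"unmapped_distinct_terms": int(len(unmapped))},
    )

    # --- scan: overall + strata ------------------------------------------
    overall = run_signal_scan(target, background, meddra, config.min_count)
    labelled: set[str] = set()
    if config.label_path:
        labelled = load_labelled_pts(config.label_path)
    overall = flag_new_signals(overall, labelled)

    top_countries = [
        label
        for label, _, _ in descriptives.demographics_table(
            target, config.top_k
        )["country"].rows
    ]
    stratified = {
        dim: stratified_scan(
            target,
            background,
            meddra,
            dim,
            config.min_count,
            config.stratified_comparator,
            labels=top_countries if dim == "country" else None,
        )
        for dim in disproportionality.STRATUM_DIMENSIONS
    }
    n_signals = sum(e.is_signal for e in overall)
    flow.add(
        "scan",
        len(overall),
        n_signals,
        reasons={"non_signal_pts": len(overall) - n_signals},
        n_tests=len(overall),
    )

    # --- onset ------------------------------------------------------------
    observations = []
    for c in target:
        obs = time_to_onset.case_onset(c, config.target_keyword)
        if obs is not None:
            observations.append(obs)
    onset_summary = time_to_onset.summarize_onset(
        [o.days for o in observations], n_unknown=len(target) - len(observations)
    )
    flow.add("onset", len(target), len(observations))

    # --- descriptives -----------------------------------------------------
    demo_tables = descriptives.demographics_table(target, config.top_k)
    soc_table = descriptives.soc_distribution(target, meddra)
    ages = descriptives.age_summary(target)
    flow.add("descriptives", len(target), len(target))

    # --- write bundle -----------------------------------------------------
    all_estimates = list(overall)
    for dim_result in stratified.values():
        for ests in dim_result.values():
            all_estimates.extend(ests)
    signals_frame(all_estimates).to_csv(out / "signals.tsv", sep="\t", index=False)

    sig_by_soc = soc_signal_counts(overall)
    soc_rows = []
    for soc, n_aes, p in soc_table.rows:
        soc_rows.append(
            {
                "soc": soc,
                "n_aes": n_aes,
                "percent": f"{p:.2f}",
                "n_signals": sig_by_soc.get(soc, 0),
            }
        )
    pd.DataFrame(soc_rows).to_csv(out / "soc_summary.tsv", sep="\t", index=False)

    def _topk_frame(by: str) -> pd.DataFrame:
        frames = [signals_frame(rank_signals(overall, by, config.top_k))]
        for dim in disproportionality.STRATUM_DIMENSIONS:
            for label in stratified[dim]:
                frames.append(
                    signals_frame(
                        rank_signals(stratified[dim][label], by, config.top_k)
                    )
                )
        non_empty = [f for f in frames if not f.empty]
        if not non_empty:
            return pd.DataFrame(columns=_SIGNAL_COLUMNS)
        return pd.concat(non_empty, ignore_index=True)

    _topk_frame("ror").to_csv(out / "top_ror.tsv", sep="\t", index=False)
    _topk_frame("count").to_csv(out / "top_count.tsv", sep="\t", index=False)
    signals_frame(new_signal_table(overall, config.new_signal_min_n)).to_csv(
        out / "new_signals.tsv", sep="\t", index=False
    )

    demo_frames = [summary_frame(t) for t in demo_tables.values()]
    pd.concat(demo_frames, ignore_index=True).to_csv(
        out / "demographics.tsv", sep="\t", index=False
    )
    age_row = {k: ("" if v is None else v) for k, v in ages.items()}
    pd.DataFrame([age_row]).to_csv(out / "age_summary.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"primaryid": o.primaryid, "days": o.days, "bin": o.bin} for o in observations]
    ).to_csv(out / "onset.tsv", sep="\t", index=False)
    onset_rows = [
        {"bin": label, "count": n, "percent": f"{p:.2f}"}
        for label, n, p in onset_summary.bins
    ]
    onset_meta = {
        "n_known": onset_summary.n_known,
        "n_unknown": onset_summary.n_unknown,
        "mean": onset_summary.mean,
        "sd": onset_summary.sd,
        "median": onset_summary.median,
        "q1": onset_summary.q1,
        "q3": onset_summary.q3,
    }
    pd.DataFrame(onset_rows).to_csv(out / "onset_summary.tsv", sep="\t", index=False)
    (out / "onset_stats.json").write_text(
        json.dumps(onset_meta, sort_keys=True, indent=1)
    )

    unmapped.to_csv(out / "unmapped_terms.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "caseid": d.caseid,
                "kept_primaryid": d.kept_primaryid,
                "discarded_primaryid": pid,
            }
            for d in decisions
            for pid in d.discarded_primaryids
        ],
        columns=["caseid", "kept_primaryid", "discarded_primaryid"],
    ).to_csv(out / "dedup_audit.tsv", sep="\t", index=False)

    (out / "run_config.json").write_text(
        json.dumps(config.to_dict(), sort_keys=True, indent=1)
    )
    flow.write(out / "flow.jsonl")

    return PipelineResult(
        config=config,
        cases=cases,
        target_cases=target,
        background_cases=background,
        overall=overall,
        stratified=stratified,
        onset_summary=onset_summary,
        flow=flow,
    )


# ---------------------------------------------------------------------------
# Human-readable report
# ---------------------------------------------------------------------------


def render_report(output_dir: str | Path) -> str:
    """Render a markdown summary from the written TSVs (single source of
    truth: numbers are re-read from the files, never recomputed)."""
    out = Path(output_dir)
    parts: list[str] = ["# Disproportionality analysis report", ""]

    def section(title: str, filename: str, formatter) -> None:
        parts.append(f"## {title}")
        path = out / filename
        if not path.exists():
            parts.append("_not available_")
            parts.append("")
            return
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
        parts.extend(formatter(df))
        parts.append("")

    def as_markdown(df: pd.DataFrame, columns: list[str]) -> list[str]:
        if df.empty:
            return ["_empty_"]
        keep = [c for c in columns if c in df.columns]
        sub = df[keep]
        header = "| " + " | ".join(keep) + " |"
        sep = "|" + "|".join(["---"] * len(keep)) + "|"
        body = ["| " + " | ".join(str(v) for v in row) + " |" for row in sub.values]
        return [header, sep, *body]

    section(
        "Demographics and report characteristics",
        "demographics.tsv",
        lambda df: as_markdown(df, ["dimension", "label", "count", "percent"]),
    )
    section(
        "Time to onset",
        "onset_summary.tsv",
        lambda df: as_markdown(df, ["bin", "count", "percent"]),
    )
    section(
        "System organ class distribution",
        "soc_summary.tsv",
        lambda df: as_markdown(df, ["soc", "n_aes", "percent", "n_signals"]),
    )
    section(
        "Top signals by reporting odds ratio",
        "top_ror.tsv",
        lambda df: as_markdown(
            df, ["stratum", "pt", "n", "ror", "ci_low", "ci_high"]
        ),
    )
    section(
        "Most frequent positive signals",
        "top_count.tsv",
        lambda df: as_markdown(
            df, ["stratum", "pt", "n", "ror", "ci_low", "ci_high"]
        ),
    )
    section(
        "New signals (outside the label, n >= threshold)",
        "new_signals.tsv",
        lambda df: as_markdown(df, ["pt", "soc", "n", "ror", "ci_low", "ci_high"]),
    )

    text = "\n".join(parts)
    (out / "report.md").write_text(text, encoding="utf-8")
    return text
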