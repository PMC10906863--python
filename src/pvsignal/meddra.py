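"""PT normalization and system-organ-class mapping.

MedDRA itself is licensed content, so the dictionary is supplied by the
user as a plain TSV with columns ``pt`` (canonical preferred term), ``soc``
(its primary system organ class) and optionally ``synonym`` (an outdated
or variant term that should resolve to the canonical PT).  Lookup is
case-insensitive and whitespace-insensitive; stored names keep their
original form.

A PT maps to exactly one primary SOC here: multi-axial secondary SOC
membership is out of scope, which keeps SOC-level counts a disjoint
partition of the mapped adverse events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._utils import norm_text

log = logging.getLogger(__name__)

#: The 27 MedDRA system organ classes (top hierarchy level).
MEDDRA_SOCS = (
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Congenital, familial and genetic disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Eye disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Nervous system disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Product issues",
    "Psychiatric disorders",
    "Renal and urinary disorders",
    "Reproductive system and breast disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Social circumstances",
    "Surgical and medical procedures",
    "Vascular disorders",
)

_SOC_KEYS = {norm_text(s) for s in MEDDRA_SOCS}


class MeddraTableError(Exception):
    """Fatal dictionary problem (conflicting SOC rows, dangling synonym)."""


@dataclass
class MeddraTable:
    """In-memory PT dictionary with case-insensitive lookup."""

    pt_to_soc: dict[str, str]
    synonym_to_pt: dict[str, str]
    version_label: str = "unversioned"
    warnings: list[str] = field(default_factory=list)
    _lookup: dict[str, tuple[str, str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for syn, pt in self.synonym_to_pt.items():
            if pt not in self.pt_to_soc:
                raise MeddraTableError(
                    f"synonym {syn!r} points to unknown PT {pt!r}"
                )
        self._lookup = {}
        for pt, soc in self.pt_to_soc.items():
            self._lookup[norm_text(pt)] = (pt, soc)
        for syn, pt in self.synonym_to_pt.items():
            self._lookup.setdefault(norm_text(syn), (pt, self.pt_to_soc[pt]))

    def normalize(self, raw_pt: str) -> tuple[str, str] | None:
        """Resolve a raw term to ``(canonical PT, SOC)``; ``None`` if unmapped."""
        return self._lookup.get(norm_text(raw_pt))

    def __contains__(self, raw_pt: str) -> bool:
        return norm_text(raw_pt) in self._lookup


def normalize_pt(raw_pt: str, table: MeddraTable) -> tuple[str, str] | None:
    """Functional form of :meth:`MeddraTable.normalize` (total, never raises)."""
    return table.normalize(raw_pt)


def load_meddra_table(path: str | Path, version_label: str | None = None) -> MeddraTable:
    """Load a PT->SOC dictionary from TSV.

    Columns: ``pt`` and ``soc`` required, ``synonym`` optional.  A row with
    a non-empty ``synonym`` declares that variant for the row's PT.  Two
    rows assigning the same PT to different SOCs are a fatal error (the
    conflicts are listed); a SOC name outside the 27 known classes is kept
    with a warning so future dictionary versions still load.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("pt", "soc"):
        if col not in df.columns:
            raise MeddraTableError(f"{path}: missing required column {col!r}")

    pt_to_soc: dict[str, str] = {}
    canonical_by_key: dict[str, str] = {}
    synonyms_raw: list[tuple[str, str]] = []
    conflicts: list[str] = []
    warnings: list[str] = []

    for row in df.itertuples(index=False):
        pt = " ".join(str(row.pt).split())
        soc = " ".join(str(row.soc).split())
        if not pt or not soc:
            continue
        key = norm_text(pt)
        if key in canonical_by_key:
            existing = canonical_by_key[key]
            if norm_text(pt_to_soc[existing]) != norm_text(soc):
                conflicts.append(
                    f"PT {pt!r}: SOC {soc!r} conflicts with {pt_to_soc[existing]!r}"
                )
        else:
            canonical_by_key[key] = pt
            pt_to_soc[pt] = soc
            if norm_text(soc) not in _SOC_KEYS:
                warnings.append(f"unknown SOC name {soc!r} for PT {pt!r}")
        syn = ""
        if "synonym" in df.columns:
            syn = " ".join(str(row.synonym).split())
        if syn:
            synonyms_raw.append((syn, pt))

    if conflicts:
        raise MeddraTableError(
            "conflicting PT->SOC rows:\n" + "\n".join(conflicts)
        )

    synonym_to_pt = {
        syn: canonical_by_key[norm_text(pt)] for syn, pt in synonyms_raw
    }
    for msg in warnings:
        log.warning("%s: %s", path, msg)
    return MeddraTable(
        pt_to_soc=pt_to_soc,
        synonym_to_pt=synonym_to_pt,
        version_label=version_label or path.stem,
        warnings=warnings,
    )


def unmapped_report(raw_terms: list[str], table: MeddraTable) -> pd.DataFrame:
    """Tabulate raw terms the dictionary cannot resolve (term, count)."""
    from collections import Counter

    misses = Counter(t for t in raw_terms if table.normalize(t) is None)
    return pd.DataFrame(
        sorted(misses.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["raw_term", "count"],
    )
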