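"""Record-level curation of spontaneous-report tables into CMM-ADR pairs.

A raw pharmacovigilance export carries one row per (case, reaction) with case
versioning: a case resubmitted with corrections appears under the same
``case_id`` with a higher ``case_version``. The curation path here is

    dedup_latest_version -> filter_non_adr -> aggregate_pairs ->
    union_with_literature

which turns report-reaction records into weighted CMM-ADR associations with
per-pair report counts and a provenance flag (``faers`` vs ``literature``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

FAERS = "faers"
LITERATURE = "literature"


@dataclass(frozen=True)
class ReportRecord:
    """One report-reaction row of a spontaneous-report export."""

    case_id: str
    case_version: int
    cmm_id: str
    pt: str
    n_drugs_in_report: int = 1


@dataclass(frozen=True)
class PairAssociation:
    """An aggregated CMM-ADR association with report count and provenance."""

    cmm_id: str
    pt: str
    report_count: int
    provenance: str

    def __post_init__(self):
        if self.report_count < 0:
            raise ValueError("report_count must be non-negative")
        if self.provenance not in (FAERS, LITERATURE):
            raise ValueError(f"unknown provenance {self.provenance!r}")


class CurationError(ValueError):
    pass


def dedup_latest_version(records: list[ReportRecord]) -> list[ReportRecord]:
    """Keep exactly one record per case: the one with the highest version.

    Duplicate (case_id, case_version) pairs are a validation error; with that
    invariant enforced the maximum version per case is unique. Input order is
    otherwise preserved.
    """
    seen_versions: set[tuple[str, int]] = set()
    best: dict[str, tuple[int, int]] = {}  # case_id -> (version, position)
    for pos, rec in enumerate(records):
        key = (rec.case_id, rec.case_version)
        if key in seen_versions:
            raise CurationError(
                f"duplicate (case_id, case_version) = {key!r} in input")
        seen_versions.add(key)
        cur = best.get(rec.case_id)
        if cur is None or rec.case_version >= cur[0]:
            best[rec.case_id] = (rec.case_version, pos)
    keep = {pos for _, pos in best.values()}
    return [rec for pos, rec in enumerate(records) if pos in keep]


def filter_non_adr(records: list[ReportRecord],
                   blacklist: set[str]) -> tuple[list[ReportRecord], int]:
    """Drop records whose PT is on the non-ADR blacklist.

    Returns the retained records and the number removed. The blacklist holds
    exact Preferred Term strings (administrative / product-quality terms that
    do not describe an adverse reaction).
    """
    kept = [r for r in records if r.pt not in blacklist]
    removed = len(records) - len(kept)
    return kept, removed


def aggregate_pairs(records: list[ReportRecord]) -> list[PairAssociation]:
    """Aggregate deduplicated, filtered records to (cmm, pt) report counts."""
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.cmm_id, rec.pt)
        counts[key] = counts.get(key, 0) + 1
    return [PairAssociation(cmm_id=c, pt=p, report_count=n, provenance=FAERS)
            for (c, p), n in counts.items()]


def union_with_literature(faers_pairs: list[PairAssociation],
                          literature_pairs: list[PairAssociation]
                          ) -> list[PairAssociation]:
    """Union of report-derived and literature-curated associations.

    Keyed on (cmm_id, pt). On overlap the report-derived record wins, keeping
    its report count and ``faers`` provenance, so that count evidence survives
    into the edge feature vector. Literature entries must carry zero counts.
    """
    for p in literature_pairs:
        if p.provenance != LITERATURE or p.report_count != 0:
            raise CurationError(
                "literature pairs must have provenance='literature' and "
                f"report_count=0; got {p}")
    out = list(faers_pairs)
    faers_keys = {(p.cmm_id, p.pt) for p in faers_pairs}
    n_overlap = 0
    for p in literature_pairs:
        if (p.cmm_id, p.pt) in faers_keys:
            n_overlap += 1
        else:
            out.append(p)
    if n_overlap:
        logger.info("union_with_literature: %d overlapping pairs kept the "
                    "report-derived record", n_overlap)
    return out


def monotherapy_subset(records: list[ReportRecord]) -> list[ReportRecord]:
    """Restrict to reports listing exactly one unique drug (monotherapy proxy)."""
    return [r for r in records if r.n_drugs_in_report == 1]


# -- tabular IO --------------------------------------------------------------

_RECORD_COLS = ["case_id", "case_version", "cmm_id", "pt", "n_drugs_in_report"]


def records_from_frame(df: pd.DataFrame) -> list[ReportRecord]:
    missing = [c for c in _RECORD_COLS if c not in df.columns]
    if missing:
        raise CurationError(f"record table missing columns: {missing}")
    return [ReportRecord(case_id=str(r.case_id),
                         case_version=int(r.case_version),
                         cmm_id=str(r.cmm_id), pt=str(r.pt),
                         n_drugs_in_report=int(r.n_drugs_in_report))
            for r in df.itertuples(index=False)]


def records_to_frame(records: list[ReportRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=_RECORD_COLS)


def pairs_to_frame(pairs: list[PairAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.cmm_id, p.pt, p.report_count, p.provenance) for p in pairs],
        columns=["cmm_id", "pt", "report_count", "provenance"])


def pairs_from_frame(df: pd.DataFrame) -> list[PairAssociation]:
    return [PairAssociation(cmm_id=str(r.cmm_id), pt=str(r.pt),
                            report_count=int(r.report_count),
                            provenance=str(r.provenance))
            for r in df.itertuples(index=False)]


def read_records_tsv(path) -> list[ReportRecord]:
    return records_from_frame(pd.read_csv(path, sep="\t", dtype=str))


def read_blacklist(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_pairs_tsv(pairs: list[PairAssociation], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def curate(records: list[ReportRecord], blacklist: set[str],
           literature_pairs: list[PairAssociation] | None = None
           ) -> list[PairAssociation]:
    """Full curation pipeline from raw records to curated associations."""
    deduped = dedup_latest_version(records)
    kept, removed = filter_non_adr(deduped, blacklist)
    logger.info("curate: %d records after dedup, %d removed as non-ADR",
                len(deduped), removed)
    faers_pairs = aggregate_pairs(kept)
    if literature_pairs is None:
        return faers_pairs
    return union_with_literature(faers_pairs, literature_pairs)
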