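"""Mapping source-database annotations to application-ontology classes.

Data sources (EVA, UniProt, ArrayExpress, ...) annotate records with textual
trait names and prefixed identifier cross-references (OMIM, SNOMED-CT,
MeSH-style ids).  The application ontology carries the reciprocal
cross-references on its classes, so mapping proceeds by:

1. building an index from normalized prefixed id to the set of classes that
   cite it;
2. mapping each record through its ids — a unique hit is a 1:1 mapping; a
   1-to-many hit is resolved only when the record's trait name equals the
   preferred label or an *exact*-scoped synonym of exactly one candidate
   (broad/narrow synonyms never qualify); everything else is deferred to
   manual curation;
3. applying a manual-curation table for records the automatic pass could not
   place;
4. reporting per-source coverage as integer percentages.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ontology import OntologyClass

logger = logging.getLogger(__name__)

MAPPED_1TO1 = "mapped_1to1"
MAPPED_SYNONYM = "mapped_synonym_resolved"
UNMAPPED = "unmapped_needs_curation"

#: prefix synonyms folded to a canonical uppercase form; extensible
DEFAULT_PREFIX_SYNONYMS = {
    "MIM": "OMIM",
    "OMIM": "OMIM",
    "ORPHA": "ORPHANET",
    "ORDO": "ORPHANET",
    "ORPHANET": "ORPHANET",
    "SNOMED": "SNOMEDCT",
    "SNOMED-CT": "SNOMEDCT",
    "SNOMEDCT": "SNOMEDCT",
    "MESH": "MESH",
    "MSH": "MESH",
}

_XREF_RE = re.compile(r"^\s*([A-Za-z][A-Za-z0-9.-]*)[\s:_]+(\S+)\s*$")


def normalize_xref(xref: str,
                   prefix_synonyms: Mapping[str, str] | None = None) -> str | None:
    """Normalize a prefixed identifier to ``PREFIX:ID`` canonical form.

    ``"OMIM:115500"``, ``"MIM 115500"`` and ``"omim_115500"`` all become
    ``"OMIM:115500"``.  Returns ``None`` for strings that do not look like
    a prefixed identifier.
    """
    if prefix_synonyms is None:
        prefix_synonyms = DEFAULT_PREFIX_SYNONYMS
    m = _XREF_RE.match(xref)
    if not m:
        return None
    prefix, ident = m.group(1).upper(), m.group(2)
    prefix = prefix_synonyms.get(prefix, prefix)
    return f"{prefix}:{ident}"


@dataclass(frozen=True)
class SourceRecord:
    """One source-database annotation."""

    source: str
    record_id: str
    trait_label: str
    xrefs: tuple[str, ...] = ()


@dataclass(frozen=True)
class MappingResult:
    record_id: str
    status: str
    target_iri: str | None = None
    evidence: str = ""

    def __post_init__(self):
        if (self.target_iri is None) != (self.status == UNMAPPED):
            raise ValueError(
                "target_iri must be present exactly when the record is mapped")

    @property
    def mapped(self) -> bool:
        return self.status != UNMAPPED


def build_xref_index(ontology: Mapping[str, OntologyClass] | Iterable[OntologyClass],
                     prefix_synonyms: Mapping[str, str] | None = None,
                     ) -> dict[str, frozenset[str]]:
    """Index from normalized prefixed id to the set of class IRIs citing it."""
    if isinstance(ontology, Mapping):
        ontology = ontology.values()
    index: dict[str, set[str]] = {}
    for cls in ontology:
        for raw in cls.xrefs:
            key = normalize_xref(raw, prefix_synonyms)
            if key is not None:
                index.setdefault(key, set()).add(cls.iri)
    return {k: frozenset(v) for k, v in index.items()}


def _norm_label(text: str) -> str:
    # case-insensitive, whitespace-collapsed, no stemming
    return " ".join(text.casefold().split())


def map_record(record: SourceRecord,
               index: Mapping[str, frozenset[str]],
               ontology: Mapping[str, OntologyClass],
               prefix_synonyms: Mapping[str, str] | None = None) -> MappingResult:
    """Map one record through its cross-references.

    Deterministic and independent of ontology iteration order.  Ambiguity is
    a status (``unmapped_needs_curation``), never an exception.
    """
    hits: dict[str, frozenset[str]] = {}
    for raw in record.xrefs:
        key = normalize_xref(raw, prefix_synonyms)
        if key is not None and key in index:
            hits[key] = index[key]
    if not hits:
        return MappingResult(record.record_id, UNMAPPED,
                             evidence="no cross-reference hit")
    all_candidates = sorted(set().union(*hits.values()))
    if len(all_candidates) == 1:
        key = sorted(hits)[0]
        return MappingResult(record.record_id, MAPPED_1TO1, all_candidates[0],
                             evidence=f"xref {key}")
    if len(hits) > 1:
        # two xrefs hitting different classes: defer to curation
        return MappingResult(
            record.record_id, UNMAPPED,
            evidence="conflicting xrefs; candidates: " + ", ".join(all_candidates))
    # one xref, many classes: resolve by exact-scoped synonym or label only
    key = next(iter(hits))
    wanted = _norm_label(record.trait_label)
    resolved = []
    for iri in all_candidates:
        cls = ontology[iri]
        names = [cls.label] + cls.exact_synonyms()
        if any(_norm_label(n) == wanted for n in names):
            resolved.append(iri)
    if len(resolved) == 1:
        return MappingResult(record.record_id, MAPPED_SYNONYM, resolved[0],
                             evidence=f"xref {key} resolved by exact synonym match")
    return MappingResult(
        record.record_id, UNMAPPED,
        evidence=f"xref {key} ambiguous; candidates: " + ", ".join(all_candidates))


def map_records(records: Sequence[SourceRecord],
                ontology: Mapping[str, OntologyClass],
                prefix_synonyms: Mapping[str, str] | None = None,
                ) -> dict[str, MappingResult]:
    """Map a batch of records; results keyed by record_id."""
    index = build_xref_index(ontology, prefix_synonyms)
    return {r.record_id: map_record(r, index, ontology, prefix_synonyms)
            for r in records}


def apply_manual_map(results: Mapping[str, MappingResult] | Sequence[MappingResult],
                     manual: Mapping[str, str],
                     ontology: Mapping[str, OntologyClass],
                     ) -> dict[str, MappingResult]:
    """Overlay a manual-curation table (record_id -> target IRI).

    Only unmapped records change; rows naming already-mapped records are
    logged and ignored.  Manual targets absent from the ontology raise a
    ``ValueError`` listing all offenders before anything is applied.
    """
    if not isinstance(results, Mapping):
        results = {r.record_id: r for r in results}
    bogus = sorted(iri for iri in manual.values() if iri not in ontology)
    if bogus:
        raise ValueError("manual map targets absent from ontology: "
                         + ", ".join(bogus))
    out = dict(results)
    for record_id, iri in manual.items():
        existing = out.get(record_id)
        if existing is None:
            logger.warning("manual map names unknown record %s", record_id)
            continue
        if existing.mapped:
            logger.warning("manual map names already-mapped record %s; ignored",
                           record_id)
            continue
        out[record_id] = MappingResult(record_id, MAPPED_1TO1, iri,
                                       evidence="manual")
    return out


@dataclass(frozen=True)
class CoverageRow:
    source: str
    n_labels: int
    n_mapped: int
    percent: int          # round-half-up, as printed in summary tables
    percent_raw: float


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def coverage_report(records: Sequence[SourceRecord],
                    results: Mapping[str, MappingResult],
                    min_frequency: int | None = None) -> list[CoverageRow]:
    """Per-source mapping coverage over distinct trait labels.

    ``percent = 100 * mapped / total`` rounded half-up to an integer; the
    raw value is retained.  ``min_frequency`` restricts the computation to
    trait labels occurring more than that many times (coverage of frequent
    annotations).  Sources with zero qualifying records are omitted with a
    warning.
    """
    by_source: dict[str, list[SourceRecord]] = {}
    for rec in records:
        by_source.setdefault(rec.source, []).append(rec)
    rows = []
    for source in sorted(by_source):
        recs = by_source[source]
        freq = Counter(_norm_label(r.trait_label) for r in recs)
        if min_frequency is not None:
            keep = {lbl for lbl, n in freq.items() if n > min_frequency}
        else:
            keep = set(freq)
        if not keep:
            logger.warning("source %s has no qualifying records; omitted", source)
            continue
        mapped_labels = {
            _norm_label(r.trait_label) for r in recs
            if _norm_label(r.trait_label) in keep
            and r.record_id in results and results[r.record_id].mapped}
        pct = 100.0 * len(mapped_labels) / len(keep)
        rows.append(CoverageRow(source, len(keep), len(mapped_labels),
                                _round_half_up(pct), pct))
    return rows


# ---------------------------------------------------------------------------
# TSV interfaces


def read_records_tsv(source) -> list[SourceRecord]:
    """Records TSV: source, record_id, trait_label, xrefs (semicolon-joined)."""
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_records_tsv(fh)
    reader = csv.reader(source, delimiter="\t")
    next(reader, None)
    out = []
    for row in reader:
        if not row or not row[0]:
            continue
        source_name, record_id, trait_label, xrefs = (row + [""] * 4)[:4]
        out.append(SourceRecord(
            source_name, record_id, trait_label,
            tuple(x for x in xrefs.split(";") if x)))
    return out


def write_records_tsv(records: Sequence[SourceRecord], path=None) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["source", "record_id", "trait_label", "xrefs"])
    for r in records:
        w.writerow([r.source, r.record_id, r.trait_label, ";".join(r.xrefs)])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_manual_map_tsv(source) -> dict[str, str]:
    """Two-column TSV: record_id, target IRI."""
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_manual_map_tsv(fh)
    reader = csv.reader(source, delimiter="\t")
    next(reader, None)
    return {row[0]: row[1] for row in reader if row and row[0]}


def write_results_tsv(results: Mapping[str, MappingResult], path=None) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["record_id", "status", "target_iri", "evidence"])
    for record_id in sorted(results):
        r = results[record_id]
        w.writerow([r.record_id, r.status, r.target_iri or "", r.evidence])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_coverage_tsv(rows: Sequence[CoverageRow], path=None) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["source", "n_labels", "n_mapped", "percent"])
    for r in rows:
        w.writerow([r.source, r.n_labels, r.n_mapped, r.percent])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
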