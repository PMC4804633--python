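"""Dictionary-based mining of candidate disease-phenotype associations.

The pipeline mirrors a literature-mining workflow over a local corpus of
abstracts: select the documents that mention a disease (by preferred label
or any synonym), match a phenotype dictionary (HP/MP-style labels plus
exact synonyms) against the selected abstracts, score each phenotype by
corpus-wide term frequency and inverse document frequency, discard
non-informative stoplist terms ("All", "Chronic", "death", ...), and merge
expert curation votes under a 2-of-3 agreement rule.

Matching is case-insensitive, token-boundary, longest-match-wins and
non-overlapping within a document.  Tokens split on non-alphanumerics with
word-internal apostrophes kept intact, so "Crohn's" is one token.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ontology import OntologyClass

logger = logging.getLogger(__name__)

#: phenotype labels that are valid ontology terms but uninformative as
#: mined phenotypes; user-extensible
DEFAULT_STOPLIST = frozenset({"all", "chronic", "death", "sudden death"})

STATUS_CANDIDATE = "candidate"
STATUS_STOPLISTED = "stoplisted"
STATUS_ACCEPTED = "accepted"
STATUS_REJECTED = "rejected"
STATUS_UNDECIDED = "undecided"

VOTE_VALUES = ("yes", "no", "maybe")

# apostrophe is word-internal: "Crohn's" tokenizes as one token
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z0-9]+)*")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Lower-cased tokens with character spans."""
    return [(m.group(0).casefold(), m.start(), m.end())
            for m in _TOKEN_RE.finditer(text)]


def _form_tokens(form: str) -> tuple[str, ...]:
    return tuple(t for t, _, _ in tokenize(form))


@dataclass(frozen=True)
class DictionaryEntry:
    """A phenotype term and the surface forms that match it in text."""

    phenotype_iri: str
    label: str
    surface_forms: tuple[str, ...]

    def __post_init__(self):
        if not self.surface_forms:
            raise ValueError(f"{self.phenotype_iri}: surface forms must be non-empty")
        seen, dedup = set(), []
        for f in self.surface_forms:
            key = f.casefold()
            if key not in seen:
                seen.add(key)
                dedup.append(f)
        object.__setattr__(self, "surface_forms", tuple(dedup))


def build_dictionary(ontology: Mapping[str, OntologyClass] | Iterable[OntologyClass],
                     namespaces: Sequence[str] = ("HP", "MP"),
                     ) -> list[DictionaryEntry]:
    """Dictionary from the phenotype namespaces of an ontology: preferred
    label plus exact-scoped synonyms, deduplicated case-insensitively."""
    if isinstance(ontology, Mapping):
        ontology = ontology.values()
    entries = []
    for cls in sorted(ontology, key=lambda c: c.iri):
        if namespaces and cls.namespace not in namespaces:
            continue
        entries.append(DictionaryEntry(
            cls.iri, cls.label, (cls.label, *cls.exact_synonyms())))
    return entries


@dataclass(frozen=True)
class CorpusDoc:
    doc_id: str
    text: str


@dataclass(frozen=True)
class TermMatch:
    """One dictionary hit: IRI, document, character span and matched text."""

    phenotype_iri: str
    doc_id: str
    start: int
    end: int
    text: str


def select_corpus(docs: Iterable[CorpusDoc],
                  disease_labels: Sequence[str]) -> list[CorpusDoc]:
    """Documents mentioning at least one disease label (case-insensitive,
    token-boundary).  Uses the same matcher as phenotype terms."""
    if not disease_labels:
        raise ValueError("disease_labels must be non-empty")
    entries = [DictionaryEntry("urn:obanlink:corpus-query", disease_labels[0],
                               tuple(disease_labels))]
    selected = []
    for doc in sorted(docs, key=lambda d: d.doc_id):
        if match_terms([doc], entries):
            selected.append(doc)
    if not selected:
        logger.warning("no document mentions any of %d disease labels",
                       len(disease_labels))
    return selected


def match_terms(corpus: Iterable[CorpusDoc],
                dictionary: Sequence[DictionaryEntry]) -> list[TermMatch]:
    """Greedy leftmost-longest, non-overlapping dictionary matching.

    At each token position the longest surface form starting there wins and
    matching resumes after it; ties between phenotypes sharing a surface
    form report every owner of that form at the same span.
    """
    if not dictionary:
        raise ValueError("dictionary must be non-empty")
    forms: dict[tuple[str, ...], list[DictionaryEntry]] = defaultdict(list)
    for entry in dictionary:
        for form in entry.surface_forms:
            toks = _form_tokens(form)
            if toks:
                forms[toks].append(entry)
    max_len = max(len(t) for t in forms)
    matches: list[TermMatch] = []
    for doc in sorted(corpus, key=lambda d: d.doc_id):
        tokens = tokenize(doc.text)
        i = 0
        while i < len(tokens):
            hit_len = 0
            for length in range(min(max_len, len(tokens) - i), 0, -1):
                window = tuple(t for t, _, _ in tokens[i:i + length])
                if window in forms:
                    hit_len = length
                    break
            if hit_len:
                start = tokens[i][1]
                end = tokens[i + hit_len - 1][2]
                window = tuple(t for t, _, _ in tokens[i:i + hit_len])
                for entry in sorted(forms[window], key=lambda e: e.phenotype_iri):
                    matches.append(TermMatch(entry.phenotype_iri, doc.doc_id,
                                             start, end, doc.text[start:end]))
                i += hit_len
            else:
                i += 1
    return matches


@dataclass(frozen=True)
class CandidateAssociation:
    """A mined disease-phenotype pair with its ranking statistics."""

    disease_iri: str
    disease_label: str
    phenotype_iri: str
    phenotype_label: str
    tf: int
    idf: float
    doc_ids: tuple[str, ...]
    status: str = STATUS_CANDIDATE

    def pair(self) -> tuple[str, str]:
        return (self.disease_iri, self.phenotype_iri)


def score_candidates(matches: Sequence[TermMatch],
                     corpus: Sequence[CorpusDoc],
                     disease_iri: str,
                     disease_label: str,
                     labels: Mapping[str, str] | None = None,
                     ) -> list[CandidateAssociation]:
    """One candidate per phenotype matched anywhere in the corpus.

    ``tf`` is the corpus-wide raw match count; ``idf = ln(N/df)`` with N the
    corpus size and df the number of documents with at least one match.
    Phenotypes with no match yield no row.  Rows are ordered tf-descending
    then by IRI.
    """
    n_docs = len(corpus)
    doc_ids = {d.doc_id for d in corpus}
    tf: Counter[str] = Counter()
    docs_of: dict[str, set[str]] = defaultdict(set)
    sample_text: dict[str, str] = {}
    for m in matches:
        if m.doc_id not in doc_ids:
            raise ValueError(f"match references {m.doc_id} outside the corpus")
        tf[m.phenotype_iri] += 1
        docs_of[m.phenotype_iri].add(m.doc_id)
        sample_text.setdefault(m.phenotype_iri, m.text)
    out = []
    for iri in tf:
        df = len(docs_of[iri])
        label = labels.get(iri) if labels else None
        out.append(CandidateAssociation(
            disease_iri=disease_iri, disease_label=disease_label,
            phenotype_iri=iri,
            phenotype_label=label if label is not None else sample_text[iri],
            tf=tf[iri], idf=math.log(n_docs / df),
            doc_ids=tuple(sorted(docs_of[iri]))))
    out.sort(key=lambda c: (-c.tf, c.phenotype_iri))
    return out


def apply_stoplist(candidates: Sequence[CandidateAssociation],
                   stoplist: Iterable[str] | None = None,
                   ) -> list[CandidateAssociation]:
    """Relabel candidates whose phenotype label or IRI is stoplisted.

    Counts are conserved: rows are never deleted, only given
    ``status='stoplisted'``.
    """
    if stoplist is None:
        stoplist = DEFAULT_STOPLIST
    stopset = {s.casefold() for s in stoplist}
    out = []
    for c in candidates:
        if c.phenotype_label.casefold() in stopset or c.phenotype_iri in stoplist:
            out.append(replace(c, status=STATUS_STOPLISTED))
        else:
            out.append(c)
    return out


@dataclass(frozen=True)
class Vote:
    disease_iri: str
    phenotype_iri: str
    reviewer_id: str
    vote: str

    def __post_init__(self):
        if self.vote not in VOTE_VALUES:
            raise ValueError(f"vote must be one of {VOTE_VALUES}, got {self.vote!r}")


def merge_votes(candidates: Sequence[CandidateAssociation],
                votes: Sequence[Vote],
                quorum: int = 2, panel: int = 3,
                ) -> list[CandidateAssociation]:
    """Merge expert votes: accept/reject on a quorum of agreeing votes.

    A pair is ``accepted`` with >= quorum "yes" votes, ``rejected`` with
    >= quorum "no" votes, otherwise ``undecided`` — "maybe" counts toward
    neither side, and an undecided pair is retained, not dropped.  More than
    ``panel`` votes for one pair, or two votes from one reviewer, is an
    error; votes on unknown pairs are an error; votes on stoplisted rows
    are ignored with a warning.
    """
    known = {c.pair(): c.status for c in candidates}
    by_pair: dict[tuple[str, str], list[Vote]] = defaultdict(list)
    for v in votes:
        pair = (v.disease_iri, v.phenotype_iri)
        if pair not in known:
            raise KeyError(f"vote references unknown candidate pair {pair}")
        if known[pair] == STATUS_STOPLISTED:
            logger.warning("ignoring vote on stoplisted pair %s", pair)
            continue
        if any(prev.reviewer_id == v.reviewer_id for prev in by_pair[pair]):
            raise ValueError(
                f"reviewer {v.reviewer_id} voted twice on pair {pair}")
        by_pair[pair].append(v)
        if len(by_pair[pair]) > panel:
            raise ValueError(f"more than {panel} votes for pair {pair}")
    out = []
    for c in candidates:
        pair_votes = by_pair.get(c.pair())
        if c.status == STATUS_STOPLISTED or not pair_votes:
            out.append(c)
            continue
        counts = Counter(v.vote for v in pair_votes)
        yes, no = counts["yes"], counts["no"]
        if yes >= quorum and no >= quorum:
            status = STATUS_UNDECIDED  # conflicting quorums (panel > 2*quorum-1)
        elif yes >= quorum:
            status = STATUS_ACCEPTED
        elif no >= quorum:
            status = STATUS_REJECTED
        else:
            status = STATUS_UNDECIDED
        out.append(replace(c, status=status))
    return out


def precision(candidates: Sequence[CandidateAssociation]) -> float:
    """Fraction of reviewed candidates deemed correct, as a percentage with
    one decimal: accepted / (accepted + rejected + undecided) over
    non-stoplisted candidates."""
    counts = Counter(c.status for c in candidates)
    reviewed = (counts[STATUS_ACCEPTED] + counts[STATUS_REJECTED]
                + counts[STATUS_UNDECIDED])
    if reviewed == 0:
        raise ValueError("no reviewed candidates to compute precision over")
    return round(100.0 * counts[STATUS_ACCEPTED] / reviewed, 1)


# ---------------------------------------------------------------------------
# TSV interfaces


def export_candidates(candidates: Sequence[CandidateAssociation], path=None) -> str:
    """Spreadsheet-style TSV, stable row order (tf desc, then IRIs)."""
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["disease_iri", "disease_label", "phenotype_iri",
                "phenotype_label", "tf", "idf", "doc_ids", "status"])
    ordered = sorted(candidates,
                     key=lambda c: (-c.tf, c.disease_iri, c.phenotype_iri))
    for c in ordered:
        w.writerow([c.disease_iri, c.disease_label, c.phenotype_iri,
                    c.phenotype_label, c.tf, repr(c.idf),
                    ";".join(c.doc_ids), c.status])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_candidates(source) -> list[CandidateAssociation]:
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_candidates(fh)
    reader = csv.reader(source, delimiter="\t")
    next(reader, None)
    out = []
    for row in reader:
        if not row or not row[0]:
            continue
        out.append(CandidateAssociation(
            disease_iri=row[0], disease_label=row[1], phenotype_iri=row[2],
            phenotype_label=row[3], tf=int(row[4]), idf=float(row[5]),
            doc_ids=tuple(x for x in row[6].split(";") if x), status=row[7]))
    return out


def read_votes_tsv(source) -> list[Vote]:
    """Vote sheet TSV: disease_iri, phenotype_iri, reviewer_id, vote."""
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_votes_tsv(fh)
    reader = csv.reader(source, delimiter="\t")
    next(reader, None)
    return [Vote(*row[:4]) for row in reader if row and row[0]]


def write_votes_tsv(votes: Sequence[Vote], path=None) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["disease_iri", "phenotype_iri", "reviewer_id", "vote"])
    for v in votes:
        w.writerow([v.disease_iri, v.phenotype_iri, v.reviewer_id, v.vote])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_corpus_tsv(source) -> list[CorpusDoc]:
    """Corpus TSV: doc_id, text (one abstract per row)."""
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_corpus_tsv(fh)
    reader = csv.reader(source, delimiter="\t")
    next(reader, None)
    docs, seen = [], set()
    for row in reader:
        if not row or not row[0]:
            continue
        if row[0] in seen:
            raise ValueError(f"duplicate doc_id {row[0]} in corpus")
        seen.add(row[0])
        docs.append(CorpusDoc(row[0], row[1]))
    return docs


def write_corpus_tsv(docs: Sequence[CorpusDoc], path=None) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["doc_id", "text"])
    for d in docs:
        w.writerow([d.doc_id, d.text])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_corpus_dir(path) -> list[CorpusDoc]:
    """Directory of ``.txt`` files; doc_id from filename stem."""
    docs = []
    for p in sorted(Path(path).glob("*.txt")):
        docs.append(CorpusDoc(p.stem, p.read_text(encoding="utf-8")))
    return docs
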