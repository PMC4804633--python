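"""Ontology classes and their on-disk representations.

An application ontology (EFO-style) assembles disease and phenotype classes
from several namespaces (EFO-native common diseases, Orphanet-imported rare
diseases, HP/MP phenotypes).  Each class carries a preferred label, scoped
synonyms (exact / broad / narrow / related) and cross-references to external
vocabularies (OMIM, SNOMED-CT, MeSH, ...).  Two serializations are supported:

* a simplified 6-column TSV dialect (``iri, label, synonym, scope, xref,
  namespace``) used for fixtures and quick editing — one row per
  synonym/xref slot, rows aggregated by IRI;
* OWL (read with rdflib; labels via ``rdfs:label``, synonyms via the
  oboInOwl synonym properties, cross-references via ``oboInOwl:hasDbXref``
  or any EFO-style ``*_definition_citation`` annotation property).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS, OWL

SYNONYM_SCOPES = ("exact", "broad", "narrow", "related")

OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"
_SCOPE_PROPS = {
    "exact": URIRef(OBOINOWL + "hasExactSynonym"),
    "broad": URIRef(OBOINOWL + "hasBroadSynonym"),
    "narrow": URIRef(OBOINOWL + "hasNarrowSynonym"),
    "related": URIRef(OBOINOWL + "hasRelatedSynonym"),
}
_PROP_SCOPES = {v: k for k, v in _SCOPE_PROPS.items()}
HAS_DBXREF = URIRef(OBOINOWL + "hasDbXref")


@dataclass(frozen=True)
class Synonym:
    """A synonym with its scope qualifier.

    Only ``exact``-scoped synonyms may resolve ambiguous cross-reference
    mappings; broad/narrow/related synonyms never qualify.
    """

    text: str
    scope: str = "exact"

    def __post_init__(self) -> None:
        if self.scope not in SYNONYM_SCOPES:
            raise ValueError(f"unknown synonym scope {self.scope!r}")


@dataclass
class OntologyClass:
    """One ontology term: the unit of all mapping."""

    iri: str
    label: str
    synonyms: list[Synonym] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    namespace: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"ontology class {self.iri} has empty label")
        if not self.namespace:
            self.namespace = namespace_of(self.iri)

    def exact_synonyms(self) -> list[str]:
        return [s.text for s in self.synonyms if s.scope == "exact"]


def local_name(iri: str) -> str:
    """Local part of an IRI (after the last ``/`` or ``#``)."""
    return iri.rstrip("/").rsplit("/", 1)[-1].rsplit("#", 1)[-1]


def namespace_of(iri: str) -> str:
    """Namespace prefix of an IRI's local name, e.g. ``EFO`` for
    ``.../EFO_0004144``.  Empty string when the local name has no
    underscore-delimited prefix."""
    name = local_name(iri)
    if "_" in name:
        return name.rsplit("_", 1)[0]
    return ""


# ---------------------------------------------------------------------------
# tabular dialect


def read_ontology_tsv(source) -> dict[str, OntologyClass]:
    """Read the 6-column tabular ontology dialect.

    Columns: iri, label, synonym, scope, xref, namespace.  Several rows may
    share an IRI, each contributing at most one synonym and one xref; empty
    cells are skipped.  Returns classes keyed by IRI.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_ontology_tsv(fh)
    classes: dict[str, OntologyClass] = {}
    reader = csv.reader(source, delimiter="\t")
    header = next(reader, None)
    if header is None:
        return classes
    for row in reader:
        if not row or not row[0]:
            continue
        iri, label, synonym, scope, xref, namespace = (row + [""] * 6)[:6]
        cls = classes.get(iri)
        if cls is None:
            cls = OntologyClass(iri=iri, label=label, namespace=namespace)
            classes[iri] = cls
        if synonym:
            syn = Synonym(synonym, scope or "exact")
            if syn not in cls.synonyms:
                cls.synonyms.append(syn)
        if xref and xref not in cls.xrefs:
            cls.xrefs.append(xref)
    return classes


def write_ontology_tsv(classes: Mapping[str, OntologyClass] | Iterable[OntologyClass],
                       path=None) -> str:
    """Write the tabular dialect; deterministic (classes sorted by IRI)."""
    if isinstance(classes, Mapping):
        classes = classes.values()
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["iri", "label", "synonym", "scope", "xref", "namespace"])
    for cls in sorted(classes, key=lambda c: c.iri):
        slots = max(1, len(cls.synonyms), len(cls.xrefs))
        for i in range(slots):
            syn = cls.synonyms[i] if i < len(cls.synonyms) else None
            xref = cls.xrefs[i] if i < len(cls.xrefs) else ""
            writer.writerow([
                cls.iri, cls.label,
                syn.text if syn else "", syn.scope if syn else "",
                xref, cls.namespace,
            ])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# OWL


def read_ontology_owl(source, rdf_format: str | None = None) -> dict[str, OntologyClass]:
    """Read ontology classes from an OWL/RDF file via rdflib.

    Labels come from ``rdfs:label``; synonyms from the oboInOwl synonym
    properties; cross-references from ``oboInOwl:hasDbXref`` plus any
    annotation property whose IRI contains ``definition_citation`` (the
    EFO convention, e.g. ``OMIM_definition_citation``).
    """
    g = Graph()
    if rdf_format is None:
        rdf_format = _sniff_format(source)
    g.parse(source, format=rdf_format)
    classes: dict[str, OntologyClass] = {}
    for s in sorted(g.subjects(RDF.type, OWL.Class)):
        if not isinstance(s, URIRef):
            continue
        label = g.value(s, RDFS.label)
        if label is None:
            continue
        cls = OntologyClass(iri=str(s), label=str(label))
        for prop, scope in sorted(_PROP_SCOPES.items()):
            for o in sorted(g.objects(s, prop)):
                cls.synonyms.append(Synonym(str(o), scope))
        xrefs = {str(o) for o in g.objects(s, HAS_DBXREF)}
        for p, o in g.predicate_objects(s):
            if "definition_citation" in str(p):
                xrefs.add(str(o))
        cls.xrefs = sorted(xrefs)
        classes[str(s)] = cls
    return classes


def ontology_to_triples(classes: Mapping[str, OntologyClass]):
    """Flatten an ontology to rdflib triples (for the deterministic RDF
    writers in :mod:`obanlink.oban`)."""
    triples = []
    for cls in classes.values():
        s = URIRef(cls.iri)
        triples.append((s, RDF.type, OWL.Class))
        triples.append((s, RDFS.label, Literal(cls.label)))
        for syn in cls.synonyms:
            triples.append((s, _SCOPE_PROPS[syn.scope], Literal(syn.text)))
        for xref in cls.xrefs:
            triples.append((s, HAS_DBXREF, Literal(xref)))
    return triples


def _sniff_format(source) -> str:
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower()
        if suffix in {".ttl", ".n3"}:
            return "turtle"
        if suffix in {".owl", ".rdf", ".xml"}:
            return "xml"
        head = Path(source).read_bytes()[:200].lstrip()
        return "xml" if head.startswith(b"<") else "turtle"
    return "xml"
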