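"""The OBAN association model: reified disease-phenotype links with provenance.

Class-level OWL axioms assert relations that hold for *every* member of a
class ("always true").  Disease-phenotype relations are usually "sometimes
associated": not every Crohn's disease patient has diarrhea.  OBAN therefore
reifies each link as a named individual of an ``association`` class with
exactly one ``association_has_subject`` and one ``association_has_object``
property, plus one or more ``provenance`` individuals (typed by an
evidence-code class) that validate the statement.  The disease and phenotype
individuals are *punned*: the individual carries the same IRI as the
ontology class, so no parallel instance IRIs are minted.

Serialization is deliberately deterministic — triples are sorted
lexicographically before writing — so that re-running a build on identical
inputs yields byte-identical Turtle/RDF-XML.  Parsing accepts any RDF
dialect rdflib understands.

Class-level patterns for the relations that *are* always true (disease
location, abnormal biological process) are emitted as Manchester-syntax
text by :func:`emit_class_axiom`, contrasting with the instance-level
association model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping
from urllib.parse import urlparse
from xml.sax.saxutils import escape, quoteattr

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS, OWL, split_uri

from .ontology import OntologyClass

# Published OBAN vocabulary
OBAN_NS = "http://purl.org/oban/"
ASSOCIATION_CLASS = OBAN_NS + "association"
PROVENANCE_CLASS = OBAN_NS + "provenance"
HAS_SUBJECT = OBAN_NS + "association_has_subject"
HAS_OBJECT = OBAN_NS + "association_has_object"
HAS_PROVENANCE = OBAN_NS + "has_provenance"

# Minimal built-in evidence vocabulary (Evidence & Conclusion Ontology);
# user-supplied evidence IRIs pass through unchanged.
ECO_MANUAL_ASSERTION = "http://purl.obolibrary.org/obo/ECO_0000218"
ECO_AUTOMATIC_ASSERTION = "http://purl.obolibrary.org/obo/ECO_0000203"
EVIDENCE_LABELS = {
    ECO_MANUAL_ASSERTION: "manual assertion",
    ECO_AUTOMATIC_ASSERTION: "automatic assertion (text mining)",
}

# Common attribute predicates for provenance records
PUBMED_PREDICATE = OBAN_NS + "has_pubmed_id"
CURATOR_PREDICATE = OBAN_NS + "has_curator"
CONFIDENCE_PREDICATE = OBAN_NS + "has_confidence"

ENTITY_KINDS = ("disease", "phenotype", "other")


class OBANValidationError(ValueError):
    """An association or graph violates a model invariant."""


class GraphLookupError(KeyError):
    """A referenced association id is absent from the graph."""


class StructuralError(ValueError):
    """A parsed document is structurally incomplete (names the individual)."""


@dataclass(frozen=True)
class OBANConfig:
    """IRIs used when minting and serializing associations.

    ``base_namespace`` is where association ids are minted and where the
    package's own annotation vocabulary (the ``entity_kind`` marker) lives.
    The four OBAN property/class IRIs default to the published vocabulary.
    """

    base_namespace: str = "http://purl.example.org/obanlink/"
    association_class: str = ASSOCIATION_CLASS
    provenance_class: str = PROVENANCE_CLASS
    has_subject: str = HAS_SUBJECT
    has_object: str = HAS_OBJECT
    has_provenance: str = HAS_PROVENANCE
    dialect: str = "turtle"

    @property
    def entity_kind_predicate(self) -> str:
        return self.base_namespace + "entity_kind"

    @property
    def ontology_iri(self) -> str:
        return self.base_namespace + "ontology"

    @classmethod
    def from_dict(cls, d: Mapping) -> "OBANConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


DEFAULT_CONFIG = OBANConfig()


def _require_absolute_iri(iri: str, what: str) -> None:
    parsed = urlparse(iri)
    if not iri or not parsed.scheme or not (parsed.netloc or parsed.path):
        raise OBANValidationError(f"{what} is not an absolute IRI: {iri!r}")


@dataclass(frozen=True)
class BiologicalEntity:
    """A punned biological entity: same IRI as its ontology class."""

    iri: str
    label: str
    entity_kind: str = "other"

    def __post_init__(self) -> None:
        _require_absolute_iri(self.iri, "entity IRI")
        if self.entity_kind not in ENTITY_KINDS:
            raise OBANValidationError(
                f"entity_kind must be one of {ENTITY_KINDS}, got {self.entity_kind!r}")


@dataclass(frozen=True)
class ProvenanceRecord:
    """Evidence individual typed by an evidence-code class.

    ``attributes`` is an open-ended set of (predicate IRI, value) pairs —
    PubMed id, curator name, confidence score ... — a predicate may repeat
    with distinct values.
    """

    prov_id: str
    evidence_type: str
    attributes: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        _require_absolute_iri(self.prov_id, "provenance IRI")
        if not self.evidence_type:
            raise OBANValidationError("provenance requires an evidence_type IRI")
        _require_absolute_iri(self.evidence_type, "evidence_type")
        object.__setattr__(self, "attributes", frozenset(self.attributes))


@dataclass(frozen=True)
class ObanAssociation:
    """One reified subject-object link with its provenance references.

    Stored directionally (CTTV convention: subject=disease,
    object=phenotype); :meth:`link` gives the undirected view used for
    linkage queries.
    """

    assoc_id: str
    subject: BiologicalEntity
    object: BiologicalEntity
    provenance: tuple[ProvenanceRecord, ...]

    def __post_init__(self) -> None:
        _require_absolute_iri(self.assoc_id, "association IRI")
        if not self.provenance:
            raise OBANValidationError(
                f"association {self.assoc_id} has no provenance")
        if self.subject.iri == self.object.iri:
            raise OBANValidationError(
                f"association subject and object share IRI {self.subject.iri}")
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def link(self) -> frozenset[str]:
        """Undirected subject/object IRI pair."""
        return frozenset((self.subject.iri, self.object.iri))

    def _key(self):
        return (self.assoc_id, self.subject, self.object,
                frozenset(p.prov_id for p in self.provenance))


def mint_association_iri(subject_iri: str, object_iri: str,
                         base_namespace: str = DEFAULT_CONFIG.base_namespace) -> str:
    """Deterministic association IRI: content digest of the (subject,
    object) IRI pair under the configured base namespace, so re-runs are
    stable and idempotent."""
    digest = hashlib.sha1(f"{subject_iri}|{object_iri}".encode()).hexdigest()[:16]
    return f"{base_namespace}association/{digest}"


def build_association(subject: BiologicalEntity, object: BiologicalEntity,
                      provenance: Iterable[ProvenanceRecord],
                      config: OBANConfig = DEFAULT_CONFIG) -> ObanAssociation:
    """Create an association with a freshly minted deterministic id.

    Raises :class:`OBANValidationError` on empty provenance or identical
    subject/object IRIs.  Provenance order is preserved.
    """
    provenance = tuple(provenance)
    if not provenance:
        raise OBANValidationError("an association requires at least one provenance")
    if subject.iri == object.iri:
        raise OBANValidationError(
            f"self-association rejected: {subject.iri}")
    return ObanAssociation(
        assoc_id=mint_association_iri(subject.iri, object.iri, config.base_namespace),
        subject=subject, object=object, provenance=provenance)


@dataclass
class AssociationGraph:
    """A set of associations, their provenance records and punned entities.

    Invariants: every provenance referenced by an association is registered;
    association ids are unique; a provenance record may be shared by many
    associations but is stored once.
    """

    associations: dict[str, ObanAssociation] = field(default_factory=dict)
    provenances: dict[str, ProvenanceRecord] = field(default_factory=dict)
    entities: dict[str, BiologicalEntity] = field(default_factory=dict)

    def add_association(self, assoc: ObanAssociation) -> ObanAssociation:
        if assoc.assoc_id in self.associations:
            raise OBANValidationError(f"duplicate association id {assoc.assoc_id}")
        deduped = []
        for prov in assoc.provenance:
            deduped.append(self._register_provenance(prov))
        assoc = replace(assoc, provenance=tuple(deduped))
        self.associations[assoc.assoc_id] = assoc
        for ent in (assoc.subject, assoc.object):
            self.entities.setdefault(ent.iri, ent)
        return assoc

    def _register_provenance(self, prov: ProvenanceRecord) -> ProvenanceRecord:
        # an existing record with the same id is referenced, not duplicated
        return self.provenances.setdefault(prov.prov_id, prov)

    def add_provenance(self, assoc_id: str, prov: ProvenanceRecord) -> "AssociationGraph":
        """Attach one more provenance to an existing association."""
        if assoc_id not in self.associations:
            raise GraphLookupError(f"unknown association id {assoc_id}")
        prov = self._register_provenance(prov)
        assoc = self.associations[assoc_id]
        if prov.prov_id not in {p.prov_id for p in assoc.provenance}:
            self.associations[assoc_id] = replace(
                assoc, provenance=assoc.provenance + (prov,))
        return self

    def validate(self) -> None:
        for assoc in self.associations.values():
            for prov in assoc.provenance:
                if prov.prov_id not in self.provenances:
                    raise OBANValidationError(
                        f"association {assoc.assoc_id} references unregistered "
                        f"provenance {prov.prov_id}")

    def undirected_links(self) -> set[frozenset[str]]:
        return {a.link() for a in self.associations.values()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssociationGraph):
            return NotImplemented
        return (
            {a._key() for a in self.associations.values()}
            == {a._key() for a in other.associations.values()}
            and set(self.provenances.values()) == set(other.provenances.values())
            and set(self.entities.values()) == set(other.entities.values()))

    def __len__(self) -> int:
        return len(self.associations)


# ---------------------------------------------------------------------------
# deterministic serialization


def _graph_triples(graph: AssociationGraph, config: OBANConfig):
    triples: list[tuple[URIRef, URIRef, URIRef | Literal]] = []
    kind_pred = URIRef(config.entity_kind_predicate)
    triples.append((URIRef(config.ontology_iri), RDF.type, OWL.Ontology))
    for ent in graph.entities.values():
        s = URIRef(ent.iri)
        triples.append((s, RDF.type, OWL.NamedIndividual))
        triples.append((s, RDFS.label, Literal(ent.label)))
        triples.append((s, kind_pred, Literal(ent.entity_kind)))
    for prov in graph.provenances.values():
        s = URIRef(prov.prov_id)
        triples.append((s, RDF.type, URIRef(config.provenance_class)))
        triples.append((s, RDF.type, URIRef(prov.evidence_type)))
        for pred, value in prov.attributes:
            triples.append((s, URIRef(pred), Literal(value)))
    for assoc in graph.associations.values():
        s = URIRef(assoc.assoc_id)
        triples.append((s, RDF.type, OWL.NamedIndividual))
        triples.append((s, RDF.type, URIRef(config.association_class)))
        triples.append((s, URIRef(config.has_subject), URIRef(assoc.subject.iri)))
        triples.append((s, URIRef(config.has_object), URIRef(assoc.object.iri)))
        for prov in assoc.provenance:
            triples.append((s, URIRef(config.has_provenance), URIRef(prov.prov_id)))
    return triples


def serialize_triples(triples, dialect: str = "turtle") -> bytes:
    """Write triples deterministically: sorted by subject, predicate,
    object n3 form.  ``turtle`` emits one fully-spelled triple per line
    (an N-Triples subset, hence valid Turtle); ``rdfxml`` groups by
    subject with generated namespace prefixes."""
    ordered = sorted(set(triples), key=lambda t: (t[0].n3(), t[1].n3(), t[2].n3()))
    if dialect == "turtle":
        lines = [f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in ordered]
        return ("\n".join(lines) + "\n").encode("utf-8")
    if dialect == "rdfxml":
        return _write_rdfxml(ordered)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'turtle' or 'rdfxml')")


def _write_rdfxml(ordered) -> bytes:
    namespaces: dict[str, str] = {str(RDF): "rdf"}
    for _, p, _ in ordered:
        ns, _local = split_uri(str(p))
        if ns not in namespaces:
            namespaces[ns] = f"ns{len(namespaces)}"
    ns_attrs = "".join(
        f'\n  xmlns:{prefix}={quoteattr(ns)}'
        for ns, prefix in sorted(namespaces.items(), key=lambda kv: kv[1]))
    out = ['<?xml version="1.0" encoding="utf-8"?>', f"<rdf:RDF{ns_attrs}>"]
    current = None
    for s, p, o in ordered:
        if s != current:
            if current is not None:
                out.append("  </rdf:Description>")
            out.append(f"  <rdf:Description rdf:about={quoteattr(str(s))}>")
            current = s
        ns, local = split_uri(str(p))
        qname = f"{namespaces[ns]}:{local}"
        if isinstance(o, URIRef):
            out.append(f"    <{qname} rdf:resource={quoteattr(str(o))}/>")
        else:
            out.append(f"    <{qname}>{escape(str(o))}</{qname}>")
    if current is not None:
        out.append("  </rdf:Description>")
    out.append("</rdf:RDF>")
    return ("\n".join(out) + "\n").encode("utf-8")


def serialize(graph: AssociationGraph, dialect: str = "turtle",
              config: OBANConfig = DEFAULT_CONFIG) -> bytes:
    """Serialize a validated graph; byte-identical across runs for the same
    graph and dialect."""
    graph.validate()
    return serialize_triples(_graph_triples(graph, config), dialect)


def parse(document: bytes | str, dialect: str | None = None,
          config: OBANConfig = DEFAULT_CONFIG) -> AssociationGraph:
    """Parse an OBAN RDF document back into an :class:`AssociationGraph`.

    Unknown extra triples on provenance individuals are preserved as
    attributes.  An association individual lacking a subject, object or
    provenance raises :class:`StructuralError` naming the individual, as
    does a provenance individual with no evidence-code type.  Entities
    without an explicit kind annotation are inferred positionally
    (subject=disease, object=phenotype).
    """
    if isinstance(document, bytes):
        text = document.decode("utf-8")
    else:
        text = document
    if dialect is None:
        head = text.lstrip()
        dialect = "rdfxml" if head.startswith(("<?xml", "<rdf:RDF")) else "turtle"
    rdf_format = {"turtle": "turtle", "rdfxml": "xml"}.get(dialect)
    if rdf_format is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    g = Graph()
    g.parse(data=text, format=rdf_format)

    kind_pred = URIRef(config.entity_kind_predicate)
    out = AssociationGraph()

    prov_records: dict[str, ProvenanceRecord] = {}

    def provenance_for(node: URIRef) -> ProvenanceRecord:
        iri = str(node)
        if iri in prov_records:
            return prov_records[iri]
        types = {str(t) for t in g.objects(node, RDF.type)}
        evidence = sorted(types - {config.provenance_class, str(OWL.NamedIndividual)})
        if not evidence:
            raise StructuralError(
                f"provenance individual {iri} has no evidence-code type")
        attrs = set()
        for p, o in g.predicate_objects(node):
            if p == RDF.type:
                continue
            attrs.add((str(p), str(o)))
        rec = ProvenanceRecord(prov_id=iri, evidence_type=evidence[0],
                               attributes=frozenset(attrs))
        prov_records[iri] = rec
        return rec

    def entity_for(node: URIRef, role_kind: str) -> BiologicalEntity:
        iri = str(node)
        if iri in out.entities:
            return out.entities[iri]
        label = g.value(node, RDFS.label)
        kind = g.value(node, kind_pred)
        ent = BiologicalEntity(
            iri=iri,
            label=str(label) if label is not None else iri.rsplit("/", 1)[-1],
            entity_kind=str(kind) if kind is not None else role_kind)
        out.entities[iri] = ent
        return ent

    assoc_class = URIRef(config.association_class)
    for node in sorted(g.subjects(RDF.type, assoc_class)):
        iri = str(node)
        subjects = list(g.objects(node, URIRef(config.has_subject)))
        objects = list(g.objects(node, URIRef(config.has_object)))
        provs = sorted(g.objects(node, URIRef(config.has_provenance)))
        if len(subjects) != 1:
            raise StructuralError(
                f"association {iri} has {len(subjects)} subject triples (need 1)")
        if len(objects) != 1:
            raise StructuralError(
                f"association {iri} has {len(objects)} object triples (need 1)")
        if not provs:
            raise StructuralError(f"association {iri} has no provenance")
        assoc = ObanAssociation(
            assoc_id=iri,
            subject=entity_for(subjects[0], "disease"),
            object=entity_for(objects[0], "phenotype"),
            provenance=tuple(provenance_for(p) for p in provs))
        if iri in out.associations:
            raise StructuralError(f"duplicate association individual {iri}")
        out.associations[iri] = assoc
        for prov in assoc.provenance:
            out.provenances.setdefault(prov.prov_id, prov)
    # drop entities never used by an association (e.g. orphan individuals)
    used = {e for a in out.associations.values() for e in (a.subject.iri, a.object.iri)}
    out.entities = {iri: e for iri, e in out.entities.items() if iri in used}
    out.validate()
    return out


# ---------------------------------------------------------------------------
# class-level axiom patterns ("always true" relations)


@dataclass(frozen=True)
class ClassAxiomPattern:
    """A class-level existential axiom request.

    ``disease_location`` asserts where a disease manifests anatomically;
    ``abnormal_process`` asserts the abnormal biological process a disease
    is realized in.  These contrast with OBAN associations: the axioms hold
    for every instance of the disease class.
    """

    pattern: str
    disease_iri: str
    target_iri: str


def emit_class_axiom(pattern: ClassAxiomPattern,
                     ontology: Mapping[str, OntologyClass]) -> str:
    """Render the Manchester-syntax text of a class-level axiom pattern.

    Both IRIs must resolve in the supplied ontology (labels are substituted
    into the expression).  Unknown pattern names raise ``ValueError``.
    """
    for iri, what in ((pattern.disease_iri, "disease"), (pattern.target_iri, "target")):
        if iri not in ontology:
            raise KeyError(f"{what} IRI {iri} not found in ontology")
    disease = ontology[pattern.disease_iri].label
    target = ontology[pattern.target_iri].label
    if pattern.pattern == "disease_location":
        return f"'{disease}' SubClassOf: 'has_disease_location' some '{target}'"
    if pattern.pattern == "abnormal_process":
        return (f"'{disease}' SubClassOf: 'realized_in' some ('disease course'"
                f" and ('has_part' some '{target}')"
                f" and ('bearer_of' some 'abnormal'))")
    raise ValueError(f"unknown axiom pattern {pattern.pattern!r}")
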