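"""Synthetic fixtures with known ground truth for every pipeline input.

The generator emulates, at desk scale, the five inputs the pipeline
consumes: an application ontology (EFO-style common diseases,
Orphanet-style rare diseases, HP/MP-style phenotypes, scoped synonyms,
cross-references), source-record annotation tables, a local corpus of
abstracts, curation vote sheets, and OBAN association graphs.  Every
planted structure — mapping coverage per source, term/document frequencies,
vote outcomes, bridge topology — is emitted alongside as ground truth, so
each pipeline stage can be checked by exact parameter recovery.

A single integer seed drives all randomness; the same seed yields
byte-identical fixture directories.  Text is assembled from a small word
list, never a language model; it is not realistic clinical prose and makes
no attempt to emulate PubMed XML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from random import Random
from typing import Sequence

import yaml

from . import oban
from .oban import (AssociationGraph, BiologicalEntity, OBANConfig,
                   ProvenanceRecord, build_association, DEFAULT_CONFIG)
from .ontology import (OntologyClass, Synonym, ontology_to_triples,
                       write_ontology_tsv)
from .mining import (CorpusDoc, Vote, CandidateAssociation, STATUS_ACCEPTED,
                     STATUS_REJECTED, STATUS_UNDECIDED, STATUS_STOPLISTED)
from .xref import (SourceRecord, MAPPED_1TO1, MAPPED_SYNONYM, UNMAPPED,
                   _round_half_up)

# -- word material ----------------------------------------------------------

_NAME_A = ["Aldervane", "Bexworth", "Cranmere", "Dunwell", "Eastvale",
           "Farrowby", "Gildenham", "Hollowell", "Ironcliff", "Jasperford",
           "Kelmscott", "Larkmoor"]
_NAME_B = ["Abbey", "Barrow", "Cradley", "Denholm", "Elmsley", "Fenwick",
           "Garrow", "Hathern", "Ingleby", "Jarrow"]

_PHENO_ADJ = ["recurrent", "nocturnal", "progressive", "intermittent",
              "severe", "transient", "persistent", "focal", "diffuse",
              "episodic", "refractory", "juvenile", "familial", "acute",
              "secondary", "primary", "bilateral", "proximal", "distal",
              "generalized", "localized", "atypical", "congenital", "latent"]
_PHENO_NOUN = ["arthralgia", "pyrexia", "alopecia", "dysphagia", "anemia",
               "uveitis", "tremor", "fatigue", "pruritus", "cachexia",
               "malabsorption", "diarrhea", "stomatitis", "ataxia",
               "neutropenia", "myalgia", "vertigo", "edema", "ascites",
               "ileus", "glossitis", "melena", "tenesmus", "anorexia",
               "insomnia"]

# filler vocabulary is disjoint from every dictionary surface form
_FILLER = ["the", "cohort", "was", "reviewed", "during", "followup",
           "visits", "clinical", "notes", "described", "routine",
           "management", "without", "complications", "over", "twelve",
           "months", "of", "observation", "in", "this", "registry"]

_STOPLIST_LABELS = ["All", "Chronic", "death", "sudden death"]

EFO_BASE = "http://www.ebi.ac.uk/efo/EFO_"
ORDO_BASE = "http://www.orpha.net/ORDO/Orphanet_"
HP_BASE = "http://purl.obolibrary.org/obo/HP_"
MP_BASE = "http://purl.obolibrary.org/obo/MP_"


@dataclass
class FixtureSpec:
    """All knobs of the generator; defaults are the study conditions.

    Per-source coverage targets mirror the published mapping-summary
    percentages; the default vote profile yields the published 41.6 %
    curation precision at n=500; the default linkage structure plants 535
    bridge phenotypes over 20 common and 85 rare diseases.
    """

    seed: int = 7
    # ontology
    n_common: int = 20
    n_rare: int = 85
    n_phenotypes: int = 600
    n_nested_phenotypes: int = 3   # bare-noun terms nested inside longer labels
    include_stoplist_terms: bool = True
    # source records: source -> (n_records, target percent mapped)
    coverage_targets: dict = field(default_factory=lambda: {
        "EVA": (100, 89), "ArrayExpress": (100, 77), "UniProt": (100, 78),
        "Reactome": (100, 100), "ChEMBL": (100, 99), "GWAS_Catalog": (100, 100)})
    # corpus / mining
    n_mined_common: int = 3
    n_mined_rare: int = 3
    docs_per_disease: int = 8
    assocs_per_disease: int = 5
    max_tf: int = 6
    max_df: int = 3
    n_planted_bridge_phenotypes: int = 4
    # votes: exact counts (accepted, rejected, undecided) or a profile
    vote_counts: tuple[int, int, int] | None = None
    vote_profile: tuple[float, float, float] = (0.416, 0.36, 0.224)
    # standalone linkage graph
    n_bridge_phenotypes: int = 535
    n_nonbridge_phenotypes: int = 30
    n_linked_common: int = 20
    n_linked_rare: int = 85
    n_shared_provenances: int = 40

    def __post_init__(self):
        if self.n_phenotypes > len(_PHENO_ADJ) * len(_PHENO_NOUN):
            raise ValueError("n_phenotypes exceeds the label vocabulary")
        if self.n_common > len(_NAME_A) * len(_NAME_B) // 2:
            raise ValueError("n_common exceeds the name vocabulary")
        if self.n_bridge_phenotypes + self.n_nonbridge_phenotypes > self.n_phenotypes:
            raise ValueError("linkage structure exceeds n_phenotypes")
        if self.n_linked_common > self.n_common or self.n_linked_rare > self.n_rare:
            raise ValueError("linked disease counts exceed disease counts")

    @classmethod
    def from_yaml(cls, source) -> "FixtureSpec":
        if isinstance(source, (str, Path)):
            data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        else:
            data = yaml.safe_load(source)
        data = data or {}
        if "coverage_targets" in data:
            data["coverage_targets"] = {
                k: tuple(v) for k, v in data["coverage_targets"].items()}
        for key in ("vote_counts", "vote_profile"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        data = asdict(self)
        data["coverage_targets"] = {k: list(v)
                                    for k, v in data["coverage_targets"].items()}
        for key in ("vote_counts", "vote_profile"):
            if data[key] is not None:
                data[key] = list(data[key])
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


@dataclass(frozen=True)
class PlantedAssociation:
    """Ground truth for one mined disease-phenotype pair."""

    disease_iri: str
    phenotype_iri: str
    tf: int
    df: int
    doc_ids: tuple[str, ...]
    expected_status: str


@dataclass
class FixtureSet:
    """Everything the generator produces, plus ground truth."""

    spec: FixtureSpec
    ontology: dict[str, OntologyClass]
    common_iris: list[str]
    rare_iris: list[str]
    phenotype_iris: list[str]
    records: list[SourceRecord]
    expected_mapping: dict[str, tuple[str, str | None]]  # record_id -> (status, target)
    expected_coverage: dict[str, int]                    # source -> percent
    docs: list[CorpusDoc]
    mined_diseases: list[tuple[str, list[str]]]          # (iri, search labels)
    planted: list[PlantedAssociation]
    decoys: list[PlantedAssociation]
    votes: list[Vote]
    expected_candidates: list[CandidateAssociation]
    expected_graph: AssociationGraph                     # from accepted pairs
    expected_mined_linkage: dict[str, int]
    linkage_graph: AssociationGraph                      # standalone, at scale
    expected_linkage: dict[str, int]


# -- helpers ----------------------------------------------------------------


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    quotas = [total * f for f in fractions]
    counts = [int(q) for q in quotas]
    short = total - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: -(quotas[i] - counts[i]))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _vote_pools() -> dict[str, list[tuple[str, str, str]]]:
    """All 27 three-vote combinations bucketed by the 2-of-3 rule."""
    pools = {STATUS_ACCEPTED: [], STATUS_REJECTED: [], STATUS_UNDECIDED: []}
    for a in ("yes", "no", "maybe"):
        for b in ("yes", "no", "maybe"):
            for c in ("yes", "no", "maybe"):
                votes = (a, b, c)
                yes, no = votes.count("yes"), votes.count("no")
                if yes >= 2:
                    pools[STATUS_ACCEPTED].append(votes)
                elif no >= 2:
                    pools[STATUS_REJECTED].append(votes)
                else:
                    pools[STATUS_UNDECIDED].append(votes)
    return pools


def _pheno_label(i: int) -> str:
    adj = _PHENO_ADJ[i % len(_PHENO_ADJ)]
    noun = _PHENO_NOUN[i // len(_PHENO_ADJ)]
    return f"{adj} {noun}"


# -- generation -------------------------------------------------------------


def generate(spec: FixtureSpec, config: OBANConfig = DEFAULT_CONFIG) -> FixtureSet:
    """Build the full fixture set deterministically from ``spec.seed``."""
    rng = Random(spec.seed)
    ontology: dict[str, OntologyClass] = {}

    names = [f"{a}-{b}" for a in _NAME_A for b in _NAME_B]
    common_iris, rare_iris = [], []
    for i in range(spec.n_common):
        iri = f"{EFO_BASE}{1000000 + i}"
        label = f"{names[i]} disease"
        ontology[iri] = OntologyClass(iri, label, synonyms=[
            Synonym(f"{names[i]} disorder", "exact")])
        common_iris.append(iri)
    for i in range(spec.n_rare):
        iri = f"{ORDO_BASE}{500000 + i}"
        name = names[spec.n_common + i]
        ontology[iri] = OntologyClass(iri, f"{name} syndrome", synonyms=[
            Synonym(f"{name} disorder", "exact")])
        rare_iris.append(iri)

    phenotype_iris = []
    for i in range(spec.n_phenotypes):
        base = MP_BASE if i % 7 == 3 else HP_BASE
        iri = f"{base}{2000000 + i}"
        label = _pheno_label(i)
        noun, adj = label.split()[1], label.split()[0]
        ontology[iri] = OntologyClass(iri, label, synonyms=[
            Synonym(f"{noun}, {adj} type", "exact"),
            Synonym(f"{label} variant", "narrow")])
        phenotype_iris.append(iri)
    nested_iris = []
    for j in range(spec.n_nested_phenotypes):
        iri = f"{HP_BASE}{2100000 + j}"
        ontology[iri] = OntologyClass(iri, _PHENO_NOUN[j], synonyms=[
            Synonym(f"{_PHENO_NOUN[j]} variant", "narrow")])
        nested_iris.append(iri)
    if spec.include_stoplist_terms:
        for j, label in enumerate(_STOPLIST_LABELS):
            iri = f"{HP_BASE}{2999990 + j}"
            ontology[iri] = OntologyClass(iri, label)

    records, expected_mapping, expected_coverage = _gen_records(
        spec, rng, ontology, common_iris, rare_iris, phenotype_iris)

    (docs, mined, planted, decoys, votes, expected_candidates,
     expected_graph, expected_mined_linkage) = _gen_corpus_votes(
        spec, rng, ontology, common_iris, rare_iris, phenotype_iris, config)

    linkage_graph, expected_linkage = _gen_linkage_graph(
        spec, rng, ontology, common_iris, rare_iris, phenotype_iris, config)

    return FixtureSet(
        spec=spec, ontology=ontology, common_iris=common_iris,
        rare_iris=rare_iris, phenotype_iris=phenotype_iris,
        records=records, expected_mapping=expected_mapping,
        expected_coverage=expected_coverage, docs=docs,
        mined_diseases=mined, planted=planted, decoys=decoys, votes=votes,
        expected_candidates=expected_candidates, expected_graph=expected_graph,
        expected_mined_linkage=expected_mined_linkage,
        linkage_graph=linkage_graph, expected_linkage=expected_linkage)


def _gen_records(spec, rng, ontology, common_iris, rare_iris, phenotype_iris):
    pool = common_iris + rare_iris + phenotype_iris
    records: list[SourceRecord] = []
    expected: dict[str, tuple[str, str | None]] = {}
    coverage: dict[str, int] = {}
    xref_counter = 600000
    xref_styles = ["OMIM:{}", "MIM {}", "omim_{}", "MESH:{}", "SNOMEDCT:{}"]
    for s_idx, source in enumerate(sorted(spec.coverage_targets)):
        n, pct = spec.coverage_targets[source]
        k = _round_half_up(n * pct / 100.0)
        coverage[source] = _round_half_up(100.0 * k / n)
        used = set()
        for i in range(n):
            record_id = f"{source}:{i:04d}"
            if i < k:
                # mappable: mint a fresh xref on a target class
                target = pool[(s_idx * 37 + i * 3) % len(pool)]
                while target in used:
                    target = pool[(pool.index(target) + 1) % len(pool)]
                used.add(target)
                xref_counter += 1
                style = xref_styles[i % len(xref_styles)]
                raw = style.format(xref_counter)
                # index building normalizes both sides, so the ontology can
                # carry the same surface form the record uses
                ontology[target].xrefs.append(raw)
                if i % 5 == 4:
                    # 1-to-many: second class shares the xref; exact
                    # synonym/label of the target resolves it
                    other = pool[(pool.index(target) + 7) % len(pool)]
                    ontology[other].xrefs.append(raw)
                    label = (ontology[target].label if i % 2 == 0
                             else ontology[target].exact_synonyms()[0]
                             if ontology[target].exact_synonyms()
                             else ontology[target].label)
                    records.append(SourceRecord(source, record_id, label, (raw,)))
                    expected[record_id] = (MAPPED_SYNONYM, target)
                else:
                    records.append(SourceRecord(
                        source, record_id, ontology[target].label, (raw,)))
                    expected[record_id] = (MAPPED_1TO1, target)
            else:
                j = i - k
                if j % 3 == 1:
                    # narrow-synonym trap: ambiguous xref, trait equals a
                    # narrow synonym only -> stays unmapped
                    target = pool[(s_idx * 11 + j) % len(phenotype_iris)
                                  + len(common_iris) + len(rare_iris)]
                    other = pool[(pool.index(target) + 13) % len(pool)]
                    xref_counter += 1
                    raw = f"OMIM:{xref_counter}"
                    ontology[target].xrefs.append(raw)
                    ontology[other].xrefs.append(raw)
                    narrow = [s.text for s in ontology[target].synonyms
                              if s.scope == "narrow"]
                    label = narrow[0] if narrow else f"unlisted trait {source} {j}"
                    records.append(SourceRecord(source, record_id, label, (raw,)))
                elif j % 3 == 2:
                    # conflicting xrefs hitting two different classes
                    t1 = pool[(s_idx * 5 + j) % len(pool)]
                    t2 = pool[(s_idx * 5 + j + 29) % len(pool)]
                    xref_counter += 1
                    r1 = f"OMIM:{xref_counter}"
                    xref_counter += 1
                    r2 = f"MESH:{xref_counter}"
                    ontology[t1].xrefs.append(r1)
                    ontology[t2].xrefs.append(r2)
                    records.append(SourceRecord(
                        source, record_id, f"conflicted trait {source} {j}", (r1, r2)))
                else:
                    records.append(SourceRecord(
                        source, record_id, f"uncatalogued condition {source} {j}", ()))
                expected[record_id] = (UNMAPPED, None)
    return records, expected, coverage


def _disease_search_labels(cls: OntologyClass) -> list[str]:
    return [cls.label] + cls.exact_synonyms()


def _gen_corpus_votes(spec, rng, ontology, common_iris, rare_iris,
                      phenotype_iris, config):
    mined_iris = (common_iris[:spec.n_mined_common]
                  + rare_iris[:spec.n_mined_rare])
    mined = [(iri, _disease_search_labels(ontology[iri])) for iri in mined_iris]

    # plant pairs: bridge phenotypes first (shared by a common and a rare
    # mined disease), then per-disease extras from the remaining pool
    pairs: list[tuple[str, str]] = []
    per_disease: dict[str, list[str]] = {iri: [] for iri in mined_iris}
    n_bridge = min(spec.n_planted_bridge_phenotypes,
                   spec.assocs_per_disease * min(spec.n_mined_common,
                                                 spec.n_mined_rare))
    bridge_phenos = phenotype_iris[:n_bridge]
    for b, phen in enumerate(bridge_phenos):
        c = common_iris[b % spec.n_mined_common]
        r = rare_iris[b % spec.n_mined_rare]
        for d in (c, r):
            if len(per_disease[d]) < spec.assocs_per_disease:
                pairs.append((d, phen))
                per_disease[d].append(phen)
    pool = phenotype_iris[n_bridge:]
    for iri in mined_iris:
        need = spec.assocs_per_disease - len(per_disease[iri])
        picks = rng.sample(pool, need)
        for phen in picks:
            pairs.append((iri, phen))
            per_disease[iri].append(phen)

    # vote statuses
    pools = _vote_pools()
    if spec.vote_counts is not None:
        a, r_, u = spec.vote_counts
        if a + r_ + u != len(pairs):
            raise ValueError(
                f"vote_counts sum {a + r_ + u} != {len(pairs)} planted pairs")
        statuses = ([STATUS_ACCEPTED] * a + [STATUS_REJECTED] * r_
                    + [STATUS_UNDECIDED] * u)
        rng.shuffle(statuses)
        status_of = dict(zip(pairs, statuses))
    else:
        status_of = {}
        bridge_pairs = [p for p in pairs if p[1] in set(bridge_phenos)]
        rest = [p for p in pairs if p[1] not in set(bridge_phenos)]
        for p in bridge_pairs:
            status_of[p] = STATUS_ACCEPTED
        counts = _largest_remainder(len(rest), spec.vote_profile)
        statuses = ([STATUS_ACCEPTED] * counts[0] + [STATUS_REJECTED] * counts[1]
                    + [STATUS_UNDECIDED] * counts[2])
        rng.shuffle(statuses)
        status_of.update(zip(rest, statuses))

    votes: list[Vote] = []
    for (d, p) in pairs:
        triple = rng.choice(pools[status_of[(d, p)]])
        for i, v in enumerate(triple):
            votes.append(Vote(d, p, f"clinician_{i + 1}", v))

    # corpus: docs per disease, tf over df docs per planted pair
    docs: list[CorpusDoc] = []
    planted: list[PlantedAssociation] = []
    decoys: list[PlantedAssociation] = []
    doc_counter = 7000000
    doc_sentences: dict[str, list[str]] = {}
    doc_ids_of: dict[str, list[str]] = {}
    for iri in mined_iris:
        labels = _disease_search_labels(ontology[iri])
        ids = []
        for k in range(spec.docs_per_disease):
            doc_counter += 1
            doc_id = f"PMID{doc_counter}"
            ids.append(doc_id)
            mention = labels[k % len(labels)]
            sentences = [f"We studied patients with {mention}."]
            n_filler = rng.randint(1, 3)
            for _ in range(n_filler):
                words = rng.sample(_FILLER, rng.randint(4, 7))
                sentences.append(" ".join(words).capitalize() + ".")
            doc_sentences[doc_id] = sentences
        doc_ids_of[iri] = ids
        if spec.include_stoplist_terms:
            doc_sentences[ids[0]].append(
                "Chronic illness and sudden death were recorded.")
            for stop_label, tf in (("Chronic", 1), ("sudden death", 1)):
                stop_iri = next(i for i, c in ontology.items()
                                if c.label == stop_label)
                decoys.append(PlantedAssociation(
                    iri, stop_iri, tf, 1, (ids[0],), STATUS_STOPLISTED))

    for (d, p) in pairs:
        tf = rng.randint(1, spec.max_tf)
        df = rng.randint(1, min(spec.max_df, spec.docs_per_disease, tf))
        chosen = sorted(rng.sample(doc_ids_of[d], df))
        counts = {doc_id: 1 for doc_id in chosen}
        for _ in range(tf - df):
            counts[rng.choice(chosen)] += 1
        cls = ontology[p]
        for doc_id, n in counts.items():
            for _ in range(n):
                form = cls.label
                exact = cls.exact_synonyms()
                if exact and rng.random() < 0.25:
                    form = exact[0]
                doc_sentences[doc_id].append(f"Cases presented {form}.")
        planted.append(PlantedAssociation(d, p, tf, df, tuple(chosen),
                                          status_of[(d, p)]))

    for iri in mined_iris:
        for doc_id in doc_ids_of[iri]:
            sentences = doc_sentences[doc_id]
            lead, rest = sentences[0], sentences[1:]
            rng.shuffle(rest)
            docs.append(CorpusDoc(doc_id, " ".join([lead] + rest)))
    docs.sort(key=lambda d: d.doc_id)

    # expected candidates (post stoplist + vote merge)
    expected_candidates: list[CandidateAssociation] = []
    import math
    for pa in planted + decoys:
        expected_candidates.append(CandidateAssociation(
            disease_iri=pa.disease_iri,
            disease_label=ontology[pa.disease_iri].label,
            phenotype_iri=pa.phenotype_iri,
            phenotype_label=ontology[pa.phenotype_iri].label,
            tf=pa.tf, idf=math.log(spec.docs_per_disease / pa.df),
            doc_ids=pa.doc_ids, status=pa.expected_status))

    expected_graph = graph_from_candidates(
        [c for c in expected_candidates if c.status == STATUS_ACCEPTED], config)

    accepted = [pa for pa in planted if pa.expected_status == STATUS_ACCEPTED]
    rare_set = set(rare_iris)
    common_set = set(common_iris)
    rare_of: dict[str, set] = {}
    common_of: dict[str, set] = {}
    for pa in accepted:
        side = rare_of if pa.disease_iri in rare_set else common_of
        side.setdefault(pa.phenotype_iri, set()).add(pa.disease_iri)
    bridge_set = set(rare_of) & set(common_of)
    expected_mined_linkage = {
        "n_associations": len(accepted),
        "n_provenances": len({doc for pa in accepted for doc in pa.doc_ids}),
        "n_bridges": len(bridge_set),
        "n_common_linked": len({d for p in bridge_set for d in common_of[p]}),
        "n_rare_linked": len({d for p in bridge_set for d in rare_of[p]}),
    }
    return (docs, mined, planted, decoys, votes, expected_candidates,
            expected_graph, expected_mined_linkage)


def _gen_linkage_graph(spec, rng, ontology, common_iris, rare_iris,
                       phenotype_iris, config):
    graph = AssociationGraph()
    prov_pool = []
    for i in range(spec.n_shared_provenances):
        prov_pool.append(ProvenanceRecord(
            prov_id=f"{config.base_namespace}provenance/PMID{8000000 + i}",
            evidence_type=oban.ECO_AUTOMATIC_ASSERTION,
            attributes=frozenset({(oban.PUBMED_PREDICATE, f"PMID{8000000 + i}")})))

    linked_common = common_iris[:spec.n_linked_common]
    linked_rare = rare_iris[:spec.n_linked_rare]
    bridge_phenos = phenotype_iris[-spec.n_bridge_phenotypes:]
    nonbridge = phenotype_iris[:spec.n_nonbridge_phenotypes]

    def entity(iri, kind):
        return BiologicalEntity(iri, ontology[iri].label, kind)

    def link(disease_iri, phen_iri):
        provs = rng.sample(prov_pool, rng.randint(1, 2))
        assoc = build_association(entity(disease_iri, "disease"),
                                  entity(phen_iri, "phenotype"), provs, config)
        if assoc.assoc_id not in graph.associations:
            graph.add_association(assoc)

    for j, phen in enumerate(bridge_phenos):
        # round-robin guarantees every linked disease joins >=1 bridge
        link(linked_rare[j % len(linked_rare)], phen)
        link(linked_common[j % len(linked_common)], phen)
        if rng.random() < 0.3:
            link(rng.choice(linked_rare), phen)
        if rng.random() < 0.2:
            link(rng.choice(linked_common), phen)
    for j, phen in enumerate(nonbridge):
        # one side only: never a bridge
        if j % 2 == 0:
            link(rng.choice(linked_rare), phen)
        else:
            link(rng.choice(linked_common), phen)

    expected = {
        "n_bridges": spec.n_bridge_phenotypes,
        "n_common_linked": spec.n_linked_common,
        "n_rare_linked": spec.n_linked_rare,
        "n_associations": len(graph.associations),
        "n_provenances": len(graph.provenances),
    }
    return graph, expected


def graph_from_candidates(candidates: Sequence[CandidateAssociation],
                          config: OBANConfig = DEFAULT_CONFIG,
                          evidence_type: str = oban.ECO_AUTOMATIC_ASSERTION,
                          ) -> AssociationGraph:
    """Build an OBAN graph from curated candidates: one association per
    pair, one shared provenance individual per supporting abstract."""
    graph = AssociationGraph()
    for c in sorted(candidates, key=lambda c: (c.disease_iri, c.phenotype_iri)):
        provs = [ProvenanceRecord(
            prov_id=f"{config.base_namespace}provenance/{doc_id}",
            evidence_type=evidence_type,
            attributes=frozenset({(oban.PUBMED_PREDICATE, doc_id)}))
            for doc_id in c.doc_ids]
        assoc = build_association(
            BiologicalEntity(c.disease_iri, c.disease_label, "disease"),
            BiologicalEntity(c.phenotype_iri, c.phenotype_label, "phenotype"),
            provs, config)
        graph.add_association(assoc)
    return graph


def gen_random_graph(seed: int, n_associations: int = 10,
                     config: OBANConfig = DEFAULT_CONFIG) -> AssociationGraph:
    """A small random association graph for serialization round-trip tests.

    Mixes namespaces and entity kinds, shares provenance records across
    associations, and gives provenances open-ended attributes including
    repeated predicates with distinct values.
    """
    rng = Random(seed)
    graph = AssociationGraph()
    n_dis = max(2, n_associations // 2)
    n_phe = max(2, n_associations // 2)
    diseases = []
    for i in range(n_dis):
        base, kind = rng.choice([(EFO_BASE, "disease"), (ORDO_BASE, "disease"),
                                 ("http://example.org/local/DIS_", "other")])
        diseases.append(BiologicalEntity(f"{base}{3000 + i}",
                                         f"disease {3000 + i}", kind))
    phenotypes = [BiologicalEntity(f"{HP_BASE}{4000 + i}", f"phenotype {4000 + i}",
                                   "phenotype") for i in range(n_phe)]
    evidence = [oban.ECO_MANUAL_ASSERTION, oban.ECO_AUTOMATIC_ASSERTION,
                "http://example.org/evidence/custom_panel_review"]
    provs = []
    for i in range(max(1, n_associations // 2)):
        attrs = {(oban.PUBMED_PREDICATE, f"PMID{9000000 + i}")}
        if rng.random() < 0.5:
            attrs.add((oban.PUBMED_PREDICATE, f"PMID{9100000 + i}"))
        if rng.random() < 0.5:
            attrs.add((oban.CURATOR_PREDICATE, f"curator_{rng.randint(1, 5)}"))
        if rng.random() < 0.3:
            attrs.add((oban.CONFIDENCE_PREDICATE, f"{rng.random():.3f}"))
        provs.append(ProvenanceRecord(
            f"{config.base_namespace}provenance/r{seed}_{i}",
            rng.choice(evidence), frozenset(attrs)))
    seen_pairs = set()
    while len(graph.associations) < n_associations:
        d, p = rng.choice(diseases), rng.choice(phenotypes)
        if (d.iri, p.iri) in seen_pairs:
            continue
        seen_pairs.add((d.iri, p.iri))
        chosen = rng.sample(provs, rng.randint(1, min(3, len(provs))))
        graph.add_association(build_association(d, p, chosen, config))
    return graph


# -- convenience slices (the operations named in the module surface) --------


def gen_ontology(spec: FixtureSpec) -> dict[str, OntologyClass]:
    return generate(spec).ontology


def gen_records(spec: FixtureSpec):
    fx = generate(spec)
    return fx.records, fx.expected_mapping, fx.expected_coverage


def gen_corpus(spec: FixtureSpec):
    fx = generate(spec)
    return fx.docs, fx.planted + fx.decoys


def gen_votes(spec: FixtureSpec):
    fx = generate(spec)
    return fx.votes, {(p.disease_iri, p.phenotype_iri): p.expected_status
                      for p in fx.planted}


def gen_graph(spec: FixtureSpec):
    fx = generate(spec)
    return fx.linkage_graph, fx.expected_linkage


# -- fixture directory ------------------------------------------------------


def write_fixture_dir(spec: FixtureSpec, outdir,
                      config: OBANConfig = DEFAULT_CONFIG) -> Path:
    """Write a self-contained fixture directory (same seed -> identical
    bytes), with ground truth under ``ground_truth/``."""
    from . import mining, xref as xref_mod
    from .oban import serialize, serialize_triples

    fx = generate(spec, config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gt = out / "ground_truth"
    gt.mkdir(exist_ok=True)

    spec.to_yaml(out / "spec.yaml")
    write_ontology_tsv(fx.ontology, out / "ontology.tsv")
    (out / "ontology.owl").write_bytes(
        serialize_triples(ontology_to_triples(
            dict(sorted(fx.ontology.items()))), "rdfxml"))
    xref_mod.write_records_tsv(fx.records, out / "records.tsv")
    mining.write_corpus_tsv(fx.docs, out / "corpus.tsv")
    mining.write_votes_tsv(fx.votes, out / "votes.tsv")
    (out / "stoplist.txt").write_text(
        "\n".join(sorted(mining.DEFAULT_STOPLIST)) + "\n", encoding="utf-8")
    with open(out / "diseases.tsv", "w", encoding="utf-8") as fh:
        fh.write("disease_iri\tdisease_label\tsearch_labels\n")
        for iri, labels in fx.mined_diseases:
            fh.write(f"{iri}\t{fx.ontology[iri].label}\t{';'.join(labels)}\n")
    (out / "graph.ttl").write_bytes(serialize(fx.linkage_graph, "turtle", config))

    with open(gt / "mappings.tsv", "w", encoding="utf-8") as fh:
        fh.write("record_id\texpected_status\texpected_target\n")
        for record_id in sorted(fx.expected_mapping):
            status, target = fx.expected_mapping[record_id]
            fh.write(f"{record_id}\t{status}\t{target or ''}\n")
    (gt / "coverage.json").write_text(
        json.dumps(fx.expected_coverage, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    mining.export_candidates(fx.expected_candidates, gt / "candidates.tsv")
    (gt / "planted.json").write_text(json.dumps(
        [asdict(p) for p in sorted(fx.planted + fx.decoys,
                                   key=lambda p: (p.disease_iri, p.phenotype_iri))],
        indent=2, sort_keys=True) + "\n", encoding="utf-8")
    (gt / "graph.ttl").write_bytes(serialize(fx.expected_graph, "turtle", config))
    (gt / "mined_linkage.json").write_text(
        json.dumps(fx.expected_mined_linkage, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    (gt / "linkage.json").write_text(
        json.dumps(fx.expected_linkage, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return out
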