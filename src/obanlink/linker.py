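"""Linking rare and common diseases through shared phenotypes.

A disease is classified rare or common from its IRI namespace: rare
diseases are imported from the Orphanet rare-disease ontology
(``Orphanet_*`` local names), common diseases are defined natively in the
application ontology (``EFO_*``).  A phenotype *bridge* is a phenotype
associated — in either direction — with at least one rare and at least one
common disease; bridges induce rare-common disease pairs with the shared
phenotypes listed per pair.
"""

from __future__ import annotations

import io
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .oban import AssociationGraph
from .ontology import namespace_of

logger = logging.getLogger(__name__)

RARE = "rare"
COMMON = "common"
UNKNOWN = "unknown"

#: IRI local-name prefix -> disease class; configurable
DEFAULT_NAMESPACE_RULES = {"Orphanet": RARE, "ORDO": RARE, "EFO": COMMON}


@dataclass(frozen=True)
class DiseaseClassification:
    disease_iri: str
    klass: str


def classify_disease(iri: str,
                     overrides: Mapping[str, str] | None = None,
                     namespace_rules: Mapping[str, str] | None = None,
                     ) -> DiseaseClassification:
    """Classify a disease IRI as rare/common/unknown.

    A pure function of the IRI namespace plus an override table (overrides
    win).  Phenotype namespaces (HP, MP) and anything unrecognized come
    back ``unknown``.
    """
    if overrides and iri in overrides:
        return DiseaseClassification(iri, overrides[iri])
    rules = DEFAULT_NAMESPACE_RULES if namespace_rules is None else namespace_rules
    return DiseaseClassification(iri, rules.get(namespace_of(iri), UNKNOWN))


@dataclass(frozen=True)
class PhenotypeBridge:
    """A phenotype shared by >=1 rare and >=1 common disease."""

    phenotype_iri: str
    rare_diseases: frozenset[str]
    common_diseases: frozenset[str]

    def __post_init__(self):
        if not self.rare_diseases or not self.common_diseases:
            raise ValueError("a bridge requires both a rare and a common disease")

    @property
    def degree(self) -> int:
        return len(self.rare_diseases) + len(self.common_diseases)


def _disease_side(assoc):
    """(disease entity, phenotype entity) for an association, using entity
    kinds with the subject=disease convention as fallback."""
    s, o = assoc.subject, assoc.object
    if s.entity_kind == "phenotype" and o.entity_kind != "phenotype":
        return o, s
    return s, o


def _phenotype_neighbourhoods(graph: AssociationGraph,
                              overrides: Mapping[str, str] | None,
                              namespace_rules: Mapping[str, str] | None):
    rare_of: dict[str, set[str]] = defaultdict(set)
    common_of: dict[str, set[str]] = defaultdict(set)
    n_unknown = 0
    for assoc in graph.associations.values():
        disease, phenotype = _disease_side(assoc)
        klass = classify_disease(disease.iri, overrides, namespace_rules).klass
        if klass == RARE:
            rare_of[phenotype.iri].add(disease.iri)
        elif klass == COMMON:
            common_of[phenotype.iri].add(disease.iri)
        else:
            n_unknown += 1
    if n_unknown:
        logger.info("%d associations with unclassifiable disease excluded "
                    "from bridge computation", n_unknown)
    return rare_of, common_of


def find_bridges(graph: AssociationGraph,
                 overrides: Mapping[str, str] | None = None,
                 namespace_rules: Mapping[str, str] | None = None,
                 ) -> list[PhenotypeBridge]:
    """Phenotypes associated with >=1 rare and >=1 common disease.

    Association direction is ignored (the link is undirected for linkage
    queries).  Output sorted by degree descending, then phenotype IRI.
    """
    rare_of, common_of = _phenotype_neighbourhoods(graph, overrides, namespace_rules)
    bridges = []
    for phen in set(rare_of) & set(common_of):
        bridges.append(PhenotypeBridge(phen, frozenset(rare_of[phen]),
                                       frozenset(common_of[phen])))
    bridges.sort(key=lambda b: (-b.degree, b.phenotype_iri))
    return bridges


@dataclass(frozen=True)
class RareCommonPair:
    rare_iri: str
    common_iri: str
    shared_phenotypes: tuple[str, ...]


def rare_common_pairs(bridges: Sequence[PhenotypeBridge]) -> list[RareCommonPair]:
    """Cartesian pairing within each bridge, merged across bridges.

    Each (rare, common) pair is reported once, with every bridging
    phenotype listed, not once per phenotype.
    """
    shared: dict[tuple[str, str], set[str]] = defaultdict(set)
    for bridge in bridges:
        for rare in bridge.rare_diseases:
            for common in bridge.common_diseases:
                shared[(rare, common)].add(bridge.phenotype_iri)
    return [RareCommonPair(r, c, tuple(sorted(phens)))
            for (r, c), phens in sorted(shared.items())]


@dataclass
class LinkageSummary:
    """Counts describing one association graph's rare-common linkage."""

    n_associations: int
    n_provenances: int
    n_bridges: int
    n_common_linked: int
    n_rare_linked: int
    per_group: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"associations:        {self.n_associations}\n")
        buf.write(f"provenances:         {self.n_provenances}\n")
        buf.write(f"phenotype bridges:   {self.n_bridges}\n")
        buf.write(f"common diseases in >=1 rare-common pair: {self.n_common_linked}\n")
        buf.write(f"rare diseases in >=1 rare-common pair:   {self.n_rare_linked}\n")
        for group in sorted(self.per_group):
            counts = self.per_group[group]
            buf.write(f"  {group}: {counts['n_associations']} associations, "
                      f"{counts['n_provenances']} provenances\n")
        return buf.getvalue()


def summarize(graph: AssociationGraph,
              bridges: Sequence[PhenotypeBridge] | None = None,
              overrides: Mapping[str, str] | None = None,
              namespace_rules: Mapping[str, str] | None = None,
              ) -> LinkageSummary:
    """Linkage statistics, all reproducible by brute-force recount.

    Per-group rows count associations (and their distinct provenances) by
    the disease side's classification; counts are invariant under
    association reordering and subject/object swaps.
    """
    if bridges is None:
        bridges = find_bridges(graph, overrides, namespace_rules)
    pairs = rare_common_pairs(bridges)
    per_group: dict[str, dict[str, set | int]] = {}
    group_provs: dict[str, set[str]] = defaultdict(set)
    group_assocs: dict[str, int] = defaultdict(int)
    for assoc in graph.associations.values():
        disease, _ = _disease_side(assoc)
        klass = classify_disease(disease.iri, overrides, namespace_rules).klass
        group_assocs[klass] += 1
        group_provs[klass].update(p.prov_id for p in assoc.provenance)
    for group in group_assocs:
        per_group[group] = {"n_associations": group_assocs[group],
                            "n_provenances": len(group_provs[group])}
    return LinkageSummary(
        n_associations=len(graph.associations),
        n_provenances=len(graph.provenances),
        n_bridges=len(bridges),
        n_common_linked=len({p.common_iri for p in pairs}),
        n_rare_linked=len({p.rare_iri for p in pairs}),
        per_group=per_group)


# ---------------------------------------------------------------------------
# TSV/JSON interfaces


def read_overrides_tsv(source) -> dict[str, str]:
    """Two-column TSV: disease IRI, class (rare/common/unknown)."""
    import csv
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_overrides_tsv(fh)
    reader = csv.reader(source, delimiter="\t")
    next(reader, None)
    out = {}
    for row in reader:
        if not row or not row[0]:
            continue
        if row[1] not in (RARE, COMMON, UNKNOWN):
            raise ValueError(f"bad disease class {row[1]!r} for {row[0]}")
        out[row[0]] = row[1]
    return out


def write_bridges_tsv(bridges: Sequence[PhenotypeBridge], path=None) -> str:
    import csv
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["phenotype_iri", "rare_diseases", "common_diseases"])
    for b in bridges:
        w.writerow([b.phenotype_iri, ";".join(sorted(b.rare_diseases)),
                    ";".join(sorted(b.common_diseases))])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_pairs_tsv(pairs: Sequence[RareCommonPair], path=None) -> str:
    import csv
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["rare_iri", "common_iri", "shared_phenotypes"])
    for p in pairs:
        w.writerow([p.rare_iri, p.common_iri, ";".join(p.shared_phenotypes)])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
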