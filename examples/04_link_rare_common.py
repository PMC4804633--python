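"""Link rare and common diseases through shared phenotypes.

Builds a small association graph in which pruritus is associated with both
psoriasis (a common disease, EFO namespace) and lamellar ichthyosis (a rare
disease, Orphanet namespace), making it a phenotype bridge.
"""

from obanlink import oban
from obanlink.linker import find_bridges, rare_common_pairs, summarize
from obanlink.oban import (AssociationGraph, BiologicalEntity,
                           ProvenanceRecord, build_association)


def entity(iri, label, kind):
    return BiologicalEntity(iri, label, kind)


psoriasis = entity("http://www.ebi.ac.uk/efo/EFO_0000676", "psoriasis",
                   "disease")
ichthyosis = entity("http://www.orpha.net/ORDO/Orphanet_313",
                    "lamellar ichthyosis", "disease")
crohns = entity("http://www.ebi.ac.uk/efo/EFO_0000384", "Crohn's disease",
                "disease")
pruritus = entity("http://purl.obolibrary.org/obo/HP_0000989", "pruritus",
                  "phenotype")
diarrhea = entity("http://purl.obolibrary.org/obo/HP_0002014", "diarrhea",
                  "phenotype")

prov = ProvenanceRecord(
    "http://purl.example.org/obanlink/provenance/PMID9",
    oban.ECO_AUTOMATIC_ASSERTION,
    frozenset({(oban.PUBMED_PREDICATE, "PMID9")}))

graph = AssociationGraph()
for disease, phenotype in [(psoriasis, pruritus), (ichthyosis, pruritus),
                           (crohns, diarrhea)]:
    graph.add_association(build_association(disease, phenotype, [prov]))

bridges = find_bridges(graph)
for b in bridges:
    print(f"bridge: {b.phenotype_iri}")
    print(f"  rare:   {sorted(b.rare_diseases)}")
    print(f"  common: {sorted(b.common_diseases)}")

for pair in rare_common_pairs(bridges):
    print(f"pair: {pair.rare_iri} <-> {pair.common_iri} "
          f"via {len(pair.shared_phenotypes)} shared phenotype(s)")

# diarrhea touches only a common disease, so it is not a bridge
print(summarize(graph, bridges).to_text(), end="")
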