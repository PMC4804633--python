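"""Map source-database annotations to ontology classes via cross-references.

Three records illustrate the three outcomes: a unique cross-reference hit
(1:1), an ambiguous hit resolved by an exact-scoped synonym, and a record
the automatic pass defers to manual curation.
"""

from obanlink.ontology import OntologyClass, Synonym
from obanlink.xref import (SourceRecord, build_xref_index, coverage_report,
                           map_record, map_records)

EFO = "http://www.ebi.ac.uk/efo/EFO_"

ontology = {c.iri: c for c in [
    OntologyClass(f"{EFO}0004144", "Acatalasia", xrefs=["OMIM:115500"]),
    OntologyClass(f"{EFO}0000100", "congenital adrenal hyperplasia",
                  synonyms=[Synonym("adrenal hyperplasia, congenital", "exact"),
                            Synonym("salt-wasting form", "narrow")],
                  xrefs=["SNOMEDCT:237751000"]),
    OntologyClass(f"{EFO}0000101", "adrenal disorder",
                  xrefs=["SNOMEDCT:237751000"]),
]}

records = [
    # protein annotation carrying a unique OMIM id
    SourceRecord("UniProt", "P04040", "acatalasia", ("OMIM:115500",)),
    # id shared by two classes; the exact synonym picks one
    SourceRecord("EVA", "RCV01", "adrenal hyperplasia, congenital",
                 ("SNOMEDCT:237751000",)),
    # free-text trait with no usable identifier
    SourceRecord("EVA", "RCV02", "Glucose-6-phosphate transport defect", ()),
]

index = build_xref_index(ontology)
for record in records:
    result = map_record(record, index, ontology)
    print(f"{record.record_id:8s} {result.status:28s} "
          f"{result.target_iri or '-':45s} ({result.evidence})")

results = map_records(records, ontology)
for row in coverage_report(records, results):
    # percent of distinct trait labels mapped, per source
    print(f"{row.source}: {row.n_mapped}/{row.n_labels} labels mapped "
          f"= {row.percent} %")
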