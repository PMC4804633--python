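# obanlink

Tools for building a disease–phenotype association knowledge base: mapping
heterogeneous database annotations to an application ontology, mining
candidate disease–phenotype associations from abstracts, merging expert
curation votes, representing the validated associations in the OBAN (Open
Biomedical AssociatioN) model with full provenance, and linking rare to
common diseases through the phenotypes they share.

It is written for ontologists and bioinformaticians who integrate disease
and phenotype annotations across resources (EFO/ORDO/HP-style ontologies,
OMIM/SNOMED-CT/MeSH-style identifiers) and need a machine-readable,
evidence-qualified representation of "sometimes associated" relations.

## The model

An OWL class axiom such as `disease has_phenotype some phenotype` asserts a
relation that holds for *every* instance of the disease — too strong for
most disease–phenotype knowledge, where not every patient shows every
phenotype. OBAN reifies each link instead:

```
:assoc  a  oban:association ;
    oban:association_has_subject  efo:Crohns_disease ;
    oban:association_has_object   hp:diarrhea ;
    oban:has_provenance           :prov1 .

:prov1  a  oban:provenance , eco:manual_assertion ;
    oban:has_curator  "clinician A" .
```

The disease and phenotype individuals are **punned** — they carry the same
IRI as the ontology classes, so no parallel instance IRIs are minted.
Provenance individuals are typed by an evidence-code class (manual
assertion, automatic/text-mining assertion, or any user-supplied IRI) and
carry open-ended attribute triples (PubMed id, curator, confidence). One
provenance individual may support many associations, and one association
may cite many provenances.

Around this model the package provides:

* **Cross-reference mapping** (`obanlink.xref`) — records map to classes by
  normalized prefixed identifiers; 1-to-many hits are resolved only when
  the trait name equals the preferred label or an *exact*-scoped synonym of
  exactly one candidate (broad/narrow synonyms never qualify); everything
  else is deferred to manual curation. Coverage is reported as percent of
  distinct trait labels mapped per source.
* **Phenotype mining** (`obanlink.mining`) — disease-specific corpus
  selection, case-insensitive token-boundary longest-match dictionary
  matching, corpus-wide term frequency with `idf = ln(N/df)`, a stoplist
  for uninformative terms ("All", "Chronic", "death", "sudden death"), and
  2-of-3 expert vote merging where "maybe" counts toward neither side.
* **Linkage** (`obanlink.linker`) — a phenotype associated with ≥1 rare
  (Orphanet-namespace) and ≥1 common (EFO-namespace) disease is a *bridge*;
  bridges induce rare–common disease pairs with the shared phenotypes
  listed per pair.
* **Synthetic fixtures** (`obanlink.fixtures`) — seeded generators for all
  five pipeline inputs with planted ground truth.

## Worked example

`examples/03_mine_phenotypes.py` mines a four-abstract corpus for Crohn's
disease phenotypes and merges a three-clinician vote sheet:

```
corpus: 3 of 4 abstracts mention the disease
diarrhea        tf=2 idf=0.405 docs=PMID1,PMID2 -> accepted
cachexia        tf=1 idf=1.099 docs=PMID3 -> undecided
abdominal pain  tf=1 idf=1.099 docs=PMID1 -> accepted
Chronic         tf=1 idf=1.099 docs=PMID2 -> stoplisted
precision over reviewed candidates: 66.7 %
```

`tf` counts every mention across the selected corpus; `idf = ln(N/df)`
(here `ln(3/2) = 0.405` for diarrhea, seen in 2 of 3 abstracts) rewards
phenotypes concentrated in few abstracts. Two yes votes accept a pair, two
no votes reject it, anything else stays undecided; "Chronic" is a valid
ontology term but uninformative, so it is stoplisted before review.
Precision is the accepted fraction of reviewed pairs (2 of 3 here). The
other scripts in `examples/` cover graph building and serialization,
annotation mapping, and rare–common linkage.

## Command line

The same stages are available as shell commands for batch runs:

```
obanlink fixtures --out fx --seed 7
obanlink map   --ontology fx/ontology.tsv --records fx/records.tsv \
               --out mapped.tsv --report coverage.tsv
obanlink mine  --corpus fx/corpus.tsv --ontology fx/ontology.tsv \
               --diseases fx/diseases.tsv --out candidates.tsv
obanlink curate --candidates candidates.tsv --votes fx/votes.tsv --out curated.tsv
obanlink build-oban --candidates curated.tsv --out associations.ttl
obanlink link  --oban associations.ttl --summary summary.json
```

Re-running any command on identical inputs yields byte-identical output:
serialization sorts triples lexicographically before writing.

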