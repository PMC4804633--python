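# Methods

## The association model

OBAN reifies a disease–phenotype link as a named individual of an
`association` class with exactly one `association_has_subject` and one
`association_has_object` property and at least one `has_provenance` link to
a `provenance` individual. This separates "sometimes associated" knowledge
from class-level OWL axioms, which are interpreted as true for every member
of a class. The package also emits the two contrasting class-level
patterns for relations that *are* always true, as Manchester-syntax text:
`disease SubClassOf has_disease_location some <organism part>` and the
nested `realized_in (disease course and (has_part some <process>) and
(bearer_of some abnormal))` form for abnormal biological processes. No
reasoning is performed over either.

Modelling choices:

* **Punning.** Entity individuals reuse the ontology-class IRI. The entity
  kind (disease/phenotype/other) is carried as a literal annotation in the
  configurable base namespace rather than a type triple, so that a triple
  scan of any serialized document shows the entity-individual IRIs exactly
  equal to the entity-class IRIs in use. Documents produced elsewhere
  without this annotation are read with the positional convention
  (subject = disease, object = phenotype).
* **Association IRIs** are minted deterministically as a SHA-1 digest of
  the (subject IRI, object IRI) pair under a configurable base namespace;
  rebuilding the same graph is idempotent.
* **Direction.** Graphs are stored directionally (disease as subject by
  convention) but every linkage query uses the undirected view; swapping
  subject and object of any association changes no linkage statistic.
* **Evidence vocabulary.** A minimal built-in vocabulary covers manual
  assertion (ECO_0000218) and automatic/text-mining assertion
  (ECO_0000203); any other evidence-class IRI passes through unchanged.
* **Provenance attributes** are an open set of (predicate IRI, string
  value) pairs; a predicate may repeat with distinct values. RDF carries
  no list order, so round-trip equality treats an association's provenance
  as a set keyed by provenance IRI (in-memory construction still preserves
  the order given).
* **Determinism.** Serialization sorts triples by subject, predicate,
  object (N3 form) before writing; Turtle output is one fully-spelled
  triple per line, RDF/XML groups by subject with generated prefixes.
  Output is byte-identical across runs and processes. Parsing goes through
  rdflib and accepts any layout of the two dialects.

## Cross-reference mapping

Identifiers are normalized to `PREFIX:ID` with a configurable prefix-synonym
table (`MIM` → `OMIM`, `ORPHA`/`ORDO` → `ORPHANET`, `SNOMED-CT` → `SNOMEDCT`,
...), accepting `:`, `_` or whitespace separators. Resolution rules, in
order: a single candidate class across all of a record's identifiers maps
1:1; identifiers that disagree (two hits on different classes) defer to
curation with the candidates listed; a single ambiguous identifier is
resolved only by a case-insensitive, whitespace-collapsed equality between
the trait name and the label or an exact-scoped synonym of exactly one
candidate — broad and narrow synonyms never resolve, because exactness is
the criterion that keeps automatic mapping safe. No stemming, no fuzzy
scores: lexical mapping with scores is a different tool's job, and new-term
creation is out of scope.

Coverage is percent of **distinct trait labels** mapped per source (not raw
records), rounded half-up to an integer as summary tables print it, with
the raw value retained; an optional frequency filter restricts the
denominator to labels occurring more than a threshold number of times.

## Mining

Tokenization splits on non-alphanumerics and keeps apostrophes
word-internal ("Crohn's" is one token). Matching is case-insensitive,
token-boundary, greedy leftmost-longest and non-overlapping per document;
phenotypes sharing a surface form are all reported at the same span.
Corpus selection for a disease uses the same matcher over the preferred
label and synonyms. `tf` is the corpus-wide raw match count (a per-abstract
variant would change only the export, not the pipeline shape); `idf =
ln(N/df)` over the selected corpus. Both follow the common raw-count/log
convention and live behind one function so alternative conventions can be
swapped.

The default stoplist is {All, Chronic, death, sudden death}; stoplisting
relabels rows, never deletes them, so status counts are conserved through
the pipeline. Vote merging accepts at ≥ quorum (default 2 of a panel of 3)
"yes" votes, rejects at ≥ quorum "no", and leaves everything else
undecided; "maybe" counts toward neither side and undecided rows are
retained. With a panel large enough for both sides to reach quorum the
conflict resolves to undecided. Votes cast on stoplisted rows are ignored
with a warning. Precision is accepted / (accepted + rejected + undecided)
over non-stoplisted rows, reported as a percentage with one decimal;
unvoted rows are excluded from the denominator.

## Linkage

Disease class is a pure function of the IRI local-name prefix
(`Orphanet_*` rare, `EFO_*` common, anything else unknown) plus an
override table; unknowns are excluded from bridge computation but counted.
A bridge is a phenotype associated, in either direction, with at least one
rare and at least one common disease. Rare–common pairs are the cartesian
product within each bridge, merged across bridges, each pair reported once
with all shared phenotypes. Gene/pathway-mediated linkage and
anatomical-system rollups are out of scope.

## Synthetic fixtures

One integer seed drives a `random.Random`; identical seeds produce
byte-identical fixture directories. The generator plants, and emits as
ground truth: per-source mapping coverage (defaults mirror the published
per-source percentages: EVA 89, ArrayExpress 77, UniProt 78, Reactome 100,
ChEMBL 99, GWAS Catalog 100, at 100 records per source), term and document
frequencies per planted pair (6 mined diseases × 5 pairs over 8 abstracts
each by default), vote outcomes (the default profile reproduces 41.6 %
precision when measured over 500 reviewed pairs), and a linkage graph with
535 bridge phenotypes over 20 common and 85 rare diseases, round-robin
assigned so every linked disease joins at least one bridge. Abstracts are
assembled from a fixed word list kept disjoint from every dictionary
surface form, with decoy sentences containing stoplist terms and nested
term labels ("arthralgia" inside "recurrent arthralgia") to exercise
longest-match resolution.

What passing recovery tests shows — and does not. The fixtures prove the
pipeline recovers exactly what was planted under clean conditions:
unambiguous sentence boundaries, synonym lists that are complete, no
negation, no hedging, one disease per abstract. Real abstracts violate all
of these, so exact recovery here bounds implementation correctness, not
real-world mining precision; the dictionary matcher by design does no
negation detection or NLP beyond token matching.

## Numerical and edge-case choices

* Integer percentages round half-up; precision rounds to one decimal.
* `idf` uses natural log; a term in every document has idf 0 exactly.
* Ties between phenotypes sharing a surface form are broken by IRI order
  in exports; export rows sort by tf descending, then IRIs.
* Empty graphs serialize to a valid document with an ontology header.
* Degenerate inputs fail loudly: self-associations, empty provenance,
  relative IRIs, votes on unknown pairs, duplicate reviewer votes, more
  votes than the panel size, manual-map targets missing from the ontology,
  and structurally incomplete association documents (the error names the
  offending individual).

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
planted structures are still non-trivial: 100-graph serialization
round-trips, 50-document matcher-oracle corpora, 200-record mapping
oracles, 50-disease/100-phenotype linkage oracles, a 500-pair precision
fixture and a 1.3k-association linkage graph. All counts are recomputed by
brute-force oracles in the tests.
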