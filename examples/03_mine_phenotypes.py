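"""Mine candidate disease-phenotype associations from a small corpus.

Selects the abstracts mentioning Crohn's disease, matches a phenotype
dictionary, ranks candidates by term frequency and inverse document
frequency, drops uninformative stoplist terms, and merges a 2-of-3
clinician vote sheet.
"""

from obanlink.mining import (CorpusDoc, DictionaryEntry, Vote, apply_stoplist,
                             match_terms, merge_votes, precision,
                             score_candidates, select_corpus)

HP = "http://purl.obolibrary.org/obo/HP_"
CROHNS = "http://www.ebi.ac.uk/efo/EFO_0000384"

dictionary = [
    DictionaryEntry(f"{HP}0002014", "diarrhea", ("diarrhea", "loose stools")),
    DictionaryEntry(f"{HP}0004326", "cachexia", ("cachexia",)),
    DictionaryEntry(f"{HP}0011458", "abdominal pain", ("abdominal pain",)),
    DictionaryEntry(f"{HP}0999991", "Chronic", ("chronic",)),  # stoplisted
]

docs = [
    CorpusDoc("PMID1", "Crohn's disease patients reported diarrhea and "
                       "abdominal pain during flares."),
    CorpusDoc("PMID2", "We observed chronic diarrhea in Crohn's disease."),
    CorpusDoc("PMID3", "Granulomatous colitis with cachexia and weight loss."),
    CorpusDoc("PMID4", "An unrelated cardiology cohort."),
]

corpus = select_corpus(docs, ["Crohn's disease", "granulomatous colitis"])
print(f"corpus: {len(corpus)} of {len(docs)} abstracts mention the disease")

matches = match_terms(corpus, dictionary)
candidates = score_candidates(matches, corpus, CROHNS, "Crohn's disease",
                              {e.phenotype_iri: e.label for e in dictionary})
candidates = apply_stoplist(candidates)

votes = [Vote(CROHNS, f"{HP}0002014", f"clinician_{i}", v)
         for i, v in enumerate(["yes", "yes", "maybe"])]
votes += [Vote(CROHNS, f"{HP}0004326", f"clinician_{i}", v)
          for i, v in enumerate(["yes", "no", "maybe"])]
votes += [Vote(CROHNS, f"{HP}0011458", f"clinician_{i}", v)
          for i, v in enumerate(["yes", "yes", "yes"])]
merged = merge_votes(candidates, votes)

# tf counts every mention in the selected corpus; idf = ln(N/df) rewards
# phenotypes concentrated in few abstracts
for c in merged:
    print(f"{c.phenotype_label:15s} tf={c.tf} idf={c.idf:.3f} "
          f"docs={','.join(c.doc_ids)} -> {c.status}")
print(f"precision over reviewed candidates: {precision(merged)} %")
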