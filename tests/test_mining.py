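"""Dictionary matching, TF-IDF scoring, stoplist and vote merging."""

import itertools
import math

import pytest

from obanlink.mining import (STATUS_ACCEPTED, STATUS_CANDIDATE,
                             STATUS_REJECTED, STATUS_STOPLISTED,
                             STATUS_UNDECIDED, CandidateAssociation, CorpusDoc,
                             DictionaryEntry, Vote, apply_stoplist,
                             build_dictionary, export_candidates, match_terms,
                             merge_votes, precision, read_candidates,
                             score_candidates, select_corpus, tokenize)

HP = "http://purl.obolibrary.org/obo/HP_"


def entry(num, *forms):
    return DictionaryEntry(f"{HP}{num}", forms[0], tuple(forms))


def test_possessive_is_one_token():
    assert [t for t, _, _ in tokenize("Crohn's disease")] == ["crohn's", "disease"]


class TestSelectCorpus:
    def docs(self):
        texts = (["Crohn's disease progression in adults."] * 2
                 + ["A report of granulomatous colitis."] * 2
                 + ["Unrelated cardiology report."] * 6)
        return [CorpusDoc(f"d{i}", t) for i, t in enumerate(texts)]

    def test_labels_and_synonyms_select_matching_docs(self):
        out = select_corpus(self.docs(),
                            ["Crohn's disease", "granulomatous colitis"])
        assert [d.doc_id for d in out] == ["d0", "d1", "d2", "d3"]

    def test_empty_label_list_is_an_error(self):
        with pytest.raises(ValueError):
            select_corpus(self.docs(), [])

    def test_no_matching_doc_returns_empty_corpus(self):
        assert select_corpus(self.docs(), ["ulcerative colitis"]) == []


class TestMatchTerms:
    def test_plain_containment(self):
        docs = [CorpusDoc("d1", "patients with diarrhea and weight loss")]
        matches = match_terms(docs, [entry(1, "diarrhea"), entry(2, "weight loss")])
        assert {(m.phenotype_iri, m.text) for m in matches} == {
            (f"{HP}1", "diarrhea"), (f"{HP}2", "weight loss")}

    def test_longest_match_wins_over_nested_form(self):
        docs = [CorpusDoc("d1", "an abnormal neurological response was seen")]
        matches = match_terms(docs, [entry(1, "abnormal"),
                                     entry(2, "abnormal neurological response")])
        assert [(m.phenotype_iri, m.text) for m in matches] == [
            (f"{HP}2", "abnormal neurological response")]

    def test_no_hits_is_empty(self):
        docs = [CorpusDoc("d1", "nothing of interest here")]
        assert match_terms(docs, [entry(1, "diarrhea")]) == []

    def test_span_reproduces_surface_form(self):
        docs = [CorpusDoc("d1", "Severe DIARRHEA, recurring weekly.")]
        (m,) = match_terms(docs, [entry(1, "diarrhea")])
        assert docs[0].text[m.start:m.end].casefold() == "diarrhea"


def brute_force_match(corpus, dictionary):
    """Quadratic oracle: try every surface form at every token position,
    then resolve overlaps leftmost-longest."""
    out = set()
    for doc in corpus:
        tokens = tokenize(doc.text)
        candidates = []
        for e in dictionary:
            for form in e.surface_forms:
                ftoks = [t for t, _, _ in tokenize(form)]
                for i in range(len(tokens) - len(ftoks) + 1):
                    if [t for t, _, _ in tokens[i:i + len(ftoks)]] == ftoks:
                        candidates.append((i, i + len(ftoks), e.phenotype_iri))
        chosen_spans = []
        for start, end, iri in sorted(candidates,
                                      key=lambda c: (c[0], -(c[1] - c[0]), c[2])):
            if all(end <= s or start >= e for s, e, _ in chosen_spans):
                chosen_spans.append((start, end, iri))
            elif any(s == start and e == end for s, e, _ in chosen_spans):
                chosen_spans.append((start, end, iri))  # shared surface form
        for start, end, iri in chosen_spans:
            out.add((doc.doc_id, tokens[start][1], tokens[end - 1][2], iri))
    return out


def test_matcher_agrees_with_brute_force_on_generated_corpus(small_fixture):
    fx = small_fixture
    dictionary = build_dictionary(fx.ontology)
    fast = match_terms(fx.docs, dictionary)
    assert {(m.doc_id, m.start, m.end, m.phenotype_iri) for m in fast} == \
        brute_force_match(fx.docs, dictionary)


class TestScoring:
    def corpus(self, n=8):
        return [CorpusDoc(f"d{i}", "background text") for i in range(n)]

    def test_tf_and_idf_closed_form(self):
        from obanlink.mining import TermMatch
        # 5 mentions across 2 of 8 abstracts
        matches = [TermMatch(f"{HP}1", "d0", 0, 1, "x")] * 3 \
            + [TermMatch(f"{HP}1", "d1", 0, 1, "x")] * 2
        (c,) = score_candidates(matches, self.corpus(), "http://d", "D")
        assert c.tf == 5
        assert c.idf == pytest.approx(math.log(4), abs=1e-12)

    def test_idf_zero_when_term_in_every_doc(self):
        from obanlink.mining import TermMatch
        matches = [TermMatch(f"{HP}1", f"d{i}", 0, 1, "x") for i in range(8)]
        (c,) = score_candidates(matches, self.corpus(), "http://d", "D")
        assert c.idf == 0.0

    def test_unmatched_phenotype_has_no_row(self):
        assert score_candidates([], self.corpus(), "http://d", "D") == []

    def test_idf_non_increasing_in_df(self):
        from obanlink.mining import TermMatch
        idfs = []
        for df in range(1, 9):
            matches = [TermMatch(f"{HP}1", f"d{i}", 0, 1, "x")
                       for i in range(df)]
            (c,) = score_candidates(matches, self.corpus(), "http://d", "D")
            idfs.append(c.idf)
        assert idfs == sorted(idfs, reverse=True)


def candidate(pheno_label, status=STATUS_CANDIDATE, num=1):
    return CandidateAssociation(
        "http://www.ebi.ac.uk/efo/EFO_1", "disease", f"{HP}{num}", pheno_label,
        tf=2, idf=0.5, doc_ids=("d0",), status=status)


class TestStoplist:
    def test_default_stoplist_catches_uninformative_terms(self):
        out = apply_stoplist([candidate("Chronic"), candidate("diarrhea", num=2)])
        assert [c.status for c in out] == [STATUS_STOPLISTED, STATUS_CANDIDATE]

    def test_empty_stoplist_is_identity(self):
        cands = [candidate("Chronic")]
        assert apply_stoplist(cands, stoplist=()) == cands

    def test_unmatched_stoplist_entry_changes_nothing(self):
        cands = [candidate("diarrhea")]
        assert apply_stoplist(cands, {"no such term"}) == cands

    def test_counts_conserved(self):
        cands = [candidate(lbl, num=i) for i, lbl in
                 enumerate(["Chronic", "death", "diarrhea", "tremor"])]
        out = apply_stoplist(cands)
        assert len(out) == len(cands)


def expected_status(votes, quorum=2):
    """Independent statement of the agreement rule."""
    yes, no = votes.count("yes"), votes.count("no")
    if yes >= quorum and no < quorum:
        return STATUS_ACCEPTED
    if no >= quorum and yes < quorum:
        return STATUS_REJECTED
    return STATUS_UNDECIDED


class TestMergeVotes:
    def run(self, votes, **kw):
        cands = [candidate("diarrhea")]
        sheet = [Vote(cands[0].disease_iri, cands[0].phenotype_iri,
                      f"clinician_{i}", v) for i, v in enumerate(votes)]
        (out,) = merge_votes(cands, sheet, **kw)
        return out.status

    def test_full_three_vote_truth_table(self):
        # all 27 combinations against the independently stated rule
        for votes in itertools.product(("yes", "no", "maybe"), repeat=3):
            assert self.run(list(votes)) == expected_status(votes), votes

    @pytest.mark.parametrize("votes,status", [
        (["yes", "yes", "maybe"], STATUS_ACCEPTED),
        (["yes", "no", "maybe"], STATUS_UNDECIDED),
        (["no", "no", "no"], STATUS_REJECTED),
    ])
    def test_agreement_rule_examples(self, votes, status):
        assert self.run(votes) == status

    def test_unvoted_candidate_keeps_status(self):
        cands = [candidate("diarrhea")]
        assert merge_votes(cands, []) == cands

    def test_more_votes_than_panel_errors(self):
        with pytest.raises(ValueError, match="more than"):
            self.run(["yes"] * 4)

    def test_duplicate_reviewer_errors(self):
        cands = [candidate("diarrhea")]
        sheet = [Vote(cands[0].disease_iri, cands[0].phenotype_iri,
                      "clinician_0", v) for v in ("yes", "no")]
        with pytest.raises(ValueError, match="twice"):
            merge_votes(cands, sheet)

    def test_vote_on_unknown_pair_errors(self):
        with pytest.raises(KeyError):
            merge_votes([candidate("diarrhea")],
                        [Vote("http://other", f"{HP}1", "c1", "yes")])

    def test_votes_on_stoplisted_rows_are_ignored(self):
        cands = [candidate("Chronic", status=STATUS_STOPLISTED)]
        sheet = [Vote(cands[0].disease_iri, cands[0].phenotype_iri,
                      f"c{i}", "yes") for i in range(2)]
        (out,) = merge_votes(cands, sheet)
        assert out.status == STATUS_STOPLISTED

    def test_status_counts_conserved_through_pipeline(self, small_fixture):
        fx = small_fixture
        from collections import Counter
        merged = fx.expected_candidates
        counts = Counter(c.status for c in merged)
        assert sum(counts.values()) == len(fx.planted) + len(fx.decoys)


class TestPrecision:
    def make(self, accepted, rejected, undecided, stoplisted=0):
        out = []
        n = 0
        for status, k in ((STATUS_ACCEPTED, accepted),
                          (STATUS_REJECTED, rejected),
                          (STATUS_UNDECIDED, undecided),
                          (STATUS_STOPLISTED, stoplisted)):
            for _ in range(k):
                out.append(candidate(f"pheno {n}", status=status, num=n))
                n += 1
        return out

    def test_five_of_twelve_reviewed(self):
        assert precision(self.make(5, 4, 3)) == 41.7

    def test_all_accepted(self):
        assert precision(self.make(4, 0, 0)) == 100.0

    def test_planned_208_of_500(self):
        assert precision(self.make(208, 180, 112)) == 41.6

    def test_stoplisted_rows_excluded_from_denominator(self):
        assert precision(self.make(5, 4, 3, stoplisted=10)) == 41.7

    def test_no_reviewed_rows_errors(self):
        with pytest.raises(ValueError):
            precision(self.make(0, 0, 0, stoplisted=2))


class TestExport:
    def test_round_trip_is_lossless(self, tmp_path):
        cands = [candidate("diarrhea", num=1),
                 candidate("tremor", status=STATUS_ACCEPTED, num=2)]
        path = tmp_path / "cand.tsv"
        export_candidates(cands, path)
        assert sorted(read_candidates(path), key=lambda c: c.phenotype_iri) == \
            sorted(cands, key=lambda c: c.phenotype_iri)

    def test_header_only_when_empty(self, tmp_path):
        text = export_candidates([])
        assert text.count("\n") == 1

    def test_rows_ordered_by_tf_descending(self):
        import dataclasses
        a = dataclasses.replace(candidate("a", num=1), tf=1)
        b = dataclasses.replace(candidate("b", num=2), tf=9)
        lines = export_candidates([a, b]).splitlines()
        assert lines[1].split("\t")[2] == f"{HP}2"
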