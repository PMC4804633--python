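"""Cross-reference mapping: normalization, resolution rules, coverage."""

import pytest

from obanlink.fixtures import FixtureSpec, generate
from obanlink.ontology import OntologyClass, Synonym
from obanlink.xref import (MAPPED_1TO1, MAPPED_SYNONYM, UNMAPPED, SourceRecord,
                           apply_manual_map, build_xref_index, coverage_report,
                           map_record, map_records, normalize_xref)

EFO = "http://www.ebi.ac.uk/efo/EFO_"


@pytest.fixture()
def ontology():
    """A tiny EFO-like slice with an ambiguous cross-reference."""
    acatalasia = OntologyClass(f"{EFO}0004144", "Acatalasia",
                               xrefs=["OMIM:115500"])
    cah = OntologyClass(
        f"{EFO}0000100", "congenital adrenal hyperplasia",
        synonyms=[Synonym("adrenal hyperplasia, congenital", "exact"),
                  Synonym("salt-wasting adrenal hyperplasia", "narrow")],
        xrefs=["SNOMEDCT:237751000"])
    lookalike = OntologyClass(
        f"{EFO}0000101", "adrenal disorder",
        synonyms=[Synonym("adrenal gland disease", "exact")],
        xrefs=["SNOMEDCT:237751000"])
    return {c.iri: c for c in (acatalasia, cah, lookalike)}


@pytest.mark.parametrize("raw", ["OMIM:115500", "MIM 115500", "omim_115500",
                                 "mim:115500"])
def test_xref_normalization_folds_prefix_variants(raw):
    assert normalize_xref(raw) == "OMIM:115500"


def test_non_identifier_text_does_not_normalize():
    assert normalize_xref("just a label") is None


class TestIndex:
    def test_unique_xref_maps_to_single_class(self, ontology):
        index = build_xref_index(ontology)
        assert index["OMIM:115500"] == frozenset({f"{EFO}0004144"})

    def test_shared_xref_keeps_both_classes(self, ontology):
        index = build_xref_index(ontology)
        assert len(index["SNOMEDCT:237751000"]) == 2

    def test_no_xrefs_yields_empty_index(self):
        only = OntologyClass(f"{EFO}1", "bare class")
        assert build_xref_index({only.iri: only}) == {}


class TestMapRecord:
    def test_one_to_one_mapping(self, ontology):
        # protein annotated with an OMIM id maps straight to the disease class
        index = build_xref_index(ontology)
        res = map_record(SourceRecord("UniProt", "P04040", "acatalasia",
                                      ("OMIM:115500",)), index, ontology)
        assert res.status == MAPPED_1TO1
        assert res.target_iri == f"{EFO}0004144"

    def test_ambiguous_xref_resolved_by_exact_synonym(self, ontology):
        index = build_xref_index(ontology)
        res = map_record(SourceRecord(
            "EVA", "r1", "adrenal hyperplasia, congenital",
            ("SNOMEDCT:237751000",)), index, ontology)
        assert res.status == MAPPED_SYNONYM
        assert res.target_iri == f"{EFO}0000100"

    def test_narrow_synonym_never_resolves(self, ontology):
        index = build_xref_index(ontology)
        res = map_record(SourceRecord(
            "EVA", "r2", "salt-wasting adrenal hyperplasia",
            ("SNOMEDCT:237751000",)), index, ontology)
        assert res.status == UNMAPPED
        assert res.target_iri is None

    def test_record_without_usable_xref_needs_curation(self, ontology):
        index = build_xref_index(ontology)
        res = map_record(SourceRecord(
            "EVA", "r3", "Glucose-6-phosphate transport defect", ()),
            index, ontology)
        assert res.status == UNMAPPED

    def test_conflicting_xrefs_defer_to_curation_listing_candidates(self, ontology):
        index = build_xref_index(ontology)
        res = map_record(SourceRecord(
            "EVA", "r4", "some trait",
            ("OMIM:115500", "SNOMEDCT:237751000")), index, ontology)
        assert res.status == UNMAPPED
        assert f"{EFO}0004144" in res.evidence

    def test_results_independent_of_ontology_order(self, ontology):
        records = [SourceRecord("EVA", f"r{i}", label, xrefs)
                   for i, (label, xrefs) in enumerate([
                       ("acatalasia", ("OMIM:115500",)),
                       ("adrenal hyperplasia, congenital", ("SNOMEDCT:237751000",)),
                       ("nothing", ())])]
        forward = map_records(records, ontology)
        reversed_onto = dict(reversed(list(ontology.items())))
        assert map_records(records, reversed_onto) == forward


class TestManualMap:
    def test_manual_row_maps_unmapped_record(self, ontology):
        results = {"r1": map_record(SourceRecord("EVA", "r1", "mystery", ()),
                                    {}, ontology)}
        out = apply_manual_map(results, {"r1": f"{EFO}0004144"}, ontology)
        assert out["r1"].mapped and out["r1"].evidence == "manual"

    def test_manual_row_for_mapped_record_is_ignored(self, ontology):
        index = build_xref_index(ontology)
        results = {"P04040": map_record(
            SourceRecord("UniProt", "P04040", "acatalasia", ("OMIM:115500",)),
            index, ontology)}
        out = apply_manual_map(results, {"P04040": f"{EFO}0000100"}, ontology)
        assert out["P04040"].target_iri == f"{EFO}0004144"

    def test_bogus_manual_target_raises(self, ontology):
        with pytest.raises(ValueError, match="EFO_9999"):
            apply_manual_map({}, {"r1": f"{EFO}9999"}, ontology)


class TestCoverage:
    def _results(self, records, mapped_ids):
        from obanlink.xref import MappingResult
        return {r.record_id: (MappingResult(r.record_id, MAPPED_1TO1,
                                            f"{EFO}1", "x")
                              if r.record_id in mapped_ids
                              else MappingResult(r.record_id, UNMAPPED))
                for r in records}

    def test_77_of_100_reports_77_percent(self):
        records = [SourceRecord("ArrayExpress", f"r{i}", f"trait {i}", ())
                   for i in range(100)]
        results = self._results(records, {f"r{i}" for i in range(77)})
        (row,) = coverage_report(records, results)
        assert row.percent == 77

    def test_all_mapped_is_100_percent(self):
        records = [SourceRecord("Reactome", f"r{i}", f"trait {i}", ())
                   for i in range(8)]
        results = self._results(records, {r.record_id for r in records})
        (row,) = coverage_report(records, results)
        assert row.percent == 100

    def test_frequency_filter_matches_brute_force_recount(self):
        # labels with planted occurrence counts; only frequent ones count
        counts = {"common trait": 12, "mid trait": 5, "rare trait": 1}
        mapped_labels = {"common trait", "rare trait"}
        records, rid = [], 0
        for label, n in counts.items():
            for _ in range(n):
                records.append(SourceRecord("EVA", f"r{rid}", label, ()))
                rid += 1
        mapped_ids = {r.record_id for r in records
                      if r.trait_label in mapped_labels}
        results = self._results(records, mapped_ids)
        for threshold in (None, 1, 4, 11):
            (row,) = coverage_report(records, results, min_frequency=threshold)
            keep = {lbl for lbl, n in counts.items()
                    if threshold is None or n > threshold}
            expect = 100.0 * len(keep & mapped_labels) / len(keep)
            assert row.percent == int(expect + 0.5)
            assert row.percent_raw == pytest.approx(expect)


def brute_force_map(record, ontology):
    """Independent quadratic oracle: scan every (record xref, class xref)
    pair and re-apply the resolution rules from first principles."""
    hits = {}
    for raw in record.xrefs:
        key = normalize_xref(raw)
        if key is None:
            continue
        classes = {cls.iri for cls in ontology.values()
                   if any(normalize_xref(x) == key for x in cls.xrefs)}
        if classes:
            hits[key] = classes
    if not hits:
        return (UNMAPPED, None)
    union = set().union(*hits.values())
    if len(union) == 1:
        return (MAPPED_1TO1, next(iter(union)))
    if len(hits) > 1:
        return (UNMAPPED, None)
    wanted = " ".join(record.trait_label.casefold().split())
    matching = []
    for iri in union:
        cls = ontology[iri]
        names = [cls.label] + [s.text for s in cls.synonyms if s.scope == "exact"]
        if any(" ".join(n.casefold().split()) == wanted for n in names):
            matching.append(iri)
    if len(matching) == 1:
        return (MAPPED_SYNONYM, matching[0])
    return (UNMAPPED, None)


def test_mapping_agrees_with_brute_force_on_generated_records(small_fixture):
    fx = small_fixture
    results = map_records(fx.records, fx.ontology)
    for record in fx.records:
        expect = brute_force_map(record, fx.ontology)
        got = results[record.record_id]
        assert (got.status, got.target_iri) == expect, record


def test_generated_records_recover_planted_mapping_statuses(small_fixture):
    fx = small_fixture
    results = map_records(fx.records, fx.ontology)
    for record_id, (status, target) in fx.expected_mapping.items():
        got = results[record_id]
        assert (got.status, got.target_iri) == (status, target)


def test_unique_xrefs_give_complete_coverage():
    spec = FixtureSpec(seed=2, coverage_targets={"GWAS_Catalog": (40, 100)},
                       n_bridge_phenotypes=5, n_nonbridge_phenotypes=5,
                       n_linked_common=3, n_linked_rare=3)
    fx = generate(spec)
    results = map_records(fx.records, fx.ontology)
    (row,) = coverage_report(fx.records, results)
    assert (row.source, row.percent) == ("GWAS_Catalog", 100)
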