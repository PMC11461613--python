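import pytest
from hypothesis import given, settings, strategies as st

from targetatlas.traits import (
    CurationOverlay,
    MappingResult,
    ResolutionPolicy,
    TraitRecord,
    candidate_concepts,
    collapse_to_disease_set,
    map_icd10_traits,
    map_trait_cascade,
    resolve_candidates,
)
from targetatlas.vocab import ConceptStore, SemanticTypeTable


def _store_of(rows):
    store = ConceptStore()
    for cui, term, sab in rows:
        store.add_synonym(cui, term, sab, code=f"X-{cui}")
    return store


@pytest.fixture()
def small_store():
    return _store_of(
        [
            ("C1", "Crohn Disease", "MSH"),
            ("C2", "Lung Carcinoma", "MSH"),
            ("C3", "Blood Pressure Finding", "MSH"),
            ("C4", "Carcinoma", "MSH"),
        ]
    )


@pytest.fixture()
def small_types():
    return SemanticTypeTable(
        rows={
            "C1": {"Disease or Syndrome"},
            "C2": {"Neoplastic Process"},
            "C3": {"Finding"},
            "C4": {"Neoplastic Process"},
        }
    )


class TestCandidateConcepts:
    def test_exact_synonym_included(self, small_store):
        assert "C1" in candidate_concepts("crohn disease", small_store)

    def test_token_subset_rule(self, small_store):
        cands = candidate_concepts("severe crohn disease pediatric", small_store)
        assert cands == {"C1"}

    def test_single_token_floor(self, small_store):
        # 'carcinoma' alone: no exact match entry is single-token-proof,
        # and the two-token floor blocks subset matches.
        assert candidate_concepts("carcinomatosis", small_store) == set()

    def test_multiword_trait_matches_both(self, small_store):
        cands = candidate_concepts(
            "severe crohn disease with lung carcinoma", small_store
        )
        assert cands == {"C1", "C2"}


class TestResolveCandidates:
    def test_direct_match_wins(self, small_store, small_types):
        resolved = resolve_candidates(
            "crohn disease", {"C1", "C2"}, small_store, small_types
        )
        assert resolved == {"C1"}

    def test_priority_scan(self, small_store, small_types):
        # Disease or Syndrome outranks Finding.
        resolved = resolve_candidates(
            "unmatched text", {"C1", "C3"}, small_store, small_types
        )
        assert resolved == {"C1"}
        # Neoplastic Process outranks Finding; ties within a tier are kept.
        resolved = resolve_candidates(
            "unmatched text", {"C2", "C3", "C4"}, small_store, small_types
        )
        assert resolved == {"C2", "C4"}

    def test_untyped_candidates_returned_unchanged(self, small_store):
        bare = SemanticTypeTable(rows={})
        resolved = resolve_candidates(
            "unmatched text", {"C1", "C2"}, small_store, bare
        )
        assert resolved == {"C1", "C2"}

    def test_empty_input_rejected(self, small_store, small_types):
        with pytest.raises(ValueError):
            resolve_candidates("x", set(), small_store, small_types)

    @settings(derandomize=True, max_examples=100)
    @given(st.sets(st.sampled_from(["C1", "C2", "C3", "C4"]), min_size=1))
    def test_never_empties_never_grows(self, candidates):
        store = _store_of(
            [
                ("C1", "Crohn Disease", "MSH"),
                ("C2", "Lung Carcinoma", "MSH"),
                ("C3", "Blood Pressure Finding", "MSH"),
                ("C4", "Carcinoma", "MSH"),
            ]
        )
        types = SemanticTypeTable(
            rows={"C1": {"Disease or Syndrome"}, "C3": {"Finding"}}
        )
        resolved = resolve_candidates("no direct hit", set(candidates), store, types)
        assert resolved
        assert resolved <= candidates


class TestCascade:
    def test_planted_traits_resolve_at_intended_stage(self, exact_run):
        result, ledger = exact_run
        by_key = {r.trait.key: r for r in result.trait_results}
        for text, truth in ledger.trait_truth.items():
            got = by_key[text]
            assert got.stage == truth.stage, text
            assert set(got.cuis) == set(truth.cuis), text

    def test_stage_partition_of_traits(self, exact_run):
        result, _ledger = exact_run
        by_stage = {}
        for r in result.trait_results:
            by_stage[r.stage] = by_stage.get(r.stage, 0) + 1
        assert sum(by_stage.values()) == len(result.trait_results)

    def test_overlay_preempts_direct_match(self, small_store, small_types):
        overlay = CurationOverlay(decisions={"crohn disease": frozenset({"C9"})})
        result = map_trait_cascade(
            TraitRecord(reported_trait="Crohn Disease"),
            small_store, small_types, overlay=overlay,
        )
        assert result.stage == "curation_overlay"
        assert result.cuis == {"C9"}

    def test_overlay_empty_decision_forces_unmapped(self, small_store, small_types):
        overlay = CurationOverlay(decisions={"crohn disease": frozenset()})
        result = map_trait_cascade(
            TraitRecord(reported_trait="crohn disease"),
            small_store, small_types, overlay=overlay,
        )
        assert result.stage == "curation_overlay"
        assert result.is_unmapped

    def test_unmapped_trait(self, small_store, small_types):
        result = map_trait_cascade(
            TraitRecord(reported_trait="completely unknown thing"),
            small_store, small_types,
        )
        assert result.stage == "unmapped"
        assert result.cuis == frozenset()

    def test_cascade_is_deterministic(self, exact_bundle, world_store):
        outdir, _ledger = exact_bundle
        store, types = world_store
        from targetatlas.traits import read_gwas_traits

        traits = read_gwas_traits(outdir / "gwas_traits.tsv")
        first = [map_trait_cascade(t, store, types) for t in traits]
        second = [map_trait_cascade(t, store, types) for t in traits]
        assert [(r.stage, r.cuis) for r in first] == [
            (r.stage, r.cuis) for r in second
        ]


class TestIcd10:
    @pytest.fixture()
    def coded_store(self):
        store = ConceptStore()
        store.add_synonym("C10", "Essential Hypertension", "ICD10", "I10")
        store.add_synonym("C10", "Essential Hypertension", "MSH", "D000010")
        return store

    def test_exact_code_match_not_string(self, coded_store):
        results = map_icd10_traits(["I10"], coded_store)
        assert results[0].stage == "icd10_code"
        assert results[0].cuis == {"C10"}
        # a code formatted like a matching *string* must not match
        assert map_icd10_traits(["D00", "E11"], coded_store)[0].is_unmapped

    def test_absent_and_duplicate_codes(self, coded_store):
        results = map_icd10_traits(["I10", "Z99", "I10"], coded_store)
        assert [r.is_unmapped for r in results] == [False, True, False]
        assert results[0].cuis == results[2].cuis

    def test_malformed_code_continues(self, coded_store):
        results = map_icd10_traits(["not-a-code", "I10"], coded_store)
        assert results[0].is_unmapped
        assert "error" in results[0].audit
        assert results[1].cuis == {"C10"}

    def test_planted_codes_match_ledger(self, exact_bundle, world_store):
        outdir, ledger = exact_bundle
        store, _types = world_store
        codes = [
            line.strip()
            for line in (outdir / "icd10_phenotypes.tsv").read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        results = map_icd10_traits(codes, store)
        for code, res in zip(codes, results):
            truth = ledger.icd10_truth[code]
            if truth is None:
                assert res.is_unmapped
            else:
                assert res.cuis == {truth}


def _mapped(cuis):
    return MappingResult(
        trait=TraitRecord(reported_trait="t" + "".join(sorted(cuis))),
        cuis=frozenset(cuis),
        stage="direct_string",
    )


class TestCollapse:
    def test_exclusive_excluded_chapter_dropped(self):
        results = [_mapped({f"C{i}"}) for i in range(5)]
        chapters = {f"C{i}": {"Kept chapter"} for i in range(4)}
        chapters["C4"] = {"Animal diseases"}
        kept, rollup = collapse_to_disease_set(
            results, chapters, {"Animal diseases"}
        )
        assert len(kept) == 4
        assert rollup["unique"] == 4

    def test_mixed_chapter_disease_retained(self):
        results = [_mapped({"C1"})]
        chapters = {"C1": {"Animal diseases", "Kept chapter"}}
        kept, _ = collapse_to_disease_set(results, chapters, {"Animal diseases"})
        assert kept == {"C1"}

    def test_uncovered_cui_goes_to_unclassified(self):
        results = [_mapped({"C1"})]
        kept, rollup = collapse_to_disease_set(results, {}, {"Animal diseases"})
        assert kept == {"C1"}
        assert rollup["per_chapter"] == {"Unclassified": 1}

    def test_rollup_counts_once_per_chapter(self):
        results = [_mapped({"C1"}), _mapped({"C2"})]
        chapters = {"C1": {"A", "B"}, "C2": {"A"}}
        kept, rollup = collapse_to_disease_set(results, chapters, set())
        assert rollup["per_chapter"] == {"A": 2, "B": 1}
        assert rollup["unique"] == 2


def test_trait_record_requires_text_or_code():
    with pytest.raises(ValueError):
        TraitRecord()


def test_policy_rejects_duplicate_priorities():
    with pytest.raises(ValueError):
        ResolutionPolicy(priority=("Finding", "finding"))
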