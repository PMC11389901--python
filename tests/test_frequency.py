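import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import recount_frequency

from rwdtextminer import frequency_analytics as fa
from rwdtextminer import ingest, synthetic_ehr as se
from rwdtextminer.extraction import DictionaryTagger, detect_negation, filter_negated
from rwdtextminer.normalization import link_mo_products, normalize_corpus


def _pipeline_lists(corpus):
    aligned = ingest.align(corpus.dpc_records, corpus.mo_records, corpus.documents)
    tagger = DictionaryTagger(corpus.disease_dictionary, corpus.drug_dictionary)
    mentions = []
    for e in aligned.events:
        d = aligned.docs[e]
        mentions.extend(detect_negation(d, tagger.tag(d), corpus.config.negation_cues))
    normalized, _ = normalize_corpus(
        filter_negated(mentions), (corpus.disease_dictionary, corpus.drug_dictionary)
    )
    linked_mo = link_mo_products(corpus.mo_records, corpus.drug_dictionary)
    return aligned, normalized, linked_mo, fa.build_event_entity_lists(
        aligned, normalized, linked_mo
    )


class TestSummarize:
    def test_hand_counted_single_event(self):
        lists = {"e1": [("a_surf", "A"), ("a_surf", "A"), ("b_surf", "B")]}
        r = fa.summarize(lists, "TEXT", "disease")
        assert r.total_entities == 3
        assert r.total_normalized == 3
        assert r.total_concepts == 2
        assert r.vocabulary_size == 2
        assert r.concepts_per_event.mean == 2.0

    def test_unlinked_entities_count_toward_entities_only(self):
        lists = {"e1": [("x", None), ("a", "A")]}
        r = fa.summarize(lists, "TEXT", "disease")
        assert (r.total_entities, r.total_normalized, r.total_concepts) == (2, 1, 1)
        assert r.normalized_rate == 0.5

    def test_events_without_entities_excluded_from_per_event_stats(self):
        lists = {"e1": [("a", "A")], "e2": []}
        r = fa.summarize(lists, "TEXT", "disease")
        assert r.total_events_with_entities == 1
        assert r.entities_per_event.mean == 1.0

    def test_empty_lists_report_null_stats(self):
        r = fa.summarize({}, "TEXT", "drug")
        assert r.total_entities == 0
        assert r.normalized_rate is None
        assert r.entities_per_event is None

    @pytest.mark.parametrize("seed", range(6))
    def test_reports_equal_brute_force_recount_on_random_corpora(self, seed):
        cfg = se.SynthConfig(
            seed=100 + seed,
            n_patients=12,
            p_negated=0.2,
            p_surface_perturb=0.15,
            p_out_of_dictionary=0.2,
        )
        corpus = se.generate_corpus(cfg)
        _, _, _, lists = _pipeline_lists(corpus)
        for (src, et), lst in lists.items():
            got = fa.summarize(lst, src, et).to_dict()
            want = recount_frequency(lst)
            for key, val in want.items():
                if isinstance(val, dict):
                    for stat, v in val.items():
                        assert got[key][stat] == pytest.approx(v), (src, et, key, stat)
                elif isinstance(val, float):
                    assert got[key] == pytest.approx(val), (src, et, key)
                else:
                    assert got[key] == val, (src, et, key)

    def test_concepts_normalized_entities_ordering_invariant(self, noisy_corpus):
        _, _, _, lists = _pipeline_lists(noisy_corpus)
        for (src, et), lst in lists.items():
            r = fa.summarize(lst, src, et)
            assert r.total_concepts <= r.total_normalized <= r.total_entities
            for occ in lst.values():
                linked = [c for _, c in occ if c is not None]
                assert len(set(linked)) <= len(linked) <= len(occ)

    def test_removing_an_event_never_increases_totals(self, clean_corpus):
        _, _, _, lists = _pipeline_lists(clean_corpus)
        lst = lists[("TEXT", "disease")]
        full = fa.summarize(lst, "TEXT", "disease")
        victim = next(iter(lst))
        reduced = fa.summarize({e: v for e, v in lst.items() if e != victim}, "TEXT", "disease")
        assert reduced.total_entities <= full.total_entities
        assert reduced.total_normalized <= full.total_normalized
        assert reduced.total_concepts <= full.total_concepts
        assert reduced.vocabulary_size <= full.vocabulary_size


class TestDpcListsAndCommon:
    def test_dpc_lists_are_fully_normalized(self, clean_corpus):
        _, _, _, lists = _pipeline_lists(clean_corpus)
        r = fa.summarize(lists[("TABLE_DPC", "disease")], "TABLE_DPC", "disease")
        assert r.total_normalized == r.total_entities > 0
        assert r.normalized_rate == 1.0

    def test_single_code_event_yields_one_element_list(self):
        from rwdtextminer.types import Document, DPCRecord

        rec = DPCRecord(event_id="e1", patient_id="p1", icd_codes=("C50",))
        doc = Document(doc_id="d1", event_id="e1", patient_id="p1", text="")
        aligned = ingest.align([rec], [], [doc])
        lists = fa.build_event_entity_lists(aligned, [], [])
        assert lists[("TABLE_DPC", "disease")]["e1"] == [("C50", "C50")]

    def test_common_counts_toy_vocabularies(self):
        a = {"e1": [("a", "A"), ("b", "B"), ("c", "C")]}
        b = {"e2": [("b", "B"), ("c", "C"), ("d", "D")]}
        assert fa.common_counts(a, b) == {"common_entities": 2, "common_concepts": 2}

    def test_common_counts_identical_and_disjoint(self):
        a = {"e1": [("a", "A"), ("b", None)]}
        assert fa.common_counts(a, a)["common_entities"] == 2
        assert fa.common_counts(a, {"e2": [("z", "Z")]}) == {
            "common_entities": 0,
            "common_concepts": 0,
        }


class TestTopK:
    def test_hand_ranked_toy_corpus(self):
        lists = {
            "e1": [("s1", "B"), ("s1", "B"), ("s2", "A")],
            "e2": [("s2", "A"), ("s3", "C"), ("x", None), ("s1", "B")],
        }
        rows = fa.top_k(lists, k=2, descriptions={"B": "concept b"})
        assert [(r.rank, r.concept_id, r.frequency) for r in rows] == [(1, "B", 3), (2, "A", 2)]
        assert rows[0].description == "concept b"

    def test_frequency_ties_break_by_concept_id(self):
        lists = {"e1": [("s", "B"), ("s", "A"), ("t", "B"), ("t", "A"), ("u", "C")]}
        rows = fa.top_k(lists, k=3)
        assert [r.concept_id for r in rows] == ["A", "B", "C"]
        assert [r.frequency for r in rows] == [2, 2, 1]

    def test_k_larger_than_concept_count_returns_all(self):
        lists = {"e1": [("s", "A")]}
        assert len(fa.top_k(lists, k=20)) == 1


class TestOriginRegression:
    def test_exact_fit_has_slope_two_and_unit_r2(self):
        reg = fa.origin_regression([1, 2, 3], [2, 4, 6])
        assert reg.slope == pytest.approx(2.0)
        assert reg.r2_uncentered == pytest.approx(1.0)
        assert reg.r2_centered == pytest.approx(1.0)

    def test_single_point_is_an_error(self):
        with pytest.raises(ValueError):
            fa.origin_regression([1.0], [2.0])

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            fa.origin_regression([0, 1], [1, 2])

    @given(st.integers(0, 2**31 - 1))
    def test_slope_equals_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        x = rng.uniform(0.5, 100, size=n)
        y = rng.uniform(0.5, 100, size=n)
        reg = fa.origin_regression(x, y)
        assert reg.slope == pytest.approx(float(np.sum(x * y) / np.sum(x * x)))
        assert reg.r2_uncentered <= 1.0

    def test_route_groups_fitted_separately(self, clean_corpus):
        _, _, linked_mo, lists = _pipeline_lists(clean_corpus)
        pairs = fa.medication_frequency_pairs(
            lists[("TEXT", "drug")], lists[("TABLE_MO", "drug")], linked_mo
        )
        assert not pairs.empty
        assert set(pairs["route"]).issubset({"oral", "injection"})
        fits = fa.origin_regression_by_route(pairs)
        for reg in fits.values():
            assert reg.n >= 2
            assert reg.slope > 0


class TestPrintedArithmetic:
    def test_normalized_rate_from_printed_totals(self):
        assert fa.normalized_entity_rate(8_614_858, 10_384_586) == pytest.approx(83.0, abs=0.05)

    def test_events_per_patient_from_printed_totals(self):
        assert fa.events_per_patient(138_656, 44_502) == pytest.approx(3.12, abs=0.005)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            fa.normalized_entity_rate(2, 0)
        with pytest.raises(ValueError):
            fa.normalized_entity_rate(3, 2)
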