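import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_force_link, lev_dp

from rwdtextminer import normalization as nz
from rwdtextminer import synthetic_ehr as se
from rwdtextminer.extraction import DictionaryTagger, detect_negation, filter_negated
from rwdtextminer.types import DictionaryEntry, EntityMention, MORecord


def _entry(surface, concept):
    return DictionaryEntry(surface=surface, concept_id=concept, concept_name=concept)


class TestNls:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("stomatitis", "stomatitis", 100.0),
            ("abcd", "abce", 75.0),  # lev 1 over max length 4
            ("ab", "cd", 0.0),  # lev 2 over max length 2
            ("stomatits", "stomatitis", 90.0),  # one deletion over length 10
        ],
    )
    def test_reference_scores(self, a, b, expected):
        assert nz.nls(a, b) == pytest.approx(expected)

    def test_empty_string_is_an_error(self):
        with pytest.raises(ValueError):
            nz.nls("", "abc")
        with pytest.raises(ValueError):
            nz.nls("abc", "   ")  # whitespace-only canonicalizes to empty

    def test_case_and_width_fold_before_scoring(self):
        assert nz.nls("DOCE", "doce") == 100.0
        assert nz.nls("ＤＯＣＥ", "doce") == 100.0

    @given(
        st.text(alphabet="abcdef", min_size=1, max_size=12),
        st.text(alphabet="abcdef", min_size=1, max_size=12),
    )
    def test_symmetry_bounds_and_identity(self, a, b):
        s = nz.nls(a, b)
        assert 0.0 <= s <= 100.0
        assert s == pytest.approx(nz.nls(b, a))
        assert nz.nls(a, a) == 100.0
        assert (s == 100.0) == (a == b)

    @given(
        st.text(alphabet="abcdef", min_size=1, max_size=10),
        st.text(alphabet="abcdef", min_size=1, max_size=10),
    )
    def test_edlib_distance_agrees_with_textbook_dp(self, a, b):
        assert nz.levenshtein(a, b) == lev_dp(a, b)


DICT = [
    _entry("stomatitis", "K120"),
    _entry("mucositis9", "K121"),
    _entry("sharedsurf", "K200"),
    _entry("sharedsurf", "K201"),
]


def _mention(surface, etype="disease"):
    return EntityMention("d1", "e1", 0, len(surface), surface, etype)


class TestLinkMention:
    def test_exact_surface_links_at_score_100(self):
        nm = nz.link_mention(_mention("stomatitis"), (DICT, [_entry("doce", "docetaxel")]))
        assert (nm.status, nm.concept_id, nm.score) == ("linked", "K120", 100.0)

    def test_one_edit_on_ten_chars_links_at_cutoff_70(self):
        nm = nz.link_mention(_mention("stomatits"), (DICT, [_entry("doce", "docetaxel")]))
        assert nm.status == "linked"
        assert nm.concept_id == "K120"
        assert nm.score == pytest.approx(90.0)

    def test_distant_surface_is_unlinked(self):
        nm = nz.link_mention(_mention("zzzz"), (DICT, [_entry("doce", "docetaxel")]))
        assert nm.status == "unlinked"
        assert nm.concept_id is None

    def test_top_tie_across_concepts_is_ambiguous_and_excluded(self):
        nm = nz.link_mention(_mention("sharedsurf"), (DICT, [_entry("doce", "docetaxel")]))
        assert nm.status == "ambiguous"
        assert nm.concept_id is None

    def test_tie_within_one_concept_is_harmless(self):
        entries = [_entry("abcdefghij", "K1"), _entry("abcdefghiz", "K1")]
        linker = nz.ConceptLinker(entries)
        concept, score, status = linker.link_surface("abcdefghix")
        assert (concept, status) == ("K1", "linked")
        assert score == pytest.approx(90.0)

    def test_empty_dictionary_is_an_error(self):
        with pytest.raises(ValueError):
            nz.ConceptLinker([])

    def test_raising_cutoff_never_increases_linked_count(self):
        rng = np.random.default_rng(5)
        cfg = se.SynthConfig(seed=5, n_disease_concepts=20)
        disease, _ = se.generate_dictionaries(cfg)
        surfaces = [se.perturb_surface(e.surface, rng) for e in disease for _ in range(3)]
        counts = []
        for cutoff in (50.0, 70.0, 90.0, 100.0):
            linker = nz.ConceptLinker(disease, cutoff)
            counts.append(
                sum(1 for s in surfaces if linker.link_surface(s)[2] == "linked")
            )
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        cfg = se.SynthConfig(seed=17, n_disease_concepts=40, surfaces_per_concept=2)
        disease, _ = se.generate_dictionaries(cfg)
        linker = nz.ConceptLinker(disease)
        for _ in range(50):
            base = disease[rng.integers(0, len(disease))].surface
            surface = base
            for _ in range(rng.integers(0, 3)):
                surface = se.perturb_surface(surface, rng)
            got = linker.link_surface(surface)
            concept, score, status, _winners = brute_force_link(surface, disease)
            assert got[0] == concept
            assert got[1] == pytest.approx(score)
            assert got[2] == status


class TestNormalizeCorpus:
    def test_zero_mentions_reports_null_rate(self):
        normalized, report = nz.normalize_corpus([], (DICT, [_entry("doce", "docetaxel")]))
        assert normalized == []
        assert report["disease"]["rate"] is None

    def test_all_exact_surfaces_give_rate_one(self, clean_corpus):
        tagger = DictionaryTagger(clean_corpus.disease_dictionary, clean_corpus.drug_dictionary)
        mentions = [m for d in clean_corpus.documents for m in tagger.tag(d)]
        _, report = nz.normalize_corpus(
            mentions, (clean_corpus.disease_dictionary, clean_corpus.drug_dictionary)
        )
        assert report["disease"]["rate"] == 1.0
        assert report["drug"]["rate"] == 1.0

    def test_statuses_partition_the_mentions(self, noisy_corpus):
        tagger = DictionaryTagger(noisy_corpus.disease_dictionary, noisy_corpus.drug_dictionary)
        mentions = [m for d in noisy_corpus.documents for m in tagger.tag(d)]
        normalized, _ = nz.normalize_corpus(
            mentions, (noisy_corpus.disease_dictionary, noisy_corpus.drug_dictionary)
        )
        assert len(normalized) == len(mentions)
        by_status = {s: sum(1 for n in normalized if n.status == s) for s in
                     ("linked", "unlinked", "ambiguous")}
        assert sum(by_status.values()) == len(mentions)

    def test_out_of_dictionary_rate_matches_planting_probability(self):
        # mentions come from ground truth (the ML-NER adapter path), so
        # out-of-dictionary plants are present but unlinkable
        p_ood = 0.4
        cfg = se.SynthConfig(seed=41, n_patients=40, p_out_of_dictionary=p_ood)
        corpus = se.generate_corpus(cfg)
        mentions = [
            EntityMention(m.doc_id, m.event_id, m.start, m.end, m.surface, m.entity_type)
            for m in corpus.ground_truth.mentions
        ]
        _, report = nz.normalize_corpus(
            mentions, (corpus.disease_dictionary, corpus.drug_dictionary)
        )
        total = sum(report[t]["total_entities"] for t in ("disease", "drug"))
        linked = sum(report[t]["total_normalized"] for t in ("disease", "drug"))
        rate = linked / total
        se_binom = (p_ood * (1 - p_ood) / total) ** 0.5
        assert abs(rate - (1 - p_ood)) < 4 * se_binom


class TestLinkMoProducts:
    DRUGS = [_entry("abcdefghij", "ing_a"), _entry("qrstuvwxyz", "ing_b")]

    def test_exact_product_name_links_to_its_ingredient(self):
        (lm,) = nz.link_mo_products(
            [MORecord(event_id="e1", product_name="abcdefghij", route="oral")], self.DRUGS
        )
        assert (lm.ingredient, lm.status) == ("ing_a", "linked")

    def test_one_edit_product_name_links_at_90(self):
        (lm,) = nz.link_mo_products(
            [MORecord(event_id="e1", product_name="abcdefghiX", route="oral")], self.DRUGS
        )
        assert lm.ingredient == "ing_a"
        assert lm.score == pytest.approx(90.0)

    def test_unlinked_products_are_counted_not_dropped(self):
        records = [
            MORecord(event_id="e1", product_name="abcdefghij", route="oral"),
            MORecord(event_id="e1", product_name="zzz", route="oral"),
        ]
        linked = nz.link_mo_products(records, self.DRUGS)
        assert len(linked) == 2
        assert [lm.status for lm in linked] == ["linked", "unlinked"]


def test_normalization_pipeline_ground_truth_on_clean_corpus(clean_corpus):
    """On a clean corpus the full extract -> negate -> filter -> link chain
    reproduces the planted concept multiset exactly."""
    tagger = DictionaryTagger(clean_corpus.disease_dictionary, clean_corpus.drug_dictionary)
    mentions = []
    for d in clean_corpus.documents:
        mentions.extend(detect_negation(d, tagger.tag(d), clean_corpus.config.negation_cues))
    positives = filter_negated(mentions)
    normalized, _ = nz.normalize_corpus(
        positives, (clean_corpus.disease_dictionary, clean_corpus.drug_dictionary)
    )
    got = sorted((n.mention.event_id, n.concept_id) for n in normalized)
    want = sorted(
        (m.event_id, m.true_concept_id)
        for m in clean_corpus.ground_truth.mentions
        if m.factuality == "positive"
    )
    assert got == want
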