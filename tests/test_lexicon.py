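"""Dictionary NER: normalization, matching, abbreviations, GO resolution,
conflict resolution, ensemble merging and gold-constrained lookup."""

import pytest
from hypothesis import given, settings, strategies as st

from belex.core import NamespaceId
from belex.fixtures import (
    WORKED_SENTENCES,
    dictionary_entries,
    gene_go_associations,
    go_parents,
    gold_entity_entries,
)
from belex.lexicon import (
    AcronymPair,
    DictionaryEntry,
    EntityMention,
    LexiconError,
    LexiconIndex,
    detect_acronyms,
    dictionary_lookup,
    edit_similarity,
    gold_constrained_lookup,
    infer_class_from_acronym,
    merge_ensemble,
    normalize_surface,
    propagate_class_by_similarity,
    resolve_cross_dictionary_conflict,
    resolve_go_term,
)

SENTENCES = dict(WORKED_SENTENCES)


class TestNormalizeSurface:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("bone morphogenetic protein-2", "bone morphogenetic protein 2"),
            ("ERK-1", "erk 1"),
            ("Erk1", "erk 1"),
            ("", ""),
            ("LPS/IFN-gamma", "lps ifn gamma"),
            ("  Two   Spaces ", "two spaces"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_surface(raw) == expected

    @settings(max_examples=300, derandomize=True)
    @given(st.text(max_size=40))
    def test_idempotent_on_random_strings(self, text):
        once = normalize_surface(text)
        assert normalize_surface(once) == once


class TestDictionaryLookup:
    def test_orthographic_variant_matches_via_normalization(self, dict_index):
        text = SENTENCES["W14"]
        mentions = dictionary_lookup(text, "W14", dict_index)
        bmp2 = [m for m in mentions if m.nsid == NamespaceId("HGNC", "BMP2")]
        assert len(bmp2) == 1
        assert bmp2[0].text == "bone morphogenetic protein-2"
        assert bmp2[0].semclass == "gene_protein"

    def test_no_dictionary_entry_no_mentions(self, dict_index):
        assert dictionary_lookup("the xyzzy frobnicator binds", "S", dict_index) == []

    def test_empty_dictionary_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="belex.lexicon"):
            out = dictionary_lookup("any sentence", "S", [])
        assert out == []
        assert any("empty" in r.message for r in caplog.records)

    def test_spans_reproduce_sentence_substrings(self, dict_index):
        for sid, text in WORKED_SENTENCES:
            for m in dictionary_lookup(text, sid, dict_index):
                assert text[m.start:m.end] == m.text

    def test_longest_match_no_proper_subspans_within_vocab(self, dict_index):
        for sid, text in WORKED_SENTENCES:
            mentions = dictionary_lookup(text, sid, dict_index)
            for a in mentions:
                for b in mentions:
                    if a is b or a.semclass != b.semclass:
                        continue
                    assert not (a.start >= b.start and a.end <= b.end and a != b)

    def test_token_alignment_blocks_partial_word_hits(self):
        entries = [DictionaryEntry("CAT", "HGNC", "CAT", "gene_protein", "Entrez")]
        assert dictionary_lookup("concatenation of files", "S", entries) == []


class TestAcronyms:
    def test_long_short_order(self):
        [pair] = detect_acronyms("vasoactive intestinal peptide (VIP) and others")
        assert pair.long_form == "vasoactive intestinal peptide"
        assert pair.short_form == "VIP"

    def test_short_long_order(self):
        [pair] = detect_acronyms(
            "the repressor ZEB (zinc finger E box binding protein) interacts"
        )
        assert pair.long_form == "zinc finger E box binding protein"
        assert pair.short_form == "ZEB"

    def test_alignment_failure_yields_no_pair(self):
        assert detect_acronyms("the cell (see Methods)") == []

    def test_short_form_must_be_shorter(self):
        with pytest.raises(LexiconError):
            AcronymPair("AR", (0, 2), "Aldose reductase", (4, 20))


class TestClassInference:
    def test_short_form_inherits_long_form_class(self):
        text = ("Aldose reductase (AR) converts glucose to sorbitol, and "
                "inhibition of the AR by tolrestat normalized the sorbitol levels.")
        long_start = text.index("Aldose reductase")
        donor = EntityMention(
            "W13", long_start, long_start + len("Aldose reductase"),
            "Aldose reductase", "gene_protein", NamespaceId("HGNC", "AKR1B1"),
        )
        pairs = detect_acronyms(text)
        out = infer_class_from_acronym(pairs, [donor], text, "W13")
        ars = [m for m in out if m.text == "AR"]
        assert len(ars) == 2  # parenthesized definition + "the AR"
        assert all(m.semclass == "gene_protein" for m in ars)
        assert all(m.nsid == NamespaceId("HGNC", "AKR1B1") for m in ars)
        assert all(m.match_kind == "inferred" for m in ars)

    def test_short_form_without_long_form_unchanged(self):
        text = "the AR was inhibited"
        assert infer_class_from_acronym([], [], text, "S") == []

    def test_every_later_occurrence_classed(self):
        text = "vasoactive intestinal peptide (VIP) rose; VIP binds; more VIP."
        donor = EntityMention(
            "S", 0, len("vasoactive intestinal peptide"),
            "vasoactive intestinal peptide", "gene_protein",
            NamespaceId("HGNC", "VIP"),
        )
        out = infer_class_from_acronym(detect_acronyms(text), [donor], text, "S")
        vips = [m for m in out if m.text == "VIP"]
        # enumerated by scanning: offsets of all three standalone "VIP" tokens
        assert [m.start for m in vips] == [31, 42, 58]


class TestSimilarityPropagation:
    def test_near_variant_gets_class_and_namespace(self, dict_index):
        classed = EntityMention(
            "W12", 0, 11, "Gi alpha(1)", "gene_protein", NamespaceId("HGNC", "GNAI1")
        )
        out = propagate_class_by_similarity(
            "Gi alpha(2)", (30, 41), "W12", [classed], dict_index.entries
        )
        assert out is not None
        assert out.semclass == "gene_protein"
        assert out.nsid == NamespaceId("HGNC", "GNAI2")

    def test_identical_candidate_same_class(self, dict_index):
        classed = EntityMention(
            "S", 0, 11, "Gi alpha(1)", "gene_protein", NamespaceId("HGNC", "GNAI1")
        )
        out = propagate_class_by_similarity(
            "Gi alpha(1)", (20, 31), "S", [classed], dict_index.entries
        )
        assert out is not None and out.semclass == "gene_protein"

    def test_dissimilar_candidate_rejected(self, dict_index):
        # oracle: normalized edit similarity of the two surfaces is far below
        # the 0.85 threshold
        assert edit_similarity("Gi alpha(2)", "interleukin 6") < 0.85
        classed = EntityMention(
            "S", 0, 13, "interleukin 6", "gene_protein", NamespaceId("HGNC", "IL6")
        )
        out = propagate_class_by_similarity(
            "Gi alpha(2)", (20, 31), "S", [classed], dict_index.entries
        )
        assert out is None


class TestGoResolution:
    def setup_method(self):
        self.parent = NamespaceId("GOBP", "response to ionizing radiation")
        self.child = NamespaceId("GOBP", "cellular response to ionizing radiation")
        self.parents = go_parents()
        self.assoc = gene_go_associations()

    def test_gene_association_prefers_the_parent(self):
        out = resolve_go_term(
            "ionizing radiation", [self.parent, self.child],
            [NamespaceId("HGNC", "JUN")], self.assoc, self.parents,
        )
        assert out == self.parent

    def test_without_context_most_specific_wins(self):
        out = resolve_go_term(
            "ionizing radiation", [self.parent, self.child], [], [], self.parents
        )
        assert out == self.child

    def test_single_candidate_returned(self):
        out = resolve_go_term("x", [self.parent], [], [], {})
        assert out == self.parent


class TestConflictResolution:
    def _mesh(self, kind="exact"):
        return EntityMention(
            "W08", 0, 16, "oxidative stress", "disease",
            NamespaceId("MESHD", "Oxidative Stress"), "internal", kind,
        )

    def _go(self, kind="fuzzy", source="internal"):
        return EntityMention(
            "W08", 0, 16, "oxidative stress", "bioprocess",
            NamespaceId("GOBP", "response to oxidative stress"), source, kind,
        )

    def test_exact_beats_partial_in_phase1(self):
        winner = resolve_cross_dictionary_conflict(
            "oxidative stress", [self._go(), self._mesh()], "phase1"
        )
        assert winner.semclass == "disease"

    def test_gold_beats_ordinary_in_phase2(self):
        winner = resolve_cross_dictionary_conflict(
            "oxidative stress", [self._mesh(), self._go(kind="exact", source="gold")],
            "phase2_gold",
        )
        assert winner.semclass == "bioprocess"
        assert winner.nsid.value == "response to oxidative stress"

    def test_single_match_passes_through(self):
        m = self._mesh()
        assert resolve_cross_dictionary_conflict("x", [m], "phase1") is m

    def test_two_exact_matches_use_class_priority(self):
        winner = resolve_cross_dictionary_conflict(
            "oxidative stress", [self._go(kind="exact"), self._mesh()], "phase1"
        )
        assert winner.semclass == "disease"  # disease > bioprocess


def _m(sid, start, end, text, semclass, ns=None, source="internal", kind="exact"):
    return EntityMention(sid, start, end, text, semclass, ns, source, kind)


class TestEnsembleMerging:
    def test_pubtator_wins_over_shorter_becas_span(self):
        pub = _m("S", 0, 11, "Gi alpha(1)", "gene_protein",
                 NamespaceId("HGNC", "GNAI1"), "pubtator")
        bec = _m("S", 0, 8, "Gi alpha", "gene_protein", None, "becas")
        out = merge_ensemble({"pubtator": [pub], "becas": [bec], "internal": []})
        assert out == [pub]

    def test_becas_internal_consensus_accepted(self):
        bec = _m("S", 10, 19, "tolrestat", "chemical",
                 NamespaceId("CHEBI", "tolrestat"), "becas")
        intl = _m("S", 10, 19, "tolrestat", "chemical",
                  NamespaceId("CHEBI", "tolrestat"), "internal")
        out = merge_ensemble({"becas": [bec], "internal": [intl]})
        assert len(out) == 1 and out[0].semclass == "chemical"

    def test_internal_exact_match_alone_accepted(self):
        intl = _m("S", 0, 28, "bone morphogenetic protein-2", "gene_protein",
                  NamespaceId("HGNC", "BMP2"))
        out = merge_ensemble({"internal": [intl]})
        assert out == [intl]

    def test_internal_fuzzy_alone_rejected_for_gcd_classes(self):
        intl = _m("S", 0, 9, "tolrestat", "chemical",
                  NamespaceId("CHEBI", "tolrestat"), kind="fuzzy")
        assert merge_ensemble({"internal": [intl]}) == []

    def test_go_terms_becas_first_supplemented_by_internal(self):
        bec = _m("S", 0, 11, "mitogenesis", "bioprocess",
                 NamespaceId("GOBP", "positive regulation of cell proliferation"),
                 "becas")
        intl = _m("S", 20, 29, "apoptosis", "bioprocess",
                  NamespaceId("GOBP", "apoptotic process"))
        out = merge_ensemble({"becas": [bec], "internal": [intl]})
        assert {m.nsid.value for m in out} \
            == {"positive regulation of cell proliferation", "apoptotic process"}

    def test_no_same_class_overlaps_in_merged_output(self):
        pub = _m("S", 0, 11, "Gi alpha(1)", "gene_protein",
                 NamespaceId("HGNC", "GNAI1"), "pubtator")
        intl = _m("S", 3, 11, "alpha(1)", "gene_protein",
                  NamespaceId("HGNC", "GNAI1"))
        out = merge_ensemble({"pubtator": [pub], "internal": [intl]})
        for a in out:
            for b in out:
                assert a is b or not (a.overlaps(b) and a.semclass == b.semclass)


class TestGoldConstrainedLookup:
    def test_gold_span_replaces_conflicting_ensemble_mention(self):
        text = SENTENCES["W10"]
        cal_start = text.index("calcium")
        ensemble = [
            _m("W10", cal_start, cal_start + 7, "calcium", "chemical",
               NamespaceId("CHEBI", "calcium"), "pubtator"),
        ]
        out = gold_constrained_lookup(text, "W10", gold_entity_entries(), ensemble)
        cal = [m for m in out if "calcium" in m.text.lower()]
        assert len(cal) == 1
        assert cal[0].text == "calcium ionophore"
        assert cal[0].nsid == NamespaceId("CHEBI", "Calcium ionophore")

    def test_gold_go_dictionary_renormalizes_mitogenesis(self):
        text = SENTENCES["W11"]
        out = gold_constrained_lookup(text, "W11", gold_entity_entries())
        mito = [m for m in out if m.text == "mitogenesis"]
        assert mito and mito[0].nsid == NamespaceId("GOBP", "mitosis")

    def test_empty_gold_set_restricts_to_nothing(self):
        assert gold_constrained_lookup("any text", "S", []) == []

    def test_all_gold_mentions_come_from_gold_list(self):
        gold = gold_entity_entries()
        allowed = {(e.namespace, e.identifier) for e in gold}
        for sid, text in WORKED_SENTENCES:
            for m in gold_constrained_lookup(text, sid, gold):
                assert (m.nsid.namespace, m.nsid.value) in allowed
                assert m.source == "gold"


@pytest.fixture(scope="module")
def dict_index():
    return LexiconIndex(dictionary_entries())
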