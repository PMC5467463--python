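"""Shallow semantic parser: tagging, chunking, masking and the event rules."""

import pytest

from belex.core import NamespaceId
from belex.fixtures import WORKED_SENTENCES, dictionary_entries
from belex.lexicon import LexiconIndex, dictionary_lookup
from belex.parser import (
    EventFrame,
    EntityMention,
    apply_binding_rule,
    apply_regulation_rule,
    apply_transport_rule,
    build_elements,
    chunk,
    default_lexicon,
    distribute_coordination,
    link_cross_clausal,
    mask_appositions,
    parse_events,
    tokenize_and_tag,
)

SENTENCES = dict(WORKED_SENTENCES)


@pytest.fixture(scope="module")
def index():
    return LexiconIndex(dictionary_entries())


def mentions_of(text, index, sid="S"):
    return dictionary_lookup(text, sid, index)


def elements_of(text, index):
    mentions = mentions_of(text, index)
    tokens = tokenize_and_tag(text)
    return build_elements(chunk(tokens), mentions), mentions


def frames_of(text, index):
    return parse_events(text, mentions_of(text, index))[0]


def entity_args(frame, role="Theme"):
    return [v.nsid.value for r, v in frame.args
            if r == role and isinstance(v, EntityMention)]


class TestTokenizeAndTag:
    def test_verb_tagged_in_simple_clause(self):
        tokens = tokenize_and_tag("FoxO1 protects beta cells")
        assert [t.text for t in tokens] == ["FoxO1", "protects", "beta", "cells"]
        assert tokens[1].tag == "VB"

    def test_empty_sentence(self):
        assert tokenize_and_tag("") == []

    def test_hyphenated_verb_kept_intact(self):
        tokens = tokenize_and_tag("they down-regulate it")
        downreg = [t for t in tokens if t.text == "down-regulate"]
        assert len(downreg) == 1 and downreg[0].tag == "VB"
        assert downreg[0].lemma == "down-regulate"

    def test_all_caps_symbol_not_closed_class(self):
        # "NO" (nitric oxide) must stay a noun, unlike the particle "no"
        tokens = tokenize_and_tag("inducible NO synthase")
        assert [t.tag for t in tokens] == ["NN", "NN", "NN"]


class TestChunking:
    def test_nominal_pp_bracketing(self, index):
        elements, _ = elements_of("interaction of cyclin A1 with E2F-1", index)
        assert [(e.kind, e.chunk.text) for e in elements] == [
            ("NP", "interaction"),
            ("PP", "of cyclin A1"),
            ("PP", "with E2F-1"),
        ]

    def test_single_noun_sentence_is_one_np(self, index):
        elements, _ = elements_of("apoptosis", index)
        assert [e.kind for e in elements] == ["NP"]

    def test_passive_verb_group(self, index):
        elements, _ = elements_of("is cleaved by CPP32", index)
        assert elements[0].kind == "VP"
        assert elements[0].passive is True
        assert elements[1].kind == "PP" and elements[1].prep == "by"


class TestMaskAppositions:
    def test_worked_simplification(self, index):
        text = SENTENCES["W01"]
        res = mask_appositions(text, mentions_of(text, index, "W01"))
        assert res.text == (
            "The VIP and the PACAP down-regulate IL-12 p40 and inducible NO "
            "synthase expression in LPS/IFN-gamma-stimulated macrophages."
        )
        # abbreviations retained as mentions
        kept = {m.text for m in res.mentions}
        assert {"VIP", "PACAP", "IL-12 p40", "inducible NO synthase"} <= kept

    def test_sentence_without_commas_unchanged(self, index):
        text = "Insulin enhances glycerol kinase enzymatic activity."
        res = mask_appositions(text, mentions_of(text, index))
        assert res.text == text

    def test_idempotent(self, index):
        text = SENTENCES["W01"]
        res = mask_appositions(text, mentions_of(text, index, "W01"))
        again = mask_appositions(res.text, res.mentions)
        assert again.text == res.text
        assert [m.span for m in again.mentions] == [m.span for m in res.mentions]

    def test_offset_map_projects_back_to_raw(self, index):
        text = SENTENCES["W01"]
        res = mask_appositions(text, mentions_of(text, index, "W01"))
        for m in res.mentions:
            raw_span = res.project(m.span)
            assert text[raw_span[0]:raw_span[1]] == m.text

    def test_mentions_outside_mask_preserved(self, index):
        text = SENTENCES["W02"]
        before = mentions_of(text, index, "W02")
        res = mask_appositions(text, before)
        projected = {text[res.project(m.span)[0]:res.project(m.span)[1]]
                     for m in res.mentions}
        assert projected == {m.text for m in before}


class TestBindingRule:
    def test_nominal_of_with_pattern(self, index):
        frames = frames_of("the interaction of cyclin A1 with E2F-1 in vitro", index)
        binding = [f for f in frames if f.category == "BindingEvent"]
        assert len(binding) == 1
        assert sorted(entity_args(binding[0])) == ["CCNA1", "E2F1"]

    def test_passive_complexed_with(self, index):
        frames = frames_of("cyclin A1 was complexed with CDK2", index)
        [binding] = [f for f in frames if f.category == "BindingEvent"]
        assert sorted(entity_args(binding)) == ["CCNA1", "CDK2"]

    def test_coordinated_subjects_of_interact(self, index):
        text = "Tip60 and the transcriptional repressor ZEB interact in cells"
        frames = frames_of(text, index)
        [binding] = [f for f in frames if f.category == "BindingEvent"]
        assert sorted(entity_args(binding)) == ["KAT5", "ZEB1"]

    def test_fewer_than_two_themes_no_frame(self, index):
        elements, _ = elements_of("the interaction of cyclin A1", index)
        assert apply_binding_rule(elements) == []


class TestTransportRule:
    def test_bare_translocation_nominal(self, index):
        frames = frames_of("translocation of HSF1 was observed", index)
        [transport] = [f for f in frames if f.category == "TransportEvent"]
        assert entity_args(transport) == ["HSF1"]

    def test_source_and_destination_locations(self, index):
        frames = frames_of(
            "translocation of HSF1 from the cytoplasm to the nucleus", index
        )
        [transport] = [f for f in frames if f.category == "TransportEvent"]
        assert entity_args(transport) == ["HSF1"]
        assert entity_args(transport, "SourceLoc") == ["cytoplasm"]
        assert entity_args(transport, "DestLoc") == ["nucleus"]

    def test_no_trigger_no_frame(self, index):
        elements, _ = elements_of("HSF1 binds DNA", index)
        assert apply_transport_rule(elements) == []


class TestRegulationRule:
    def test_active_voice_agent_theme(self, index):
        frames = frames_of("FcgammaRIIB can suppress inflammation", index)
        [f] = [f for f in frames if f.category == "NegativeRegulation"]
        assert entity_args(f, "Agent") == ["FCGR2B"]
        assert entity_args(f, "Theme") == ["Inflammation"]

    def test_passive_voice_swaps_roles(self, index):
        frames = frames_of("gamma-PAK is cleaved by CPP32", index)
        [f] = [f for f in frames if f.category == "Cleavage"]
        assert entity_args(f, "Agent") == ["CASP3"]
        assert entity_args(f, "Theme") == ["PAK2"]

    def test_subjectless_verb_yields_agentless_frame(self, index):
        frames = frames_of("and activates STAT3", index)
        [f] = [f for f in frames if f.category == "PositiveRegulation"]
        assert f.agents == []
        assert entity_args(f, "Theme") == ["STAT3"]

    def test_directly_adverb_sets_direct_flag(self, index):
        frames = frames_of("Insulin directly induces obesity", index)
        [f] = [f for f in frames if f.category == "PositiveRegulation"]
        assert f.direct is True

    def test_surface_negation_flag_recorded(self, index):
        frames = frames_of("Insulin does not suppress inflammation", index)
        negs = [f for f in frames if f.category == "NegativeRegulation"]
        assert negs and negs[0].negated is True

    def test_nominal_inhibition_of_by(self, index):
        frames = frames_of("inhibition of PDE3B by tolrestat", index)
        [f] = [f for f in frames if f.category == "NegativeRegulation"]
        assert entity_args(f, "Agent") == ["tolrestat"]
        assert entity_args(f, "Theme") == ["PDE3B"]


class TestCoordination:
    def test_two_by_two_distribution(self, index):
        text = SENTENCES["W01"]
        frames = parse_events(text, mentions_of(text, index, "W01"))[0]
        regs = [f for f in frames if f.category == "NegativeRegulation"]
        assert len(regs) == 4
        pairs = set()
        for f in regs:
            [agent] = entity_args(f, "Agent")
            theme = f.themes[0]
            theme_id = (theme.nsid.value if isinstance(theme, EntityMention)
                        else theme.themes[0].nsid.value)
            pairs.add((agent, theme_id))
        assert pairs == {
            ("VIP", "IL12B"), ("VIP", "NOS2"),
            ("ADCYAP1", "IL12B"), ("ADCYAP1", "NOS2"),
        }

    def test_shared_agent_over_coordinated_objects(self, index):
        text = SENTENCES["W02"]
        frames = parse_events(text, mentions_of(text, index, "W02"))[0]
        regs = [f for f in frames if f.category == "NegativeRegulation"]
        assert len(regs) == 2
        assert all(entity_args(f, "Agent") == ["FCGR2B"] for f in regs)
        themes = {entity_args(f, "Theme")[0] for f in regs}
        assert themes == {"Inflammation", "Autoimmune Diseases"}

    def test_event_inherited_as_subject(self, index):
        text = SENTENCES["W03"]
        frames = parse_events(text, mentions_of(text, index, "W03"))[0]
        regs = [f for f in frames if f.category == "NegativeRegulation"]
        assert len(regs) == 1
        [agent] = regs[0].agents
        assert isinstance(agent, EventFrame)
        assert agent.category == "BindingEvent"
        assert sorted(entity_args(agent)) == ["KAT5", "ZEB1"]

    def test_distribution_never_reduces_frame_count(self, index):
        for sid, text in WORKED_SENTENCES:
            mentions = mentions_of(text, index, sid)
            masked = mask_appositions(text, mentions)
            tokens = tokenize_and_tag(masked.text)
            elements = build_elements(chunk(tokens), masked.mentions)
            pre = apply_binding_rule(elements) + apply_transport_rule(elements)
            pre = pre + apply_regulation_rule(elements, masked.mentions, pre)
            assert len(distribute_coordination(pre)) >= len(pre)


class TestCrossClausalLinking:
    def test_composite_rule_binding_regulates_transport(self, index):
        text = ("The interaction of cyclin A1 with E2F-1 inhibits the "
                "translocation of HSF1 from the cytoplasm to the nucleus.")
        frames = frames_of(text, index)
        regs = [f for f in frames if f.category == "NegativeRegulation"]
        assert len(regs) == 1
        [agent] = regs[0].agents
        [theme] = regs[0].themes
        assert agent.category == "BindingEvent"
        assert theme.category == "TransportEvent"
        # consumed component frames lose top-level status
        assert not any(f.category == "BindingEvent" for f in frames)
        assert not any(f.category == "TransportEvent" for f in frames)

    def test_single_frame_sentence_unchanged(self, index):
        frames = frames_of("Insulin induces obesity", index)
        assert len(frames) == 1
        assert link_cross_clausal(frames) == frames

    def test_no_dangling_frame_arguments(self, index):
        for sid, text in WORKED_SENTENCES:
            mentions = mentions_of(text, index, sid)
            frames, masked = parse_events(text, mentions)
            mention_spans = {m.span for m in masked.mentions}

            def check(frame):
                for _, v in frame.args:
                    if isinstance(v, EventFrame):
                        check(v)
                    else:
                        assert v.span in mention_spans
            for f in frames:
                check(f)

    def test_rule_application_is_deterministic(self, index):
        for sid, text in WORKED_SENTENCES:
            a = parse_events(text, mentions_of(text, index, sid))[0]
            b = parse_events(text, mentions_of(text, index, sid))[0]
            assert [(f.trigger_lemma, f.category, f.rule_id) for f in a] \
                == [(f.trigger_lemma, f.category, f.rule_id) for f in b]
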