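"""Frame-based shallow semantic parser.

The parser is deliberately shallow: a deterministic tokenizer and closed-class
POS tagger feed a declarative chunk grammar (base NPs, verb groups, PPs), and
frame rules walk the linear chunk sequence. Recursion enters only through the
constructions the rules handle explicitly: appositive masking, coordination
(entity and clausal), nominalized event triggers, passive voice, hyphenated
participle compounds (``X-induced Y``) and event-as-subject linking across
clausal boundaries.

Rule priority is fixed (binding, transport, regulation, coordination
distribution, cross-clausal linking) so repeated runs produce identical frame
sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .lexicon import AcronymPair, EntityMention, detect_acronyms, _PAREN

log = logging.getLogger(__name__)

REGULATION_CATEGORIES = frozenset({"PositiveRegulation", "NegativeRegulation", "Cleavage"})
#: event categories that take precedence over bare entities when filling a slot
EVENT_SLOT_CATEGORIES = frozenset(
    {"BindingEvent", "TransportEvent", "Phosphorylation", "Expression", "Activity", "Generic"}
)

_THEME_PREPS = frozenset({"of", "between", "with"})
_NEGATION_WORDS = frozenset({"not", "never", "no"})


class ParserError(Exception):
    pass


# ---------------------------------------------------------------------------
# Verb lexicon

@dataclass(frozen=True)
class VerbLexiconEntry:
    """A trigger lemma with its inflections, semantic category and polarity."""

    lemma: str
    inflections: frozenset
    category: str
    polarity: int
    nominal_forms: frozenset = frozenset()

    def __post_init__(self):
        if self.category in ("NegativeRegulation", "Cleavage") and self.polarity != -1:
            raise ParserError(f"{self.lemma}: {self.category} requires polarity -1")
        if self.category == "PositiveRegulation" and self.polarity != 1:
            raise ParserError(f"{self.lemma}: PositiveRegulation requires polarity +1")
        if self.category not in REGULATION_CATEGORIES and self.polarity != 0:
            raise ParserError(f"{self.lemma}: non-causal category requires polarity 0")


class VerbLexicon:
    """Form -> entry maps for verbal inflections and nominal trigger forms."""

    def __init__(self, entries: Sequence[VerbLexiconEntry]):
        self.entries = list(entries)
        self.verbal: Dict[str, VerbLexiconEntry] = {}
        self.nominal: Dict[str, VerbLexiconEntry] = {}
        for e in self.entries:
            if e.inflections or e.lemma not in e.nominal_forms:
                self.verbal.setdefault(e.lemma, e)
            for form in e.inflections:
                self.verbal.setdefault(form, e)
            for form in e.nominal_forms:
                self.nominal.setdefault(form, e)
        # a lemma listed only as nominal (e.g. "activity") is not a verb form
        for e in self.entries:
            if not e.inflections and e.lemma in e.nominal_forms:
                self.verbal.pop(e.lemma, None)

    @classmethod
    def load(cls, path=None) -> "VerbLexicon":
        if path is None:
            path = importlib_resources.files("belex.resources") / "verb_lexicon.tsv"
        entries = []
        with open(str(path), encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("lemma\t"):
                    continue
                cols = line.split("\t")
                lemma = cols[0]
                inflections = frozenset(f for f in cols[1].split(",") if f) if len(cols) > 1 else frozenset()
                category = cols[2] if len(cols) > 2 else "Generic"
                polarity = int(cols[3]) if len(cols) > 3 and cols[3] else 0
                nominal = frozenset(f for f in cols[4].split(",") if f) if len(cols) > 4 else frozenset()
                entries.append(VerbLexiconEntry(lemma, inflections, category, polarity, nominal))
        return cls(entries)


_DEFAULT_LEXICON: Optional[VerbLexicon] = None


def default_lexicon() -> VerbLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = VerbLexicon.load()
    return _DEFAULT_LEXICON


# ---------------------------------------------------------------------------
# Tokenizer and POS tagger

@dataclass(frozen=True)
class Token:
    text: str
    lemma: str
    tag: str
    start: int
    end: int


_WORD = re.compile(r"\w+(?:[-/]\w+|\(\w+\))*|[^\w\s]")

_CLOSED = {
    "DT": {"the", "a", "an", "this", "these", "those", "both", "all", "each",
           "such", "its", "their", "our", "some", "any"},
    "IN": {"of", "in", "on", "by", "with", "from", "to", "upon", "against",
           "between", "for", "into", "through", "at", "as", "via", "during",
           "within", "without", "after", "before", "under", "over", "toward", "towards"},
    "CC": {"and", "or", "but", "nor"},
    "MD": {"can", "could", "may", "might", "must", "shall", "should", "will", "would"},
    "BE": {"is", "are", "was", "were", "be", "been", "being", "am"},
    "WDT": {"that", "which", "who", "whom", "whose"},
    "RB": {"not", "never", "also", "more", "most", "only", "very", "no"},
    "CD": {"one", "two", "three", "four", "five", "six", "seven", "eight", "nine", "ten"},
}
_CLOSED_LOOKUP = {w: tag for tag, words in _CLOSED.items() for w in words}

_PAST_SUFFIX = ("ed",)
_IRREGULAR_PAST = {"bound"}


def _closed_class_tag(text: str) -> Optional[str]:
    # only all-lowercase or capitalized-initial words can be closed class, so
    # all-caps symbols like "NO" (nitric oxide) stay nouns
    if not text.isalpha():
        return None
    if text.islower() or (text[0].isupper() and text[1:].islower()):
        return _CLOSED_LOOKUP.get(text.lower())
    return None


def tokenize_and_tag(sentence: str, lexicon: Optional[VerbLexicon] = None) -> List[Token]:
    """Deterministic tokenization and POS tagging.

    Hyphenated compounds are kept as single tokens (``down-regulate`` stays a
    verb; ``methionine-induced`` becomes an adjectival participle compound);
    parenthesized material is kept as tokens.
    """
    lexicon = lexicon or default_lexicon()
    tokens = []
    for m in _WORD.finditer(sentence):
        text = m.group()
        lower = text.lower()
        lemma = lower
        tag = _closed_class_tag(text)
        if tag is None:
            if not any(c.isalnum() for c in text):
                tag = "PUNCT"
            elif lower in lexicon.verbal:
                entry = lexicon.verbal[lower]
                lemma = entry.lemma
                tag = "VBN" if (lower.endswith(_PAST_SUFFIX) or lower in _IRREGULAR_PAST) else "VB"
            elif ("-" in text or "/" in text) and lower.rsplit("-", 1)[-1] in lexicon.verbal:
                tag = "JJ"  # participle compound: "LPS/IFN-gamma-stimulated"
            elif lower in lexicon.nominal:
                lemma = lexicon.nominal[lower].lemma
                tag = "NN"
            elif re.fullmatch(r"\d+(?:[.,]\d+)*", text):
                tag = "CD"
            elif lower.endswith("ly") and len(lower) > 4:
                tag = "RB"
            else:
                tag = "NN"
        tokens.append(Token(text, lemma, tag, m.start(), m.end()))
    return tokens


# ---------------------------------------------------------------------------
# Chunk grammar

@dataclass
class Chunk:
    """A base chunk over a contiguous token run; ``head`` indexes ``tokens``."""

    kind: str
    tokens: List[Token]
    head: int = -1

    @property
    def start(self) -> int:
        return self.tokens[0].start

    @property
    def end(self) -> int:
        return self.tokens[-1].end

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)


_PATTERN_TOKEN = re.compile(r"[A-Z]+|\(|\)|\||\?|\*|\+")


class ChunkGrammar:
    """Named tag patterns, one rule per line, compiled to regexes over the
    space-joined tag stream. Rules are tried in file order; longest match wins
    within a rule."""

    def __init__(self, rules: Sequence[Tuple[str, str]]):
        self.rules = []
        for name, pattern in rules:
            parts = []
            for tok in _PATTERN_TOKEN.findall(pattern):
                if tok == "(":
                    parts.append("(?:")
                elif tok in (")", "|", "?", "*", "+"):
                    parts.append(tok)
                else:
                    parts.append(f"(?:{tok} )")
            self.rules.append((name, re.compile("".join(parts))))

    @classmethod
    def load(cls, path=None) -> "ChunkGrammar":
        if path is None:
            path = importlib_resources.files("belex.resources") / "chunk_grammar.txt"
        rules = []
        with open(str(path), encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, _, pattern = line.partition(":")
                rules.append((name.strip(), pattern.strip()))
        return cls(rules)


_DEFAULT_GRAMMAR: Optional[ChunkGrammar] = None


def default_grammar() -> ChunkGrammar:
    global _DEFAULT_GRAMMAR
    if _DEFAULT_GRAMMAR is None:
        _DEFAULT_GRAMMAR = ChunkGrammar.load()
    return _DEFAULT_GRAMMAR


def chunk(tokens: Sequence[Token], grammar: Optional[ChunkGrammar] = None) -> List[Chunk]:
    """Chunk tagged tokens into maximal base NPs, verb groups and copulas.

    Tokens not absorbed by any rule become singleton ``TOK`` chunks, so the
    output covers the sentence. PP structure (preposition + NP) is attached in
    :func:`build_elements`.
    """
    grammar = grammar or default_grammar()
    tag_stream = "".join(t.tag + " " for t in tokens)
    starts = []
    pos = 0
    for t in tokens:
        starts.append(pos)
        pos += len(t.tag) + 1
    start_to_index = {s: i for i, s in enumerate(starts)}
    chunks: List[Chunk] = []
    i = 0
    while i < len(tokens):
        matched = False
        for name, rx in grammar.rules:
            m = rx.match(tag_stream, starts[i])
            if m and m.end() > m.start():
                n_tokens = start_to_index.get(m.end(), len(tokens)) - i
                toks = list(tokens[i: i + n_tokens])
                head = len(toks) - 1
                if name == "NP":
                    for j in range(len(toks) - 1, -1, -1):
                        if toks[j].tag in ("NN", "CD"):
                            head = j
                            break
                chunks.append(Chunk(name, toks, head))
                i += n_tokens
                matched = True
                break
        if not matched:
            chunks.append(Chunk("TOK", [tokens[i]]))
            i += 1
    return chunks


# ---------------------------------------------------------------------------
# Elements: chunks with PP attachment and aligned entity mentions

@dataclass
class Element:
    kind: str  # NP | VP | PP | COP | TOK
    chunk: Chunk
    prep: Optional[str] = None            # PP: preposition lemma
    inner: Optional[Chunk] = None         # PP: the governed NP
    mentions: List[EntityMention] = field(default_factory=list)
    passive: bool = False                 # VP
    entry: Optional[VerbLexiconEntry] = None  # VP: main verb lexicon entry
    verb_token: Optional[Token] = None

    @property
    def span(self) -> Tuple[int, int]:
        return self.chunk.span

    @property
    def tag(self) -> str:
        return self.chunk.tokens[0].tag


def build_elements(
    chunks: Sequence[Chunk],
    mentions: Sequence[EntityMention],
    lexicon: Optional[VerbLexicon] = None,
) -> List[Element]:
    """Assemble the element sequence: PPs from IN+NP, verb-group analysis,
    and mention alignment (a mention aligns to every element it overlaps)."""
    lexicon = lexicon or default_lexicon()
    elements: List[Element] = []
    i = 0
    while i < len(chunks):
        ch = chunks[i]
        if ch.kind == "TOK" and ch.tokens[0].tag == "IN" and i + 1 < len(chunks) \
                and chunks[i + 1].kind == "NP":
            np = chunks[i + 1]
            merged = Chunk("PP", ch.tokens + np.tokens, 0)
            elements.append(Element("PP", merged, prep=ch.tokens[0].lemma, inner=np))
            i += 2
            continue
        el = Element(ch.kind if ch.kind in ("NP", "VP", "COP") else "TOK", ch)
        if ch.kind == "VP":
            has_be = any(t.tag == "BE" for t in ch.tokens)
            verb_tokens = [t for t in ch.tokens if t.tag in ("VB", "VBN")]
            main = verb_tokens[-1] if verb_tokens else None
            el.verb_token = main
            el.entry = lexicon.verbal.get(main.lemma) if main else None
            if el.entry is None and main is not None:
                el.entry = lexicon.verbal.get(main.text.lower())
            el.passive = bool(has_be and main is not None and main.tag == "VBN")
        elements.append(el)
        i += 1
    for m in mentions:
        for el in elements:
            if m.start < el.span[1] and el.span[0] < m.end:
                el.mentions.append(m)
    for el in elements:
        el.mentions.sort(key=lambda m: (m.start, -(m.end - m.start)))
    return elements


# ---------------------------------------------------------------------------
# Apposition masking / text simplification

@dataclass
class MaskResult:
    """A simplified sentence with remapped mentions and an offset map back to
    the raw sentence (``raw_pos[i]`` is the raw index of simplified char i)."""

    text: str
    mentions: List[EntityMention]
    raw_pos: List[int]

    def project(self, span: Tuple[int, int]) -> Tuple[int, int]:
        """Project a simplified-sentence span back onto the raw sentence."""
        s, e = span
        if e <= s:
            return (self.raw_pos[s] if s < len(self.raw_pos) else len(self.raw_pos), ) * 2
        return (self.raw_pos[s], self.raw_pos[e - 1] + 1)


def _apply_removals(text: str, removals: Sequence[Tuple[int, int]], raw_pos: Sequence[int]):
    if not removals:
        return text, list(raw_pos)
    merged: List[List[int]] = []
    for s, e in sorted(removals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    pos = []
    prev = 0
    for s, e in merged:
        out.append(text[prev:s])
        pos.extend(raw_pos[prev:s])
        prev = e
    out.append(text[prev:])
    pos.extend(raw_pos[prev:])
    new_text = "".join(out)
    # collapse doubled spaces introduced by removal
    collapsed = []
    cpos = []
    for i, ch in enumerate(new_text):
        if ch == " " and collapsed and collapsed[-1] == " ":
            continue
        collapsed.append(ch)
        cpos.append(pos[i])
    return "".join(collapsed), cpos


def _remap_mentions(mentions, old_pos, new_pos):
    raw_to_new = {raw: i for i, raw in enumerate(new_pos)}
    out = []
    for m in mentions:
        raws = old_pos[m.start: m.end]
        new_idx = [raw_to_new.get(r) for r in raws]
        if any(i is None for i in new_idx) or not new_idx:
            continue  # inside a masked region
        out.append(replace(m, start=new_idx[0], end=new_idx[-1] + 1))
    return out


def mask_appositions(
    sentence: str,
    mentions: Sequence[EntityMention],
    lexicon: Optional[VerbLexicon] = None,
) -> MaskResult:
    """Simplify a sentence before rule application. Three masks, in order:

    1. abbreviation definitions collapse to the short form
       (``vasoactive intestinal peptide (VIP)`` -> ``VIP``);
    2. parenthesized alias lists right after an entity mention are removed;
    3. comma-flanked appositive NPs following an entity-bearing NP are removed
       when not introduced by a coordinating conjunction and mention-free.

    Idempotent; the offset map projects spans back to the raw sentence.
    """
    lexicon = lexicon or default_lexicon()
    raw_pos = list(range(len(sentence)))
    removals: List[Tuple[int, int]] = []
    for pair in detect_acronyms(sentence):
        (ls, le), (ss, se) = pair.long_span, pair.short_span
        if ls < ss:  # LONG (SHORT) -> keep SHORT
            close = sentence.find(")", se)
            if close >= 0:
                removals.append((ls, ss))
                removals.append((se, close + 1))
        else:  # SHORT (LONG) -> drop the parenthetical
            opn = sentence.rfind("(", se, ls)
            close = sentence.find(")", le)
            if opn >= 0 and close >= 0:
                start = opn - 1 if opn > 0 and sentence[opn - 1] == " " else opn
                removals.append((start, close + 1))
    removed_so_far = list(removals)
    for m in _PAREN.finditer(sentence):
        if any(s <= m.start() < e for s, e in removed_so_far):
            continue
        before = sentence[: m.start()].rstrip()
        if any(mn.end == len(before) for mn in mentions):
            start = m.start() - 1 if m.start() > 0 and sentence[m.start() - 1] == " " else m.start()
            removals.append((start, m.end()))
    text1, pos1 = _apply_removals(sentence, removals, raw_pos)
    mentions1 = _remap_mentions(mentions, raw_pos, pos1)

    appositive_removals: List[Tuple[int, int]] = []
    commas = [i for i, ch in enumerate(text1) if ch == ","]
    for idx, c1 in enumerate(commas):
        if any(s <= c1 < e for s, e in appositive_removals):
            continue
        c2 = commas[idx + 1] if idx + 1 < len(commas) else -1
        if c2 < 0:
            continue
        if not any(m.end == c1 for m in mentions1):
            continue
        segment = text1[c1 + 1: c2].strip()
        if not segment:
            continue
        first = segment.split()[0].lower()
        if first in _CLOSED["CC"] or first in _CLOSED["IN"] or first in lexicon.verbal:
            continue
        if any(c1 < m.start and m.end <= c2 for m in mentions1):
            continue
        appositive_removals.append((c1, c2 + 1))
    text2, pos2 = _apply_removals(text1, appositive_removals, pos1)
    mentions2 = _remap_mentions(mentions1, pos1, pos2)
    return MaskResult(text2, mentions2, pos2)


# ---------------------------------------------------------------------------
# Event frames

SlotValue = Union[EntityMention, "EventFrame"]


@dataclass
class EventFrame:
    """A predicate with role-labelled arguments.

    Before :func:`distribute_coordination`, coordinated slots may carry
    several ``Agent``/``Theme`` entries; afterwards regulation frames have at
    most one Agent and exactly one Theme.
    """

    trigger_lemma: str
    trigger_span: Tuple[int, int]
    category: str
    args: List[Tuple[str, SlotValue]] = field(default_factory=list)
    polarity: int = 0
    negated: bool = False
    direct: bool = False
    rule_id: str = ""
    anchor: Tuple[int, int] = (0, 0)
    site: Optional[str] = None

    def values(self, role: str) -> List[SlotValue]:
        return [v for r, v in self.args if r == role]

    @property
    def agents(self) -> List[SlotValue]:
        return self.values("Agent")

    @property
    def themes(self) -> List[SlotValue]:
        return self.values("Theme")


def _slot_mentions(els: Sequence[Element]) -> List[EntityMention]:
    seen = []
    for el in els:
        for m in el.mentions:
            if m.semclass == "cellcomponent":
                continue
            if not any(m.span == s.span for s in seen):
                seen.append(m)
    return seen


def _frame_at(frames: Sequence[EventFrame], span: Tuple[int, int],
              categories=EVENT_SLOT_CATEGORIES) -> Optional[EventFrame]:
    best = None
    for f in frames:
        if f.category not in categories:
            continue
        if f.anchor[0] < span[1] and span[0] < f.anchor[1]:
            if best is None or (f.anchor[1] - f.anchor[0]) > (best.anchor[1] - best.anchor[0]):
                best = f
    return best


def _group_value(els: Sequence[Element], frames: Sequence[EventFrame]) -> List[SlotValue]:
    """Value(s) contributed by one conjunct group: an anchored event frame
    beats a hyphenated regulation frame beats bare entity mentions."""
    span = (min(e.span[0] for e in els), max(e.span[1] for e in els))
    f = _frame_at(frames, span)
    if f is not None:
        return [f]
    hyph = _frame_at(frames, span, categories=REGULATION_CATEGORIES)
    if hyph is not None and hyph.rule_id == "hyphen":
        return [hyph]
    return list(_slot_mentions(els))


def _conjunct_groups(elements: Sequence[Element], indices: Sequence[int]) -> List[List[Element]]:
    groups: List[List[Element]] = []
    for i in indices:
        el = elements[i]
        if el.kind == "NP":
            groups.append([el])
        elif el.kind == "PP" and groups:
            groups[-1].append(el)
        elif el.kind == "PP":
            groups.append([el])
    return groups


def _subject_indices(elements: Sequence[Element], vp_idx: int) -> Optional[List[int]]:
    i = vp_idx - 1
    while i >= 0 and elements[i].kind == "TOK" and elements[i].tag in ("RB", "MD"):
        i -= 1
    if i < 0:
        return None
    el = elements[i]
    if el.kind == "TOK" and el.tag in ("CC", "PUNCT", "WDT"):
        return None
    if el.kind not in ("NP", "PP"):
        return None
    picked: List[int] = []
    while i >= 0:
        el = elements[i]
        if el.kind in ("NP", "PP"):
            picked.append(i)
            i -= 1
            continue
        if el.kind == "TOK" and el.tag == "CC" and i - 1 >= 0 and elements[i - 1].kind == "NP":
            picked.append(i)
            i -= 1
            continue
        break
    picked.reverse()
    return picked or None


def _object_indices(elements: Sequence[Element], vp_idx: int) -> List[int]:
    picked: List[int] = []
    i = vp_idx + 1
    while i < len(elements):
        el = elements[i]
        if el.kind == "TOK" and el.tag == "RB":
            i += 1
            continue
        if el.kind in ("NP", "PP"):
            picked.append(i)
            i += 1
            continue
        if el.kind == "TOK" and el.tag == "CC" and i + 1 < len(elements) \
                and elements[i + 1].kind == "NP":
            # an NP right before a verb group is the next clause's subject
            if i + 2 < len(elements) and elements[i + 2].kind == "VP":
                break
            picked.append(i)
            picked.append(i + 1)
            i += 2
            continue
        break
    return picked


def _pp_after(elements: Sequence[Element], start: int, preps) -> Optional[Element]:
    for el in elements[start:]:
        if el.kind == "PP" and el.prep in preps:
            return el
        if el.kind in ("VP", "COP") or (el.kind == "TOK" and el.tag == "PUNCT"):
            return None
    return None


def _vp_flags(elements: Sequence[Element], vp_idx: int) -> Tuple[bool, bool]:
    vp = elements[vp_idx]
    words = {t.lemma for t in vp.chunk.tokens}
    direct = "directly" in words
    negated = bool(words & _NEGATION_WORDS)
    j = vp_idx - 1
    while j >= 0 and elements[j].kind == "TOK" and elements[j].tag == "RB":
        w = elements[j].chunk.tokens[0].lemma
        direct = direct or w == "directly"
        negated = negated or w in _NEGATION_WORDS
        j -= 1
    return direct, negated


# --- nominal trigger pass ---------------------------------------------------

def _nominal_trigger(el: Element, lexicon: VerbLexicon) -> Optional[Tuple[Token, VerbLexiconEntry]]:
    if el.kind != "NP":
        return None
    for t in reversed(el.chunk.tokens):
        entry = lexicon.nominal.get(t.text.lower())
        if entry is not None:
            return t, entry
    return None


def _chunk_trigger(np_chunk: Chunk, lexicon: VerbLexicon) -> Optional[Tuple[Token, VerbLexiconEntry]]:
    for t in reversed(np_chunk.tokens):
        entry = lexicon.nominal.get(t.text.lower())
        if entry is not None:
            return t, entry
    return None


def _nominal_event_frames(elements: Sequence[Element], lexicon: VerbLexicon) -> List[EventFrame]:
    # NPs in subject/object position, plus NPs governed by a preposition
    # (trigger nominals like "PP1c activity" occur freely inside PPs)
    candidates = []
    for idx, el in enumerate(elements):
        if el.kind == "NP":
            candidates.append((idx, el, el.chunk, el.mentions, False))
        elif el.kind == "PP" and el.inner is not None:
            inner = [m for m in el.mentions if m.end > el.inner.start]
            candidates.append((idx, el, el.inner, inner, True))
    frames: List[EventFrame] = []
    for idx, el, np_chunk, np_mentions, in_pp in candidates:
        hit = _chunk_trigger(np_chunk, lexicon)
        if hit is None:
            continue
        trig, entry = hit
        cat = entry.category
        if in_pp and cat not in ("Expression", "Activity", "Generic", "Phosphorylation"):
            continue
        anchor_start = np_chunk.start
        anchor_end = np_chunk.end
        args: List[Tuple[str, SlotValue]] = []
        site = None
        if cat == "BindingEvent":
            themes: List[EntityMention] = list(_slot_mentions([el]))
            j = idx + 1
            while j < len(elements):
                nxt = elements[j]
                if nxt.kind == "PP" and nxt.prep in _THEME_PREPS:
                    themes.extend(_slot_mentions([nxt]))
                    anchor_end = nxt.span[1]
                    j += 1
                    continue
                if nxt.kind == "TOK" and nxt.tag == "CC" and j + 1 < len(elements) \
                        and elements[j + 1].kind == "NP" \
                        and not (j + 2 < len(elements) and elements[j + 2].kind == "VP"):
                    themes.extend(_slot_mentions([elements[j + 1]]))
                    anchor_end = elements[j + 1].span[1]
                    j += 2
                    continue
                break
            uniq = []
            for m in themes:
                if not any(m.span == u.span for u in uniq):
                    uniq.append(m)
            if len(uniq) < 2:
                continue
            args = [("Theme", m) for m in uniq]
        elif cat == "TransportEvent":
            of_pp = _pp_after(elements, idx + 1, {"of"})
            theme = _slot_mentions([of_pp]) if of_pp else _slot_mentions([el])
            if not theme:
                continue
            args = [("Theme", theme[0])]
            if of_pp is not None:
                anchor_end = of_pp.span[1]
            src = _pp_after(elements, idx + 1, {"from"})
            dst = _pp_after(elements, idx + 1, {"to", "into"})
            for role, pp in (("SourceLoc", src), ("DestLoc", dst)):
                if pp is None:
                    continue
                anchor_end = max(anchor_end, pp.span[1])
                locs = [m for m in pp.mentions if m.semclass == "cellcomponent"]
                if locs:
                    args.append((role, locs[0]))
        elif cat == "Phosphorylation":
            of_pp = _pp_after(elements, idx + 1, {"of"})
            theme = _slot_mentions([of_pp]) if of_pp else []
            if not theme:
                pre = [m for m in np_mentions if m.end <= trig.start]
                theme = pre[-1:]
            if not theme:
                continue
            args = [("Theme", theme[0])]
            if of_pp is not None:
                anchor_end = of_pp.span[1]
            site_pp = _pp_after(elements, idx + 1, {"on", "at"})
            if site_pp is not None and site_pp.inner is not None:
                site = site_pp.inner.text
                anchor_end = max(anchor_end, site_pp.span[1])
        elif cat in ("Expression", "Activity", "Generic"):
            pre = [m for m in np_mentions if m.end <= trig.start and m.semclass != "cellcomponent"]
            theme = pre[-1:]
            if not theme and not in_pp:
                preps = {"of", "by"} if cat == "Generic" else {"of"}
                pp = _pp_after(elements, idx + 1, preps)
                if pp is not None:
                    theme = _slot_mentions([pp])[:1]
                    if theme:
                        anchor_end = pp.span[1]
            if not theme:
                continue
            args = [("Theme", theme[0])]
        else:
            continue  # regulation nominals are handled by the regulation rule
        frames.append(
            EventFrame(
                entry.lemma, (trig.start, trig.end), cat, args,
                polarity=entry.polarity,
                rule_id={"BindingEvent": "rule1-nominal", "TransportEvent": "rule2-nominal"}.get(
                    cat, f"nominal-{cat.lower()}"
                ),
                anchor=(anchor_start, anchor_end),
                site=site,
            )
        )
    return frames


def _hyphen_regulation_frames(
    tokens: Sequence[Token],
    mentions: Sequence[EntityMention],
    lexicon: VerbLexicon,
) -> List[EventFrame]:
    """``X-induced Y`` style participle compounds become regulation frames."""
    frames: List[EventFrame] = []
    for tok in tokens:
        if "-" not in tok.text or tok.tag not in ("JJ", "NN"):
            continue
        last = tok.text.lower().rsplit("-", 1)[-1]
        entry = lexicon.verbal.get(last)
        if entry is None or entry.category not in REGULATION_CATEGORIES:
            continue
        hyph_pos = tok.start + len(tok.text) - len(last) - 1
        agent = next((m for m in mentions if m.end == hyph_pos), None)
        if agent is None:
            continue
        theme = next(
            (m for m in mentions
             if m.start >= tok.end and m.start - tok.end <= 30
             and m.semclass != "cellcomponent"),
            None,
        )
        if theme is None:
            continue
        frames.append(
            EventFrame(
                entry.lemma, (hyph_pos + 1, tok.end), entry.category,
                [("Agent", agent), ("Theme", theme)],
                polarity=entry.polarity, rule_id="hyphen",
                anchor=(agent.start, theme.end),
            )
        )
    return frames


# --- public rule operations -------------------------------------------------

def apply_binding_rule(
    elements: Sequence[Element],
    lexicon: Optional[VerbLexicon] = None,
) -> List[EventFrame]:
    """Physical interactions between >= 2 entities: nominal triggers
    (interaction/association/complex of|between|with ...) and verbal triggers
    (interact, bind, associate, complexed with)."""
    lexicon = lexicon or default_lexicon()
    frames = [f for f in _nominal_event_frames(elements, lexicon) if f.category == "BindingEvent"]
    for idx, el in enumerate(elements):
        if el.kind != "VP" or el.entry is None or el.entry.category != "BindingEvent":
            continue
        themes: List[EntityMention] = []
        subj = _subject_indices(elements, idx)
        if subj:
            themes.extend(_slot_mentions([elements[i] for i in subj]))
        obj = _object_indices(elements, idx)
        for i in obj:
            nxt = elements[i]
            if nxt.kind == "NP" or (nxt.kind == "PP" and nxt.prep in _THEME_PREPS):
                themes.extend(_slot_mentions([nxt]))
        uniq: List[EntityMention] = []
        for m in themes:
            if not any(m.span == u.span for u in uniq):
                uniq.append(m)
        if len(uniq) < 2:
            continue
        anchor = (min(m.start for m in uniq), max(m.end for m in uniq))
        vt = el.verb_token
        frames.append(
            EventFrame(
                el.entry.lemma, (vt.start, vt.end), "BindingEvent",
                [("Theme", m) for m in uniq], rule_id="rule1",
                anchor=(min(anchor[0], el.span[0]), max(anchor[1], el.span[1])),
            )
        )
    return frames


def apply_transport_rule(
    elements: Sequence[Element],
    lexicon: Optional[VerbLexicon] = None,
) -> List[EventFrame]:
    """Movement of a protein between subcellular locations: ``translocation of
    X from A to B`` nominals and ``X translocates ...`` verbals."""
    lexicon = lexicon or default_lexicon()
    frames = [f for f in _nominal_event_frames(elements, lexicon) if f.category == "TransportEvent"]
    for idx, el in enumerate(elements):
        if el.kind != "VP" or el.entry is None or el.entry.category != "TransportEvent":
            continue
        subj = _subject_indices(elements, idx)
        theme = _slot_mentions([elements[i] for i in subj]) if subj else []
        if not theme:
            continue
        args: List[Tuple[str, SlotValue]] = [("Theme", theme[0])]
        anchor_end = el.span[1]
        for role, preps in (("SourceLoc", {"from"}), ("DestLoc", {"to", "into"})):
            pp = _pp_after(elements, idx + 1, preps)
            if pp is None:
                continue
            anchor_end = max(anchor_end, pp.span[1])
            locs = [m for m in pp.mentions if m.semclass == "cellcomponent"]
            if locs:
                args.append((role, locs[0]))
        vt = el.verb_token
        frames.append(
            EventFrame(
                el.entry.lemma, (vt.start, vt.end), "TransportEvent", args,
                rule_id="rule2", anchor=(theme[0].start, anchor_end),
            )
        )
    return frames


@dataclass
class Clause:
    vp_index: int
    subject_values: List[SlotValue]
    frame: Optional[EventFrame]


def _dedupe_values(values: Sequence[SlotValue]) -> List[SlotValue]:
    out: List[SlotValue] = []
    for v in values:
        if isinstance(v, EventFrame):
            if any(v is o for o in out):
                continue
        else:
            if any(
                isinstance(o, EntityMention) and o.span == v.span and o.semclass == v.semclass
                for o in out
            ):
                continue
        out.append(v)
    return out


def apply_regulation_rule(
    elements: Sequence[Element],
    mentions: Sequence[EntityMention],
    prior_frames: Sequence[EventFrame],
    lexicon: Optional[VerbLexicon] = None,
) -> List[EventFrame]:
    """Causal-verb frames: Agent = subject NP/event, Theme = object NP/event;
    passive voice swaps roles via the by-PP; a subjectless coordinated verb
    inherits the subject — or the event — of the verb it coordinates with;
    nominal patterns (``inhibition of X by Y``, ``... is an inhibitor of X``)
    are included."""
    lexicon = lexicon or default_lexicon()
    frames: List[EventFrame] = []
    pool: List[EventFrame] = list(prior_frames)
    clauses: List[Clause] = []

    for idx, el in enumerate(elements):
        if el.kind != "VP" or el.entry is None:
            continue
        entry = el.entry
        subj = _subject_indices(elements, idx)
        subject_values: List[SlotValue] = []
        if subj:
            for group in _conjunct_groups(elements, subj):
                subject_values.extend(_group_value(group, pool))
        subject_values = _dedupe_values(subject_values)
        inherited = False
        if not subject_values and clauses:
            prev = clauses[-1]
            if prev.frame is not None and prev.frame.category in ("BindingEvent", "TransportEvent"):
                subject_values = [prev.frame]
            else:
                subject_values = list(prev.subject_values)
            inherited = True
        if entry.category not in REGULATION_CATEGORIES:
            vt = el.verb_token
            own = None
            if vt is not None:
                own = next(
                    (f for f in pool if f.trigger_span == (vt.start, vt.end)), None
                )
            clauses.append(Clause(idx, subject_values, own))
            continue
        direct, negated = _vp_flags(elements, idx)
        if el.passive:
            theme_values = subject_values if not inherited else []
            if subj:
                theme_values = []
                for group in _conjunct_groups(elements, subj):
                    theme_values.extend(_group_value(group, pool))
            by_pp = _pp_after(elements, idx + 1, {"by"})
            agent_values = _group_value([by_pp], pool) if by_pp else []
            rule_id = "reg-passive"
        else:
            agent_values = subject_values
            theme_values = []
            obj = _object_indices(elements, idx)
            for group in _conjunct_groups(elements, obj):
                theme_values.extend(_group_value(group, pool))
            rule_id = "reg-active"
        agent_values = _dedupe_values(agent_values)
        theme_values = _dedupe_values(theme_values)
        frame = None
        if theme_values:
            vt = el.verb_token
            frame = EventFrame(
                entry.lemma, (vt.start, vt.end), entry.category,
                [("Agent", v) for v in agent_values] + [("Theme", v) for v in theme_values],
                polarity=entry.polarity, negated=negated, direct=direct,
                rule_id=rule_id, anchor=el.span,
            )
            frames.append(frame)
            pool.append(frame)
        clauses.append(Clause(idx, subject_values if not el.passive else agent_values, frame))

    # nominal regulation: "inhibition of X by Y" / "<subj> is a ... inhibitor of X"
    for idx, el in enumerate(elements):
        hit = _nominal_trigger(el, lexicon)
        if hit is None:
            continue
        trig, entry = hit
        if entry.category not in REGULATION_CATEGORIES:
            continue
        of_pp = _pp_after(elements, idx + 1, {"of"})
        if of_pp is None:
            continue
        theme_values = _group_value([of_pp], pool)
        if not theme_values:
            continue
        by_pp = _pp_after(elements, idx + 1, {"by"})
        agent_values = _group_value([by_pp], pool) if by_pp else []
        if not agent_values:
            j = idx - 1
            while j >= 0 and elements[j].kind in ("TOK",) and elements[j].tag == "RB":
                j -= 1
            if j >= 0 and elements[j].kind == "COP":
                subj = _subject_indices(elements, j)
                if subj:
                    for group in _conjunct_groups(elements, subj):
                        agent_values.extend(_group_value(group, pool))
        frame = EventFrame(
            entry.lemma, (trig.start, trig.end), entry.category,
            [("Agent", v) for v in agent_values] + [("Theme", v) for v in theme_values],
            polarity=entry.polarity, rule_id="nominal-reg",
            anchor=(el.span[0], of_pp.span[1]),
        )
        frames.append(frame)
        pool.append(frame)
    return frames


def distribute_coordination(frames: Sequence[EventFrame]) -> List[EventFrame]:
    """Replicate regulation frames over coordinated Agent/Theme conjuncts
    (cartesian product). Binding frames keep all their themes; frame count
    never decreases."""
    out: List[EventFrame] = []
    for f in frames:
        if f.category not in REGULATION_CATEGORIES:
            out.append(f)
            continue
        agents = f.agents or [None]
        themes = f.themes
        if not themes:
            out.append(f)
            continue
        for a in agents:
            for t in themes:
                args = [("Agent", a)] if a is not None else []
                args.append(("Theme", t))
                out.append(replace(f, args=args))
    return out


def link_cross_clausal(frames: Sequence[EventFrame]) -> List[EventFrame]:
    """Finalize event nesting: frames consumed as arguments of another frame
    lose top-level status, except regulation frames (their causal link is
    still asserted, e.g. the inner half of an ``X-induced Y`` chain)."""
    consumed = set()
    for f in frames:
        for _, v in f.args:
            if isinstance(v, EventFrame):
                consumed.add(id(v))
    return [f for f in frames if id(f) not in consumed or f.category in REGULATION_CATEGORIES]


def parse_events(
    sentence: str,
    mentions: Sequence[EntityMention],
    lexicon: Optional[VerbLexicon] = None,
    grammar: Optional[ChunkGrammar] = None,
    anaphora_resolver=None,
) -> Tuple[List[EventFrame], MaskResult]:
    """Full cascade on one sentence: mask, tokenize, chunk, apply the rules in
    fixed priority order, distribute coordination and resolve nesting.

    ``anaphora_resolver`` is a hook ``(text, mentions) -> mentions`` invoked
    before rule application; no resolver ships with the package (pronouns and
    event anaphora are a documented non-capability).

    Returns the top-level frames and the mask result (for span projection).
    """
    lexicon = lexicon or default_lexicon()
    if anaphora_resolver is not None:
        mentions = anaphora_resolver(sentence, list(mentions))
    masked = mask_appositions(sentence, mentions, lexicon)
    tokens = tokenize_and_tag(masked.text, lexicon)
    chunks = chunk(tokens, grammar)
    elements = build_elements(chunks, masked.mentions, lexicon)
    frames: List[EventFrame] = []
    frames.extend(_hyphen_regulation_frames(tokens, masked.mentions, lexicon))
    frames.extend(apply_binding_rule(elements, lexicon))
    frames.extend(apply_transport_rule(elements, lexicon))
    frames.extend(
        f for f in _nominal_event_frames(elements, lexicon)
        if f.category in ("Phosphorylation", "Expression", "Activity", "Generic")
    )
    frames.extend(apply_regulation_rule(elements, masked.mentions, frames, lexicon))
    frames = distribute_coordination(frames)
    top = link_cross_clausal(frames)
    return top, masked
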