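"""Translate event frames and entity mentions into BEL terms and statements.

Entity classes map to abundance functions (gene/protein -> ``p``, chemical ->
``a``, disease -> ``path``, biological process -> ``bp``); event categories map
to function templates (binding -> ``complex``, transport -> ``tloc``,
phosphorylation -> ``pmod`` argument, activity -> ``act``). A recognized but
unnormalizable concept becomes a placeholder value (``bp(PH:Placeholder)``)
so it can be filtered rather than scored as a precision error. Only frames
whose trigger falls in one of the four causal verb classes yield statements.

Expression is configurable: ``corrected`` mode (default) maps
``expression of X`` to ``p(X)``; ``legacy`` mode reproduces the original
competition behavior (``act(p(X))``, or ``tscript(p(X))`` via
``legacy_expression_function``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

from .core import (
    BELStatement,
    BELTerm,
    Modifier,
    NamespaceId,
    Relation,
    canonicalize,
)
from .lexicon import EntityMention
from .parser import EventFrame, REGULATION_CATEGORIES

log = logging.getLogger(__name__)

FUNCTION_BY_SEMCLASS = {
    "gene_protein": "p",
    "chemical": "a",
    "disease": "path",
    "bioprocess": "bp",
}

#: trigger lemmas whose theme is reported as an activity (Table-style
#: "activates X" -> increases act(p(X)))
ACT_WRAP_LEMMAS = frozenset({"activate"})

_RESIDUE_WORDS = {"serine": "S", "threonine": "T", "tyrosine": "Y"}
_SITE_WORD = re.compile(r"(serine|threonine|tyrosine)[\s-]*(\d+)", re.IGNORECASE)
_SITE_LETTER = re.compile(r"\b([STY])[\s-]*(\d+)\b")


class MappingError(Exception):
    pass


@dataclass
class MappingConfig:
    """Mapper behavior switches.

    ``expression_mode``: ``corrected`` (expression of X -> p(X)) or ``legacy``
    (the original act/tscript wrapping). ``run_mode``: ``run1`` keeps
    placeholder-containing statements, ``run2`` drops them.
    """

    expression_mode: str = "corrected"
    run_mode: str = "run1"
    placeholder_namespace: str = "PH"
    legacy_expression_function: str = "act"

    def __post_init__(self):
        if self.expression_mode not in ("legacy", "corrected"):
            raise ValueError(f"unknown expression_mode {self.expression_mode!r}")
        if self.run_mode not in ("run1", "run2"):
            raise ValueError(f"unknown run_mode {self.run_mode!r}")
        if self.legacy_expression_function not in ("act", "tscript"):
            raise ValueError(
                f"unknown legacy_expression_function {self.legacy_expression_function!r}"
            )


def parse_site(site: str) -> Optional[Modifier]:
    """Parse a phosphorylation site string (``serine-273`` or ``S273``)."""
    m = _SITE_WORD.search(site)
    if m:
        return Modifier("P", _RESIDUE_WORDS[m.group(1).lower()], int(m.group(2)))
    m = _SITE_LETTER.search(site)
    if m:
        return Modifier("P", m.group(1), int(m.group(2)))
    return None


def map_entity(mention: EntityMention, cfg: Optional[MappingConfig] = None) -> BELTerm:
    """Map a classed mention to its abundance function; unnormalized mentions
    become a placeholder value in the configured placeholder namespace."""
    cfg = cfg or MappingConfig()
    fn = FUNCTION_BY_SEMCLASS.get(mention.semclass)
    if fn is None:
        raise MappingError(
            f"mention {mention.text!r} has no BEL abundance mapping "
            f"(class {mention.semclass!r})"
        )
    nsid = mention.nsid
    if nsid is None or nsid.namespace == cfg.placeholder_namespace:
        nsid = NamespaceId(cfg.placeholder_namespace, "Placeholder")
    return BELTerm(fn, (nsid,))


def _first_entity(frame: EventFrame) -> Optional[EntityMention]:
    for _, v in frame.args:
        if isinstance(v, EntityMention):
            return v
    for _, v in frame.args:
        if isinstance(v, EventFrame):
            inner = _first_entity(v)
            if inner is not None:
                return inner
    return None


def map_event(frame: EventFrame, cfg: Optional[MappingConfig] = None) -> BELTerm:
    """Map an event frame to a BEL term per the function templates.

    Regulation frames used in term position fall back to their proximal
    participant (Agent if present, else Theme); unmappable wrappers (generic
    events like "signaling by X") reduce to their entity argument alone.
    """
    cfg = cfg or MappingConfig()
    cat = frame.category

    def slot(value) -> BELTerm:
        if isinstance(value, EntityMention):
            return map_entity(value, cfg)
        return map_event(value, cfg)

    if cat == "BindingEvent":
        themes = [slot(t) for t in frame.themes]
        if len(themes) < 2:
            raise MappingError("binding event needs >= 2 mappable themes")
        return canonicalize(BELTerm("complex", tuple(themes)))
    if cat == "TransportEvent":
        if not frame.themes:
            raise MappingError("transport event without theme")
        return BELTerm("tloc", (slot(frame.themes[0]),))
    if cat == "Phosphorylation":
        if not frame.themes:
            raise MappingError("phosphorylation event without theme")
        base = slot(frame.themes[0])
        mod = parse_site(frame.site) if frame.site else None
        if mod is not None and base.function == "p":
            return BELTerm("p", base.args + (mod,))
        return base
    if cat == "Expression":
        if not frame.themes:
            raise MappingError("expression event without theme")
        base = slot(frame.themes[0])
        if cfg.expression_mode == "legacy":
            return BELTerm(cfg.legacy_expression_function, (base,))
        return base
    if cat == "Activity":
        if not frame.themes:
            raise MappingError("activity event without theme")
        inner = slot(frame.themes[0])
        return inner if inner.function == "act" else BELTerm("act", (inner,))
    if cat == "Generic":
        entity = _first_entity(frame)
        if entity is None:
            raise MappingError(f"no mappable argument in {frame.trigger_lemma!r} frame")
        return map_entity(entity, cfg)
    if cat in REGULATION_CATEGORIES:
        pool = frame.agents or frame.themes
        if not pool:
            raise MappingError(f"regulation frame {frame.trigger_lemma!r} has no arguments")
        return slot(pool[0])
    raise MappingError(f"no BEL mapping for event category {cat!r}")


def map_relation(frame: EventFrame) -> Optional[Relation]:
    """Causal-verb class of a frame: negative regulation and cleavage map to
    decreases, positive regulation to increases; a preceding "directly"
    upgrades to the direct forms. Other categories map to no relation."""
    if frame.category in ("NegativeRegulation", "Cleavage"):
        return Relation.DIRECTLY_DECREASES if frame.direct else Relation.DECREASES
    if frame.category == "PositiveRegulation":
        return Relation.DIRECTLY_INCREASES if frame.direct else Relation.INCREASES
    return None


@dataclass(frozen=True)
class RelationFragment:
    """A relation with object only (subject-empty frames such as "activates
    STAT3"); useful at the function level, never emitted as a statement."""

    relation: Relation
    object: BELTerm
    provenance: tuple = ()


def _wrap_activity(term: BELTerm) -> BELTerm:
    return term if term.function == "act" else BELTerm("act", (term,))


def assemble_statements(
    frames: Sequence[EventFrame],
    cfg: Optional[MappingConfig] = None,
    sentence_id: str = "",
) -> Tuple[List[BELStatement], List[RelationFragment]]:
    """Build statements from the top-level frames of one sentence.

    Frames with no causal relation produce nothing; frames without a mappable
    subject yield a relation fragment on the secondary channel. Cleavage
    themes and the themes of activity-asserting verbs are wrapped in act().
    """
    cfg = cfg or MappingConfig()
    statements: List[BELStatement] = []
    fragments: List[RelationFragment] = []
    for frame in frames:
        relation = map_relation(frame)
        if relation is None:
            continue
        if not frame.themes:
            continue
        theme = frame.themes[0]
        try:
            obj = map_entity(theme, cfg) if isinstance(theme, EntityMention) \
                else map_event(theme, cfg)
        except MappingError as exc:
            log.debug("dropping frame %r: %s", frame.trigger_lemma, exc)
            continue
        if frame.category == "Cleavage" or frame.trigger_lemma in ACT_WRAP_LEMMAS:
            obj = _wrap_activity(obj)
        provenance = (sentence_id, frame.rule_id)
        if not frame.agents:
            fragments.append(RelationFragment(relation, canonicalize(obj), provenance))
            continue
        agent = frame.agents[0]
        try:
            subj = map_entity(agent, cfg) if isinstance(agent, EntityMention) \
                else map_event(agent, cfg)
        except MappingError as exc:
            log.debug("unmappable subject in %r frame: %s", frame.trigger_lemma, exc)
            fragments.append(RelationFragment(relation, canonicalize(obj), provenance))
            continue
        statements.append(
            BELStatement(canonicalize(subj), relation, canonicalize(obj), provenance)
        )
    return statements, fragments


def contains_placeholder(stmt: BELStatement, namespace: str = "PH") -> bool:
    def term_has(term: BELTerm) -> bool:
        for arg in term.args:
            if isinstance(arg, NamespaceId) and arg.namespace == namespace:
                return True
            if isinstance(arg, BELTerm) and term_has(arg):
                return True
        return False

    return term_has(stmt.subject) or term_has(stmt.object)


def filter_statements(
    statements: Sequence[BELStatement],
    cfg: Optional[MappingConfig] = None,
) -> List[BELStatement]:
    """Final statement filter.

    Every statement must carry one of the four causal relations (guaranteed by
    assembly, asserted here). run1 keeps placeholder-containing statements;
    run2 additionally drops any statement containing the placeholder
    namespace. Duplicates collapse, order otherwise preserved.
    """
    cfg = cfg or MappingConfig()
    out: List[BELStatement] = []
    seen = set()
    for stmt in statements:
        assert isinstance(stmt.relation, Relation)
        if cfg.run_mode == "run2" and contains_placeholder(stmt, cfg.placeholder_namespace):
            log.debug("run2: dropping placeholder statement %s", stmt)
            continue
        key = (stmt.subject, stmt.relation, stmt.object)
        if key in seen:
            continue
        seen.add(key)
        out.append(stmt)
    return out
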