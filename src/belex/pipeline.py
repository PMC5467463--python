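"""End-to-end extraction pipeline: NER -> semantic parsing -> BEL mapping.

Per sentence the pipeline (1) collects internal dictionary matches plus GO
partial-match candidates resolved against the ontology, (2) resolves
cross-dictionary conflicts, (3) propagates classes through abbreviation pairs
and surface similarity, (4) merges with external standoff annotations by the
ensemble priority rules, (5) optionally replaces mentions with the gold entity
list, (6) simplifies the sentence, extracts event frames, and (7) maps frames
to BEL statements and filters them. Per-sentence failures are logged and
skipped, never fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import BELStatement
from .lexicon import (
    DEFAULT_CLASS_PRIORITY,
    DEFAULT_SIMILARITY_THRESHOLD,
    GO_CLASSES,
    DictionaryEntry,
    EntityMention,
    GeneGoAssociation,
    LexiconIndex,
    detect_acronyms,
    dictionary_lookup,
    edit_similarity,
    go_partial_candidates,
    gold_constrained_lookup,
    infer_class_from_acronym,
    match_tokens,
    merge_ensemble,
    propagate_class_by_similarity,
    resolve_cross_dictionary_conflict,
    resolve_go_term,
)
from .mapper import (
    MappingConfig,
    RelationFragment,
    assemble_statements,
    filter_statements,
)
from .parser import EventFrame, VerbLexicon, default_lexicon, parse_events

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline switches; mirrors the command-line flags."""

    run_mode: str = "run1"
    expression_mode: str = "corrected"
    legacy_expression_function: str = "act"
    phase: str = "phase1"  # phase1 | phase2_gold
    style: str = "long"
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    class_priority: Tuple[str, ...] = DEFAULT_CLASS_PRIORITY

    def mapping(self) -> MappingConfig:
        return MappingConfig(
            expression_mode=self.expression_mode,
            run_mode=self.run_mode,
            legacy_expression_function=self.legacy_expression_function,
        )


@dataclass
class PipelineResult:
    sentence_id: str
    text: str
    mentions: List[EntityMention] = field(default_factory=list)
    frames: List[EventFrame] = field(default_factory=list)
    statements: List[BELStatement] = field(default_factory=list)
    fragments: List[RelationFragment] = field(default_factory=list)


def _overlap_clusters(mentions: Sequence[EntityMention]) -> List[List[EntityMention]]:
    clusters: List[List[EntityMention]] = []
    for m in sorted(mentions, key=lambda m: (m.start, -(m.end - m.start))):
        placed = False
        for cluster in clusters:
            if any(m.overlaps(o) for o in cluster):
                cluster.append(m)
                placed = True
                break
        if not placed:
            clusters.append([m])
    return clusters


def extract_mentions(
    text: str,
    sentence_id: str,
    index: LexiconIndex,
    standoff: Optional[Mapping[str, Sequence[EntityMention]]] = None,
    gold_entries: Optional[Sequence[DictionaryEntry]] = None,
    assoc: Sequence[GeneGoAssociation] = (),
    go_parents: Optional[Mapping[str, Sequence[str]]] = None,
    cfg: Optional[PipelineConfig] = None,
) -> List[EntityMention]:
    """The full entity recognition and normalization stage for one sentence."""
    cfg = cfg or PipelineConfig()
    go_parents = go_parents or {}
    standoff = standoff or {}
    internal = dictionary_lookup(text, sentence_id, index)

    # GO partial matches resolved against the ontology and gene context
    gene_ctx = [m.nsid for m in internal if m.semclass == "gene_protein" and m.nsid]
    for source_mentions in standoff.values():
        gene_ctx.extend(
            m.nsid for m in source_mentions
            if m.sentence_id == sentence_id and m.semclass == "gene_protein" and m.nsid
        )
    go_entries = [e for e in index.entries if e.semclass in GO_CLASSES]
    for span, hits in go_partial_candidates(text, go_entries):
        if any(
            m.semclass in GO_CLASSES and m.start < span[1] and span[0] < m.end
            for m in internal
        ):
            continue
        seen = set()
        candidates = []
        for e in hits:
            if e.nsid is not None and e.nsid not in seen:
                seen.add(e.nsid)
                candidates.append(e.nsid)
        if not candidates:
            continue
        phrase = text[span[0]: span[1]]
        choice = resolve_go_term(phrase, candidates, gene_ctx, assoc, go_parents)
        semclass = {"GOBP": "bioprocess", "GOCC": "cellcomponent"}[choice.namespace]
        internal.append(
            EntityMention(
                sentence_id, span[0], span[1], phrase, semclass, choice,
                "internal", "fuzzy",
            )
        )

    # cross-dictionary conflicts: overlapping internal matches of different
    # classes resolve to one mention
    resolved: List[EntityMention] = []
    for cluster in _overlap_clusters(internal):
        if len(cluster) == 1 or len({m.semclass for m in cluster}) == 1:
            resolved.extend(cluster)
        else:
            resolved.append(
                resolve_cross_dictionary_conflict(
                    cluster[0].text, cluster,
                    mode="phase2_gold" if cfg.phase == "phase2_gold" else "phase1",
                    class_priority=cfg.class_priority,
                )
            )

    # abbreviation pairs propagate classes to short-form occurrences
    pairs = detect_acronyms(text)
    resolved = infer_class_from_acronym(pairs, resolved, text, sentence_id)

    # surface-similarity propagation for near-duplicate unclassed spans
    toks = match_tokens(text)
    classed = list(resolved)
    for m in classed:
        m_tokens = [t for t in toks if t[1] >= m.start and t[2] <= m.end]
        width = len(m_tokens)
        if width == 0:
            continue
        for i in range(len(toks) - width + 1):
            span = (toks[i][1], toks[i + width - 1][2])
            if any(span[0] < o.end and o.start < span[1] for o in resolved):
                continue
            candidate = text[span[0]: span[1]]
            if edit_similarity(candidate, m.text) < cfg.similarity_threshold:
                continue
            prop = propagate_class_by_similarity(
                candidate, span, sentence_id, [m], index.entries,
                threshold=cfg.similarity_threshold,
            )
            if prop is not None:
                resolved.append(prop)
    resolved.sort(key=lambda m: (m.start, -(m.end - m.start)))

    per_source: Dict[str, List[EntityMention]] = {"internal": resolved}
    for source in ("pubtator", "becas"):
        per_source[source] = [
            m for m in standoff.get(source, ()) if m.sentence_id == sentence_id
        ]
    merged = merge_ensemble(per_source)

    if cfg.phase == "phase2_gold" and gold_entries:
        merged = gold_constrained_lookup(text, sentence_id, gold_entries, merged)
    return merged


def run_pipeline(
    sentences: Sequence[Tuple[str, str]],
    dictionary: Iterable[DictionaryEntry],
    standoff: Optional[Mapping[str, Sequence[EntityMention]]] = None,
    gold_entities: Optional[Sequence[DictionaryEntry]] = None,
    assoc: Sequence[GeneGoAssociation] = (),
    go_parents: Optional[Mapping[str, Sequence[str]]] = None,
    cfg: Optional[PipelineConfig] = None,
    lexicon: Optional[VerbLexicon] = None,
) -> Dict[str, PipelineResult]:
    """Run the full pipeline over ``(sentence_id, text)`` pairs.

    Deterministic: identical inputs and config produce identical results.
    """
    cfg = cfg or PipelineConfig()
    lexicon = lexicon or default_lexicon()
    index = dictionary if isinstance(dictionary, LexiconIndex) else LexiconIndex(dictionary)
    mapping_cfg = cfg.mapping()
    results: Dict[str, PipelineResult] = {}
    for sid, text in sentences:
        result = PipelineResult(sid, text)
        results[sid] = result
        try:
            mentions = extract_mentions(
                text, sid, index, standoff, gold_entities, assoc, go_parents, cfg
            )
            frames, masked = parse_events(text, mentions, lexicon)
            statements, fragments = assemble_statements(frames, mapping_cfg, sid)
            result.mentions = mentions
            result.frames = frames
            result.statements = filter_statements(statements, mapping_cfg)
            result.fragments = fragments
            log.info(
                "%s: %d mentions, %d frames, %d statements",
                sid, len(mentions), len(frames), len(result.statements),
            )
        except Exception:
            log.exception("sentence %s failed; skipping", sid)
    return results


def statements_by_sentence(results: Mapping[str, PipelineResult]) -> Dict[str, List[BELStatement]]:
    return {sid: list(r.statements) for sid, r in results.items()}


# ---------------------------------------------------------------------------
# Input loaders

def load_sentences(path) -> List[Tuple[str, str]]:
    """Sentence input: TSV (``sentence_id TAB text``) or JSON-lines with
    fields ``id`` and ``text`` (detected from the first character)."""
    out: List[Tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.lstrip().startswith("{"):
                rec = json.loads(line)
                out.append((str(rec["id"]), rec["text"]))
                continue
            sid, _, text = line.partition("\t")
            if sid == "sentence_id":
                continue
            out.append((sid, text))
    return out


def load_gold_records(path) -> Dict[str, List[BELStatement]]:
    from .core import read_statement_file

    out: Dict[str, List[BELStatement]] = {}
    for sid, stmt in read_statement_file(path, lenient=True):
        out.setdefault(sid, []).append(stmt)
    return out
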