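"""Dictionary-based entity recognition and normalization.

Implements the normalization conventions that make gene/chemical/disease
surface variants comparable (``ERK-1`` and ``Erk1`` both normalize to
``erk 1``), longest token-aligned dictionary matching, Schwartz–Hearst
style long-form/short-form abbreviation detection with semantic-class
propagation, character edit-similarity class propagation, Gene Ontology
candidate resolution against the ontology hierarchy and gene–GO
associations, cross-dictionary conflict resolution, multi-source ensemble
merging (external annotators consumed from standoff files), and the
gold-constrained lookup used when a curated entity list is available.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import edlib

from .core import NamespaceId

log = logging.getLogger(__name__)

#: semantic class implied by each namespace keyword
SEMCLASS_BY_NAMESPACE = {
    "HGNC": "gene_protein",
    "MGI": "gene_protein",
    "EGID": "gene_protein",
    "CHEBI": "chemical",
    "MESHD": "disease",
    "GOBP": "bioprocess",
    "GOCC": "cellcomponent",
}

SEMCLASSES = ("gene_protein", "chemical", "disease", "bioprocess", "cellcomponent")

#: classes handled by the gene/chemical/disease ensemble arm (vs the GO arm)
GCD_CLASSES = frozenset({"gene_protein", "chemical", "disease"})
GO_CLASSES = frozenset({"bioprocess", "cellcomponent"})

DEFAULT_SIMILARITY_THRESHOLD = 0.85
DEFAULT_CLASS_PRIORITY = ("disease", "bioprocess", "chemical")


class LexiconError(Exception):
    pass


def normalize_surface(text: str) -> str:
    """Normalize a surface form: lowercase, hyphen/slash between alphanumerics
    to space, digit-letter boundaries split, whitespace collapsed. Idempotent."""
    s = text.lower()
    s = re.sub(r"(?<=[a-z0-9])[-/](?=[a-z0-9])", " ", s)
    s = re.sub(r"(?<=[a-z])(?=[0-9])|(?<=[0-9])(?=[a-z])", " ", s)
    return re.sub(r"\s+", " ", s).strip()


_MATCH_TOKEN = re.compile(r"[A-Za-z]+|[0-9]+|[^\sA-Za-z0-9]")


def match_tokens(text: str) -> List[Tuple[str, int, int]]:
    """Tokenize for dictionary matching: ``(normalized_token, start, end)``.

    Letter runs (lowercased), digit runs and punctuation characters are
    tokens; hyphens and slashes are separators, mirroring
    :func:`normalize_surface` so dictionary and sentence tokenizations agree.
    """
    out = []
    for m in _MATCH_TOKEN.finditer(text):
        tok = m.group()
        if tok in ("-", "/"):
            continue
        out.append((tok.lower(), m.start(), m.end()))
    return out


@dataclass(frozen=True)
class DictionaryEntry:
    """A normalized lexicon row mapping a surface form to a namespace value."""

    surface: str
    namespace: str
    identifier: str
    semclass: str
    source_vocab: str
    normalized: str = ""

    def __post_init__(self):
        if not self.normalized:
            object.__setattr__(self, "normalized", normalize_surface(self.surface))
        expected = SEMCLASS_BY_NAMESPACE.get(self.namespace)
        if expected is not None and self.semclass != expected:
            raise LexiconError(
                f"semclass {self.semclass!r} inconsistent with namespace "
                f"{self.namespace!r} for surface {self.surface!r}"
            )

    @property
    def tokens(self) -> Tuple[str, ...]:
        return tuple(t for t, _, _ in match_tokens(self.surface))

    @property
    def nsid(self) -> Optional[NamespaceId]:
        if self.namespace == "PH":
            return None
        return NamespaceId(self.namespace, self.identifier)


@dataclass(frozen=True)
class EntityMention:
    """An in-sentence entity span; offsets are 0-based half-open on the raw text."""

    sentence_id: str
    start: int
    end: int
    text: str
    semclass: str
    nsid: Optional[NamespaceId] = None
    source: str = "internal"
    match_kind: str = "exact"

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class AcronymPair:
    long_form: str
    long_span: Tuple[int, int]
    short_form: str
    short_span: Tuple[int, int]

    def __post_init__(self):
        if len(self.short_form) >= len(self.long_form):
            raise LexiconError("short form must be shorter than long form")


@dataclass(frozen=True)
class GeneGoAssociation:
    gene: NamespaceId
    go_term: NamespaceId


DICTIONARY_COLUMNS = ("surface", "namespace", "identifier", "semclass", "source_vocab")
STANDOFF_COLUMNS = (
    "sentence_id", "start", "end", "text", "semclass", "namespace", "identifier", "source",
)


def load_dictionary(path) -> List[DictionaryEntry]:
    """Load a dictionary TSV (columns surface, namespace, identifier, semclass,
    source_vocab; header row optional)."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if tuple(row[:5]) == DICTIONARY_COLUMNS:
                continue
            surface, namespace, identifier, semclass, source_vocab = row[:5]
            entries.append(
                DictionaryEntry(surface, namespace, identifier, semclass, source_vocab)
            )
    return entries


def load_standoff(path) -> Dict[str, List[EntityMention]]:
    """Load standoff entity annotations keyed by source (pubtator/becas/gold)."""
    by_source: Dict[str, List[EntityMention]] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if tuple(row[:8]) == STANDOFF_COLUMNS:
                continue
            sid, start, end, text, semclass, namespace, identifier, source = row[:8]
            nsid = NamespaceId(namespace, identifier) if namespace and identifier else None
            by_source.setdefault(source, []).append(
                EntityMention(sid, int(start), int(end), text, semclass, nsid, source)
            )
    return by_source


class LexiconIndex:
    """First-token index over dictionary entries, grouped by source vocabulary."""

    def __init__(self, entries: Iterable[DictionaryEntry]):
        self.entries = list(entries)
        self.by_vocab: Dict[str, Dict[str, List[DictionaryEntry]]] = {}
        for e in self.entries:
            toks = e.tokens
            if not toks:
                continue
            bucket = self.by_vocab.setdefault(e.source_vocab, {}).setdefault(toks[0], [])
            bucket.append(e)
        for vocab in self.by_vocab.values():
            for bucket in vocab.values():
                bucket.sort(key=lambda e: -len(e.tokens))

    def vocabularies(self) -> List[str]:
        return sorted(self.by_vocab)

    def entries_of_class(self, semclass: str) -> List[DictionaryEntry]:
        return [e for e in self.entries if e.semclass == semclass]


def dictionary_lookup(
    text: str,
    sentence_id: str,
    entries: Iterable[DictionaryEntry],
    source: str = "internal",
) -> List[EntityMention]:
    """All maximal token-aligned exact matches of normalized dictionary surfaces.

    Greedy longest-match per source vocabulary; matches never start or end
    inside a token of the normalized sentence. Returns mentions sorted by span.
    """
    index = entries if isinstance(entries, LexiconIndex) else LexiconIndex(entries)
    if not index.entries:
        log.warning("dictionary_lookup called with an empty dictionary")
        return []
    toks = match_tokens(text)
    norm = [t for t, _, _ in toks]
    mentions = []
    for vocab, first_index in index.by_vocab.items():
        i = 0
        while i < len(toks):
            hit = None
            for entry in first_index.get(norm[i], ()):
                k = len(entry.tokens)
                if tuple(norm[i: i + k]) == entry.tokens:
                    hit = entry
                    break  # buckets sorted longest-first
            if hit is not None:
                start = toks[i][1]
                end = toks[i + len(hit.tokens) - 1][2]
                mentions.append(
                    EntityMention(
                        sentence_id, start, end, text[start:end],
                        hit.semclass, hit.nsid, source,
                        "exact" if hit.namespace != "PH" else "inferred",
                    )
                )
                i += len(hit.tokens)
            else:
                i += 1
    mentions.sort(key=lambda m: (m.start, -(m.end - m.start)))
    return mentions


def go_partial_candidates(
    text: str,
    go_entries: Iterable[DictionaryEntry],
    min_tokens: int = 2,
    max_tokens: int = 6,
) -> List[Tuple[Tuple[int, int], List[DictionaryEntry]]]:
    """Sentence n-grams that partially match GO entry names.

    A phrase partially matches an entry when its tokens occur as a contiguous
    subsequence of the entry's name tokens but are not the full name (full
    matches are found by :func:`dictionary_lookup`). Only maximal phrases are
    kept. Used as input to GO resolution and conflict handling.
    """
    entries = [e for e in go_entries if e.semclass in GO_CLASSES]
    toks = match_tokens(text)
    norm = [t for t, _, _ in toks]
    found: List[Tuple[Tuple[int, int], List[DictionaryEntry]]] = []
    covered: Set[Tuple[int, int]] = set()
    for n in range(min(max_tokens, len(norm)), min_tokens - 1, -1):
        for i in range(len(norm) - n + 1):
            gram = tuple(norm[i: i + n])
            span = (toks[i][1], toks[i + n - 1][2])
            if any(span[0] >= s and span[1] <= e for s, e in covered):
                continue
            hits = []
            for entry in entries:
                etoks = entry.tokens
                if len(etoks) <= n:
                    continue
                if any(etoks[j: j + n] == gram for j in range(len(etoks) - n + 1)):
                    hits.append(entry)
            if hits:
                found.append((span, hits))
                covered.add(span)
    found.sort(key=lambda x: x[0])
    return found


# ---------------------------------------------------------------------------
# Abbreviation handling (Schwartz–Hearst character alignment)

_PAREN = re.compile(r"\(([^()]+)\)")


def _valid_short_form(cand: str) -> bool:
    cand = cand.strip()
    if not (2 <= len(cand) <= 10) or len(cand.split()) > 2:
        return False
    if not cand[0].isalnum() or not any(c.isalpha() for c in cand):
        return False
    return True


def _best_long_form(short: str, long: str) -> Optional[int]:
    """Classic right-to-left alignment; returns the start index of the long
    form within ``long`` or None when alignment fails."""
    s_idx = len(short) - 1
    l_idx = len(long) - 1
    while s_idx >= 0:
        ch = short[s_idx].lower()
        if not ch.isalnum():
            s_idx -= 1
            continue
        while (l_idx >= 0 and long[l_idx].lower() != ch) or (
            s_idx == 0 and l_idx > 0 and long[l_idx - 1].isalnum()
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        l_idx -= 1
        s_idx -= 1
    return l_idx + 1


def detect_acronyms(text: str) -> List[AcronymPair]:
    """Find long-form/short-form pairs in parenthesized definition patterns.

    Handles both ``LONG (SHORT)`` and ``SHORT (LONG)`` orders using the
    character-alignment criterion (every short-form character must align into
    the long form, its first character at a word start).
    """
    pairs = []
    for m in _PAREN.finditer(text):
        inner = m.group(1).strip()
        before = text[: m.start()].rstrip()
        if _valid_short_form(inner):
            short = inner
            window_words = before.split()
            if not window_words:
                continue
            n_words = min(len(window_words), len(short) + 5, len(short) * 2)
            candidate = " ".join(window_words[-n_words:])
            rel = _best_long_form(short, candidate)
            if rel is None:
                continue
            # trim to the start of the word containing rel
            word_start = candidate.rfind(" ", 0, rel) + 1
            long_form = candidate[word_start:]
            if len(long_form.split()) < 2 and len(long_form) <= len(short):
                continue
            long_start = before.rfind(long_form)
            if long_start < 0:
                continue
            inner_off = text.index(inner, m.start())
            try:
                pairs.append(
                    AcronymPair(
                        long_form, (long_start, long_start + len(long_form)),
                        short, (inner_off, inner_off + len(short)),
                    )
                )
            except LexiconError:
                continue
        else:
            # SHORT (LONG): the word before the parenthesis as short form
            words = before.split()
            if not words:
                continue
            short = words[-1]
            if not _valid_short_form(short):
                continue
            if _best_long_form(short, inner) is None:
                continue
            short_start = before.rfind(short)
            inner_off = text.index(inner, m.start())
            try:
                pairs.append(
                    AcronymPair(
                        inner, (inner_off, inner_off + len(inner)),
                        short, (short_start, short_start + len(short)),
                    )
                )
            except LexiconError:
                continue
    return pairs


def infer_class_from_acronym(
    pairs: Sequence[AcronymPair],
    mentions: Sequence[EntityMention],
    text: str,
    sentence_id: str,
) -> List[EntityMention]:
    """Propagate the semantic class (and nsid) of classed long forms to every
    occurrence of their short forms; conflicting long forms for one short form
    keep the pair nearest the short-form occurrence."""
    out = list(mentions)
    by_short: Dict[str, List[Tuple[AcronymPair, EntityMention]]] = {}
    for pair in pairs:
        donor = None
        for m in mentions:
            if m.start < pair.long_span[1] and pair.long_span[0] < m.end:
                donor = m
                break
        if donor is not None:
            by_short.setdefault(pair.short_form, []).append((pair, donor))
    for short, donors in by_short.items():
        if len({d.semclass for _, d in donors}) > 1:
            log.warning("conflicting long forms for short form %r", short)
        for occ in re.finditer(rf"(?<![A-Za-z0-9]){re.escape(short)}(?![A-Za-z0-9])", text):
            span = (occ.start(), occ.end())
            # nearest pair to this occurrence wins on conflict
            _, donor = min(donors, key=lambda pd: abs(pd[0].short_span[0] - span[0]))
            if any(
                m.start < span[1] and span[0] < m.end and m.semclass == donor.semclass
                for m in out
            ):
                continue
            out.append(
                EntityMention(
                    sentence_id, span[0], span[1], short,
                    donor.semclass, donor.nsid, donor.source, "inferred",
                )
            )
    out.sort(key=lambda m: (m.start, -(m.end - m.start)))
    return out


def edit_similarity(a: str, b: str) -> float:
    """Normalized character edit similarity of the normalized surfaces, in [0,1]."""
    na, nb = normalize_surface(a), normalize_surface(b)
    if not na or not nb:
        return 1.0 if na == nb else 0.0
    dist = edlib.align(na, nb)["editDistance"]
    return 1.0 - dist / max(len(na), len(nb))


def propagate_class_by_similarity(
    candidate_text: str,
    candidate_span: Tuple[int, int],
    sentence_id: str,
    classed: Sequence[EntityMention],
    entries: Iterable[DictionaryEntry],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> Optional[EntityMention]:
    """Assign the class of the most edit-similar classed mention (>= threshold)
    to an unclassed candidate phrase, then re-normalize the candidate against
    the dictionary of that class to obtain its own namespace value.

    Similarity ties across different classes yield no assignment.
    """
    scored = [(edit_similarity(candidate_text, m.text), m) for m in classed]
    scored = [(s, m) for s, m in scored if s >= threshold]
    if not scored:
        return None
    best = max(s for s, _ in scored)
    best_classes = {m.semclass for s, m in scored if s == best}
    if len(best_classes) > 1:
        log.warning(
            "similarity tie across classes %s for candidate %r", best_classes, candidate_text
        )
        return None
    semclass = best_classes.pop()
    nsid = None
    match_kind = "inferred"
    cand_norm = normalize_surface(candidate_text)
    best_entry_sim = 0.0
    for entry in entries:
        if entry.semclass != semclass or entry.namespace == "PH":
            continue
        sim = edit_similarity(cand_norm, entry.normalized)
        if sim > best_entry_sim:
            best_entry_sim, nsid = sim, entry.nsid
    if best_entry_sim < threshold:
        nsid = None
    elif best_entry_sim < 1.0:
        match_kind = "fuzzy"
    else:
        match_kind = "exact"
    return EntityMention(
        sentence_id, candidate_span[0], candidate_span[1], candidate_text,
        semclass, nsid, "internal", match_kind,
    )


# ---------------------------------------------------------------------------
# GO resolution

def _ancestors(value: str, parents: Mapping[str, Sequence[str]]) -> Set[str]:
    out: Set[str] = set()
    frontier = list(parents.get(value, ()))
    while frontier:
        v = frontier.pop()
        if v in out:
            continue
        out.add(v)
        frontier.extend(parents.get(v, ()))
    return out


def resolve_go_term(
    phrase: str,
    candidates: Sequence[NamespaceId],
    gene_context: Sequence[NamespaceId],
    assoc: Iterable[GeneGoAssociation],
    ontology_parents: Mapping[str, Sequence[str]],
) -> NamespaceId:
    """Pick one GO candidate for a phrase.

    Default: the most specific candidate (one no other candidate descends
    from). Override: an ancestor candidate wins when a gene in context has a
    recorded association to it ("prefers the parent over the child").
    """
    if not candidates:
        raise LexiconError("resolve_go_term requires at least one candidate")
    if len(candidates) == 1:
        return candidates[0]
    genes = {g.value for g in gene_context}
    associated = {
        a.go_term.value
        for a in assoc
        if a.gene.value in genes and a.go_term.value in {c.value for c in candidates}
    }
    if associated:
        pool = [c for c in candidates if c.value in associated]
    else:
        anc = {c.value: _ancestors(c.value, ontology_parents) for c in candidates}
        values = {c.value for c in candidates}
        # most specific: no *other* candidate is a descendant of it
        pool = [
            c for c in candidates
            if not any(c.value in anc[other] for other in values if other != c.value)
        ] or list(candidates)
    if len(pool) > 1:
        log.info("incomparable GO candidates for %r; choosing longest name", phrase)
        pool.sort(key=lambda c: (-len(c.value), c.value))
    return pool[0]


def resolve_cross_dictionary_conflict(
    phrase: str,
    matches: Sequence[EntityMention],
    mode: str = "phase1",
    class_priority: Sequence[str] = DEFAULT_CLASS_PRIORITY,
) -> EntityMention:
    """Resolve a phrase matching multiple dictionary sources.

    phase1: an exact match beats a partial (fuzzy) match; ties between exact
    matches fall back to the class priority order (disease > bioprocess >
    chemical by default). phase2_gold: a match against the gold-entity
    dictionary beats any ordinary match.
    """
    if not matches:
        raise LexiconError("no matches to resolve")
    if len(matches) == 1:
        return matches[0]
    pool = list(matches)
    if mode == "phase2_gold":
        gold = [m for m in pool if m.source == "gold"]
        if gold:
            pool = gold
    exact = [m for m in pool if m.match_kind == "exact"]
    if exact and len(exact) < len(pool):
        pool = exact
    elif len(exact) > 1:
        rank = {c: i for i, c in enumerate(class_priority)}
        log.info("multiple exact matches for %r; applying class priority", phrase)
        pool = sorted(exact, key=lambda m: rank.get(m.semclass, len(class_priority)))
    return pool[0]


# ---------------------------------------------------------------------------
# Ensemble merging

def _longest(ms: Iterable[EntityMention]) -> EntityMention:
    return max(ms, key=lambda m: (m.end - m.start, -m.start))


def merge_ensemble(per_source: Mapping[str, Sequence[EntityMention]]) -> List[EntityMention]:
    """Merge mentions from pubtator/becas/internal by the priority rules.

    Gene/chemical/disease spans: pubtator wins; absent pubtator, becas and the
    internal dictionary must agree (span overlap, same class), or an internal
    exact dictionary match alone is accepted. GO-class spans: becas wins,
    supplemented by internal. Overlapping same-class survivors with different
    boundaries keep the longest span.
    """
    pubtator = list(per_source.get("pubtator", ()))
    becas = list(per_source.get("becas", ()))
    internal = list(per_source.get("internal", ()))
    accepted: List[EntityMention] = []

    def covered(m: EntityMention) -> bool:
        return any(a.overlaps(m) and a.semclass == m.semclass for a in accepted)

    accepted.extend(m for m in pubtator if m.semclass in GCD_CLASSES)
    for m in becas:
        if m.semclass not in GCD_CLASSES or covered(m):
            continue
        partners = [
            i for i in internal
            if i.semclass == m.semclass and i.overlaps(m)
        ]
        if partners:
            accepted.append(_longest([m] + partners))
    for m in internal:
        # "inferred" = propagated from an exact long-form match via an
        # abbreviation pair; it inherits the exact-match exception
        if m.semclass in GCD_CLASSES and m.match_kind in ("exact", "inferred") \
                and not covered(m):
            accepted.append(m)
    accepted.extend(m for m in becas if m.semclass in GO_CLASSES and not covered(m))
    for m in internal:
        if m.semclass in GO_CLASSES and not covered(m):
            accepted.append(m)

    # longest-span rule among surviving same-class overlaps
    survivors: List[EntityMention] = []
    for m in sorted(accepted, key=lambda m: (-(m.end - m.start), m.start)):
        if any(s.overlaps(m) and s.semclass == m.semclass for s in survivors):
            continue
        survivors.append(m)
    survivors.sort(key=lambda m: (m.start, -(m.end - m.start)))
    return survivors


def gold_constrained_lookup(
    text: str,
    sentence_id: str,
    gold_entries: Iterable[DictionaryEntry],
    ensemble: Optional[Sequence[EntityMention]] = None,
) -> List[EntityMention]:
    """Dictionary lookup restricted to the gold entity list; gold matches
    replace conflicting ensemble mentions at overlapping spans."""
    gold_entries = list(gold_entries)
    if not gold_entries:
        return []
    matches = [
        replace(m, source="gold")
        for m in dictionary_lookup(text, sentence_id, gold_entries, source="gold")
    ]
    if ensemble is None:
        return matches
    kept = [m for m in ensemble if not any(g.overlaps(m) for g in matches)]
    out = sorted(kept + matches, key=lambda m: (m.start, -(m.end - m.start)))
    return out
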