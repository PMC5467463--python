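"""Multi-level scoring of predicted vs gold BEL statements.

Statements are compared after canonicalization at six granularities: term
(namespace values only), function (full serialized function expressions),
function_secondary (function keyword paired with the innermost namespace
value), relation (the full canonical triple), relation_secondary (innermost
subject value, relation, innermost object value) and statement (the canonical
serialization). The secondary levels award partial credit, so their true
positive counts can only be larger: statement tp <= relation tp <=
relation_secondary tp on any comparison.

Scores are micro-averaged over sentences; duplicate items within a sentence
collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

from .core import (
    BELStatement,
    BELTerm,
    NamespaceId,
    canonicalize,
    serialize_nsid,
    serialize_statement,
    serialize_term,
)

log = logging.getLogger(__name__)

LEVELS = (
    "term",
    "function",
    "function_secondary",
    "relation",
    "relation_secondary",
    "statement",
)


@dataclass(frozen=True)
class ScoreReport:
    """Micro-averaged precision/recall/F (percentages) at one level."""

    level: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _nsids(term: BELTerm) -> List[NamespaceId]:
    out = []
    for arg in term.args:
        if isinstance(arg, NamespaceId):
            out.append(arg)
        elif isinstance(arg, BELTerm):
            out.extend(_nsids(arg))
    return out


def decompose(stmt: BELStatement, level: str) -> FrozenSet:
    """Decompose a statement into the comparable items of one level."""
    stmt = canonicalize(stmt)
    subj, obj = stmt.subject, stmt.object
    if level == "term":
        return frozenset(serialize_nsid(n) for n in _nsids(subj) + _nsids(obj))
    if level == "function":
        return frozenset({serialize_term(subj), serialize_term(obj)})
    if level == "function_secondary":
        items = set()
        for side in (subj, obj):
            for n in _nsids(side):
                items.add((side.function, serialize_nsid(n)))
        return frozenset(items)
    if level == "relation":
        return frozenset(
            {(serialize_term(subj), stmt.relation.long, serialize_term(obj))}
        )
    if level == "relation_secondary":
        return frozenset(
            (serialize_nsid(s), stmt.relation.long, serialize_nsid(o))
            for s in _nsids(subj)
            for o in _nsids(obj)
        )
    if level == "statement":
        return frozenset({serialize_statement(stmt)})
    raise ValueError(f"unknown evaluation level {level!r}")


Records = Mapping[str, Sequence[BELStatement]]


def score(pred: Records, gold: Records, level: str) -> ScoreReport:
    """Micro-averaged set comparison of decomposed items per sentence.

    Sentence ids present only in the predictions count as all false
    positives; ids present only in the gold as all false negatives.
    """
    tp = fp = fn = 0
    unknown = set(pred) - set(gold)
    if unknown:
        log.warning("%d prediction sentence ids absent from gold", len(unknown))
    for sid in sorted(set(pred) | set(gold)):
        p_items = frozenset().union(*(decompose(s, level) for s in pred.get(sid, ())), frozenset())
        g_items = frozenset().union(*(decompose(s, level) for s in gold.get(sid, ())), frozenset())
        tp += len(p_items & g_items)
        fp += len(p_items - g_items)
        fn += len(g_items - p_items)
    return ScoreReport(level, tp, fp, fn)


def score_all(pred: Records, gold: Records) -> Dict[str, ScoreReport]:
    return {level: score(pred, gold, level) for level in LEVELS}


def write_score_report(path, reports: Mapping[str, ScoreReport]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("level\ttp\tfp\tfn\tprecision\trecall\tf\n")
        for level in LEVELS:
            if level not in reports:
                continue
            r = reports[level]
            fh.write(
                f"{r.level}\t{r.tp}\t{r.fp}\t{r.fn}"
                f"\t{r.precision:.2f}\t{r.recall:.2f}\t{r.f_measure:.2f}\n"
            )
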