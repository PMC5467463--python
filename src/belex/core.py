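"""BEL short-form data model: terms, relations and causal statements.

Covers the 1.0 short-form subset an evidence-sentence extractor needs:
abundance functions ``p``/``r``/``a``/``bp``/``path``, ``complex``, the
activity/location wrappers ``act``/``tloc``/``tscript``/``kin``/``cat``,
``pmod()`` protein-modification arguments and the four causal relations
(increases ``->``, decreases ``-|``, directlyIncreases ``=>``,
directlyDecreases ``=|``).

Serialization is deterministic: no whitespace outside quoted values, values
double-quoted exactly when they contain a character outside ``[A-Za-z0-9_-]``,
and ``complex()`` arguments sorted under :func:`canonicalize` so physically
unordered complexes compare equal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Union

log = logging.getLogger(__name__)

DEFAULT_NAMESPACES = ("HGNC", "MGI", "EGID", "CHEBI", "GOBP", "GOCC", "MESHD", "PH")

_registered_namespaces = set(DEFAULT_NAMESPACES)

#: one-letter codes of the 20 standard amino acids
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

SIMPLE_FUNCTIONS = frozenset({"p", "r", "a", "bp", "path"})
WRAPPER_FUNCTIONS = frozenset({"act", "tloc", "tscript", "kin", "cat"})
ALL_FUNCTIONS = SIMPLE_FUNCTIONS | WRAPPER_FUNCTIONS | {"complex"}

_UNQUOTED_VALUE = re.compile(r"[A-Za-z0-9_-]+\Z")


class BelError(Exception):
    """Base class for BEL model errors."""


class InvalidTermError(BelError):
    """A term violates the arity rules of its function keyword."""

    def __init__(self, function: str, message: str):
        self.function = function
        super().__init__(f"invalid {function}() term: {message}")


class BelParseError(BelError):
    """Malformed BEL text; ``offset`` is the character position of the fault."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (at offset {offset})")


def register_namespace(keyword: str) -> None:
    """Register an additional namespace keyword (config-extensible set)."""
    _registered_namespaces.add(keyword)


def registered_namespaces() -> frozenset:
    return frozenset(_registered_namespaces)


@dataclass(frozen=True)
class NamespaceId:
    """A namespace-qualified value such as ``HGNC:PDE3B`` or ``MESHD:"Autoimmune Diseases"``."""

    namespace: str
    value: str

    def __post_init__(self):
        if not self.value:
            raise BelError("namespace value must be non-empty")
        if self.namespace not in _registered_namespaces:
            raise BelError(f"unknown namespace keyword {self.namespace!r}")


@dataclass(frozen=True)
class Modifier:
    """A protein-modification argument; only phosphorylation (code P) is emitted."""

    code: str = "P"
    residue: str = "S"
    position: int = 1

    def __post_init__(self):
        if self.residue not in AMINO_ACIDS:
            raise BelError(f"unknown amino-acid code {self.residue!r}")
        if self.position < 1:
            raise BelError("modification position must be >= 1")


TermArg = Union[NamespaceId, "BELTerm", Modifier]


@dataclass(frozen=True)
class BELTerm:
    """A BEL function applied to an ordered argument list."""

    function: str
    args: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "args", tuple(self.args))


class Relation(Enum):
    """The four causal relations; long name and arrow form are a fixed bijection."""

    INCREASES = ("increases", "->")
    DECREASES = ("decreases", "-|")
    DIRECTLY_INCREASES = ("directlyIncreases", "=>")
    DIRECTLY_DECREASES = ("directlyDecreases", "=|")

    @property
    def long(self) -> str:
        return self.value[0]

    @property
    def arrow(self) -> str:
        return self.value[1]

    @classmethod
    def from_token(cls, token: str) -> "Relation":
        for rel in cls:
            if token in rel.value:
                return rel
        raise BelError(f"unknown relation token {token!r}")


RELATION_TOKENS = tuple(tok for rel in Relation for tok in rel.value)


@dataclass(frozen=True)
class BELStatement:
    """``subject relation object`` with provenance (sentence id, rule id).

    Provenance is excluded from equality so statement sets compare on content.
    """

    subject: BELTerm
    relation: Relation
    object: BELTerm
    provenance: tuple = field(default=(), compare=False)


def validate_term(term: BELTerm) -> None:
    """Check the arity invariants of ``term`` recursively.

    p/r/a/bp/path take one NamespaceId plus optional Modifiers; complex takes
    >= 2 term arguments; act/tloc/tscript/kin/cat take exactly one term.
    """
    fn = term.function
    if fn not in ALL_FUNCTIONS:
        raise InvalidTermError(fn, "unknown function keyword")
    if fn in SIMPLE_FUNCTIONS:
        nsids = [a for a in term.args if isinstance(a, NamespaceId)]
        mods = [a for a in term.args if isinstance(a, Modifier)]
        if len(nsids) != 1 or len(nsids) + len(mods) != len(term.args):
            raise InvalidTermError(
                fn, "takes exactly one namespace value plus optional pmod() arguments"
            )
        if term.args[0] is not nsids[0]:
            raise InvalidTermError(fn, "namespace value must be the first argument")
    elif fn == "complex":
        if len(term.args) < 2 or not all(isinstance(a, BELTerm) for a in term.args):
            raise InvalidTermError(fn, "takes >= 2 term arguments")
        for a in term.args:
            validate_term(a)
    else:  # wrappers
        if len(term.args) != 1 or not isinstance(term.args[0], BELTerm):
            raise InvalidTermError(fn, "takes exactly one term argument")
        validate_term(term.args[0])


def serialize_nsid(nsid: NamespaceId) -> str:
    if _UNQUOTED_VALUE.match(nsid.value):
        return f"{nsid.namespace}:{nsid.value}"
    escaped = nsid.value.replace('"', '\\"')
    return f'{nsid.namespace}:"{escaped}"'


def serialize_modifier(mod: Modifier) -> str:
    return f"pmod({mod.code},{mod.residue},{mod.position})"


def serialize_term(term: BELTerm, validate: bool = True) -> str:
    """Serialize ``term`` deterministically (no whitespace outside quotes)."""
    if validate:
        validate_term(term)
    parts = []
    for arg in term.args:
        if isinstance(arg, NamespaceId):
            parts.append(serialize_nsid(arg))
        elif isinstance(arg, Modifier):
            parts.append(serialize_modifier(arg))
        else:
            parts.append(serialize_term(arg, validate=False))
    return f"{term.function}({','.join(parts)})"


def serialize_statement(stmt: BELStatement, style: str = "long") -> str:
    """Render ``<subject> <relation> <object>``; ``style`` is ``long`` or ``arrow``."""
    rel = stmt.relation.long if style == "long" else stmt.relation.arrow
    return f"{serialize_term(stmt.subject)} {rel} {serialize_term(stmt.object)}"


class _Parser:
    """Recursive-descent parser for serialized terms and statements."""

    def __init__(self, text: str, lenient: bool = False):
        self.text = text
        self.pos = 0
        self.lenient = lenient

    def error(self, message: str):
        raise BelParseError(message, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self):
        while self.peek() == " ":
            self.pos += 1

    def expect(self, ch: str):
        if self.peek() != ch:
            self.error(f"expected {ch!r}")
        self.pos += 1

    def ident(self) -> str:
        m = re.match(r"[A-Za-z][A-Za-z0-9_-]*", self.text[self.pos:])
        if not m:
            self.error("expected identifier")
        self.pos += m.end()
        return m.group()

    def quoted(self) -> str:
        self.expect('"')
        out = []
        while True:
            ch = self.peek()
            if not ch:
                self.error("unterminated quoted value")
            if ch == "\\" and self.pos + 1 < len(self.text):
                out.append(self.text[self.pos + 1])
                self.pos += 2
                continue
            if ch == '"':
                self.pos += 1
                return "".join(out)
            out.append(ch)
            self.pos += 1

    def term(self) -> BELTerm:
        fn = self.ident()
        if fn not in ALL_FUNCTIONS and fn != "pmod":
            self.pos -= len(fn)
            self.error(f"unknown function keyword {fn!r}")
        self.expect("(")
        args = []
        while True:
            self.skip_ws()
            args.append(self.argument())
            self.skip_ws()
            if self.peek() == ",":
                self.pos += 1
                continue
            break
        self.expect(")")
        if fn == "pmod":
            return self._as_modifier(args)
        return BELTerm(fn, tuple(args))

    def _as_modifier(self, args) -> Modifier:
        vals = []
        for a in args:
            if isinstance(a, NamespaceId):
                self.error("pmod() takes plain arguments")
            vals.append(a)
        if len(vals) != 3:
            self.error("pmod() takes (code,residue,position)")
        code, residue, position = vals
        try:
            return Modifier(str(code), str(residue), int(position))
        except (BelError, ValueError) as exc:
            self.error(str(exc))

    def argument(self):
        start = self.pos
        m = re.match(r"[A-Za-z][A-Za-z0-9_-]*", self.text[self.pos:])
        if not m:
            if self.peek().isdigit():
                d = re.match(r"\d+", self.text[self.pos:])
                self.pos += d.end()
                return d.group()
            self.error("expected argument")
        word = m.group()
        after = self.pos + m.end()
        nxt = self.text[after] if after < len(self.text) else ""
        if nxt == "(":
            return self.term()
        if nxt == ":":
            self.pos = after + 1
            if self.peek() == '"':
                value = self.quoted()
            else:
                vm = re.match(r"[A-Za-z0-9_-]+", self.text[self.pos:])
                if not vm:
                    self.error("expected namespace value")
                value = vm.group()
                self.pos += vm.end()
            if word not in _registered_namespaces:
                if self.lenient:
                    log.warning("unknown namespace %r accepted in lenient mode", word)
                    register_namespace(word)
                else:
                    self.pos = start
                    self.error(f"unknown namespace keyword {word!r}")
            return NamespaceId(word, value)
        # bare word (pmod code/residue)
        self.pos = after
        return word


def parse_term(text: str, lenient: bool = False) -> BELTerm:
    """Parse a serialized term; inverse of :func:`serialize_term`."""
    if not text:
        raise BelParseError("empty input", 0)
    p = _Parser(text, lenient=lenient)
    p.skip_ws()
    term = p.term()
    p.skip_ws()
    if p.pos != len(text):
        p.error("trailing characters after term")
    if not isinstance(term, BELTerm):
        raise BelParseError("expected a term, got a pmod() argument", 0)
    validate_term(term)
    return term


def _split_relation(text: str):
    """Locate the relation token at depth 0 outside quoted values."""
    depth = 0
    in_quote = False
    i = 0
    while i < len(text):
        ch = text[i]
        if in_quote:
            if ch == "\\":
                i += 2
                continue
            if ch == '"':
                in_quote = False
        elif ch == '"':
            in_quote = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == " " and depth == 0:
            for tok in RELATION_TOKENS:
                cand = text[i + 1: i + 1 + len(tok)]
                if cand == tok and text[i + 1 + len(tok): i + 2 + len(tok)] == " ":
                    return text[:i], Relation.from_token(tok), text[i + 2 + len(tok):]
        i += 1
    raise BelParseError("no causal relation found in statement", 0)


def parse_statement(text: str, lenient: bool = False, provenance: tuple = ()) -> BELStatement:
    """Parse ``<subject> <relation> <object>`` in long or arrow style."""
    left, rel, right = _split_relation(text.strip())
    return BELStatement(
        subject=parse_term(left.strip(), lenient=lenient),
        relation=rel,
        object=parse_term(right.strip(), lenient=lenient),
        provenance=provenance,
    )


def canonicalize(obj):
    """Return the canonical form: complex args sorted by serialization; idempotent."""
    if isinstance(obj, BELStatement):
        return BELStatement(
            canonicalize(obj.subject),
            obj.relation,
            canonicalize(obj.object),
            obj.provenance,
        )
    if isinstance(obj, BELTerm):
        args = tuple(
            canonicalize(a) if isinstance(a, BELTerm) else a for a in obj.args
        )
        if obj.function == "complex":
            args = tuple(sorted(args, key=lambda a: serialize_term(a, validate=False)))
        return BELTerm(obj.function, args)
    return obj


def read_statement_file(path, lenient: bool = False):
    """Read a tab-separated statement file: ``sentence_id TAB statement`` per line.

    Returns a list of ``(sentence_id, BELStatement)`` pairs.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                sid, text = line.split("\t", 1)
            except ValueError:
                raise BelError(f"{path}:{lineno}: expected 'sentence_id<TAB>statement'")
            out.append((sid, parse_statement(text, lenient=lenient, provenance=(sid, "file"))))
    return out


def write_statement_file(path, items: Iterable, style: str = "long") -> None:
    """Write ``(sentence_id, BELStatement)`` pairs as a tab-separated file."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, stmt in items:
            fh.write(f"{sid}\t{serialize_statement(stmt, style=style)}\n")
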