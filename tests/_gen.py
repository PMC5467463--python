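"""Seeded random generators for valid BEL terms/statements (test helpers)."""

import random

from belex import core

_VALUES = ["PDE3B", "BMP2", "Autoimmune Diseases", "response to stress", "GK",
           "x_1-y", "IL6R", "Obesity", "a b c", "T-2"]
_NAMESPACES = ["HGNC", "MGI", "EGID", "CHEBI", "GOBP", "GOCC", "MESHD", "PH"]
_SIMPLE = ["p", "r", "a", "bp", "path"]
_WRAPPERS = ["act", "tloc", "tscript", "kin", "cat"]


def random_term(rng: random.Random, depth: int = 0) -> core.BELTerm:
    """A random valid BEL term drawn from the serializer's grammar."""
    roll = rng.random()
    if depth >= 3 or roll < 0.55:
        nsid = core.NamespaceId(rng.choice(_NAMESPACES), rng.choice(_VALUES))
        args = [nsid]
        if rng.random() < 0.3:
            args.append(core.Modifier("P", rng.choice("STY"), rng.randint(1, 999)))
        return core.BELTerm(rng.choice(_SIMPLE), tuple(args))
    if roll < 0.8:
        return core.BELTerm(rng.choice(_WRAPPERS), (random_term(rng, depth + 1),))
    n = rng.randint(2, 3)
    return core.BELTerm("complex", tuple(random_term(rng, depth + 1) for _ in range(n)))


def random_statement(rng: random.Random) -> core.BELStatement:
    return core.BELStatement(
        random_term(rng), rng.choice(list(core.Relation)), random_term(rng)
    )
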