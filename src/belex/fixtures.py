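"""Fixture corpus: worked evidence sentences and a synthetic template corpus.

The worked corpus packages real evidence sentences from the biomedical
literature (protein–protein interactions, causal regulation, transport and
phosphorylation events) together with mini-dictionaries covering their
entities, standoff annotations standing in for external NER services, gold
entity lists for the gold-constrained mode, ontology scaffolding for GO
resolution and hand-assembled gold BEL statements.

The synthetic corpus slots dictionary symbols into the extraction rule
templates (regulation, coordination, binding, transport, phosphorylation,
passive voice, activity) and derives the gold statements from the same
template, so recovery against it is a closed-loop check of the full pipeline.
All output is deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .core import BELStatement, parse_statement
from .lexicon import (
    DICTIONARY_COLUMNS,
    STANDOFF_COLUMNS,
    DictionaryEntry,
    GeneGoAssociation,
)
from .core import NamespaceId

# ---------------------------------------------------------------------------
# Worked sentences

WORKED_SENTENCES: List[Tuple[str, str]] = [
    ("W01", "The vasoactive intestinal peptide (VIP) and the pituitary adenylate "
            "cyclase-activating polypeptide (PACAP), two immunomodulatory neuropeptides "
            "that affect both innate and acquired immunity, down-regulate IL-12 p40 and "
            "inducible NO synthase expression in LPS/IFN-gamma-stimulated macrophages."),
    ("W02", "FcgammaRIIB inhibits intracellular signaling upon ligation of IgG-immune "
            "complexes, and can suppress inflammation and autoimmunity."),
    ("W03", "Tip60 and the transcriptional repressor ZEB (zinc finger E box binding "
            "protein) interact specifically in the yeast two-hybrid system and "
            "additively inhibit the CD4 enhancer/promoter activity in Jurkat cells."),
    ("W04", "AKAP220 fragment is a competitive inhibitor of PP1c activity."),
    ("W05", "P21-activated protein kinase gamma-PAK (Pak2, PAK I) is cleaved by CPP32."),
    ("W06", "More importantly, the Dnmt1 knockdown blocked the methionine-induced "
            "reelin and GAD67 mRNA down-regulation."),
    ("W07", "endoG represents a caspase-independent apoptotic pathway initiated from "
            "the mitochondria."),
    ("W08", "FoxO1 protects beta cells against oxidative stress by forming a complex "
            "with the promyelocytic leukemia protein Pml."),
    ("W09", "In the absence of CdCl2 pretreatment, ionizing radiation increased both "
            "expression and phosphorylation of c-Jun."),
    ("W10", "Dexamethasone blocked calcium ionophore-induced ICAM-1 expression."),
    ("W11", "Gi proteins are required for LPA-mediated mitogenesis."),
    ("W12", "Lovastatin decreased the levels of Gi alpha(1) and Gi alpha(2) in cell "
            "membranes."),
    ("W13", "Aldose reductase (AR) converts glucose to sorbitol, and inhibition of the "
            "AR by tolrestat normalized the sorbitol levels."),
    ("W14", "Treatment with bone morphogenetic protein-2 increased the expression of "
            "ICAM-1."),
    ("W15", "The anti-apoptotic protein Bcl-x(L) closes VDAC by binding to it directly."),
    # function-mapping sentences: each embeds one mapping-table phrase
    ("T01", "Insulin induces phosphorylation of PDE3B on serine-273."),
    ("T02", "Celastrol induces translocation of HSF1 from the cytoplasm to the nucleus."),
    ("T03", "TNF induces expression of ICAM-1."),
    ("T04", "Leptin deficiency induces truncal obesity."),
    ("T05", "The interaction of cyclin A1 with E2F-1 enhances apoptosis."),
    ("T06", "Cyclin A1 was complexed with CDK2 in leukemic cells."),
    ("T07", "Insulin enhances glycerol kinase enzymatic activity."),
    ("T08", "Signaling by the IL-6 receptor activates STAT3."),
    # placeholder behavior: recognized but unnormalizable process
    ("P01", "endoG induces the caspase-independent apoptotic pathway."),
]

# (surface, namespace, identifier, semclass, source_vocab)
DICTIONARY_ROWS: List[Tuple[str, str, str, str, str]] = [
    ("bone morphogenetic protein-2", "HGNC", "BMP2", "gene_protein", "Entrez"),
    ("BMP2", "HGNC", "BMP2", "gene_protein", "Entrez"),
    ("Tip60", "HGNC", "KAT5", "gene_protein", "Entrez"),
    ("ZEB", "HGNC", "ZEB1", "gene_protein", "Entrez"),
    ("zinc finger E box binding protein", "HGNC", "ZEB1", "gene_protein", "Entrez"),
    ("CD4", "HGNC", "CD4", "gene_protein", "Entrez"),
    ("FcgammaRIIB", "HGNC", "FCGR2B", "gene_protein", "Entrez"),
    ("AKAP220", "HGNC", "AKAP11", "gene_protein", "Entrez"),
    ("PP1c", "HGNC", "PPP1CC", "gene_protein", "Entrez"),
    ("PDE3B", "HGNC", "PDE3B", "gene_protein", "Entrez"),
    ("HSF1", "HGNC", "HSF1", "gene_protein", "Entrez"),
    ("ICAM-1", "HGNC", "ICAM1", "gene_protein", "Entrez"),
    ("cyclin A1", "HGNC", "CCNA1", "gene_protein", "Entrez"),
    ("E2F-1", "HGNC", "E2F1", "gene_protein", "Entrez"),
    ("CDK2", "HGNC", "CDK2", "gene_protein", "Entrez"),
    ("glycerol kinase", "HGNC", "GK", "gene_protein", "Entrez"),
    ("STAT3", "HGNC", "STAT3", "gene_protein", "Entrez"),
    ("CPP32", "HGNC", "CASP3", "gene_protein", "Entrez"),
    ("gamma-PAK", "HGNC", "PAK2", "gene_protein", "Entrez"),
    ("Dnmt1", "HGNC", "DNMT1", "gene_protein", "Entrez"),
    ("reelin", "HGNC", "RELN", "gene_protein", "Entrez"),
    ("Bcl-x(L)", "HGNC", "BCL2L1", "gene_protein", "Entrez"),
    ("VDAC", "HGNC", "VDAC1", "gene_protein", "Entrez"),
    ("endoG", "MGI", "Endog", "gene_protein", "Entrez"),
    ("Aldose reductase", "HGNC", "AKR1B1", "gene_protein", "Entrez"),
    ("Gi alpha(1)", "HGNC", "GNAI1", "gene_protein", "Entrez"),
    ("Gi alpha(2)", "HGNC", "GNAI2", "gene_protein", "Entrez"),
    ("c-Jun", "HGNC", "JUN", "gene_protein", "Entrez"),
    ("FoxO1", "HGNC", "FOXO1", "gene_protein", "Entrez"),
    ("Pml", "HGNC", "PML", "gene_protein", "Entrez"),
    ("p300", "HGNC", "EP300", "gene_protein", "Entrez"),
    ("IL-6 receptor", "HGNC", "IL6R", "gene_protein", "Entrez"),
    ("vasoactive intestinal peptide", "HGNC", "VIP", "gene_protein", "Entrez"),
    ("VIP", "HGNC", "VIP", "gene_protein", "Entrez"),
    ("pituitary adenylate cyclase-activating polypeptide", "HGNC", "ADCYAP1",
     "gene_protein", "Entrez"),
    ("PACAP", "HGNC", "ADCYAP1", "gene_protein", "Entrez"),
    ("IL-12 p40", "HGNC", "IL12B", "gene_protein", "Entrez"),
    ("inducible NO synthase", "HGNC", "NOS2", "gene_protein", "Entrez"),
    ("Insulin", "HGNC", "INS", "gene_protein", "Entrez"),
    ("Leptin", "HGNC", "LEP", "gene_protein", "Entrez"),
    ("TNF", "HGNC", "TNF", "gene_protein", "Entrez"),
    # chemicals
    ("methionine", "CHEBI", "methionine", "chemical", "CTD"),
    ("calcium", "CHEBI", "calcium", "chemical", "CTD"),
    ("tolrestat", "CHEBI", "tolrestat", "chemical", "CTD"),
    ("Celastrol", "CHEBI", "celastrol", "chemical", "CTD"),
    ("Dexamethasone", "CHEBI", "dexamethasone", "chemical", "CTD"),
    ("Lovastatin", "CHEBI", "lovastatin", "chemical", "CTD"),
    ("LPA", "CHEBI", "lysophosphatidic acid", "chemical", "CTD"),
    # diseases
    ("obesity", "MESHD", "Obesity", "disease", "MeSH"),
    ("inflammation", "MESHD", "Inflammation", "disease", "MeSH"),
    ("autoimmunity", "MESHD", "Autoimmune Diseases", "disease", "MeSH"),
    ("oxidative stress", "MESHD", "Oxidative Stress", "disease", "MeSH"),
    # GO biological processes
    ("apoptosis", "GOBP", "apoptotic process", "bioprocess", "GO"),
    ("response to ionizing radiation", "GOBP", "response to ionizing radiation",
     "bioprocess", "GO"),
    ("cellular response to ionizing radiation", "GOBP",
     "cellular response to ionizing radiation", "bioprocess", "GO"),
    ("response to oxidative stress", "GOBP", "response to oxidative stress",
     "bioprocess", "GO"),
    ("cellular response to oxidative stress", "GOBP",
     "cellular response to oxidative stress", "bioprocess", "GO"),
    ("mitosis", "GOBP", "mitosis", "bioprocess", "GO"),
    ("positive regulation of cell proliferation", "GOBP",
     "positive regulation of cell proliferation", "bioprocess", "GO"),
    # GO cellular components
    ("cytoplasm", "GOCC", "cytoplasm", "cellcomponent", "GO"),
    ("nucleus", "GOCC", "nucleus", "cellcomponent", "GO"),
    ("mitochondria", "GOCC", "mitochondrion", "cellcomponent", "GO"),
    # class cues: recognized concept, no namespace value (placeholder class)
    ("caspase-independent apoptotic pathway", "PH", "Placeholder", "bioprocess", "cue"),
]

#: standoff annotations standing in for the external NER services
#: (sentence_id, surface, semclass, namespace, identifier, source)
STANDOFF_ROWS: List[Tuple[str, str, str, str, str, str]] = [
    ("W02", "FcgammaRIIB", "gene_protein", "HGNC", "FCGR2B", "pubtator"),
    ("W10", "calcium", "chemical", "CHEBI", "calcium", "pubtator"),
    ("W12", "Gi alpha(1)", "gene_protein", "HGNC", "GNAI1", "pubtator"),
    ("W12", "Lovastatin", "chemical", "CHEBI", "lovastatin", "becas"),
    ("W11", "mitogenesis", "bioprocess", "GOBP",
     "positive regulation of cell proliferation", "becas"),
]

#: gold entity list (phase-2 mode): same dictionary schema, source_vocab=gold
GOLD_ENTITY_ROWS: List[Tuple[str, str, str, str, str]] = [
    ("calcium ionophore", "CHEBI", "Calcium ionophore", "chemical", "gold"),
    ("Dexamethasone", "CHEBI", "dexamethasone", "chemical", "gold"),
    ("ICAM-1", "HGNC", "ICAM1", "gene_protein", "gold"),
    ("mitogenesis", "GOBP", "mitosis", "bioprocess", "gold"),
    ("LPA", "CHEBI", "lysophosphatidic acid", "chemical", "gold"),
    ("oxidative stress", "GOBP", "response to oxidative stress", "bioprocess", "gold"),
    ("FoxO1", "HGNC", "FOXO1", "gene_protein", "gold"),
    ("Pml", "HGNC", "PML", "gene_protein", "gold"),
]

#: GO child -> parents (by term name)
GO_PARENT_ROWS: List[Tuple[str, str]] = [
    ("cellular response to ionizing radiation", "response to ionizing radiation"),
    ("response to ionizing radiation", "response to radiation"),
    ("cellular response to oxidative stress", "response to oxidative stress"),
    ("response to oxidative stress", "response to stress"),
]

#: gene -> GO term associations used for normalization refinement
GENE_GO_ASSOC_ROWS: List[Tuple[str, str]] = [
    ("JUN", "response to ionizing radiation"),
]

#: hand-assembled gold BEL statements for the worked corpus
GOLD_STATEMENTS: List[Tuple[str, str]] = [
    ("W01", "p(HGNC:VIP) decreases p(HGNC:IL12B)"),
    ("W01", "p(HGNC:VIP) decreases p(HGNC:NOS2)"),
    ("W01", "p(HGNC:ADCYAP1) decreases p(HGNC:IL12B)"),
    ("W01", "p(HGNC:ADCYAP1) decreases p(HGNC:NOS2)"),
    ("W02", "p(HGNC:FCGR2B) decreases path(MESHD:Inflammation)"),
    ("W02", 'p(HGNC:FCGR2B) decreases path(MESHD:"Autoimmune Diseases")'),
    ("W03", "complex(p(HGNC:KAT5),p(HGNC:ZEB1)) decreases act(p(HGNC:CD4))"),
    ("W04", "p(HGNC:AKAP11) decreases act(p(HGNC:PPP1CC))"),
    # the curated reading of W05 uses catalytic/kinase activities; the
    # extractor's cleavage rule cannot produce it (documented known failure)
    ("W05", "cat(p(HGNC:CASP3)) directlyIncreases kin(p(HGNC:PAK2))"),
    # the curated reading of W06 resolves the double negation to increases;
    # the extractor reports the surface polarity (documented known failure)
    ("W06", "p(HGNC:DNMT1) increases a(CHEBI:methionine)"),
    ("W06", "a(CHEBI:methionine) increases p(HGNC:RELN)"),
    ("W09", 'bp(GOBP:"response to ionizing radiation") increases p(HGNC:JUN)'),
    ("W10", "a(CHEBI:dexamethasone) decreases p(HGNC:ICAM1)"),
    ("W12", "a(CHEBI:lovastatin) decreases p(HGNC:GNAI1)"),
    ("W12", "a(CHEBI:lovastatin) decreases p(HGNC:GNAI2)"),
    ("W13", "a(CHEBI:tolrestat) decreases p(HGNC:AKR1B1)"),
    ("W14", "p(HGNC:BMP2) increases p(HGNC:ICAM1)"),
    ("W15", "complex(p(HGNC:BCL2L1),p(HGNC:VDAC1)) decreases act(p(HGNC:VDAC1))"),
    ("T01", "p(HGNC:INS) increases p(HGNC:PDE3B,pmod(P,S,273))"),
    ("T02", "a(CHEBI:celastrol) increases tloc(p(HGNC:HSF1))"),
    ("T03", "p(HGNC:TNF) increases p(HGNC:ICAM1)"),
    ("T04", "p(HGNC:LEP) increases path(MESHD:Obesity)"),
    ("T05", 'complex(p(HGNC:CCNA1),p(HGNC:E2F1)) increases bp(GOBP:"apoptotic process")'),
    ("T07", "p(HGNC:INS) increases act(p(HGNC:GK))"),
    ("T08", "p(HGNC:IL6R) increases act(p(HGNC:STAT3))"),
    ("P01", "p(MGI:Endog) increases bp(PH:Placeholder)"),
]


def dictionary_entries() -> List[DictionaryEntry]:
    return [DictionaryEntry(*row) for row in DICTIONARY_ROWS]


def gold_entity_entries() -> List[DictionaryEntry]:
    return [DictionaryEntry(*row) for row in GOLD_ENTITY_ROWS]


def go_parents() -> Dict[str, List[str]]:
    parents: Dict[str, List[str]] = {}
    for child, parent in GO_PARENT_ROWS:
        parents.setdefault(child, []).append(parent)
    return parents


def gene_go_associations() -> List[GeneGoAssociation]:
    return [
        GeneGoAssociation(NamespaceId("HGNC", gene), NamespaceId("GOBP", term))
        for gene, term in GENE_GO_ASSOC_ROWS
    ]


def standoff_mentions() -> Dict[str, List]:
    """Standoff annotations with offsets computed against the fixture
    sentences (surfaces are located programmatically, keeping the table
    readable)."""
    from .lexicon import EntityMention

    sentences = dict(WORKED_SENTENCES)
    by_source: Dict[str, List[EntityMention]] = {}
    for sid, surface, semclass, namespace, identifier, source in STANDOFF_ROWS:
        text = sentences[sid]
        start = text.index(surface)
        by_source.setdefault(source, []).append(
            EntityMention(
                sid, start, start + len(surface), surface, semclass,
                NamespaceId(namespace, identifier), source,
            )
        )
    return by_source


def gold_statements() -> Dict[str, List[BELStatement]]:
    out: Dict[str, List[BELStatement]] = {sid: [] for sid, _ in WORKED_SENTENCES}
    for sid, text in GOLD_STATEMENTS:
        out[sid].append(parse_statement(text, provenance=(sid, "gold")))
    return out


# ---------------------------------------------------------------------------
# Synthetic template corpus

_STOPLIKE = {
    "THE", "AND", "WAS", "FOR", "NOT", "ARE", "HIS", "HER", "ITS", "ALL",
    "CAN", "MAY", "BUT", "VIA",
}

_SIMPLE_VERBS = [
    ("inhibits", "decreases", False),
    ("suppresses", "decreases", False),
    ("reduces", "decreases", False),
    ("blocks", "decreases", False),
    ("induces", "increases", False),
    ("enhances", "increases", False),
    ("increases", "increases", False),
    ("activates", "increases", True),  # asserts activity of the theme
]
_PLURAL_VERBS = [
    ("inhibit", "decreases"),
    ("suppress", "decreases"),
    ("induce", "increases"),
    ("enhance", "increases"),
]


def _symbols(rng: random.Random, n: int) -> List[str]:
    out: List[str] = []
    seen = set()
    while len(out) < n:
        letters = "".join(rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ") for _ in range(3))
        sym = f"{letters}{rng.randint(1, 9)}"
        if letters in _STOPLIKE or sym in seen:
            continue
        seen.add(sym)
        out.append(sym)
    return out


def synthetic_corpus(seed: int, n_sentences: int = 240):
    """Template-generated sentences with generator-derived gold.

    Returns ``(sentences, dictionary_entries, gold)`` where gold maps sentence
    id to the statements the template encodes.
    """
    rng = random.Random(seed)
    symbols = _symbols(rng, 40)
    entries = [
        DictionaryEntry(sym, "HGNC", sym, "gene_protein", "fixture") for sym in symbols
    ]
    entries.append(DictionaryEntry("cytoplasm", "GOCC", "cytoplasm", "cellcomponent", "GO"))
    entries.append(DictionaryEntry("nucleus", "GOCC", "nucleus", "cellcomponent", "GO"))

    sentences: List[Tuple[str, str]] = []
    gold: Dict[str, List[BELStatement]] = {}
    templates = ("simple", "coord", "binding", "transport", "phospho", "passive",
                 "activity", "direct")
    for i in range(n_sentences):
        sid = f"SYN{i:04d}"
        template = templates[i % len(templates)]
        if template == "coord":
            a1, a2, b1, b2 = rng.sample(symbols, 4)
            verb, rel = rng.choice(_PLURAL_VERBS)
            text = f"{a1} and {a2} {verb} {b1} and {b2}."
            stmts = [
                f"p(HGNC:{a}) {rel} p(HGNC:{b})"
                for a in (a1, a2) for b in (b1, b2)
            ]
        elif template == "binding":
            a, b, c = rng.sample(symbols, 3)
            verb, rel, wrap = rng.choice(_SIMPLE_VERBS)
            obj = f"act(p(HGNC:{c}))" if wrap else f"p(HGNC:{c})"
            text = f"The interaction of {a} with {b} {verb} {c}."
            inner = sorted([f"p(HGNC:{a})", f"p(HGNC:{b})"])
            stmts = [f"complex({inner[0]},{inner[1]}) {rel} {obj}"]
        elif template == "transport":
            a, b = rng.sample(symbols, 2)
            verb, rel, _ = rng.choice([v for v in _SIMPLE_VERBS if not v[2]])
            text = (f"{a} {verb} translocation of {b} from the cytoplasm "
                    f"to the nucleus.")
            stmts = [f"p(HGNC:{a}) {rel} tloc(p(HGNC:{b}))"]
        elif template == "phospho":
            a, b = rng.sample(symbols, 2)
            pos = rng.randint(2, 999)
            text = f"{a} induces phosphorylation of {b} on serine-{pos}."
            stmts = [f"p(HGNC:{a}) increases p(HGNC:{b},pmod(P,S,{pos}))"]
        elif template == "passive":
            a, b = rng.sample(symbols, 2)
            text = f"{b} is inhibited by {a}."
            stmts = [f"p(HGNC:{a}) decreases p(HGNC:{b})"]
        elif template == "activity":
            a, b = rng.sample(symbols, 2)
            text = f"{a} suppresses {b} activity."
            stmts = [f"p(HGNC:{a}) decreases act(p(HGNC:{b}))"]
        elif template == "direct":
            a, b = rng.sample(symbols, 2)
            up = rng.random() < 0.5
            verb = "induces" if up else "inhibits"
            rel = "directlyIncreases" if up else "directlyDecreases"
            text = f"{a} directly {verb} {b}."
            stmts = [f"p(HGNC:{a}) {rel} p(HGNC:{b})"]
        else:  # simple
            a, b = rng.sample(symbols, 2)
            verb, rel, wrap = rng.choice(_SIMPLE_VERBS)
            obj = f"act(p(HGNC:{b}))" if wrap else f"p(HGNC:{b})"
            text = f"{a} {verb} {b}."
            stmts = [f"p(HGNC:{a}) {rel} {obj}"]
        sentences.append((sid, text))
        gold[sid] = [parse_statement(s, provenance=(sid, "gold")) for s in stmts]
    return sentences, entries, gold


# ---------------------------------------------------------------------------
# File output

def _write_tsv(path: Path, header: Sequence[str], rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def generate_fixture_corpus(seed: int, outdir, n_synthetic: int = 240) -> Dict[str, Path]:
    """Write the full fixture corpus to ``outdir``; byte-identical for a fixed
    seed. Returns the paths written, keyed by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["sentences"] = outdir / "sentences.tsv"
    _write_tsv(paths["sentences"], ("sentence_id", "text"), WORKED_SENTENCES)

    paths["dictionary"] = outdir / "dictionary.tsv"
    _write_tsv(paths["dictionary"], DICTIONARY_COLUMNS, DICTIONARY_ROWS)

    paths["standoff"] = outdir / "standoff.tsv"
    standoff_rows = []
    for source, ms in sorted(standoff_mentions().items()):
        for m in ms:
            standoff_rows.append(
                (m.sentence_id, m.start, m.end, m.text, m.semclass,
                 m.nsid.namespace, m.nsid.value, source)
            )
    standoff_rows.sort()
    _write_tsv(paths["standoff"], STANDOFF_COLUMNS, standoff_rows)

    paths["gold_entities"] = outdir / "gold_entities.tsv"
    _write_tsv(paths["gold_entities"], DICTIONARY_COLUMNS, GOLD_ENTITY_ROWS)

    paths["gold_statements"] = outdir / "gold_statements.tsv"
    _write_tsv(paths["gold_statements"], ("#sentence_id", "statement"), GOLD_STATEMENTS)

    paths["go_parents"] = outdir / "go_parents.tsv"
    _write_tsv(paths["go_parents"], ("child", "parent"), GO_PARENT_ROWS)

    paths["gene_go_assoc"] = outdir / "gene_go_assoc.tsv"
    _write_tsv(paths["gene_go_assoc"], ("gene", "go_term"), GENE_GO_ASSOC_ROWS)

    sentences, entries, gold = synthetic_corpus(seed, n_synthetic)
    paths["synthetic_sentences"] = outdir / "synthetic_sentences.tsv"
    _write_tsv(paths["synthetic_sentences"], ("sentence_id", "text"), sentences)
    paths["synthetic_dictionary"] = outdir / "synthetic_dictionary.tsv"
    _write_tsv(
        paths["synthetic_dictionary"], DICTIONARY_COLUMNS,
        [(e.surface, e.namespace, e.identifier, e.semclass, e.source_vocab)
         for e in entries],
    )
    paths["synthetic_gold"] = outdir / "synthetic_gold.tsv"
    from .core import serialize_statement

    rows = []
    for sid, _ in sentences:
        for stmt in gold[sid]:
            rows.append((sid, serialize_statement(stmt)))
    _write_tsv(paths["synthetic_gold"], ("#sentence_id", "statement"), rows)
    return paths
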