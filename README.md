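# belex

Rule-based extraction of **Biological Expression Language (BEL)** causal
statements from biomedical evidence sentences.

Curating signalling pathways from the literature means turning sentences like

> *FcgammaRIIB inhibits intracellular signaling upon ligation of IgG-immune
> complexes, and can suppress inflammation and autoimmunity.*

into machine-readable causal assertions:

```
p(HGNC:FCGR2B) -| path(MESHD:Inflammation)
p(HGNC:FCGR2B) -| path(MESHD:"Autoimmune Diseases")
```

`belex` is a deterministic, fully rule-based pipeline for this task, aimed at
text-mining researchers and pathway curators. It comprises:

1. **BEL core** — a typed data model for BEL 1.0 short-form terms
   (`p`, `r`, `a`, `bp`, `path`, `complex`, `act`, `tloc`, `tscript`, `kin`,
   `cat`, `pmod(...)`) and the four causal relations
   (`increases ->`, `decreases -|`, `directlyIncreases =>`,
   `directlyDecreases =|`), with a deterministic serializer, a parser and a
   canonicalizer (`complex` arguments are order-insensitive).
2. **Dictionary NER** — normalization (`ERK-1`/`Erk1` → `erk 1`), longest
   token-aligned dictionary matching over HGNC/MGI/EGID/CHEBI/GOBP/GOCC/MESHD
   vocabularies, Schwartz–Hearst-style abbreviation pairing with
   semantic-class propagation, edit-similarity propagation, GO candidate
   resolution against the ontology and gene–GO associations, cross-dictionary
   conflict resolution, ensemble merging with external annotators (consumed
   from standoff files), and a gold-constrained mode.
3. **Shallow semantic parser** — tokenizer, closed-class POS tagger, a
   declarative chunk grammar, apposition masking, and frame rules for binding,
   transport, phosphorylation, expression, activity and causal regulation,
   including passive voice, nominalizations, entity/clausal coordination and
   event-as-subject linking across clausal boundaries.
4. **BEL mapper** — event frames to BEL terms (binding → `complex`, transport
   → `tloc`, site strings → `pmod(P,S,273)`, …), causal-verb classes to
   relations, a placeholder policy (`bp(PH:Placeholder)`) for recognized but
   unnormalizable concepts, and run1/run2 filtering.
5. **Evaluator** — micro-averaged precision/recall/F at six granularities
   (term, function, function-secondary, relation, relation-secondary,
   statement), for partial-credit scoring: `precision = 100·tp/(tp+fp)`,
   `recall = 100·tp/(tp+fn)`, F is their harmonic mean.

## Worked example

```python
from belex import run_pipeline, serialize_statement
from belex.fixtures import dictionary_entries

sentence = ("The vasoactive intestinal peptide (VIP) and the pituitary "
            "adenylate cyclase-activating polypeptide (PACAP), two "
            "immunomodulatory neuropeptides that affect both innate and "
            "acquired immunity, down-regulate IL-12 p40 and inducible NO "
            "synthase expression in LPS/IFN-gamma-stimulated macrophages.")
results = run_pipeline([("S1", sentence)], dictionary_entries())
for stmt in results["S1"].statements:
    print(serialize_statement(stmt))
```

prints

```
p(HGNC:VIP) decreases p(HGNC:IL12B)
p(HGNC:VIP) decreases p(HGNC:NOS2)
p(HGNC:ADCYAP1) decreases p(HGNC:IL12B)
p(HGNC:ADCYAP1) decreases p(HGNC:NOS2)
```

four statements: the appositive ("two immunomodulatory neuropeptides …") is
masked, the abbreviation definitions collapse to their short forms, and the
coordinated subjects and objects distribute 2×2 over the negative-regulation
verb *down-regulate*.

The same pipeline is scriptable from the shell:

```bash
belex fixtures --seed 42 --outdir corpus/
belex extract --sentences corpus/sentences.tsv --dict corpus/dictionary.tsv \
      --standoff corpus/standoff.tsv --out pred.tsv
belex evaluate --pred pred.tsv --gold corpus/gold_statements.tsv --level all
```

`evaluate` prints one row per level (`level  tp  fp  fn  precision  recall  f`).

## Scope and limitations

Entity/event anaphora and semantic inference over negation chains are not
implemented (a double-negation sentence is shipped as a documented known
failure); external NER systems are consumed from standoff files rather than
live services; dictionaries are supplied as TSV, not built from source
databases. See `docs/methods.md` for the model, parameters and design
decisions.
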