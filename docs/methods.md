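# Methods

## The extraction model

`belex` treats BEL statement extraction as a cascade of deterministic,
rule-based stages. The guiding assumption is that most curatable causal
assertions in evidence sentences are *locally* expressed: a causal predicate
(verbal or nominalized) with its arguments in the same clause, where each
argument is either a normalized entity or a nominalized event (binding,
transport, phosphorylation, expression, activity). The rules therefore operate
on a linear chunk sequence rather than a full parse tree, and recursion is
admitted only through the constructions the rules model explicitly:
appositions, coordination (entity-level and clausal), event nominalizations,
passive voice, hyphenated participle compounds (`X-induced Y`) and
event-as-subject linking ("A and B interact … and inhibit C" makes the
binding event the causal subject).

This buys determinism and debuggability at a known cost: long-distance
dependencies, anaphora and any inference over the *semantics* of a clause
(e.g. that a blocked down-regulation is an up-regulation) are out of reach.
Both failure modes are kept in the test suite as documented known failures
rather than patched around.

## Entity recognition and normalization

Surface normalization lowercases, replaces hyphens/slashes between
alphanumerics with spaces, splits letter–digit boundaries and collapses
whitespace, so `ERK-1`, `Erk1` and `erk 1` coincide; the same tokenizer is
applied to dictionary surfaces and sentences, and matches must start and end
on token boundaries (no partial-word hits). Matching is greedy
longest-match per source vocabulary.

Around the dictionary core sit five refinements:

- **Abbreviations.** Parenthesized definitions in both `LONG (SHORT)` and
  `SHORT (LONG)` orders are detected with the Schwartz–Hearst character
  alignment criterion; a classed long form donates its class and namespace
  value to every standalone occurrence of its short form.
- **Surface similarity.** An unclassed span whose normalized character edit
  similarity (via `edlib`) to a classed mention reaches the threshold
  (default **0.85**, configurable; the metric and cutoff are package choices)
  adopts that mention's class and is re-normalized against the dictionary of
  that class.
- **GO partial matches.** A sentence phrase whose tokens form a contiguous
  subsequence of a GO term name is a partial-match candidate. Among
  candidates ordered by the ontology's parent map, the most specific wins by
  default; a recorded gene–GO association for a gene in the sentence overrides
  this toward the associated ancestor (the parent is preferred over the child
  when the annotation evidence points there).
- **Cross-dictionary conflicts.** When one phrase matches several
  vocabularies, an exact match beats a partial match; among multiple exact
  matches a configurable class priority (disease > bioprocess > chemical)
  decides, which is a package invention for a case the source rules leave
  open. In gold-constrained mode a match against the gold entity list beats
  everything.
- **Ensemble merging.** External annotators are consumed from standoff files
  (offline reproducibility; originally these were live REST services). For
  gene/chemical/disease spans the first source (pubtator) wins; otherwise a
  becas+dictionary consensus is required, except that a dictionary match that
  is exact — or inherited from an exact long form through an abbreviation
  pair — is accepted alone. For GO terms becas is primary and the dictionary
  supplements. Surviving same-class overlaps keep the longest span.

Recognized-but-unnormalizable concepts keep their class with no namespace
value and surface downstream as `bp(PH:Placeholder)`-style terms, so they can
be filtered (run2) instead of scored as precision errors (run1).

## Parsing and mapping choices

- **Tagging.** A closed-class lexicon (determiners, prepositions,
  conjunctions, modals, copulas), the verb lexicon's inflection tables, and
  three suffix rules (-ly adverbs, digits, participle compounds containing a
  hyphen) cover the tag inventory; everything else is a noun. Case matters:
  all-caps tokens such as `NO` (nitric oxide) are never closed-class.
- **Verb lexicon.** Seeded with the causal verb classes (decreases: reduce,
  decrease, suppress, block, down-regulate, inhibit, …; increases: increase,
  induce, activate, enhance, up-regulate, …; `directly` upgrades to the
  direct relations) plus the event triggers appearing in the fixture corpus
  (interact, bind, associate, complex, translocate, phosphorylate, express,
  activity, cleave, mediate, signal). Inflections are listed explicitly in
  the TSV; a fifth column carries nominal trigger forms (interaction,
  inhibition, translocation, expression, …) so nominalizations are not
  confused with verb forms. The file is an editable resource, as is the chunk
  grammar.
- **Cleavage** is classed as activity disruption: `A cleaves B` maps to
  `p(A) decreases act(p(B))`. Curated gold for proteolytic activation instead
  uses `cat(...) directlyIncreases kin(...)`; the mismatch is kept as a
  known-failure test rather than special-cased.
- **Expression** defaults to *corrected* mode (`expression of X` → `p(X)`).
  *Legacy* mode reproduces the earlier behavior of wrapping in an activity
  (`act(p(X))`, or `tscript(p(X))` via a sub-flag); the corrected mapping is
  the default because the activity wrapper misstates what an expression assay
  measures, and the toggle's diff is confined to expression-derived
  statements by construction (a tested invariant).
- **"activates X"** reports the object as `act(p(X))`; the wrap is keyed off
  the trigger lemma because the category inventory has no separate
  activation class.
- **Regulation frames in term position** (an `X-induced Y` compound as the
  object of an outer verb) contribute their *proximal participant*: the outer
  statement takes the inner frame's agent, and the inner frame is also
  emitted as its own statement, so a chain sentence yields its two binary
  links.
- **Subject-empty frames** become relation fragments (relation + object) on a
  secondary channel; they inform function-level evaluation but are never
  emitted as statements.
- **Tie-breaks.** Rules run in a fixed order (binding, transport, regulation,
  coordination distribution, cross-clausal linking); when several event
  frames could fill one slot the widest anchor wins, and overlapping trigger
  candidates prefer the longest, then leftmost. `tloc` is emitted without
  location arguments; extracted source/destination locations stay in the
  frame for provenance.

## Evaluation levels

Statements are canonicalized (complex arguments sorted, quoting normalized)
and decomposed per level: **term** — the namespace values; **function** — the
serialized subject/object expressions; **function-secondary** — (outer
function keyword, inner value) pairs; **relation** — the full canonical
triple; **relation-secondary** — (inner subject value, relation, inner object
value); **statement** — the canonical serialization. The definitions are this
package's operationalization, chosen so that within a comparison the true
positive counts can only grow from statement to relation to
relation-secondary. Scores are micro-averaged over sentences (macro vs micro
is not dictated by the task description; micro is the package's choice) and
duplicate statements per sentence collapse.

## The fixture corpus and what it shows

The worked corpus packages 24 real evidence sentences covering every rule
(coordination with apposition masking, clausal subject inheritance,
event-as-subject, nominal regulation, passive cleavage, GO resolution,
gold-constrained correction, placeholder filtering) with hand-assembled gold.
Two sentences are deliberate failures (cleavage mapping, double negation), so
its statement-level F is ~90, not 100 — by design.

The synthetic generator slots randomly drawn gene-symbol-like tokens (three
letters plus a digit, filtered against function words) into eight sentence
templates — simple regulation, 2×2 coordination, binding-as-subject,
transport, phosphorylation sites (serine-*n*), passive voice, activity
objects, `directly` modifiers — and derives the gold from the same template.
Default size is 240 sentences, which exercises every template at least 30
times while keeping the whole suite in seconds. Recovery at F = 100 therefore
demonstrates internal consistency of rules, mapper and scorer on clean,
in-grammar input; it says nothing about recall on open-domain prose, where
unseen predicates, anaphora and long-range structure dominate errors. Real
corpus-scale benchmarking would additionally require full-scale dictionaries
and an official scorer, which are out of scope here.

## Degenerate inputs and numerics

Empty sentences, empty dictionaries and unknown namespaces are handled
explicitly (empty outputs, a logged warning, and a parse error or lenient
warning respectively); per-sentence pipeline failures are logged and skipped,
never fatal. The only numeric tolerance in the package is the similarity
threshold; scores are exact rational arithmetic in floating point
(tp/fp/fn are integers). All randomness (fixture generation, property tests)
is seed-controlled; two runs with identical inputs are byte-identical.

## Known limitations

No anaphora (a hook exists where a resolver could be added), no semantic or
logical inference (double negation is reported with surface polarity), no
cross-sentence discourse, no BEL 2.x constructs (variants, fusions,
reactions, located translocations), and no species disambiguation beyond the
dictionary row's namespace. The parenthesized alias-list mask assumes alias
parentheticals follow an entity mention; unusual parenthetical content
adjacent to entities would be dropped from the simplified sentence (spans are
always recoverable through the offset map).
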