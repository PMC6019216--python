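# Methods

This note records the modelling choices, defaults and known limitations
of `metaknow`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

An **association** is the unit that receives meta-knowledge labels: an
event (trigger span + theme/cause participant references, which may be
entities or other events — nesting is preserved, never flattened) or a
binary relation (two entity arguments). Each association may carry an
`MKRecord` with the five core dimensions, the two hyperdimensions and
optional clue spans. The record enforces two invariants at construction:
dimension values must be legal, and `new_knowledge` and
`research_hypothesis` can never both be true.

Standoff serialization follows brat conventions (0-based half-open
character offsets; `T`/`E`/`R`/`A` lines). MK values become attribute
lines `A<n>\t<DimName> <target> <Value>` with booleans as `Yes`/`No`.
Clue spans, which the brat attribute grammar cannot carry, are written
as note lines `#<n>\tClueSpan <target> <dim> <start> <end>`; standard
brat tooling treats these as comments, so files stay interoperable.
Writing renumbers ids canonically; write → read → write is a fixed
point, which is how the round-trip tests phrase "identity up to id
renumbering". Sentence segmentation is taken from supplied spans when
available, otherwise from a deliberately simple punctuation splitter —
linguistic preprocessing is an input to this package, not its job.

## Linguistic layer and operators

POS tags (Penn tagset), dependency graphs (CoNLL-U) and constituency
trees (one-per-line Penn bracketing) come from external tools through
an adapter contract: any callable producing a `LinguisticLayer` for a
sentence. Constituency leaves are the preterminals (POS + word), so the
depth of a leaf counts the edges through phrasal nodes only.

Three operator families feed the features:

- **x-command** (X ∈ {S, VP, NP}): the clue leaf's *lowest* ancestor
  labelled X dominates the target leaf. The literature uses
  "s-command/vp-command/np-command" without a formal definition; this is
  the standard c-command family restricted to a category, with dominance
  taken as reflexive (a leaf x-commands itself whenever it has an X
  ancestor). The implementation is verified against a brute-force
  oracle (exhaustive ancestor enumeration) on hundreds of random trees.
- **dependency path length**: undirected shortest path;
  "direct" / "one-hop" / "two-hop" dependencies are read as
  intervening-node counts, i.e. path lengths 1 / 2 / 3.
- **tree distances**: leaf→root depth, and leaf→furthest-leaf distance
  through the lowest common ancestor.

## Clue lexicons

A clue entry is a lowercased word or phrase with a dimension
(KnowledgeType / KnowledgeSource / Uncertainty), the value it signals,
an optional set of Knowledge Type contexts (feeding features L11–L15)
and a regex flag (for citation-shaped Knowledge Source patterns).
Matching is token-based, case-insensitive, longest-match-first and
non-overlapping; the result is independent of lexicon file order. A
lemma fallback is deliberately off by default — inflected forms are
listed explicitly, which keeps matching transparent and reproducible.

The shipped default lexicon (~20 entries per dimension) is a small,
fully user-replaceable starter; production use is expected to supply
domain-tuned lists, and downstream scores are directly tied to the
comprehensiveness of those lists.

Tense/aspect/voice of a matched clue (features L8–L10) are heuristic:
VBD/VBN → past; have-form + VBN → perfect; be-form + VBN → passive;
auxiliary iff tagged MD or a form of *be/have/do*. These are pinned by
tests as part of the contract, not claimed to be full morphology.

## Features

Seven families (sentence SE1–SE10, structural ST1–ST7, participant
PA1–PA6, lexical L1–L16 plus a per-lexicon-entry indicator block,
constituency C1–C7, dependency D1–D6, parse-tree PT1–PT4), plus an
`mk_extra` group (knowledge source, knowledge type, binarized
uncertainty) consumed only by the hyperdimension classifiers. Defaults
and degenerate-input conventions:

- POS-class ratios with a zero denominator emit the sentinel −1; all
  legal ratios are non-negative, so the sentinel cannot collide (an
  audit test enforces this).
- Missing clue: L1 = −1, L5 (a signed token offset) = −9999,
  categorical slots = `"NONE"`, flags = false.
- L5 is implemented as a signed token offset (clue before/after trigger
  with magnitude); a coarser before/after flag would also have been
  defensible, and the finer encoding subsumes it.
- The per-entry clue indicators cover the whole sentence, not a window.
- Multi-token participants take as head the token whose dependency head
  lies outside the span (fallback: last token).
- C7 ("same scope") is defined as clue and trigger sharing the same
  minimal S ancestor.
- Relations receive static structural values: one theme slot (arg2) and
  one cause slot (arg1), all event-nesting flags false; clue-distance
  features anchor at the first argument since relations have no
  trigger. These statics are configurable.
- The default Knowledge Type configuration uses all families except the
  participant features; the hyperdimension configuration additionally
  appends `mk_extra`. Group-level only-this / all-except-this ablations
  are first-class configurations, and the union of "only g" and
  "all except g" reconstructs the full vector exactly (tested).

Categorical features are one-hot encoded by a `DictVectorizer` whose
vocabulary is frozen on the training split of each fold — unseen test
categories map to all-zero columns rather than leaking vocabulary.

## Classifiers and evaluation protocol

The default learner is a random forest with library-standard settings
(100 trees, √p split candidates, fixed seed recorded on the model);
"standard parameters" differ between libraries, so the exact values are
pinned here for reproducibility. A linear SVM is provided to support
like-for-like classifier comparisons; swapping learners changes only
the fitted state, never the evaluation plumbing. No majority-class
subsampling is performed: the minority densities are treated as
representative of real abstracts.

Hyperdimension prediction runs the two binary classifiers jointly; if
both fire, the label with the higher positive-class confidence wins
(probability for forests, decision margin for SVMs). The labels
themselves are mutually exclusive but no prediction-time resolution
rule is forced by that fact alone — confidence tie-breaking is this
package's choice, and the output provably never violates exclusivity.

Cross-validation is stratified at association level with a fixed seed
(k = 10 by default); per-class precision/recall/F1 are computed per
fold and macro-averaged across folds, and the report's `Average` row is
the arithmetic mean of the class rows. Whether the original evaluation
stratified or grouped folds by abstract is not determinable, so a
grouped-by-document mode is provided as well; stratified is the default
and is the mode the recoverability study uses. Document-level grouping
is the conservative choice when cross-sentence leakage is a concern.

Cohen's kappa is computed from the closed form κ = (p_o − p_e)/(1 −
p_e); the degenerate case p_e = 1 (both raters constant and identical)
is surfaced as an explicit undefined result, not coerced to 0 or 1.
Zero-variance features in the correlation analysis get r = 0 with a
degenerate flag so rankings stay total. Majority-baseline frequency
ties break toward the negative class. F1 of a never-predicted class
is 0.

One reporting note: for the relation corpus label counts (406 positive
of 622) the count-exact majority precision is 406/622 ≈ 0.653; a
published per-fold macro-average can differ slightly (e.g. 0.644)
because fold-level ratios do not average to the pooled ratio. This
package reports the count-exact value.

## Synthetic corpus generator

The generator is first-class, tested code that defines the study
conditions for every end-to-end check. Defaults mirror the corpus
statistics the method targets: 150 documents × 10 sentences ≈ 1500+
associations (event nesting adds extra events), class priors 34.2% New
Knowledge and 5.31% Research Hypothesis (65.3% / 6.11% are the
relation-corpus analogues and can be configured), full clue fidelity,
zero noise.

Each sentence carries one association. The latent class is drawn from
the priors, then the core MK dimensions are sampled *jointly* with it
so the rule baseline is consistent by construction: New Knowledge
instances are Current/L3/{Observation, Analysis}; Research Hypotheses
are Analysis/{L1, L2}; remainder variants (background-cited
observations, known facts, methods, bare statements, uncertain
investigations) never satisfy either rule. Every clue surface form maps
to exactly one (Knowledge Type, hyperdimension) pair so that all six
Knowledge Type classes and both hyperdimensions are learnable when
fidelity is 1; `noise_rate` swaps the surface clue without touching the
latent label, controlling the learnable ceiling.

The toy linguistic annotator produces deterministic POS tags, a
projective verb-headed dependency tree and NP/VP/SBAR bracketing with
an embedded clause at each *that/whether* boundary. It emulates the
structures the features read; it does **not** emulate real biomedical
language (vocabulary size, parse ambiguity, discontinuous triggers,
section headings, coordination). Passing the recoverability study
therefore shows that the feature stack, model and evaluation plumbing
transmit a clue signal faithfully — it does not certify corpus-level
accuracy on real text, which depends on real lexicons and parsers.

## Problem sizes

Default test and acceptance runs use ~1500–1800 associations for the
recoverability study, 200 random trees/graphs (≤ 12 leaves/nodes) for
the operator oracles, and the published corpus label counts (6899 /
622) for the majority-baseline rows; these sizes make every check exact
or tightly convergent while keeping a full run in the tens of seconds.

## Known limitations

- Knowledge Source detection is sentence-local; no cross-sentence
  propagation, and the citation regex defaults are a reconstruction,
  replaceable per corpus.
- Polarity and Manner are carried in the data model but never
  predicted.
- The uncertainty *detector* is out of scope: certainty values are
  inputs (gold or upstream-system), only their binarization is owned
  here.
- Discontinuous trigger spans are rejected rather than modelled.
- Sequence-level context (an event inheriting MK from neighbouring
  events) is not modelled; the classifiers are per-association.
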