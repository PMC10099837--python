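# Methods

## Data model and XML dialect

A corpus is an ordered list of abstracts; an abstract is an ordered list of
sentences. A sentence carries its NFC-normalized text, entity mentions
(kind `SNP` or `PHENOTYPE`), negation events (cue span + scope span),
modality markers, and gold candidate annotations. All offsets are 0-based,
half-open character intervals on the sentence string, so every annotation
is recoverable as `text[start:end]` without ambiguity. An association
candidate is one (SNP mention, phenotype mention) pair; its label is one of
positive / negative / neutral (or unlabeled), and a degree of certainty
(weak / moderate / strong) is defined only for positive candidates.

The native XML dialect (`schema="snprexml"`) is:

```xml
<snprex-corpus split="train|test|unsplit" provenance="...">
  <abstract id="A0001">
    <sentence id="A0001.s0" key="true" annotated="true">
      <text>...</text>
      <entity id="A0001.s0.e0" kind="SNP" start="0" end="9"/>
      <negation cue-start=".." cue-end=".." scope-start=".." scope-end=".." source="gold"/>
      <modality start=".." end=".." source="gold"/>
      <pair snp="A0001.s0.e0" phenotype="A0001.s0.e1" label="positive" certainty="weak"/>
    </sentence>
  </abstract>
</snprex-corpus>
```

Serialization is canonical (fixed element/attribute order, UTF-8,
2-space indent), so equal corpora produce identical bytes and
`read(write(C)) = C`. A best-effort importer for the DDI-style dialect of
the published SNPPhenA distribution (`schema="snpphena"`, end-inclusive
`charOffset` attributes converted to half-open intervals) is included for
convenience; nothing in the package requires that download. Validation is
performed before any write and after every read; span violations name the
offending sentence.

## Linguistic extractors

All extractors are deterministic and configurable; those with gold
counterparts in the corpus take a GOLD/HEURISTIC mode flag, where GOLD
returns the corpus annotations unchanged (an error on unannotated input)
and HEURISTIC applies the shipped rules.

- **Tokenization** — regex word/punctuation spans (`\w+|[^\w\s]`). Token
  surfaces concatenate back to the input minus whitespace.
- **Negation** — whole-token cue match (default lexicon: no, not, without,
  neither, nor, never, cannot, lack, absence). The heuristic scope runs
  from the token after the cue to the sentence end or the start of the
  first clause connector after the cue, whichever is nearer, so a scope
  never crosses a clause boundary.
- **Scope position** — an entity is *inside* a scope iff its span
  intersects the scope interval (intersection rather than containment,
  because mentions may straddle noisy scope boundaries); otherwise its
  start offset decides left/right. For one event the six position
  possibilities (both-inside, one-left-one-inside, one-right-one-inside,
  both-left, both-right, one-left-one-right) are exhaustive and mutually
  exclusive; the last three complete the partition that the first three
  begin. Candidate-level Booleans are event-wise disjunctions: any single
  inverting configuration suffices to invert the association.
- **Neutral candidates** — regular expressions applied to the
  entity-blinded sentence (surfaces replaced by `[SNP]`/`[PHENOTYPE]`), so
  the decision is invariant to the particular mention strings. The shipped
  default rules are study-setup verbs (genotyped, examined, investigated,
  recruited, enrolled, "aim of this study", measured) with inflectional
  variants; they are editable configuration, since no published rule set
  exists for this task.
- **Clause connectors** — whole-token lexicon matches, longest phrase
  first ("even though" beats "though"); the concessive subset defaults to
  although, though, even though, whereas, while, but, however,
  nevertheless.
- **Modality markers** — whole-token lexicon (may, might, could, suggest,
  suggests, likely, possibly, appear, seem).
- **P-values** — `p`/`P` (optionally `-value(s)`) followed by a comparator
  (`<, <=, =, >, >=`, including `≤`/`≥`) and a decimal or
  scientific-notation number, covering `×10` forms and the typographic
  minus (`3.2 × 10−5`). Unparseable matches are skipped with a warning.

## The rule-based association classifier

A candidate is **neutral** when a neutral rule fires — negation cannot flip
a sentence that takes no stance, so neutrality dominates. Otherwise the
candidate is **negative** exactly when at least one of both-inside,
one-left-one-inside or one-right-one-inside holds for some negation event,
and **positive** in every other configuration. The binary view collapses
negative and neutral against positive, supporting both evaluation
granularities. The decision is a pure function of the seven Booleans;
its truth table is asserted exhaustively in the tests.

## Certainty grading

Features per positive candidate: one indicator per modality marker in the
lexicon, the marker count, presence of a p-value, −log10 of the minimum
p-value, whether any p-value mention bounds the value below α = 0.05
(configurable; `p < x` and `p ≤ x` count when `x ≤ α`, `p = x` when
`x < α`, and `>`/`≥` never do), connector presence, and concessive-clause
presence. The classifier is a linear-kernel SVM (C = 1 by default) with
optional class weights; training requires at least two distinct levels. An
all-absent feature vector carries no signal, so prediction falls back to
the training majority class and logs the fallback.

## Baselines, weighting, grid search

The baseline representation is an entity-blinded bag of tokens plus the
rule-derived Boolean blocks; the vocabulary is frozen on the training split
(unknown test tokens are dropped), preventing representation leakage.
Families: logistic regression, random forest, decision tree, gradient
boosting, Gaussian naive Bayes, k-NN, and an SVM. Class weighting uses
`w_c = N/(K·n_c)`; it is applied natively where the estimator supports
class weights, via per-sample weights for gradient boosting and naive
Bayes, and not at all for k-NN (no mechanism exists). Grid search is an
exhaustive sweep over the declared grid with seeded stratified k-fold
cross-validation; ties keep the first-listed point, so results are
reproducible bit-for-bit. The deep CNN-LSTM model exists only as a
declarative architecture specification (embedding, two conv/max-pool
blocks, LSTM, dense, softmax, early-stopping policy) that an optional
plugin with a deep-learning backend may consume; the core package trains
nothing neural.

## Evaluation harness

Per-class and macro/weighted precision/recall/F1 from the confusion matrix
(zero-division reported as 0 and flagged); the averaging mode is always
recorded because comparative tables in this literature rarely state it, and
macro is the default. Cohen's kappa uses marginal-product expected
agreement and is NaN (flagged) when expected agreement is 1. AUC is the
rank-based probability that a positive outscores a negative (ties half).
Stratified k-fold requires at least k instances of the smallest class.
Abstract-level labels aggregate sentence candidates per (document, SNP,
phenotype) group by an any-positive or majority policy, majority ties
resolving to negative (the conservative reading). Significance: paired
t-test over per-fold scores (zero-variance differences flagged as
degenerate) and an exact two-sided binomial sign test over per-instance
wins with ties dropped.

## Synthetic corpus generator

The generator emulates the published corpus's annotation structure at
sentence level. Defaults: 360 abstracts, 2–4 candidate sentences each (one
SNP and one phenotype per sentence), label mix 811:325:180
(positive:negative:neutral), certainty mix 515:124:233
(weak:moderate:strong), connector rate 0.638, concessive fraction 87/895,
p-value rate 0.4, negation-cue target 0.185. Entity inventories are
rs-identifiers and phenotype names of the kind frequent in the real
corpus.

Realization: negative candidates use frames whose cue scope covers at
least one entity; neutral candidates use study-setup frames matching the
shipped neutral rules; positive candidates use assertive frames with no
entity inside any scope. Certainty is realized deterministically — hedge
or concessive clause ⇒ weak; significant p-value without hedging ⇒
strong; otherwise moderate — with weak realized by hedging 85% of the time
(hedging, not concession, is the dominant weakening device in abstracts;
this also keeps the concessive share of connectors near its configured
fraction). The weak-first precedence of that rule is a deliberate
resolution of an otherwise unordered pair of conditions; the generator
never emits a concessive clause together with a significant p-value, so
the ambiguous case does not arise in generated data.

Because every negative must carry a cue, the marginal cue rate is floored
at the negative-class proportion; above the floor, surplus cues are planted
harmlessly (a trailing clause whose scope covers no entity) on positive or
neutral sentences. Gold annotations are derived by running the heuristic
extractors on the assembled text, which makes generator-extractor closure
hold by construction; the generator additionally re-checks every planted
label and certainty against the rule pipeline and refuses to emit a
violating sentence. All randomness flows through one `random.Random(seed)`,
and text assembly is deterministic, so a seed reproduces the corpus
byte-for-byte across platforms.

What the generator does **not** emulate: real abstract discourse (every
sentence is independent), sentence length (frames are ~12–20 tokens versus
~77 in the real corpus), multi-entity sentences, annotation noise and
inter-annotator disagreement, and lexical variety beyond the template
inventory. Perfect rule-classifier recovery on generated corpora therefore
validates the pipeline's internal consistency — extraction, features,
decision rule and bookkeeping — not performance on real text, where scopes
are noisier and neutral rules are incomplete.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 1000 candidates for
rule-classifier recovery, 500 positives with 5 folds for certainty-grader
recovery, ~1100 candidates for the baseline run and 100 two-abstract
corpora for serialization round-trips; these sizes give stable estimates
for a deterministic pipeline while keeping a full run in seconds.
Percentages are reported to one decimal alongside their denominators (the
corpus literature is inconsistent about denominators, e.g. whether a
negation-cue rate is over sentences or candidates, so both numerator and
denominator are always exposed). Statistics are computed from data only,
never copied from printed tables, which are internally inconsistent in
places.

## Known limitations

- Heuristic negation scopes are flat token windows, not syntactic scopes;
  no dependency parsing or learned scope resolution (BioScope-style CRFs)
  is attempted.
- The neutral rule set is a small editable default, not a learned
  inventory.
- The `snpphena` importer is best-effort: it guesses attribute names for
  labels and certainty and defaults to unlabeled when they are absent.
- Certainty is modeled per sentence; document-level confidence aggregation
  is limited to the label-aggregation policies of the evaluation module.
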