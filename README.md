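# snprex

Linguistically informed extraction of **ranked SNP-phenotype associations**
from biomedical sentences.

Genome-wide association studies report links between single-nucleotide
polymorphisms (SNPs, named by rs-identifiers) and phenotypes such as obesity
or smoking behaviour. Mining those reports from abstracts is harder than
plain relation extraction for two linguistic reasons:

1. **Negation.** "There were *no* associations between APOE polymorphisms
   and serum HDL-C" asserts the *absence* of an association; ignoring the
   negation cue and its scope extracts a wrong positive.
2. **Stance and strength.** A sentence may merely describe the study setup
   ("We genotyped rs123 in patients with asthma") — a *neutral* candidate
   whose status is unchanged by negation or hedging — and a genuinely
   positive claim comes with a *degree of certainty* (weak / moderate /
   strong) signalled by hedges ("may", "suggest"), reported p-values and
   concessive clauses ("although ...").

`snprex` implements the full sentence-level pipeline for researchers in
biomedical text mining: a corpus data model with XML I/O, rule/lexicon
extractors for all the signals above, the rule-based association classifier,
a trainable certainty grader, shallow ML baselines with imbalance weighting
and grid search, an evaluation harness, and a seeded synthetic corpus
generator with a complete ground-truth ledger.

## The core decision rules

Each candidate is one (SNP mention, phenotype mention) pair in a sentence.
For every detected negation event the pair occupies exactly one of six
positions relative to the negation scope (both inside; one left, one
inside; one right, one inside; both left; both right; one left, one right).
With `IsNeutralCand` from a regex-based neutral-candidate detector, the
association label is

```
neutral      if IsNeutralCand
negative     if ¬IsNeutralCand ∧ (BothInsNegSc ∨ OneLeftOneInsNegSc ∨ OneRightOneInsNegSc)
positive     otherwise
```

A binary view collapses negative and neutral against positive. For positive
candidates the certainty grade is predicted by a linear SVM over modality
marker indicators, the sentence's minimum reported p-value (and whether it
is bounded below 0.05), and clause-connector features.

Class imbalance is handled by inverse-frequency weights
`w_c = N / (K · n_c)` (N samples, K classes), which reduce to 1 for
balanced data and conserve `Σ_c n_c · w_c = N`.

## Worked example

```python
from snprex import (GeneratorConfig, generate_corpus, enumerate_candidates,
                    nnb_explain, Source, corpus_statistics)

corpus, ledger = generate_corpus(GeneratorConfig(n_abstracts=5, seed=42))
sent = corpus.documents[0].sentences[0]
print("SENT:", sent.text)

(cand,) = enumerate_candidates(sent)
res = nnb_explain(cand, sent, mode=Source.GOLD)
print("label:", res.label.label.value, "| binary:", res.label.binary_view.value)
print("neutral rule:", res.matched_neutral_rule, "| negation events:", res.n_negation_events)

stats = corpus_statistics(corpus)
print("n_candidates:", stats.n_candidates, "labels:", stats.label_counts)
```

prints

```
SENT: Carriers of the rs4293585 allele showed an increased risk of skin pigmentation, and moreover the effect was dose dependent (P < 0.001).
label: positive | binary: true_assoc
neutral rule: None | negation events: 0
n_candidates: 17 labels: {'positive': 11, 'negative': 4, 'neutral': 2}
```

The sentence carries no negation cue and matches no study-setup rule, so
the candidate is a true (positive) association; the significant p-value
without hedging grades it *strong*. Conversely,

```python
nnb_classify(cand, sent)   # on "There were no associations between
                           #     APOE polymorphisms and serum HDL-C"
```

detects cue `no` with scope `associations between APOE polymorphisms and
serum HDL-C`, placing both mentions inside the scope, and returns
`negative` / `false_assoc`.

The same pipeline is available from the shell:

```bash
snprex simulate --n 360 --seed 7 --out corpus.xml --ledger ledger.json
snprex extract --mode heuristic --in corpus.xml --out predictions.jsonl
snprex evaluate --gold corpus.xml --pred predictions.jsonl
snprex stats --in corpus.xml
```

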