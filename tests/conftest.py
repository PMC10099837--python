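from __future__ import annotations

import pytest

from snprex.corpus import (
    AbstractDocument,
    AssociationCandidate,
    CandidateAnnotation,
    Certainty,
    Corpus,
    EntityKind,
    EntityMention,
    Label,
    Sentence,
    Span,
)
from snprex.synth import GeneratorConfig, generate_corpus


def make_sentence(
    text: str,
    snps: tuple[str, ...] = (),
    phenotypes: tuple[str, ...] = (),
    sent_id: str = "d0.s0",
    **kwargs,
) -> Sentence:
    """Build a sentence, locating each entity surface by its first (or next)
    occurrence in the text."""
    entities = []
    cursor: dict[str, int] = {}
    i = 0
    for kind, surfaces in ((EntityKind.SNP, snps), (EntityKind.PHENOTYPE, phenotypes)):
        for surface in surfaces:
            start = text.index(surface, cursor.get(surface, 0))
            cursor[surface] = start + len(surface)
            entities.append(
                EntityMention(f"{sent_id}.e{i}", kind, Span(start, start + len(surface)), surface)
            )
            i += 1
    return Sentence(sent_id=sent_id, text=text, entities=entities, **kwargs)


def make_candidate(sentence: Sentence, label: Label = Label.UNLABELED,
                   certainty: Certainty = Certainty.NONE) -> AssociationCandidate:
    """First-SNP/first-phenotype candidate of a sentence."""
    snp = sentence.mentions(EntityKind.SNP)[0]
    phen = sentence.mentions(EntityKind.PHENOTYPE)[0]
    return AssociationCandidate(
        sentence_id=sentence.sent_id, snp=snp, phenotype=phen,
        gold_label=label, gold_certainty=certainty,
    )


@pytest.fixture(scope="session")
def synthetic_corpus():
    """Mid-size generated corpus shared across tests (seeded, read-only)."""
    return generate_corpus(GeneratorConfig(n_abstracts=120, seed=7))


@pytest.fixture
def tiny_corpus():
    sent = make_sentence(
        "rs1051730 was significantly associated with smoking in the study cohort.",
        snps=("rs1051730",),
        phenotypes=("smoking",),
        sent_id="D1.s0",
        is_key=True,
    )
    sent.candidates = [
        CandidateAnnotation(
            snp_id=sent.entities[0].mention_id,
            phenotype_id=sent.entities[1].mention_id,
            label=Label.POSITIVE,
            certainty=Certainty.STRONG,
        )
    ]
    return Corpus(documents=[AbstractDocument("D1", [sent])], split_tag="train")
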