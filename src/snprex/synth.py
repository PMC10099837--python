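"""Seeded generator of SNPPhenA-style synthetic corpora with full ground truth.

Sentences are assembled from hand-written English frames with [SNP] and
[PHENOTYPE] slots filled from small inventories of rs-identifiers and
phenotype names.  Every planted signal — negation cue and scope, hedging
marker, clause connector, p-value — is chosen within the competence of the
package's heuristic extractors, and the gold annotations attached to each
sentence are derived by running those extractors on the assembled text, so
generator and extractors agree by construction.  A ground-truth ledger
records the intended label, certainty and planted signals per candidate.

Default rates emulate the published corpus statistics: label mix
811:325:180 (positive:negative:neutral), certainty mix 515:124:233
(weak:moderate:strong), 63.8% of candidates with a clause connector,
87/895 of connectors concessive.  Because every negative candidate must
carry a negation cue, the negation-cue rate acts as a target with the
negative-class proportion as floor; surplus cues are planted harmlessly
(scope covering no entity) on positive or neutral sentences.

Certainty follows a deterministic rule: a hedge or a concessive clause
makes the association WEAK; otherwise a statistically significant p-value
(bounded below 0.05) makes it STRONG; otherwise MODERATE.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Sequence

from . import features as F
from .corpus import (
    AbstractDocument,
    AssociationCandidate,
    CandidateAnnotation,
    Certainty,
    Corpus,
    EntityKind,
    EntityMention,
    Label,
    Sentence,
    Source,
    Span,
)
from .nnb import AssociationLabel, nnb_predict

__all__ = [
    "GeneratorConfig",
    "TemplateInventory",
    "GroundTruthLedger",
    "LedgerEntry",
    "generate_corpus",
    "label_oracle",
    "certainty_rule",
    "DEFAULT_TEMPLATES",
]


# ---------------------------------------------------------------------------
# template inventory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateInventory:
    """Sentence frames with {SNP}/{PHEN} slots.

    ``positive_assertive``: no cue, hedge or connector; ``positive_hedged``:
    contains a modality marker; ``negative``: contains a negation cue whose
    heuristic scope covers at least one entity; ``neutral`` /
    ``neutral_with_cue``: match the shipped neutral rules (the cue variant
    also plants a negation cue); suffixes are appended before the final
    period.
    """

    positive_assertive: tuple[str, ...]
    positive_hedged: tuple[str, ...]
    negative: tuple[str, ...]
    neutral: tuple[str, ...]
    neutral_with_cue: tuple[str, ...]
    concessive_suffixes: tuple[str, ...]
    connector_suffixes: tuple[str, ...]
    significant_pvalues: tuple[str, ...]
    nonsignificant_pvalues: tuple[str, ...]
    harmless_negation_tail: str = "; no covariate adjustment was applied"

    def validate(self) -> None:
        for name in (
            "positive_assertive",
            "positive_hedged",
            "negative",
            "neutral",
            "neutral_with_cue",
            "concessive_suffixes",
            "connector_suffixes",
            "significant_pvalues",
            "nonsignificant_pvalues",
        ):
            if not getattr(self, name):
                raise ValueError(f"empty template inventory: {name}")


DEFAULT_TEMPLATES = TemplateInventory(
    positive_assertive=(
        "{SNP} was significantly associated with {PHEN} in the study cohort",
        "Carriers of the {SNP} allele showed an increased risk of {PHEN}",
        "The {SNP} polymorphism was strongly related to {PHEN} in this population",
        "A clear association between {SNP} and {PHEN} was observed",
    ),
    positive_hedged=(
        "{SNP} may be associated with {PHEN}",
        "{SNP} might contribute to the risk of {PHEN}",
        "These data suggest that {SNP} could influence {PHEN}",
        "{SNP} is possibly related to {PHEN}",
    ),
    negative=(
        "There was no association between {SNP} and {PHEN}",
        "{SNP} was not associated with {PHEN} in this cohort",
        "No significant association between {SNP} and {PHEN} was detected",
        "{SNP} showed no relation to {PHEN} in our sample",
    ),
    neutral=(
        "We genotyped {SNP} in patients with {PHEN}",
        "The present study examined the relationship between {SNP} and {PHEN}",
        "Subjects with {PHEN} were recruited and {SNP} was determined",
        "The aim of this study was to assess the role of {SNP} in {PHEN}",
    ),
    neutral_with_cue=(
        "We genotyped {SNP} in subjects with no history of {PHEN}",
        "{PHEN} was measured in carriers and in subjects not carrying {SNP}",
    ),
    concessive_suffixes=(
        ", although the effect size was modest",
        ", but the evidence remained limited",
        ", whereas the effect was weaker in men",
    ),
    connector_suffixes=(
        ", because the sample was population based",
        ", since the finding was consistent across subgroups",
        ", and moreover the effect was dose dependent",
    ),
    significant_pvalues=(
        " (P < 0.001)",
        " (P = 0.0004)",
        " (p < 0.01)",
        " (p = 3.2 × 10−5)",
    ),
    nonsignificant_pvalues=(
        " (P = 0.12)",
        " (P = 0.45)",
        " (p > 0.05)",
        " (P = 0.07)",
    ),
)

# rs-identifiers and phenotype names mirroring the corpus's most frequent
# mentions
DEFAULT_SNPS = (
    "rs12255372",
    "rs4293585",
    "rs1051730",
    "rs6627992",
    "rs1799971",
    "rs1800629",
    "rs7412",
    "rs429358",
)

DEFAULT_PHENOTYPES = (
    "smoking",
    "obesity",
    "metabolic syndrome",
    "hypertension",
    "insulin sensitivity",
    "hypertriglyceridemia",
    "glucose metabolism",
    "longevity",
    "cognitive performance",
    "skin pigmentation",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Default proportions mirror the published corpus statistics; the
    generator's ledger — not any printed table — is the ground truth of
    what was planted.
    """

    n_abstracts: int = 360
    candidates_per_abstract: tuple[int, int] = (2, 4)  # uniform inclusive
    label_proportions: tuple[float, float, float] = (811.0, 325.0, 180.0)  # pos, neg, neu
    negation_cue_rate: float = 0.185
    connector_rate: float = 0.638
    concessive_fraction: float = 87.0 / 895.0
    certainty_proportions: tuple[float, float, float] = (515.0, 124.0, 233.0)  # weak, mod, strong
    pvalue_rate: float = 0.4
    hedge_fraction_of_weak: float = 0.85  # weak realized by hedge vs concessive clause
    seed: int = 0
    templates: TemplateInventory = field(default_factory=lambda: DEFAULT_TEMPLATES)
    snp_inventory: tuple[str, ...] = DEFAULT_SNPS
    phenotype_inventory: tuple[str, ...] = DEFAULT_PHENOTYPES

    def __post_init__(self) -> None:
        for rate in (self.negation_cue_rate, self.connector_rate,
                     self.concessive_fraction, self.pvalue_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.label_proportions) < 0 or sum(self.label_proportions) <= 0:
            raise ValueError("label proportions must be a nonnegative non-zero mix")
        if min(self.certainty_proportions) < 0 or sum(self.certainty_proportions) <= 0:
            raise ValueError("certainty proportions must be a nonnegative non-zero mix")
        self.templates.validate()
        if not self.snp_inventory or not self.phenotype_inventory:
            raise ValueError("entity inventories must be nonempty")

    @property
    def label_simplex(self) -> tuple[float, float, float]:
        s = sum(self.label_proportions)
        return tuple(p / s for p in self.label_proportions)

    @property
    def certainty_simplex(self) -> tuple[float, float, float]:
        s = sum(self.certainty_proportions)
        return tuple(p / s for p in self.certainty_proportions)


# ---------------------------------------------------------------------------
# ground-truth ledger
# ---------------------------------------------------------------------------

@dataclass
class LedgerEntry:
    label: Label
    certainty: Certainty
    template: str
    cue_texts: list[str] = field(default_factory=list)
    marker_texts: list[str] = field(default_factory=list)
    connector_texts: list[str] = field(default_factory=list)
    has_concessive: bool = False
    pvalue_values: list[float] = field(default_factory=list)
    pvalue_significant: bool = False
    neutral_rule: str | None = None


@dataclass
class GroundTruthLedger:
    seed: int
    entries: dict[str, LedgerEntry] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "entries": {
                    k: {
                        "label": e.label.value,
                        "certainty": e.certainty.value,
                        "template": e.template,
                        "cue_texts": e.cue_texts,
                        "marker_texts": e.marker_texts,
                        "connector_texts": e.connector_texts,
                        "has_concessive": e.has_concessive,
                        "pvalue_values": e.pvalue_values,
                        "pvalue_significant": e.pvalue_significant,
                        "neutral_rule": e.neutral_rule,
                    }
                    for k, e in self.entries.items()
                },
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, raw: str) -> "GroundTruthLedger":
        data = json.loads(raw)
        ledger = cls(seed=data["seed"])
        for k, d in data["entries"].items():
            ledger.entries[k] = LedgerEntry(
                label=Label(d["label"]),
                certainty=Certainty(d["certainty"]),
                template=d["template"],
                cue_texts=list(d["cue_texts"]),
                marker_texts=list(d["marker_texts"]),
                connector_texts=list(d["connector_texts"]),
                has_concessive=d["has_concessive"],
                pvalue_values=list(d["pvalue_values"]),
                pvalue_significant=d["pvalue_significant"],
                neutral_rule=d["neutral_rule"],
            )
        return ledger


def label_oracle(
    ledger: GroundTruthLedger, candidate: AssociationCandidate
) -> tuple[AssociationLabel, Certainty]:
    """Planted ground truth for a generated candidate."""
    entry = ledger.entries.get(candidate.candidate_id)
    if entry is None:
        raise ValueError(f"candidate {candidate.candidate_id} not generated by this ledger")
    return AssociationLabel.from_label(entry.label), entry.certainty


def certainty_rule(has_hedge: bool, has_concessive: bool, pvalue_significant: bool) -> Certainty:
    """Deterministic certainty semantics of the generator: hedging or a
    concessive clause weakens the claim; a significant p-value without
    hedging makes it strong; otherwise moderate."""
    if has_hedge or has_concessive:
        return Certainty.WEAK
    if pvalue_significant:
        return Certainty.STRONG
    return Certainty.MODERATE


# ---------------------------------------------------------------------------
# sentence assembly
# ---------------------------------------------------------------------------

def _fill(template: str, snp: str, phen: str) -> tuple[str, Span, Span]:
    """Substitute the {SNP}/{PHEN} slots, returning the filled text and the
    character spans of both fills."""
    spans: dict[str, Span] = {}
    text = ""
    pos = 0
    while True:
        i_snp = template.find("{SNP}", pos)
        i_phen = template.find("{PHEN}", pos)
        nxt = min((i for i in (i_snp, i_phen) if i >= 0), default=-1)
        if nxt < 0:
            text += template[pos:]
            break
        text += template[pos:nxt]
        if nxt == i_snp:
            spans["snp"] = Span(len(text), len(text) + len(snp))
            text += snp
            pos = nxt + len("{SNP}")
        else:
            spans["phen"] = Span(len(text), len(text) + len(phen))
            text += phen
            pos = nxt + len("{PHEN}")
    return text, spans["snp"], spans["phen"]


def _realize(
    rng: random.Random, cfg: GeneratorConfig, label: Label
) -> tuple[str, Certainty, str]:
    """Choose a frame and suffixes for one candidate.  Returns the template
    text (with slots still open), the intended certainty and a template tag."""
    t = cfg.templates
    connector_suffix = ""
    pvalue_suffix = ""
    if label is Label.POSITIVE:
        certainty = rng.choices(
            (Certainty.WEAK, Certainty.MODERATE, Certainty.STRONG),
            weights=cfg.certainty_simplex,
        )[0]
        if certainty is Certainty.WEAK:
            if rng.random() < cfg.hedge_fraction_of_weak:
                core = rng.choice(t.positive_hedged)
                tag = "positive_hedged"
                if rng.random() < cfg.connector_rate:
                    connector_suffix = rng.choice(t.connector_suffixes)
            else:
                core = rng.choice(t.positive_assertive)
                tag = "positive_concessive"
                connector_suffix = rng.choice(t.concessive_suffixes)
            if rng.random() < cfg.pvalue_rate:
                pvalue_suffix = rng.choice(t.nonsignificant_pvalues)
        elif certainty is Certainty.STRONG:
            core = rng.choice(t.positive_assertive)
            tag = "positive_strong"
            if rng.random() < cfg.connector_rate:
                connector_suffix = rng.choice(t.connector_suffixes)
            pvalue_suffix = rng.choice(t.significant_pvalues)
        else:
            core = rng.choice(t.positive_assertive)
            tag = "positive_moderate"
            if rng.random() < cfg.connector_rate:
                connector_suffix = rng.choice(t.connector_suffixes)
            if rng.random() < cfg.pvalue_rate:
                pvalue_suffix = rng.choice(t.nonsignificant_pvalues)
    elif label is Label.NEGATIVE:
        core = rng.choice(t.negative)
        tag = "negative"
        certainty = Certainty.NONE
        if rng.random() < cfg.connector_rate:
            pool = (
                t.concessive_suffixes
                if rng.random() < cfg.concessive_fraction
                else t.connector_suffixes
            )
            connector_suffix = rng.choice(pool)
        if rng.random() < cfg.pvalue_rate:
            pvalue_suffix = rng.choice(t.nonsignificant_pvalues)
    else:  # NEUTRAL
        core = rng.choice(t.neutral)
        tag = "neutral"
        certainty = Certainty.NONE
        if rng.random() < cfg.connector_rate:
            pool = (
                t.concessive_suffixes
                if rng.random() < cfg.concessive_fraction
                else t.connector_suffixes
            )
            connector_suffix = rng.choice(pool)
    return core + connector_suffix + pvalue_suffix, certainty, tag


def _extra_cue_probability(cfg: GeneratorConfig) -> float:
    """Probability of planting a harmless cue on a non-negative candidate so
    that the marginal cue rate approaches the configured target (floored at
    the negative-class proportion)."""
    p_neg = cfg.label_simplex[1]
    if cfg.negation_cue_rate <= p_neg or p_neg >= 1.0:
        return 0.0
    return (cfg.negation_cue_rate - p_neg) / (1.0 - p_neg)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_corpus(config: GeneratorConfig | None = None) -> tuple[Corpus, GroundTruthLedger]:
    """Generate a corpus and its ground-truth ledger, reproducibly from the
    seed.  Gold annotations (negation events, modality markers, labels,
    certainty) are attached to every sentence."""
    cfg = config or GeneratorConfig()
    rng = random.Random(cfg.seed)
    p_extra = _extra_cue_probability(cfg)
    labels = (Label.POSITIVE, Label.NEGATIVE, Label.NEUTRAL)

    corpus = Corpus(split_tag="unsplit", provenance=f"snprex-synthetic seed={cfg.seed}")
    ledger = GroundTruthLedger(seed=cfg.seed)

    for a in range(cfg.n_abstracts):
        doc = AbstractDocument(doc_id=f"A{a:04d}")
        n_sent = rng.randint(*cfg.candidates_per_abstract)
        for j in range(n_sent):
            label = rng.choices(labels, weights=cfg.label_simplex)[0]
            template, certainty, tag = _realize(rng, cfg, label)
            if label is Label.POSITIVE and rng.random() < p_extra:
                template += cfg.templates.harmless_negation_tail
                tag += "+harmless_cue"
            elif label is Label.NEUTRAL and rng.random() < p_extra:
                template = rng.choice(cfg.templates.neutral_with_cue)
                tag = "neutral_with_cue"
            template += "."
            snp_name = rng.choice(cfg.snp_inventory)
            phen_name = rng.choice(cfg.phenotype_inventory)
            text, snp_span, phen_span = _fill(template, snp_name, phen_name)

            sid = f"{doc.doc_id}.s{j}"
            snp = EntityMention(f"{sid}.e0", EntityKind.SNP, snp_span, snp_name)
            phen = EntityMention(f"{sid}.e1", EntityKind.PHENOTYPE, phen_span, phen_name)
            sent = Sentence(sent_id=sid, text=text, entities=[snp, phen], is_key=True)

            # derive gold annotations by running the heuristic extractors on
            # the assembled text (templates are within their competence)
            heur_events = F.detect_negation(sent, mode=Source.HEURISTIC)
            sent.negations = [
                F.NegationEvent(e.cue_span, e.cue_text, e.scope_span, Source.GOLD)
                for e in heur_events
            ]
            heur_markers = F.detect_modality_markers(sent, mode=Source.HEURISTIC)
            sent.modality_markers = [
                F.ModalityMarker(m.span, m.text, Source.GOLD) for m in heur_markers
            ]
            connectors = F.detect_clause_connectors(sent)
            pvalues = F.extract_pvalues(sent)

            sent.candidates = [
                CandidateAnnotation(
                    snp_id=snp.mention_id,
                    phenotype_id=phen.mention_id,
                    label=label,
                    certainty=certainty,
                )
            ]
            doc.sentences.append(sent)

            cand = AssociationCandidate(
                sentence_id=sid, snp=snp, phenotype=phen,
                gold_label=label, gold_certainty=certainty,
            )
            from .certainty import DEFAULT_SIGNIFICANCE_ALPHA, _pvalue_is_significant

            significant = any(
                _pvalue_is_significant(pv, DEFAULT_SIGNIFICANCE_ALPHA) for pv in pvalues
            )
            entry = LedgerEntry(
                label=label,
                certainty=certainty,
                template=tag,
                cue_texts=[e.cue_text for e in sent.negations],
                marker_texts=[m.text for m in sent.modality_markers],
                connector_texts=[c.text for c in connectors],
                has_concessive=any(c.is_concessive for c in connectors),
                pvalue_values=[pv.value for pv in pvalues],
                pvalue_significant=significant,
                neutral_rule=None,
            )

            # construction checks: the rule pipeline must recover the plant
            is_neutral, rule_id = F.detect_neutral(cand, sent)
            entry.neutral_rule = rule_id
            feats = F.positional_features(cand, sent.negations, is_neutral)
            predicted = nnb_predict(feats).label
            if predicted is not label:
                raise RuntimeError(
                    f"generator bug: template {tag!r} realizes {predicted.value}, "
                    f"intended {label.value} ({text!r})"
                )
            if label is Label.POSITIVE:
                derived = certainty_rule(
                    bool(heur_markers), entry.has_concessive, significant
                )
                if derived is not certainty:
                    raise RuntimeError(
                        f"generator bug: template {tag!r} realizes certainty "
                        f"{derived.value}, intended {certainty.value} ({text!r})"
                    )
            ledger.entries[cand.candidate_id] = entry
        corpus.documents.append(doc)
    return corpus, ledger
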