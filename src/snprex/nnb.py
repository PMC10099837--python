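"""Negation/neutral-based (NNB) rule classifier for SNP-phenotype candidates.

The decision combines two rule systems: the six scope-position Booleans of a
candidate relative to detected negation scopes, and a regex-based neutral
candidate detector.  A non-neutral candidate with the SNP and/or phenotype
inside a negation scope — both inside, one left-one inside, or one
right-one inside — is an inverted (negative) association; any other
combination is a true association; a neutral candidate stays neutral
regardless of negation, because negation cannot flip a sentence that takes
no stance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from . import features as F
from .corpus import AssociationCandidate, Label, Sentence, Source

__all__ = [
    "BinaryView",
    "AssociationLabel",
    "NNBConfig",
    "NNBResult",
    "nnb_predict",
    "nnb_classify",
    "nnb_explain",
]


class BinaryView(str, Enum):
    """Two-class collapse: positive vs negative-and-neutral."""

    TRUE_ASSOC = "true_assoc"
    FALSE_ASSOC = "false_assoc"


@dataclass(frozen=True)
class AssociationLabel:
    label: Label
    binary_view: BinaryView

    def __post_init__(self) -> None:
        expected = (
            BinaryView.TRUE_ASSOC if self.label is Label.POSITIVE else BinaryView.FALSE_ASSOC
        )
        if self.binary_view is not expected:
            raise ValueError(
                "binary view must merge negative and neutral candidates against positives"
            )

    @classmethod
    def from_label(cls, label: Label) -> "AssociationLabel":
        return cls(
            label=label,
            binary_view=(
                BinaryView.TRUE_ASSOC if label is Label.POSITIVE else BinaryView.FALSE_ASSOC
            ),
        )


@dataclass
class NNBConfig:
    """Lexicons and rules feeding the NNB pipeline; all editable."""

    negation_cues: tuple[str, ...] = F.DEFAULT_NEGATION_CUES
    connector_lexicon: F.ConnectorLexicon = F.DEFAULT_CONNECTOR_LEXICON
    modality_markers: tuple[str, ...] = F.DEFAULT_MODALITY_MARKERS
    neutral_rules: tuple[F.NeutralRule, ...] = F.DEFAULT_NEUTRAL_RULES

    @classmethod
    def from_json(cls, path) -> "NNBConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        kwargs = {}
        if "negation_cues" in data:
            kwargs["negation_cues"] = tuple(data["negation_cues"])
        if "connectors" in data:
            kwargs["connector_lexicon"] = F.ConnectorLexicon(
                tuple(data["connectors"]), frozenset(data.get("concessive", ()))
            )
        if "modality_markers" in data:
            kwargs["modality_markers"] = tuple(data["modality_markers"])
        if "neutral_rules" in data:
            kwargs["neutral_rules"] = tuple(
                F.NeutralRule(d["rule_id"], d["pattern"], d.get("description", ""))
                for d in data["neutral_rules"]
            )
        return cls(**kwargs)


def nnb_predict(feats: F.PositionalFeatures) -> AssociationLabel:
    """Pure rule decision over the seven Booleans.

    Neutral dominates: negation never changes the status of a neutral
    candidate.  Otherwise an association is inverted exactly when the pair
    is (partly) inside a negation scope.
    """
    if feats.is_neutral_candidate:
        return AssociationLabel.from_label(Label.NEUTRAL)
    if feats.both_inside or feats.one_left_one_inside or feats.one_right_one_inside:
        return AssociationLabel.from_label(Label.NEGATIVE)
    return AssociationLabel.from_label(Label.POSITIVE)


@dataclass(frozen=True)
class NNBResult:
    """Full audit record of one NNB decision."""

    candidate_id: str
    label: AssociationLabel
    features: F.PositionalFeatures
    matched_neutral_rule: str | None
    n_negation_events: int

    def to_json_record(self) -> dict:
        return {
            "candidate_id": self.candidate_id,
            "label": self.label.label.value,
            "binary_view": self.label.binary_view.value,
            "features": dict(
                zip(
                    F.PositionalFeatures._SCOPE_FIELDS + ("is_neutral_candidate",),
                    self.features.as_tuple(),
                )
            ),
            "matched_neutral_rule": self.matched_neutral_rule,
            "n_negation_events": self.n_negation_events,
        }


def nnb_explain(
    candidate: AssociationCandidate,
    sentence: Sentence,
    config: NNBConfig | None = None,
    mode: Source = Source.HEURISTIC,
) -> NNBResult:
    """Run the full pipeline — negation detection, neutral detection,
    scope-position features, rule decision — and keep the intermediates."""
    cfg = config or NNBConfig()
    events = F.detect_negation(
        sentence, cfg.negation_cues, mode=mode, connector_lexicon=cfg.connector_lexicon
    )
    is_neutral, rule_id = F.detect_neutral(candidate, sentence, cfg.neutral_rules)
    feats = F.positional_features(candidate, events, is_neutral)
    return NNBResult(
        candidate_id=candidate.candidate_id,
        label=nnb_predict(feats),
        features=feats,
        matched_neutral_rule=rule_id,
        n_negation_events=len(events),
    )


def nnb_classify(
    candidate: AssociationCandidate,
    sentence: Sentence,
    config: NNBConfig | None = None,
    mode: Source = Source.HEURISTIC,
) -> AssociationLabel:
    """Deterministic association decision for one candidate in a sentence."""
    return nnb_explain(candidate, sentence, config, mode).label
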