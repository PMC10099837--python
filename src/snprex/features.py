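"""Rule- and lexicon-based linguistic extractors.

Everything here is deterministic: tokenization, negation cue/scope detection,
the six scope-position Booleans, neutral-candidate rules, clause connectors,
modality (hedging) markers and p-value mentions.  Each extractor that has a
gold-annotated counterpart in the corpus exposes a GOLD/HEURISTIC mode flag;
GOLD returns the corpus annotations unchanged, HEURISTIC applies the shipped
rules to raw text.

Lexicons and neutral rules are plain Python data that can also be loaded
from JSON files (one pattern per entry), so they are editable configuration
rather than hard-wired behaviour.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import (
    AssociationCandidate,
    EntityKind,
    ModalityMarker,
    NegationEvent,
    Sentence,
    Source,
    Span,
)

__all__ = [
    "tokenize",
    "ConnectorLexicon",
    "ClauseConnector",
    "NeutralRule",
    "PValueMention",
    "PositionalFeatures",
    "DEFAULT_NEGATION_CUES",
    "DEFAULT_CONNECTOR_LEXICON",
    "DEFAULT_MODALITY_MARKERS",
    "DEFAULT_NEUTRAL_RULES",
    "detect_negation",
    "detect_clause_connectors",
    "detect_modality_markers",
    "detect_neutral",
    "blind_entities",
    "extract_pvalues",
    "positional_features",
    "classify_event_position",
]


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[Span]:
    """Whitespace-and-punctuation token spans, in order.

    Word characters group into one token; every other non-space character is
    its own token.  Token surfaces concatenate back to the input with all
    whitespace removed.
    """
    return [Span(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# lexicons
# ---------------------------------------------------------------------------

DEFAULT_NEGATION_CUES: tuple[str, ...] = (
    "no",
    "not",
    "without",
    "neither",
    "nor",
    "never",
    "cannot",
    "lack",
    "absence",
)

DEFAULT_MODALITY_MARKERS: tuple[str, ...] = (
    "may",
    "might",
    "could",
    "suggest",
    "suggests",
    "likely",
    "possibly",
    "appear",
    "seem",
)


@dataclass(frozen=True)
class ConnectorLexicon:
    """Clause connectors with a concessive subset.  Entries may be
    multi-word phrases; longer phrases take precedence when matching."""

    connectors: tuple[str, ...]
    concessive: frozenset[str]

    @classmethod
    def from_json(cls, path) -> "ConnectorLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(tuple(data["connectors"]), frozenset(data["concessive"]))


DEFAULT_CONNECTOR_LEXICON = ConnectorLexicon(
    connectors=(
        "although",
        "though",
        "even though",
        "whereas",
        "while",
        "but",
        "however",
        "nevertheless",
        "because",
        "since",
        "therefore",
        "thus",
        "hence",
        "moreover",
        "furthermore",
        "whether",
    ),
    concessive=frozenset(
        {
            "although",
            "though",
            "even though",
            "whereas",
            "while",
            "but",
            "however",
            "nevertheless",
        }
    ),
)


@dataclass(frozen=True)
class ClauseConnector:
    span: Span
    text: str
    is_concessive: bool


def _phrase_pattern(phrase: str) -> re.Pattern:
    return re.compile(
        r"(?<!\w)" + r"\s+".join(re.escape(w) for w in phrase.split()) + r"(?!\w)",
        re.IGNORECASE,
    )


def detect_clause_connectors(
    sentence: Sentence | str, lexicon: ConnectorLexicon = DEFAULT_CONNECTOR_LEXICON
) -> list[ClauseConnector]:
    """Whole-token lexicon matches, longest phrase first, no overlaps."""
    text = sentence if isinstance(sentence, str) else sentence.text
    taken = [False] * len(text)
    found: list[ClauseConnector] = []
    for phrase in sorted(lexicon.connectors, key=lambda p: -len(p.split())):
        for m in _phrase_pattern(phrase).finditer(text):
            if any(taken[m.start() : m.end()]):
                continue
            for i in range(m.start(), m.end()):
                taken[i] = True
            found.append(
                ClauseConnector(
                    span=Span(m.start(), m.end()),
                    text=m.group(0),
                    is_concessive=phrase in lexicon.concessive,
                )
            )
    found.sort(key=lambda c: c.span.start)
    return found


# ---------------------------------------------------------------------------
# negation cues and scopes
# ---------------------------------------------------------------------------

def detect_negation(
    sentence: Sentence,
    cue_lexicon: Sequence[str] = DEFAULT_NEGATION_CUES,
    mode: Source = Source.HEURISTIC,
    connector_lexicon: ConnectorLexicon = DEFAULT_CONNECTOR_LEXICON,
) -> list[NegationEvent]:
    """Negation events of a sentence.

    GOLD mode returns the corpus annotations unchanged (error if the sentence
    carries none, i.e. was never annotated).  HEURISTIC mode matches
    whole-token cues from ``cue_lexicon`` and assigns as scope the interval
    from the token after the cue to the sentence end or the start of the
    first clause connector after the cue, whichever is nearer.  The scope
    therefore never crosses a clause connector.
    """
    if mode is Source.GOLD:
        if not sentence.gold_annotated:
            raise ValueError(
                f"sentence {sentence.sent_id} has no gold negation annotations"
            )
        return list(sentence.negations)

    cues = {c.lower() for c in cue_lexicon}
    tokens = tokenize(sentence.text)
    connector_starts = [
        c.span.start for c in detect_clause_connectors(sentence, connector_lexicon)
    ]
    events: list[NegationEvent] = []
    for i, tok in enumerate(tokens):
        surface = sentence.text[tok.start : tok.end]
        if surface.lower() not in cues:
            continue
        scope_start = tokens[i + 1].start if i + 1 < len(tokens) else tok.end
        scope_end = len(sentence.text)
        for cstart in connector_starts:
            if cstart >= scope_start:
                scope_end = min(scope_end, cstart)
                break
        scope_end = max(scope_end, scope_start)
        events.append(
            NegationEvent(
                cue_span=tok,
                cue_text=surface,
                scope_span=Span(scope_start, scope_end),
                source=Source.HEURISTIC,
            )
        )
    return events


# ---------------------------------------------------------------------------
# modality markers
# ---------------------------------------------------------------------------

def detect_modality_markers(
    sentence: Sentence,
    lexicon: Sequence[str] = DEFAULT_MODALITY_MARKERS,
    mode: Source = Source.HEURISTIC,
) -> list[ModalityMarker]:
    """Hedging markers.  GOLD returns annotations; HEURISTIC matches
    whole-token lexicon entries."""
    if mode is Source.GOLD:
        if not sentence.gold_annotated:
            raise ValueError(
                f"sentence {sentence.sent_id} has no gold modality annotations"
            )
        return list(sentence.modality_markers)
    wanted = {w.lower() for w in lexicon}
    out: list[ModalityMarker] = []
    for tok in tokenize(sentence.text):
        surface = sentence.text[tok.start : tok.end]
        if surface.lower() in wanted:
            out.append(ModalityMarker(span=tok, text=surface, source=Source.HEURISTIC))
    return out


# ---------------------------------------------------------------------------
# neutral-candidate rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralRule:
    rule_id: str
    pattern: str
    description: str = ""

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


DEFAULT_NEUTRAL_RULES: tuple[NeutralRule, ...] = (
    NeutralRule("genotyped", r"\bgenotyp(?:e|es|ed|ing)\b", "study-setup: genotyping statement"),
    NeutralRule("examined", r"\bexamin(?:e|es|ed|ing)\b", "study-setup: examination statement"),
    NeutralRule(
        "investigated", r"\binvestigat(?:e|es|ed|ing)\b", "study-setup: investigation statement"
    ),
    NeutralRule("recruited", r"\brecruit(?:s|ed|ing)?\b", "study-setup: recruitment statement"),
    NeutralRule("enrolled", r"\benrol(?:l|ls|led|ling)\b", "study-setup: enrolment statement"),
    NeutralRule(
        "aim_of_study", r"\baim of (?:this|the|our) study\b", "study-setup: stated study aim"
    ),
    NeutralRule("measured", r"\bmeasur(?:e|es|ed|ing)\b", "study-setup: measurement statement"),
)


def load_neutral_rules(path) -> tuple[NeutralRule, ...]:
    """Neutral rules from a JSON list of {rule_id, pattern, description}."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    rules = tuple(
        NeutralRule(d["rule_id"], d["pattern"], d.get("description", "")) for d in data
    )
    for r in rules:
        r.compiled()  # fail fast on a pattern that does not compile
    return rules


def blind_entities(sentence: Sentence) -> str:
    """Sentence text with every entity surface replaced by a placeholder tag
    ([SNP] or [PHENOTYPE]); overlapping mentions are collapsed left-to-right."""
    repl = {EntityKind.SNP: "[SNP]", EntityKind.PHENOTYPE: "[PHENOTYPE]"}
    spans = sorted(sentence.entities, key=lambda e: (e.span.start, e.span.end))
    out: list[str] = []
    pos = 0
    for ent in spans:
        if ent.span.start < pos:
            continue  # overlapping mention already covered
        out.append(sentence.text[pos : ent.span.start])
        out.append(repl[ent.kind])
        pos = ent.span.end
    out.append(sentence.text[pos:])
    return "".join(out)


def detect_neutral(
    candidate: AssociationCandidate,
    sentence: Sentence,
    rules: Sequence[NeutralRule] = DEFAULT_NEUTRAL_RULES,
) -> tuple[bool, str | None]:
    """True iff any neutral rule matches the entity-blinded sentence text.

    Rules are tried in their listed order; the first match wins, so the
    result is deterministic and invariant to the specific SNP/phenotype
    surface strings.
    """
    blinded = blind_entities(sentence)
    for rule in rules:
        if rule.compiled().search(blinded):
            return True, rule.rule_id
    return False, None


# ---------------------------------------------------------------------------
# p-value mentions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PValueMention:
    comparator: str  # one of < <= = > >=
    value: float
    span: Span


_PVALUE_RE = re.compile(
    r"""
    \b[pP]\b (?:\s*-?\s*values?)?       # p, P, p-value, P values ...
    \s* (?P<cmp><=|>=|[<>=]|≤|≥) \s*
    (?P<base>\d+(?:\.\d+)?)
    (?:
        \s*[×x*]\s*10\s*(?:\^|\*\*)?\s*\(?\s*(?P<exp10>[−‐+-]?\s*\d+)\s*\)?   # 3.2 × 10−5
      | [eE](?P<expe>[−‐+-]?\d+)                                              # 3.2e-5
    )?
    """,
    re.VERBOSE,
)

_CMP_NORM = {"≤": "<=", "≥": ">="}


def _parse_exponent(raw: str) -> int:
    raw = raw.replace("−", "-").replace("‐", "-").replace(" ", "")
    return int(raw)


def extract_pvalues(sentence: Sentence | str) -> list[PValueMention]:
    """P-value mentions such as ``P < 0.001`` or ``p = 3.2 × 10−5``.

    Handles decimal and scientific notation, the typographic minus and the
    ``×10`` exponent form.  A matched number that fails to parse is skipped
    with a warning.
    """
    text = sentence if isinstance(sentence, str) else sentence.text
    out: list[PValueMention] = []
    for m in _PVALUE_RE.finditer(text):
        try:
            value = float(m.group("base"))
            raw_exp = m.group("exp10") or m.group("expe")
            if raw_exp is not None:
                value *= 10.0 ** _parse_exponent(raw_exp)
        except ValueError:
            warnings.warn(f"unparseable p-value mention {m.group(0)!r}; skipped")
            continue
        cmp_ = _CMP_NORM.get(m.group("cmp"), m.group("cmp"))
        out.append(PValueMention(comparator=cmp_, value=value, span=Span(m.start(), m.end())))
    return out


# ---------------------------------------------------------------------------
# scope-position features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionalFeatures:
    """The seven Booleans driving the rule-based association decision: six
    mutually exclusive positions of the (SNP, phenotype) pair relative to a
    negation scope, plus the neutral-candidate indicator.

    With no negation event all six position Booleans are false.  With several
    events, candidate-level values are the event-wise disjunctions.
    """

    both_inside: bool = False  # BothInsNegSc
    one_left_one_inside: bool = False  # OneLeftOneInsNegSc
    one_right_one_inside: bool = False  # OneRightOneInsNegSc
    both_left: bool = False
    both_right: bool = False
    one_left_one_right: bool = False
    is_neutral_candidate: bool = False

    _SCOPE_FIELDS = (
        "both_inside",
        "one_left_one_inside",
        "one_right_one_inside",
        "both_left",
        "both_right",
        "one_left_one_right",
    )

    def scope_values(self) -> tuple[bool, ...]:
        return tuple(getattr(self, f) for f in self._SCOPE_FIELDS)

    def as_tuple(self) -> tuple[bool, ...]:
        return self.scope_values() + (self.is_neutral_candidate,)


def _position(entity_span: Span, scope: Span) -> str:
    """inside / left / right of a scope interval.

    "Inside" means span intersection (an entity straddling the scope
    boundary counts as inside); otherwise the entity start offset decides
    the side.
    """
    if entity_span.intersects(scope):
        return "inside"
    return "left" if entity_span.start < scope.start else "right"


def classify_event_position(
    snp_span: Span, phenotype_span: Span, scope: Span
) -> str:
    """Which of the six scope-position possibilities holds for one event.

    Exactly one possibility holds for any spans, so the six Booleans form an
    exhaustive, mutually exclusive partition.
    """
    ps, pp = _position(snp_span, scope), _position(phenotype_span, scope)
    pair = frozenset((ps, pp)) if ps != pp else {ps}
    if ps == pp == "inside":
        return "both_inside"
    if ps == pp == "left":
        return "both_left"
    if ps == pp == "right":
        return "both_right"
    if pair == frozenset(("left", "inside")):
        return "one_left_one_inside"
    if pair == frozenset(("right", "inside")):
        return "one_right_one_inside"
    return "one_left_one_right"


def positional_features(
    candidate: AssociationCandidate,
    events: Sequence[NegationEvent],
    is_neutral: bool,
) -> PositionalFeatures:
    """Candidate-level scope-position features: the disjunction, over
    negation events, of each per-event position Boolean."""
    flags = dict.fromkeys(PositionalFeatures._SCOPE_FIELDS, False)
    for ev in events:
        flags[
            classify_event_position(candidate.snp.span, candidate.phenotype.span, ev.scope_span)
        ] = True
    return PositionalFeatures(is_neutral_candidate=is_neutral, **flags)
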