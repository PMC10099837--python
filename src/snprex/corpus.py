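"""Data model and I/O for SNPPhenA-style annotated corpora.

A corpus is a collection of abstracts; each abstract is a list of sentences
carrying entity mentions (SNPs named by rs-identifiers and phenotypes),
negation events (cue + scope), modality markers and gold association
candidates.  All character offsets are 0-based half-open intervals on the
NFC-normalized sentence string.

The native XML dialect (``schema="snprexml"``) is defined by this package
and documented in ``docs/methods.md``.  A best-effort importer for the
DDI-style dialect used by the published SNPPhenA distribution is available
behind ``schema="snpphena"``; it is never required by the test suite.
"""

from __future__ import annotations

import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

from lxml import etree

__all__ = [
    "Span",
    "Label",
    "Certainty",
    "Source",
    "EntityKind",
    "EntityMention",
    "NegationEvent",
    "ModalityMarker",
    "CandidateAnnotation",
    "AssociationCandidate",
    "Sentence",
    "AbstractDocument",
    "Corpus",
    "CorpusStats",
    "CorpusParseError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "corpus_to_bytes",
    "enumerate_candidates",
    "corpus_statistics",
]


class CorpusParseError(ValueError):
    """Raised when an input file is not well-formed in the requested dialect."""


class CorpusValidationError(ValueError):
    """Raised when an annotation violates the data-model invariants."""


class Span(NamedTuple):
    """Half-open character interval ``[start, end)``."""

    start: int
    end: int

    def intersects(self, other: "Span") -> bool:
        return self.start < other.end and self.end > other.start

    def within(self, length: int) -> bool:
        return 0 <= self.start <= self.end <= length


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    UNLABELED = "unlabeled"


class Certainty(str, Enum):
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    NONE = "none"


class Source(str, Enum):
    GOLD = "gold"
    HEURISTIC = "heuristic"


class EntityKind(str, Enum):
    SNP = "SNP"
    PHENOTYPE = "PHENOTYPE"


@dataclass(frozen=True)
class EntityMention:
    mention_id: str
    kind: EntityKind
    span: Span
    surface: str


@dataclass(frozen=True)
class NegationEvent:
    cue_span: Span
    cue_text: str
    scope_span: Span
    source: Source = Source.GOLD


@dataclass(frozen=True)
class ModalityMarker:
    span: Span
    text: str
    source: Source = Source.GOLD


@dataclass(frozen=True)
class CandidateAnnotation:
    """Gold annotation for one (SNP mention, phenotype mention) pair."""

    snp_id: str
    phenotype_id: str
    label: Label = Label.UNLABELED
    certainty: Certainty = Certainty.NONE


@dataclass(frozen=True)
class AssociationCandidate:
    """One (SNP mention, phenotype mention) pair within a sentence."""

    sentence_id: str
    snp: EntityMention
    phenotype: EntityMention
    gold_label: Label = Label.UNLABELED
    gold_certainty: Certainty = Certainty.NONE

    def __post_init__(self) -> None:
        if self.snp.kind is not EntityKind.SNP:
            raise CorpusValidationError(
                f"candidate SNP slot holds a {self.snp.kind.value} mention"
            )
        if self.phenotype.kind is not EntityKind.PHENOTYPE:
            raise CorpusValidationError(
                f"candidate phenotype slot holds a {self.phenotype.kind.value} mention"
            )
        if self.gold_certainty is not Certainty.NONE and self.gold_label is not Label.POSITIVE:
            raise CorpusValidationError(
                "degree of certainty is defined only for positive candidates"
            )

    @property
    def candidate_id(self) -> str:
        return f"{self.sentence_id}|{self.snp.mention_id}|{self.phenotype.mention_id}"


@dataclass
class Sentence:
    sent_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    negations: list[NegationEvent] = field(default_factory=list)
    modality_markers: list[ModalityMarker] = field(default_factory=list)
    candidates: list[CandidateAnnotation] = field(default_factory=list)
    is_key: bool = False
    gold_annotated: bool = True

    def mentions(self, kind: EntityKind) -> list[EntityMention]:
        return [e for e in self.entities if e.kind is kind]

    def entity(self, mention_id: str) -> EntityMention:
        for e in self.entities:
            if e.mention_id == mention_id:
                return e
        raise CorpusValidationError(
            f"sentence {self.sent_id}: unknown entity id {mention_id!r}"
        )


@dataclass
class AbstractDocument:
    doc_id: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Corpus:
    documents: list[AbstractDocument] = field(default_factory=list)
    split_tag: str = "unsplit"
    provenance: str = ""

    def sentences(self) -> Iterable[tuple[AbstractDocument, Sentence]]:
        for doc in self.documents:
            for sent in doc.sentences:
                yield doc, sent


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_sentence(sentence: Sentence) -> None:
    n = len(sentence.text)
    for ent in sentence.entities:
        if not ent.span.within(n):
            raise CorpusValidationError(
                f"sentence {sentence.sent_id}: entity {ent.mention_id} span "
                f"{tuple(ent.span)} outside text of length {n}"
            )
        if sentence.text[ent.span.start : ent.span.end] != ent.surface:
            raise CorpusValidationError(
                f"sentence {sentence.sent_id}: entity {ent.mention_id} surface "
                f"does not match the text at its span"
            )
    seen: dict[str, Span] = {}
    for ent in sentence.entities:
        if ent.mention_id in seen:
            raise CorpusValidationError(
                f"sentence {sentence.sent_id}: duplicate entity id {ent.mention_id}"
            )
        seen[ent.mention_id] = ent.span
    for ev in sentence.negations:
        for sp, what in ((ev.cue_span, "negation cue"), (ev.scope_span, "negation scope")):
            if not sp.within(n):
                raise CorpusValidationError(
                    f"sentence {sentence.sent_id}: {what} span {tuple(sp)} "
                    f"outside text of length {n}"
                )
    for mk in sentence.modality_markers:
        if not mk.span.within(n):
            raise CorpusValidationError(
                f"sentence {sentence.sent_id}: modality span {tuple(mk.span)} "
                f"outside text of length {n}"
            )
    ids = {e.mention_id for e in sentence.entities}
    for cand in sentence.candidates:
        for mid in (cand.snp_id, cand.phenotype_id):
            if mid not in ids:
                raise CorpusValidationError(
                    f"sentence {sentence.sent_id}: candidate refers to unknown "
                    f"entity {mid!r}"
                )


def validate_corpus(corpus: Corpus) -> None:
    doc_ids: set[str] = set()
    for doc in corpus.documents:
        if doc.doc_id in doc_ids:
            raise CorpusValidationError(f"duplicate document id {doc.doc_id}")
        doc_ids.add(doc.doc_id)
        sent_ids: set[str] = set()
        for sent in doc.sentences:
            if sent.sent_id in sent_ids:
                raise CorpusValidationError(
                    f"document {doc.doc_id}: duplicate sentence id {sent.sent_id}"
                )
            sent_ids.add(sent.sent_id)
            validate_sentence(sent)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(sentence: Sentence) -> list[AssociationCandidate]:
    """All (SNP, phenotype) mention pairs of a sentence, in reading order.

    Pairs are ordered by (SNP span start, phenotype span start).  Gold labels
    and certainty levels are attached from the sentence's candidate
    annotations when present, else left UNLABELED/NONE.
    """
    validate_sentence(sentence)
    gold = {(c.snp_id, c.phenotype_id): c for c in sentence.candidates}
    snps = sorted(sentence.mentions(EntityKind.SNP), key=lambda e: (e.span.start, e.mention_id))
    phens = sorted(
        sentence.mentions(EntityKind.PHENOTYPE), key=lambda e: (e.span.start, e.mention_id)
    )
    out: list[AssociationCandidate] = []
    for s in snps:
        for p in phens:
            ann = gold.get((s.mention_id, p.mention_id))
            out.append(
                AssociationCandidate(
                    sentence_id=sentence.sent_id,
                    snp=s,
                    phenotype=p,
                    gold_label=ann.label if ann else Label.UNLABELED,
                    gold_certainty=ann.certainty if ann else Certainty.NONE,
                )
            )
    return out


# ---------------------------------------------------------------------------
# XML serialization (native "snprexml" dialect)
# ---------------------------------------------------------------------------

_XML_ROOT = "snprex-corpus"


def _span_attrs(el: etree._Element, prefix: str, span: Span) -> None:
    el.set(f"{prefix}start", str(span.start))
    el.set(f"{prefix}end", str(span.end))


def corpus_to_bytes(corpus: Corpus) -> bytes:
    """Canonical, deterministic UTF-8 serialization of a corpus."""
    validate_corpus(corpus)
    root = etree.Element(_XML_ROOT)
    root.set("split", corpus.split_tag)
    if corpus.provenance:
        root.set("provenance", corpus.provenance)
    for doc in corpus.documents:
        del_ = etree.SubElement(root, "abstract")
        del_.set("id", doc.doc_id)
        for sent in doc.sentences:
            sel = etree.SubElement(del_, "sentence")
            sel.set("id", sent.sent_id)
            sel.set("key", "true" if sent.is_key else "false")
            sel.set("annotated", "true" if sent.gold_annotated else "false")
            tel = etree.SubElement(sel, "text")
            tel.text = sent.text
            for ent in sent.entities:
                eel = etree.SubElement(sel, "entity")
                eel.set("id", ent.mention_id)
                eel.set("kind", ent.kind.value)
                _span_attrs(eel, "", ent.span)
            for ev in sent.negations:
                nel = etree.SubElement(sel, "negation")
                _span_attrs(nel, "cue-", ev.cue_span)
                _span_attrs(nel, "scope-", ev.scope_span)
                nel.set("source", ev.source.value)
            for mk in sent.modality_markers:
                mel = etree.SubElement(sel, "modality")
                _span_attrs(mel, "", mk.span)
                mel.set("source", mk.source.value)
            for cand in sent.candidates:
                cel = etree.SubElement(sel, "pair")
                cel.set("snp", cand.snp_id)
                cel.set("phenotype", cand.phenotype_id)
                cel.set("label", cand.label.value)
                cel.set("certainty", cand.certainty.value)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_corpus(corpus: Corpus, path) -> None:
    data = corpus_to_bytes(corpus)  # validates before any write
    with open(path, "wb") as fh:
        fh.write(data)


def _parse_span(el: etree._Element, prefix: str, sent_id: str) -> Span:
    try:
        return Span(int(el.get(f"{prefix}start")), int(el.get(f"{prefix}end")))
    except (TypeError, ValueError) as exc:
        raise CorpusParseError(
            f"sentence {sent_id}: bad {prefix or 'entity '}span attributes on "
            f"<{el.tag}> (line {el.sourceline})"
        ) from exc


def _enum_or_default(enum_cls, raw, default):
    try:
        return enum_cls(raw)
    except ValueError:
        return default


def _read_snprexml(root: etree._Element) -> Corpus:
    corpus = Corpus(
        split_tag=root.get("split", "unsplit"),
        provenance=root.get("provenance", ""),
    )
    for del_ in root.findall("abstract"):
        doc = AbstractDocument(doc_id=del_.get("id", ""))
        for sel in del_.findall("sentence"):
            sid = sel.get("id", "")
            tel = sel.find("text")
            text = unicodedata.normalize("NFC", tel.text or "") if tel is not None else ""
            sent = Sentence(
                sent_id=sid,
                text=text,
                is_key=sel.get("key") == "true",
                gold_annotated=sel.get("annotated", "true") == "true",
            )
            for eel in sel.findall("entity"):
                span = _parse_span(eel, "", sid)
                if not span.within(len(text)):
                    raise CorpusValidationError(
                        f"sentence {sid}: entity span {tuple(span)} outside text"
                    )
                sent.entities.append(
                    EntityMention(
                        mention_id=eel.get("id", ""),
                        kind=EntityKind(eel.get("kind", "SNP")),
                        span=span,
                        surface=text[span.start : span.end],
                    )
                )
            for nel in sel.findall("negation"):
                cue = _parse_span(nel, "cue-", sid)
                scope = _parse_span(nel, "scope-", sid)
                sent.negations.append(
                    NegationEvent(
                        cue_span=cue,
                        cue_text=text[cue.start : cue.end],
                        scope_span=scope,
                        source=_enum_or_default(Source, nel.get("source"), Source.GOLD),
                    )
                )
            for mel in sel.findall("modality"):
                span = _parse_span(mel, "", sid)
                sent.modality_markers.append(
                    ModalityMarker(
                        span=span,
                        text=text[span.start : span.end],
                        source=_enum_or_default(Source, mel.get("source"), Source.GOLD),
                    )
                )
            for cel in sel.findall("pair"):
                sent.candidates.append(
                    CandidateAnnotation(
                        snp_id=cel.get("snp", ""),
                        phenotype_id=cel.get("phenotype", ""),
                        label=_enum_or_default(Label, cel.get("label"), Label.UNLABELED),
                        certainty=_enum_or_default(
                            Certainty, cel.get("certainty"), Certainty.NONE
                        ),
                    )
                )
            doc.sentences.append(sent)
        corpus.documents.append(doc)
    validate_corpus(corpus)
    return corpus


def _read_ddi_style(root: etree._Element) -> Corpus:
    """Best-effort importer for the DDI-style XML used by the published
    SNPPhenA distribution: ``document``/``sentence``/``entity``/``pair``
    elements with end-inclusive ``charOffset="a-b"`` attributes.

    Unparseable optional fields default to UNLABELED/NONE.
    """
    corpus = Corpus(split_tag="unsplit", provenance="snpphena-import")
    docs = root.findall(".//document") if root.tag != "document" else [root]
    for del_ in docs:
        doc = AbstractDocument(doc_id=del_.get("id", ""))
        for sel in del_.findall("sentence"):
            sid = sel.get("id", "")
            text = unicodedata.normalize("NFC", sel.get("text", "") or "")
            sent = Sentence(sent_id=sid, text=text, is_key=True, gold_annotated=True)
            for eel in sel.findall("entity"):
                offs = (eel.get("charOffset") or "").split(";")[0]
                try:
                    a, b = offs.split("-")
                    span = Span(int(a), int(b) + 1)  # end-inclusive -> half-open
                except ValueError:
                    continue
                if not span.within(len(text)):
                    raise CorpusValidationError(
                        f"sentence {sid}: entity span {tuple(span)} outside text"
                    )
                raw_kind = (eel.get("type") or "").upper()
                kind = EntityKind.SNP if "SNP" in raw_kind else EntityKind.PHENOTYPE
                sent.entities.append(
                    EntityMention(
                        mention_id=eel.get("id", ""),
                        kind=kind,
                        span=span,
                        surface=text[span.start : span.end],
                    )
                )
            kinds = {e.mention_id: e.kind for e in sent.entities}
            for cel in sel.findall("pair"):
                e1, e2 = cel.get("e1", ""), cel.get("e2", "")
                if kinds.get(e1) is EntityKind.SNP and kinds.get(e2) is EntityKind.PHENOTYPE:
                    snp_id, phen_id = e1, e2
                elif kinds.get(e2) is EntityKind.SNP and kinds.get(e1) is EntityKind.PHENOTYPE:
                    snp_id, phen_id = e2, e1
                else:
                    continue
                raw = (cel.get("association") or cel.get("relation") or "").lower()
                label = _enum_or_default(Label, raw, Label.UNLABELED)
                if label is Label.UNLABELED and raw in ("true", "false"):
                    label = Label.POSITIVE if raw == "true" else Label.NEGATIVE
                raw_cert = (cel.get("confidence") or cel.get("certainty") or "").lower()
                cert = _enum_or_default(Certainty, raw_cert, Certainty.NONE)
                if label is not Label.POSITIVE:
                    cert = Certainty.NONE
                sent.candidates.append(
                    CandidateAnnotation(
                        snp_id=snp_id, phenotype_id=phen_id, label=label, certainty=cert
                    )
                )
            doc.sentences.append(sent)
        corpus.documents.append(doc)
    validate_corpus(corpus)
    return corpus


def read_corpus(path, schema: str = "snprexml") -> Corpus:
    """Read an annotated corpus.

    Parameters
    ----------
    path
        XML file location.
    schema
        ``"snprexml"`` (native dialect, round-trip safe) or ``"snpphena"``
        (best-effort import of the DDI-style published distribution).
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if schema == "snprexml":
        if root.tag != _XML_ROOT:
            raise CorpusParseError(
                f"{path}: expected root <{_XML_ROOT}>, found <{root.tag}>"
            )
        return _read_snprexml(root)
    if schema == "snpphena":
        return _read_ddi_style(root)
    raise ValueError(f"unknown corpus schema {schema!r}")


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

@dataclass
class CorpusStats:
    """Descriptive statistics of a corpus.

    Percentages are reported to one decimal place and always alongside their
    denominators (the corpus literature is not consistent about denominators,
    so they are made explicit here).
    """

    n_documents: int = 0
    n_sentences: int = 0
    n_key_sentences: int = 0
    n_snp_mentions: int = 0
    n_phenotype_mentions: int = 0
    n_candidates: int = 0
    label_counts: dict = field(default_factory=dict)
    certainty_counts: dict = field(default_factory=dict)
    n_candidates_with_negation_cue: int = 0
    n_sentences_with_negation_cue: int = 0
    n_candidates_with_connector: int = 0
    n_connector_analyzed: int = 0
    n_concessive: int = 0
    mean_tokens_per_sentence: float | None = None
    mean_snps_per_sentence: float | None = None
    mean_phenotypes_per_sentence: float | None = None
    negation_cue_frequency_table: dict = field(default_factory=dict)

    @property
    def concessive_pct(self) -> float | None:
        """100 * n_concessive / n_connector_analyzed, one decimal."""
        if self.n_connector_analyzed == 0:
            return None
        return round(100.0 * self.n_concessive / self.n_connector_analyzed, 1)

    @property
    def negation_cue_candidate_pct(self) -> float | None:
        if self.n_candidates == 0:
            return None
        return round(100.0 * self.n_candidates_with_negation_cue / self.n_candidates, 1)

    def to_frame(self):
        """Flat one-row pandas DataFrame view, suitable for CSV export."""
        import pandas as pd

        row = {
            k: v
            for k, v in self.__dict__.items()
            if not isinstance(v, dict)
        }
        for lab, cnt in sorted(self.label_counts.items()):
            row[f"n_label_{lab}"] = cnt
        for lev, cnt in sorted(self.certainty_counts.items()):
            row[f"n_certainty_{lev}"] = cnt
        row["concessive_pct"] = self.concessive_pct
        row["negation_cue_candidate_pct"] = self.negation_cue_candidate_pct
        return pd.DataFrame([row])


def corpus_statistics(corpus: Corpus, tokenizer=None, connector_lexicon=None) -> CorpusStats:
    """Exact descriptive counts of a corpus, computed from the data.

    ``tokenizer`` defaults to the package tokenizer; ``connector_lexicon``
    defaults to the shipped clause-connector lexicon.  Mean statistics are
    ``None`` (flagged absent) on an empty corpus.
    """
    from . import features  # local import: features depends on this module

    tok = tokenizer or features.tokenize
    lex = connector_lexicon or features.DEFAULT_CONNECTOR_LEXICON

    stats = CorpusStats()
    stats.label_counts = Counter()
    stats.certainty_counts = Counter()
    cue_freq: Counter = Counter()
    tok_counts: list[int] = []
    snp_counts: list[int] = []
    phen_counts: list[int] = []

    for doc in corpus.documents:
        stats.n_documents += 1
        for sent in doc.sentences:
            stats.n_sentences += 1
            if sent.is_key:
                stats.n_key_sentences += 1
            snps = sent.mentions(EntityKind.SNP)
            phens = sent.mentions(EntityKind.PHENOTYPE)
            stats.n_snp_mentions += len(snps)
            stats.n_phenotype_mentions += len(phens)
            tok_counts.append(len(tok(sent.text)))
            snp_counts.append(len(snps))
            phen_counts.append(len(phens))
            if sent.negations:
                stats.n_sentences_with_negation_cue += 1
            for ev in sent.negations:
                cue_freq[ev.cue_text.lower()] += 1
            cands = enumerate_candidates(sent)
            connectors = features.detect_clause_connectors(sent, lex)
            for cand in cands:
                stats.n_candidates += 1
                stats.label_counts[cand.gold_label.value] += 1
                if cand.gold_certainty is not Certainty.NONE:
                    stats.certainty_counts[cand.gold_certainty.value] += 1
                if sent.negations:
                    stats.n_candidates_with_negation_cue += 1
                if connectors:
                    stats.n_candidates_with_connector += 1
                stats.n_connector_analyzed += len(connectors)
                stats.n_concessive += sum(1 for c in connectors if c.is_concessive)

    if stats.n_sentences:
        stats.mean_tokens_per_sentence = sum(tok_counts) / stats.n_sentences
        stats.mean_snps_per_sentence = sum(snp_counts) / stats.n_sentences
        stats.mean_phenotypes_per_sentence = sum(phen_counts) / stats.n_sentences
    stats.negation_cue_frequency_table = dict(
        sorted(cue_freq.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    stats.label_counts = dict(stats.label_counts)
    stats.certainty_counts = dict(stats.certainty_counts)
    return stats
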