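"""Modality-based supervised (MBS) degree-of-certainty grading.

Positive SNP-phenotype associations carry a three-level strength annotation
(weak / moderate / strong) reflecting the author's confidence.  The MBS
classifier predicts it from three linguistic signal groups extracted by
regular expressions: hedging (modality) markers, the sentence's reported
p-value, and clause connectors (concessive clauses weaken certainty).  The
classifier itself is a margin (SVM-family) model; gold and heuristic marker
sources are supported symmetrically so the pipeline also runs on
unannotated text.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from . import features as F
from .corpus import AssociationCandidate, Certainty, Label, Sentence, Source

__all__ = [
    "CertaintyFeatureVector",
    "CertaintyModel",
    "mbs_features",
    "train_certainty_model",
    "predict_certainty",
    "DEFAULT_SIGNIFICANCE_ALPHA",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class CertaintyFeatureVector:
    """Features feeding the certainty classifier.

    ``marker_indicators`` has one Boolean per lexicon marker (the schema is
    the marker lexicon, in order).  P-value fields are absent/false when no
    p-value is mentioned.
    """

    marker_indicators: tuple[bool, ...]
    marker_lexicon: tuple[str, ...]
    n_markers: int
    has_pvalue: bool
    min_pvalue: float | None
    pvalue_significant: bool
    has_connector: bool
    has_concessive: bool

    def __post_init__(self) -> None:
        if not self.has_pvalue and (self.min_pvalue is not None or self.pvalue_significant):
            raise ValueError("p-value fields must be absent when has_pvalue is false")
        if len(self.marker_indicators) != len(self.marker_lexicon):
            raise ValueError("marker indicators must align with the marker lexicon")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"marker:{m}" for m in self.marker_lexicon) + (
            "n_markers",
            "has_pvalue",
            "neglog_min_pvalue",
            "pvalue_significant",
            "has_connector",
            "has_concessive",
        )

    def to_array(self) -> np.ndarray:
        neglog = 0.0
        if self.min_pvalue is not None and self.min_pvalue > 0:
            neglog = -np.log10(self.min_pvalue)
        return np.array(
            [float(b) for b in self.marker_indicators]
            + [
                float(self.n_markers),
                float(self.has_pvalue),
                neglog,
                float(self.pvalue_significant),
                float(self.has_connector),
                float(self.has_concessive),
            ]
        )


def _pvalue_is_significant(pv: F.PValueMention, alpha: float) -> bool:
    """Whether the mention bounds the p-value below ``alpha``."""
    if pv.comparator in ("<", "<="):
        return pv.value <= alpha
    if pv.comparator == "=":
        return pv.value < alpha
    return False  # '>' and '>=' never bound the p-value from above


def mbs_features(
    candidate: AssociationCandidate,
    sentence: Sentence,
    marker_lexicon: Sequence[str] = F.DEFAULT_MODALITY_MARKERS,
    connector_lexicon: F.ConnectorLexicon = F.DEFAULT_CONNECTOR_LEXICON,
    mode: Source = Source.HEURISTIC,
    alpha: float = DEFAULT_SIGNIFICANCE_ALPHA,
    label: Label | None = None,
) -> CertaintyFeatureVector:
    """Certainty features for a POSITIVE candidate.

    ``label`` overrides the candidate's gold label (e.g. a predicted label);
    a non-positive candidate is an error because degree of certainty is
    undefined for it.
    """
    effective = label if label is not None else candidate.gold_label
    if effective is not Label.POSITIVE:
        raise ValueError(
            f"certainty is defined only for positive candidates, got {effective.value}"
        )
    markers = F.detect_modality_markers(sentence, marker_lexicon, mode=mode)
    marker_words = {m.text.lower() for m in markers}
    pvalues = F.extract_pvalues(sentence)
    connectors = F.detect_clause_connectors(sentence, connector_lexicon)
    has_pvalue = bool(pvalues)
    min_pvalue = min((pv.value for pv in pvalues), default=None) if has_pvalue else None
    significant = has_pvalue and any(_pvalue_is_significant(pv, alpha) for pv in pvalues)
    return CertaintyFeatureVector(
        marker_indicators=tuple(m.lower() in marker_words for m in marker_lexicon),
        marker_lexicon=tuple(m.lower() for m in marker_lexicon),
        n_markers=len(markers),
        has_pvalue=has_pvalue,
        min_pvalue=min_pvalue,
        pvalue_significant=significant,
        has_connector=bool(connectors),
        has_concessive=any(c.is_concessive for c in connectors),
    )


def _schema_fingerprint(names: tuple[str, ...]) -> str:
    return hashlib.sha256(" ".join(names).encode("utf-8")).hexdigest()[:16]


@dataclass
class CertaintyModel:
    """A fitted margin classifier plus the metadata needed to reuse it
    safely: feature schema fingerprint, hyperparameters, seed, and the
    training majority class (fallback for degenerate inputs)."""

    estimator: SVC
    feature_names: tuple[str, ...]
    schema_fingerprint: str
    hyperparameters: dict
    seed: int
    majority_class: Certainty
    classes: tuple[Certainty, ...]


def train_certainty_model(
    vectors: Sequence[CertaintyFeatureVector],
    labels: Sequence[Certainty],
    class_weights: dict | None = None,
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> CertaintyModel:
    """Fit the certainty classifier.

    Raises on an empty training set or a single-level one (a margin
    classifier needs at least two distinct levels).
    """
    if len(vectors) == 0:
        raise ValueError("empty training set")
    if len(vectors) != len(labels):
        raise ValueError("features and labels differ in length")
    distinct = set(labels)
    if len(distinct) < 2:
        raise ValueError("training set contains a single certainty level")
    names = vectors[0].feature_names
    for v in vectors:
        if v.feature_names != names:
            raise ValueError("inconsistent feature schemas in training set")
    X = np.vstack([v.to_array() for v in vectors])
    y = np.array([lab.value for lab in labels])
    weight_arg = (
        {k.value if isinstance(k, Certainty) else k: w for k, w in class_weights.items()}
        if class_weights
        else None
    )
    est = SVC(C=C, kernel=kernel, class_weight=weight_arg, random_state=seed)
    est.fit(X, y)
    majority = Certainty(Counter(lab.value for lab in labels).most_common(1)[0][0])
    return CertaintyModel(
        estimator=est,
        feature_names=names,
        schema_fingerprint=_schema_fingerprint(names),
        hyperparameters={"C": C, "kernel": kernel, "class_weight": weight_arg},
        seed=seed,
        majority_class=majority,
        classes=tuple(Certainty(c) for c in est.classes_),
    )


def predict_certainty(model: CertaintyModel, vector: CertaintyFeatureVector) -> Certainty:
    """Predict the certainty level of one positive candidate.

    An all-absent feature vector (no marker, no p-value, no connector)
    carries no signal; the model's training majority class is returned and
    the fallback is logged.
    """
    if _schema_fingerprint(vector.feature_names) != model.schema_fingerprint:
        raise ValueError("feature schema does not match the trained model")
    x = vector.to_array()
    if not np.any(x):
        logger.warning(
            "all-absent certainty features; falling back to majority class %s",
            model.majority_class.value,
        )
        return model.majority_class
    return Certainty(model.estimator.predict(x[None, :])[0])
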