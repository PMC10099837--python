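"""Shallow baseline classifiers, imbalance weighting, grid search, and the
declarative CNN-LSTM architecture specification.

The feature representation for the baselines is an entity-blinded bag of
tokens concatenated with the rule-derived Boolean blocks (scope-position
features and certainty signals); the vocabulary is built from the training
split only, so no test token ever leaks into the representation.

Class weighting follows the inverse-frequency form w_c = N / (K * n_c)
(N total samples, K classes): balanced data gets unit weights and
sum_c n_c * w_c = N always holds.  Deep encoder fine-tuning is out of the
core package; only the architecture specification (layer list + early
stopping policy) is modeled, for consumption by an optional plugin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import get_scorer
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import features as F
from .certainty import DEFAULT_SIGNIFICANCE_ALPHA, _pvalue_is_significant
from .corpus import AssociationCandidate, Sentence, Source

__all__ = [
    "ClassWeighting",
    "compute_class_weights",
    "CandidateVectorizer",
    "GridSearchSpec",
    "GridSearchResult",
    "grid_search",
    "TrainedBaseline",
    "train_baseline",
    "BASELINE_FAMILIES",
    "LayerSpec",
    "ArchitectureSpec",
    "build_cnn_lstm_spec",
]


# ---------------------------------------------------------------------------
# class weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeighting:
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("class weights must be positive")

    def sample_weights(self, y: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[label] for label in y])


def compute_class_weights(counts: Mapping[str, int]) -> ClassWeighting:
    """Inverse-frequency weights w_c = N / (K * n_c).

    Reduces to unit weights for balanced counts and conserves
    sum_c n_c * w_c = N.  A zero-count class is an error (its weight is
    undefined).
    """
    if not counts:
        raise ValueError("no classes given")
    if any(n <= 0 for n in counts.values()):
        raise ValueError("every class must have a positive count")
    total = sum(counts.values())
    k = len(counts)
    return ClassWeighting({c: total / (k * n) for c, n in counts.items()})


# ---------------------------------------------------------------------------
# feature representation
# ---------------------------------------------------------------------------

def _blinded_tokens(sentence: Sentence) -> list[str]:
    blinded = F.blind_entities(sentence)
    return [blinded[s:e].lower() for s, e in F.tokenize(blinded)]


_BOOL_BLOCK_NAMES = tuple(
    f"pos:{n}" for n in F.PositionalFeatures._SCOPE_FIELDS + ("is_neutral_candidate",)
) + (
    "cert:has_marker",
    "cert:has_pvalue",
    "cert:pvalue_significant",
    "cert:has_connector",
    "cert:has_concessive",
)


@dataclass
class CandidateVectorizer:
    """Entity-blinded bag-of-tokens + rule Booleans.

    ``fit`` builds the vocabulary from the training candidates only;
    ``transform`` maps any candidate onto that fixed vocabulary (unknown
    tokens are dropped), so the representation is deterministic and
    leakage-free.
    """

    mode: Source = Source.HEURISTIC
    neutral_rules: tuple = F.DEFAULT_NEUTRAL_RULES
    vocabulary: dict[str, int] = field(default_factory=dict)

    def fit(self, pairs: Sequence[tuple[AssociationCandidate, Sentence]]) -> "CandidateVectorizer":
        vocab: set[str] = set()
        for _cand, sent in pairs:
            vocab.update(_blinded_tokens(sent))
        self.vocabulary = {tok: i for i, tok in enumerate(sorted(vocab))}
        return self

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.vocabulary, key=self.vocabulary.get)) + _BOOL_BLOCK_NAMES

    def transform_one(self, candidate: AssociationCandidate, sentence: Sentence) -> np.ndarray:
        bag = np.zeros(len(self.vocabulary))
        for tok in _blinded_tokens(sentence):
            idx = self.vocabulary.get(tok)
            if idx is not None:
                bag[idx] += 1.0
        events = F.detect_negation(sentence, mode=self.mode)
        is_neutral, _ = F.detect_neutral(candidate, sentence, self.neutral_rules)
        pos = F.positional_features(candidate, events, is_neutral)
        markers = F.detect_modality_markers(sentence, mode=self.mode)
        pvalues = F.extract_pvalues(sentence)
        connectors = F.detect_clause_connectors(sentence)
        bools = np.array(
            [float(b) for b in pos.as_tuple()]
            + [
                float(bool(markers)),
                float(bool(pvalues)),
                float(
                    any(
                        _pvalue_is_significant(pv, DEFAULT_SIGNIFICANCE_ALPHA)
                        for pv in pvalues
                    )
                ),
                float(bool(connectors)),
                float(any(c.is_concessive for c in connectors)),
            ]
        )
        return np.concatenate([bag, bools])

    def transform(self, pairs: Sequence[tuple[AssociationCandidate, Sentence]]) -> np.ndarray:
        if not pairs:
            return np.zeros((0, len(self.vocabulary) + len(_BOOL_BLOCK_NAMES)))
        return np.vstack([self.transform_one(c, s) for c, s in pairs])


# ---------------------------------------------------------------------------
# baselines and grid search
# ---------------------------------------------------------------------------

BASELINE_FAMILIES = (
    "logreg",
    "random_forest",
    "decision_tree",
    "gradient_boosting",
    "naive_bayes",
    "knn",
    "svm",
)

_SUPPORTS_CLASS_WEIGHT = {"logreg", "random_forest", "decision_tree", "svm"}
_SUPPORTS_SAMPLE_WEIGHT = {"gradient_boosting", "naive_bayes"}


def _make_estimator(family: str, seed: int, class_weight: dict | None, params: dict):
    if family == "logreg":
        return LogisticRegression(
            max_iter=2000, random_state=seed, class_weight=class_weight, **params
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, class_weight=class_weight, **params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, class_weight=class_weight, **params)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "naive_bayes":
        return GaussianNB(**params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "svm":
        return SVC(random_state=seed, class_weight=class_weight, **params)
    raise ValueError(f"unknown model family {family!r}; choose from {BASELINE_FAMILIES}")


@dataclass(frozen=True)
class GridSearchSpec:
    """Exhaustive parameter grid with seeded stratified cross-validation."""

    grid: Mapping[str, Sequence]
    k: int = 5
    scoring: str = "f1_macro"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("empty parameter grid")
        if self.k < 2:
            raise ValueError("fold count must be at least 2")


@dataclass
class GridSearchResult:
    best_params: dict
    best_score: float
    scores: list[tuple[dict, float]]  # per-point mean CV score, grid order


def grid_search(
    spec: GridSearchSpec,
    model_family: str,
    X: np.ndarray,
    y: Sequence[str],
    class_weight: dict | None = None,
) -> GridSearchResult:
    """Exhaustively evaluate the grid with seeded stratified k-fold CV.

    Ties are broken in favour of the first-listed parameter point (strict
    improvement is required to displace the incumbent).
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < spec.k:
        raise ValueError(
            f"stratified {spec.k}-fold needs at least {spec.k} examples per class "
            f"(smallest class has {counts.min()})"
        )
    cw = class_weight if model_family in _SUPPORTS_CLASS_WEIGHT else None
    scorer = get_scorer(spec.scoring)
    skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    results: list[tuple[dict, float]] = []
    best: tuple[dict, float] | None = None
    for params in ParameterGrid(dict(spec.grid)):
        fold_scores = []
        for train_idx, test_idx in skf.split(X, y):
            est = _make_estimator(model_family, spec.seed, cw, params)
            est.fit(X[train_idx], y[train_idx])
            fold_scores.append(scorer(est, X[test_idx], y[test_idx]))
        mean_score = float(np.mean(fold_scores))
        results.append((params, mean_score))
        if best is None or mean_score > best[1]:
            best = (params, mean_score)
    return GridSearchResult(best_params=best[0], best_score=best[1], scores=results)


@dataclass
class TrainedBaseline:
    estimator: object
    family: str
    seed: int
    params: dict
    class_weighting: ClassWeighting | None


def train_baseline(
    family: str,
    X: np.ndarray,
    y: Sequence[str],
    weighting: ClassWeighting | None = None,
    seed: int = 0,
    params: dict | None = None,
) -> TrainedBaseline:
    """Fit one shallow baseline with all randomness seeded.

    Class weights are applied natively where the family supports them,
    through per-sample weights for gradient boosting and Gaussian naive
    Bayes, and not at all for k-NN (which has no weighting mechanism).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    params = dict(params or {})
    cw = dict(weighting.weights) if weighting and family in _SUPPORTS_CLASS_WEIGHT else None
    est = _make_estimator(family, seed, cw, params)
    if weighting and family in _SUPPORTS_SAMPLE_WEIGHT:
        est.fit(X, y, sample_weight=weighting.sample_weights(y))
    else:
        est.fit(X, y)
    return TrainedBaseline(
        estimator=est, family=family, seed=seed, params=params, class_weighting=weighting
    )


# ---------------------------------------------------------------------------
# declarative CNN-LSTM architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str
    params: tuple[tuple[str, object], ...]

    @classmethod
    def of(cls, kind: str, **params) -> "LayerSpec":
        return cls(kind=kind, params=tuple(sorted(params.items())))

    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the CNN-LSTM network: embedding, two
    convolution + max-pool blocks, a recurrent memory (LSTM) layer, a fully
    connected layer and a softmax output, with an optional early-stopping
    policy.  No training happens in the core package; an optional deep
    plugin may consume this spec."""

    layers: tuple[LayerSpec, ...]
    n_classes: int
    early_stopping: tuple[tuple[str, object], ...] | None

    def __post_init__(self) -> None:
        out = self.layers[-1]
        if out.kind != "softmax" or out.param_dict().get("units") != self.n_classes:
            raise ValueError("output layer width must equal the number of classes")

    @property
    def has_early_stopping(self) -> bool:
        return self.early_stopping is not None

    def to_dict(self) -> dict:
        return {
            "layers": [{"kind": l.kind, "params": l.param_dict()} for l in self.layers],
            "n_classes": self.n_classes,
            "early_stopping": dict(self.early_stopping) if self.early_stopping else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "ArchitectureSpec":
        return cls(
            layers=tuple(
                LayerSpec.of(l["kind"], **l["params"]) for l in data["layers"]
            ),
            n_classes=data["n_classes"],
            early_stopping=(
                tuple(sorted(data["early_stopping"].items()))
                if data.get("early_stopping")
                else None
            ),
        )

    @classmethod
    def from_json(cls, raw: str) -> "ArchitectureSpec":
        return cls.from_dict(json.loads(raw))


def build_cnn_lstm_spec(
    n_classes: int = 3,
    vocab_size: int = 20000,
    embedding_dim: int = 128,
    conv_filters: tuple[int, int] = (128, 64),
    kernel_size: int = 3,
    pool_size: int = 2,
    lstm_units: int = 64,
    dense_units: int = 64,
    early_stopping_patience: int | None = 5,
    monitored_metric: str = "val_loss",
) -> ArchitectureSpec:
    """The declarative CNN-LSTM layer list: embedding, two conv+max-pool
    blocks, an LSTM memory layer, a dense layer and a softmax output."""
    if n_classes < 2:
        raise ValueError("a classifier needs at least two classes")
    layers = [LayerSpec.of("embedding", vocab_size=vocab_size, dim=embedding_dim)]
    for filters in conv_filters:
        layers.append(LayerSpec.of("conv1d", filters=filters, kernel_size=kernel_size))
        layers.append(LayerSpec.of("max_pool1d", pool_size=pool_size))
    layers.append(LayerSpec.of("lstm", units=lstm_units))
    layers.append(LayerSpec.of("dense", units=dense_units, activation="relu"))
    layers.append(LayerSpec.of("softmax", units=n_classes))
    early = (
        tuple(sorted({"patience": early_stopping_patience, "monitor": monitored_metric}.items()))
        if early_stopping_patience is not None
        else None
    )
    return ArchitectureSpec(layers=tuple(layers), n_classes=n_classes, early_stopping=early)
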