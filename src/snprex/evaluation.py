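"""Evaluation harness: P/R/F1, Cohen's kappa, ROC/AUC, stratified k-fold,
abstract-level aggregation and paired significance tests.

Averaging mode is always explicit in the report (macro by default) because
comparative tables in this literature rarely state it.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .corpus import Label

__all__ = [
    "MetricsReport",
    "SignificanceResult",
    "prf_metrics",
    "cohen_kappa",
    "roc_auc",
    "kfold_split",
    "aggregate_to_abstract",
    "paired_significance",
]


@dataclass
class MetricsReport:
    """Per-class and averaged precision/recall/F1 with supports."""

    per_class: dict  # label -> dict(precision, recall, f1, support)
    macro: tuple[float, float, float]
    weighted: tuple[float, float, float]
    averaging: str = "macro"
    zero_division_flag: bool = False

    @property
    def precision(self) -> float:
        return (self.macro if self.averaging == "macro" else self.weighted)[0]

    @property
    def recall(self) -> float:
        return (self.macro if self.averaging == "macro" else self.weighted)[1]

    @property
    def f1(self) -> float:
        return (self.macro if self.averaging == "macro" else self.weighted)[2]


def _as_strings(labels: Sequence) -> list[str]:
    return [l.value if isinstance(l, Label) else str(l) for l in labels]


def prf_metrics(gold: Sequence, predicted: Sequence, averaging: str = "macro") -> MetricsReport:
    """Multi-class precision/recall/F1 from the confusion matrix.

    Zero-division cases (a class never predicted, or absent from gold) are
    reported as 0 and flagged.
    """
    if len(gold) != len(predicted):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted")
    if len(gold) == 0:
        raise ValueError("empty label sequences")
    if averaging not in ("macro", "weighted"):
        raise ValueError("averaging must be 'macro' or 'weighted'")
    g, p = _as_strings(gold), _as_strings(predicted)
    labels = sorted(set(g) | set(p))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        prec, rec, f1, supp = precision_recall_fscore_support(
            g, p, labels=labels, zero_division=0
        )
    # zero-division detection: a class with no predicted (precision) or no
    # gold (recall) instances
    pred_counts = Counter(p)
    gold_counts = Counter(g)
    zflag = any(pred_counts[l] == 0 or gold_counts[l] == 0 for l in labels)
    per_class = {
        l: {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(supp[i]),
        }
        for i, l in enumerate(labels)
    }
    macro = (float(np.mean(prec)), float(np.mean(rec)), float(np.mean(f1)))
    w = np.array([gold_counts[l] for l in labels], dtype=float)
    if w.sum() > 0:
        w = w / w.sum()
    weighted = (
        float(np.dot(prec, w)),
        float(np.dot(rec, w)),
        float(np.dot(f1, w)),
    )
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        weighted=weighted,
        averaging=averaging,
        zero_division_flag=zflag,
    )


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) with
    marginal-product expected agreement.

    Returns NaN (with a warning) when p_e = 1, i.e. both annotators are
    constant and identical, where kappa is undefined.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("sequences differ in length")
    if len(labels_a) == 0:
        raise ValueError("empty sequences")
    a, b = _as_strings(labels_a), _as_strings(labels_b)
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    pe = sum(ca[l] * cb[l] for l in set(a) | set(b)) / (n * n)
    if pe == 1.0:
        warnings.warn("expected agreement is 1; kappa is undefined")
        return float("nan")
    return (po - pe) / (1.0 - pe)


def roc_auc(scores: Sequence[float], gold: Sequence[int]) -> float:
    """Rank-based AUC: the probability that a positive instance outscores a
    negative one, ties counting one half."""
    gold = np.asarray(gold)
    if len(set(gold.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(gold, np.asarray(scores, dtype=float)))


def kfold_split(
    y: Sequence, k: int, stratify: bool = True, seed: int = 0
) -> np.ndarray:
    """Fold assignment (0..k-1) per instance; stratified folds preserve class
    ratios within one instance."""
    y = np.asarray(_as_strings(y))
    if k < 2:
        raise ValueError("need at least 2 folds")
    if stratify:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"stratified {k}-fold infeasible: smallest class has {counts.min()} instances"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        if len(y) < k:
            raise ValueError("fewer instances than folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def aggregate_to_abstract(
    predictions: Sequence[tuple[Hashable, Hashable, Hashable, Label]],
    policy: str = "any-positive",
) -> dict[tuple, Label]:
    """Collapse sentence-level candidate labels to one label per
    (document, SNP, phenotype) group.

    ``any-positive``: POSITIVE if any candidate is positive, else NEGATIVE
    if any is negative, else NEUTRAL.  ``majority``: most frequent label;
    ties resolve to NEGATIVE.
    """
    if policy not in ("any-positive", "majority"):
        raise ValueError("policy must be 'any-positive' or 'majority'")
    groups: dict[tuple, list[Label]] = {}
    for doc_id, snp_key, phen_key, label in predictions:
        groups.setdefault((doc_id, snp_key, phen_key), []).append(label)
    out: dict[tuple, Label] = {}
    for key, labels in groups.items():
        if policy == "any-positive":
            if Label.POSITIVE in labels:
                out[key] = Label.POSITIVE
            elif Label.NEGATIVE in labels:
                out[key] = Label.NEGATIVE
            else:
                out[key] = Label.NEUTRAL
        else:
            counts = Counter(labels)
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                out[key] = Label.NEGATIVE
            else:
                out[key] = top[0][0]
    return out


@dataclass
class SignificanceResult:
    test: str  # "t" (paired, per-fold scores) or "sign" (per-instance)
    statistic: float
    p_value: float
    unit: str
    degenerate: bool = False


def paired_significance(
    a: Sequence[float], b: Sequence[float], test: str = "t"
) -> SignificanceResult:
    """Paired comparison between two systems.

    ``t``: paired t-test over aligned per-fold scores; zero variance of the
    differences makes the statistic undefined (flagged).  ``sign``: exact
    two-sided binomial sign test over per-instance wins/losses, ties
    dropped; all ties is degenerate (p = 1, flagged).
    """
    if len(a) != len(b):
        raise ValueError("paired sequences differ in length")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "t":
        diffs = a - b
        if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
            return SignificanceResult(
                test="t", statistic=float("nan"), p_value=float("nan"),
                unit="fold", degenerate=True,
            )
        stat, p = sps.ttest_rel(a, b)
        return SignificanceResult(test="t", statistic=float(stat), p_value=float(p), unit="fold")
    if test == "sign":
        wins = int(np.sum(a > b))
        losses = int(np.sum(b > a))
        n = wins + losses
        if n == 0:
            return SignificanceResult(
                test="sign", statistic=0.0, p_value=1.0, unit="instance", degenerate=True
            )
        res = sps.binomtest(wins, n, 0.5, alternative="two-sided")
        return SignificanceResult(
            test="sign", statistic=float(wins), p_value=float(res.pvalue), unit="instance"
        )
    raise ValueError("test must be 't' or 'sign'")
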