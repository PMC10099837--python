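"""Metrics against brute-force count-based oracles, k-fold splitting,
abstract aggregation and paired significance tests."""

from __future__ import annotations

import math
import random
from collections import Counter

import numpy as np
import pytest

from snprex.corpus import Label
from snprex.evaluation import (
    aggregate_to_abstract,
    cohen_kappa,
    kfold_split,
    paired_significance,
    prf_metrics,
    roc_auc,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_prf(gold, pred):
    labels = sorted(set(gold) | set(pred))
    per = {}
    for lab in labels:
        tp = sum(1 for g, p in zip(gold, pred) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold, pred) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold, pred) if g == lab and p != lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[lab] = (prec, rec, f1)
    macro = tuple(sum(v[i] for v in per.values()) / len(per) for i in range(3))
    return per, macro


def brute_kappa(a, b):
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    pe = sum(ca[l] * cb[l] for l in set(a) | set(b)) / n**2
    return (po - pe) / (1 - pe)


def brute_auc(scores, gold):
    pos = [s for s, g in zip(scores, gold) if g == 1]
    neg = [s for s, g in zip(scores, gold) if g == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_sign_p(wins, n):
    """Exact two-sided binomial p: total probability of outcomes no more
    likely than the observed one under a fair coin."""
    pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
    obs = pmf[wins]
    return min(1.0, sum(p for p in pmf if p <= obs + 1e-12))


class TestPRF:
    def test_perfect_predictions(self):
        r = prf_metrics(["a", "b", "a"], ["a", "b", "a"])
        assert r.macro == (1.0, 1.0, 1.0)

    def test_all_one_class_on_balanced_two_class(self):
        gold = ["a"] * 5 + ["b"] * 5
        pred = ["a"] * 10
        r = prf_metrics(gold, pred)
        assert r.per_class["a"]["recall"] == 1.0
        assert r.per_class["b"]["recall"] == 0.0
        assert r.macro[2] == pytest.approx(1 / 3)
        assert r.zero_division_flag

    def test_three_class_confusion_matrix_arithmetic(self):
        """Confusion matrix [[5,0,0],[1,3,0],[0,0,1]] by direct counts."""
        gold = ["x"] * 5 + ["y"] * 4 + ["z"]
        pred = ["x"] * 5 + ["x"] + ["y"] * 3 + ["z"]
        r = prf_metrics(gold, pred)
        assert r.per_class["x"]["precision"] == pytest.approx(5 / 6)
        assert r.per_class["x"]["recall"] == 1.0
        assert r.per_class["x"]["f1"] == pytest.approx(10 / 11)
        assert r.per_class["y"]["precision"] == 1.0
        assert r.per_class["y"]["recall"] == pytest.approx(3 / 4)
        assert r.per_class["y"]["f1"] == pytest.approx(6 / 7)
        assert r.per_class["z"]["f1"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            prf_metrics(["a"], ["a", "b"])

    def test_micro_recall_equals_accuracy_identity(self):
        rng = random.Random(0)
        gold = [rng.choice("abc") for _ in range(200)]
        pred = [rng.choice("abc") for _ in range(200)]
        r = prf_metrics(gold, pred)
        acc = sum(g == p for g, p in zip(gold, pred)) / len(gold)
        micro_recall = (
            sum(r.per_class[l]["recall"] * r.per_class[l]["support"] for l in r.per_class)
            / len(gold)
        )
        assert micro_recall == pytest.approx(acc)

    def test_random_sets_match_brute_force(self):
        rng = random.Random(42)
        for _ in range(250):
            n = rng.randint(2, 30)
            gold = [rng.choice("abc") for _ in range(n)]
            pred = [rng.choice("abc") for _ in range(n)]
            r = prf_metrics(gold, pred)
            per, macro = brute_prf(gold, pred)
            for lab, (p_, r_, f_) in per.items():
                assert r.per_class[lab]["precision"] == pytest.approx(p_)
                assert r.per_class[lab]["recall"] == pytest.approx(r_)
                assert r.per_class[lab]["f1"] == pytest.approx(f_)
            assert r.macro == pytest.approx(macro)


class TestKappa:
    def test_identical_nonconstant_sequences(self):
        assert cohen_kappa(["a", "b", "a"], ["a", "b", "a"]) == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        # marginals 50/50 with agreement exactly 0.5 -> kappa 0
        a = ["x", "x", "y", "y"]
        b = ["x", "y", "x", "y"]
        assert cohen_kappa(a, b) == pytest.approx(0.0)

    def test_paired_count_table(self):
        """Agreement table (30, 10 / 10, 50): kappa = (0.8-0.52)/0.48."""
        a = ["p"] * 40 + ["n"] * 60
        b = ["p"] * 30 + ["n"] * 10 + ["p"] * 10 + ["n"] * 50
        assert cohen_kappa(a, b) == pytest.approx((0.8 - 0.52) / 0.48)

    def test_symmetry_and_brute_force(self):
        rng = random.Random(7)
        for _ in range(250):
            n = rng.randint(2, 30)
            a = [rng.choice("ab") for _ in range(n)]
            b = [rng.choice("ab") for _ in range(n)]
            if len(set(a)) == 1 and a == b:
                continue
            k = cohen_kappa(a, b)
            assert k == pytest.approx(brute_kappa(a, b))
            assert k == pytest.approx(cohen_kappa(b, a))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = random.Random(3)
        a = [rng.choice("abc") for _ in range(100)]
        b = [rng.choice("abc") for _ in range(100)]
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_degenerate_constant_identical_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(cohen_kappa(["a", "a"], ["a", "a"]))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [1] * 5 + [0] * 5) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        gold = rng.integers(0, 2, 10_000)
        assert roc_auc(scores, gold) == pytest.approx(0.5, abs=0.02)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        gold = rng.integers(0, 2, 200)
        assert roc_auc(scores, gold) == pytest.approx(roc_auc(np.exp(5 * scores), gold))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_counting_oracle(self):
        rng = random.Random(11)
        for _ in range(250):
            n = rng.randint(4, 25)
            gold = [rng.randint(0, 1) for _ in range(n)]
            if len(set(gold)) < 2:
                continue
            scores = [rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]) for _ in range(n)]
            assert roc_auc(scores, gold) == pytest.approx(brute_auc(scores, gold))


class TestKFold:
    def test_partition_covers_and_balances(self):
        folds = kfold_split(["a"] * 10, 5, stratify=False, seed=0)
        assert sorted(Counter(folds).values()) == [2, 2, 2, 2, 2]

    def test_stratified_preserves_class_ratio(self):
        y = ["maj"] * 90 + ["min"] * 10
        folds = kfold_split(y, 5, stratify=True, seed=0)
        for f in range(5):
            labels = [y[i] for i in np.flatnonzero(folds == f)]
            assert Counter(labels) == {"maj": 18, "min": 2}

    def test_same_seed_same_assignment(self):
        y = ["a"] * 30 + ["b"] * 20
        assert (kfold_split(y, 5, seed=4) == kfold_split(y, 5, seed=4)).all()

    def test_infeasible_stratification_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            kfold_split(["a"] * 10 + ["b"] * 2, 5, stratify=True)


class TestAbstractAggregation:
    def test_single_candidate_passes_through(self):
        out = aggregate_to_abstract([("d1", "rs1", "obesity", Label.NEGATIVE)])
        assert out[("d1", "rs1", "obesity")] is Label.NEGATIVE

    def test_any_positive_policy(self):
        out = aggregate_to_abstract(
            [
                ("d1", "rs1", "t", Label.POSITIVE),
                ("d1", "rs1", "t", Label.NEGATIVE),
            ],
            policy="any-positive",
        )
        assert out[("d1", "rs1", "t")] is Label.POSITIVE

    def test_majority_tie_resolves_negative(self):
        out = aggregate_to_abstract(
            [
                ("d1", "rs1", "t", Label.POSITIVE),
                ("d1", "rs1", "t", Label.NEUTRAL),
            ],
            policy="majority",
        )
        assert out[("d1", "rs1", "t")] is Label.NEGATIVE

    def test_majority_matches_brute_force_voting(self):
        rng = random.Random(2)
        labels = [Label.POSITIVE, Label.NEGATIVE, Label.NEUTRAL]
        records = []
        for g in range(40):
            for _ in range(rng.randint(1, 6)):
                records.append((f"d{g}", "rs1", "t", rng.choice(labels)))
        out = aggregate_to_abstract(records, policy="majority")
        groups: dict = {}
        for doc, s, p, lab in records:
            groups.setdefault((doc, s, p), []).append(lab)
        for key, labs in groups.items():
            counts = Counter(labs)
            top = max(counts.values())
            winners = [l for l, c in counts.items() if c == top]
            expected = winners[0] if len(winners) == 1 else Label.NEGATIVE
            assert out[key] is expected


class TestPairedSignificance:
    def test_identical_inputs_sign_test_p_one(self):
        r = paired_significance([1, 0, 1], [1, 0, 1], test="sign")
        assert r.p_value == 1.0
        assert r.degenerate

    def test_ten_zero_sweep_two_sided_p(self):
        """a beats b on all 10 pairs: p = 2 * (1/2)^10."""
        r = paired_significance([1.0] * 10, [0.0] * 10, test="sign")
        assert r.p_value == pytest.approx(2 * 0.5**10)
        assert r.p_value == pytest.approx(0.001953125)

    def test_sign_test_matches_exact_binomial_oracle(self):
        rng = random.Random(9)
        for _ in range(250):
            n = rng.randint(1, 20)
            a = [rng.random() for _ in range(n)]
            b = [rng.random() for _ in range(n)]
            wins = sum(x > y for x, y in zip(a, b))
            losses = sum(y > x for x, y in zip(a, b))
            if wins + losses == 0:
                continue
            r = paired_significance(a, b, test="sign")
            assert r.p_value == pytest.approx(brute_sign_p(wins, wins + losses))

    def test_zero_variance_t_test_flagged(self):
        r = paired_significance([0.5, 0.6, 0.7], [0.4, 0.5, 0.6], test="t")
        assert r.degenerate
        assert math.isnan(r.statistic)

    def test_t_test_on_fold_scores(self):
        a = [0.90, 0.88, 0.92, 0.91, 0.89]
        b = [0.80, 0.82, 0.79, 0.81, 0.80]
        r = paired_significance(a, b, test="t")
        assert not r.degenerate
        assert r.p_value < 0.01
        assert r.unit == "fold"
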