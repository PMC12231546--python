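"""Metric suite against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idrfuse.io import DISORDERED, ORDERED, UNLABELED
from idrfuse.metrics import (
    ConfusionCounts,
    confusion,
    evaluate_scores,
    pr_summary,
    roc_auc,
    threshold_metrics,
)


def _brute_force_auc(scores, labels):
    """O(n^2) pair counting: P(random positive outscores random negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def _enumerate_pr(scores, labels):
    """Exhaustive threshold sweep: APS and Fmax from first principles."""
    thresholds = np.unique(scores)[::-1]
    n_pos = int((labels == 1).sum())
    points = []
    for t in thresholds:
        calls = scores >= t
        tp = int((calls & (labels == 1)).sum())
        fp = int((calls & (labels == 0)).sum())
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / n_pos
        points.append((prec, rec))
    aps, prev_rec, fmax = 0.0, 0.0, 0.0
    for prec, rec in points:
        aps += (rec - prev_rec) * prec
        prev_rec = rec
        if prec + rec > 0:
            fmax = max(fmax, 2 * prec * rec / (prec + rec))
    return aps, fmax


class TestConfusion:
    def test_perfect_call(self):
        c = confusion(np.array([DISORDERED, ORDERED]),
                      np.array([DISORDERED, ORDERED]))
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_unlabeled_excluded(self):
        c = confusion(np.array([DISORDERED, ORDERED, UNLABELED]),
                      np.array([DISORDERED, DISORDERED, DISORDERED]))
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 1, 0, 0)
        assert c.n == 2

    def test_random_case_equals_tally_loop(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([ORDERED, DISORDERED, UNLABELED], size=50)
        calls = rng.choice([ORDERED, DISORDERED], size=50)
        c = confusion(labels, calls)
        tp = fp = tn = fn = 0
        for l, k in zip(labels, calls):
            if l == UNLABELED:
                continue
            if l == DISORDERED and k == DISORDERED:
                tp += 1
            elif l == ORDERED and k == DISORDERED:
                fp += 1
            elif l == ORDERED and k == ORDERED:
                tn += 1
            else:
                fn += 1
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        m, flags = threshold_metrics(ConfusionCounts(TP=1, FP=0, TN=1, FN=0))
        assert m == {"Sn": 1.0, "Sp": 1.0, "BACC": 1.0, "MCC": 1.0, "F1": 1.0}
        assert flags == ()

    def test_worked_example(self):
        TP, FP, TN, FN = 5, 1, 10, 2
        m, _ = threshold_metrics(ConfusionCounts(TP, FP, TN, FN))
        assert m["Sn"] == pytest.approx(5 / 7)
        assert m["Sp"] == pytest.approx(10 / 11)
        assert m["BACC"] == pytest.approx((5 / 7 + 10 / 11) / 2)
        assert m["MCC"] == pytest.approx(
            (5 * 10 - 1 * 2) / np.sqrt(6.0 * 7 * 11 * 12))
        assert m["F1"] == pytest.approx(10 / 13)

    def test_degenerate_denominators_flagged_zero(self):
        # no positive calls: Sn = 0 is a genuine value, MCC's denominator is 0
        m, flags = threshold_metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=2))
        assert m["Sn"] == 0.0 and m["MCC"] == 0.0
        assert "MCC" in flags and "Sn" not in flags
        # no labeled positives at all: Sn itself is degenerate
        m2, flags2 = threshold_metrics(ConfusionCounts(TP=0, FP=1, TN=3, FN=0))
        assert m2["Sn"] == 0.0 and "Sn" in flags2

    def test_thousand_random_tables_match_scalar_evaluation(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            TP, FP, TN, FN = (int(v) for v in rng.integers(0, 40, size=4))
            m, _ = threshold_metrics(ConfusionCounts(TP, FP, TN, FN))
            sn = TP / (TP + FN) if TP + FN else 0.0
            sp = TN / (TN + FP) if TN + FP else 0.0
            den = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
            mcc = (TP * TN - FP * FN) / np.sqrt(den) if den else 0.0
            f1 = 2 * TP / (2 * TP + FP + FN) if 2 * TP + FP + FN else 0.0
            assert m["Sn"] == pytest.approx(sn, abs=1e-12)
            assert m["Sp"] == pytest.approx(sp, abs=1e-12)
            assert m["BACC"] == pytest.approx((sn + sp) / 2, abs=1e-12)
            assert m["MCC"] == pytest.approx(mcc, abs=1e-12)
            assert m["F1"] == pytest.approx(f1, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([DISORDERED, DISORDERED, ORDERED, ORDERED])
        assert roc_auc(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        scores = np.full(10, 0.4)
        labels = np.array([DISORDERED] * 5 + [ORDERED] * 5)
        assert roc_auc(scores, labels) == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pair_counting_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = 200
        # quantized scores force ties
        scores = np.round(rng.random(n), 1)
        labels = rng.choice([ORDERED, DISORDERED], size=n)
        if len(np.unique(labels)) < 2:
            labels[0] = ORDERED
            labels[1] = DISORDERED
        expected = _brute_force_auc(scores, (labels == DISORDERED).astype(int))
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_unlabeled_scores_cannot_affect_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = rng.choice([ORDERED, DISORDERED, UNLABELED], size=30)
        labels[:2] = [ORDERED, DISORDERED]
        base = roc_auc(scores, labels)
        perturbed = scores.copy()
        perturbed[labels == UNLABELED] = rng.random((labels == UNLABELED).sum())
        assert roc_auc(perturbed, labels) == base

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([ORDERED, ORDERED]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(60)
        labels = rng.choice([ORDERED, DISORDERED], size=60)
        labels[:2] = [ORDERED, DISORDERED]
        transformed = 1.0 / (1.0 + np.exp(-(5 * scores - 1)))
        assert roc_auc(transformed, labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12)

    def test_class_swap_complement_without_ties(self):
        rng = np.random.default_rng(5)
        scores = rng.permutation(40) / 40.0  # distinct scores, no ties
        labels = rng.choice([ORDERED, DISORDERED], size=40)
        labels[:2] = [ORDERED, DISORDERED]
        swapped = np.where(labels == ORDERED, DISORDERED, ORDERED)
        assert roc_auc(scores, labels) + roc_auc(scores, swapped) == \
            pytest.approx(1.0, abs=1e-12)


class TestPrSummary:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([DISORDERED, DISORDERED, ORDERED, ORDERED])
        aps, fmax, _ = pr_summary(scores, labels)
        assert aps == 1.0 and fmax == 1.0

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(10 + trial)
        n = 25
        scores = np.round(rng.random(n), 1)
        labels = rng.choice([ORDERED, DISORDERED], size=n)
        labels[0] = DISORDERED
        aps, fmax, thr = pr_summary(scores, labels)
        y = (labels == DISORDERED).astype(int)
        aps_ref, fmax_ref = _enumerate_pr(scores, y)
        assert aps == pytest.approx(aps_ref, abs=1e-10)
        assert fmax == pytest.approx(fmax_ref, abs=1e-10)
        assert thr in scores  # maximizing threshold is an observed score

    def test_six_residue_toy_case(self):
        scores = np.array([0.9, 0.7, 0.6, 0.4, 0.3, 0.1])
        labels = np.array([DISORDERED, ORDERED, DISORDERED, DISORDERED,
                           ORDERED, ORDERED])
        aps, fmax, _ = pr_summary(scores, labels)
        aps_ref, fmax_ref = _enumerate_pr(scores,
                                          (labels == DISORDERED).astype(int))
        assert aps == pytest.approx(aps_ref, abs=1e-12)
        assert fmax == pytest.approx(fmax_ref, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fmax_at_least_f1_at_fixed_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.random(n)
        labels = rng.choice([ORDERED, DISORDERED], size=n)
        labels[0] = DISORDERED
        _, fmax, _ = pr_summary(scores, labels)
        calls = np.where(scores >= 0.5, DISORDERED, ORDERED)
        m, _ = threshold_metrics(confusion(labels, calls))
        assert fmax >= m["F1"] - 1e-12

    def test_no_positives_is_an_error(self):
        with pytest.raises(ValueError):
            pr_summary(np.array([0.1, 0.9]), np.array([ORDERED, ORDERED]))


class TestEvaluateScores:
    @staticmethod
    def _random_proteins(rng, n=3):
        scores, labels = [], []
        for _ in range(n):
            L = int(rng.integers(10, 30))
            scores.append(rng.random(L))
            labels.append(rng.choice([ORDERED, DISORDERED, UNLABELED], size=L))
        labels[0][:2] = [ORDERED, DISORDERED]
        return scores, labels

    def test_bacc_identity(self):
        scores, labels = self._random_proteins(np.random.default_rng(20))
        r = evaluate_scores(scores, labels)
        assert r.BACC == pytest.approx((r.Sn + r.Sp) / 2, abs=1e-12)

    def test_protein_order_invariance(self):
        scores, labels = self._random_proteins(np.random.default_rng(21), n=5)
        r1 = evaluate_scores(scores, labels)
        r2 = evaluate_scores(scores[::-1], labels[::-1])
        assert r1.to_dict() == r2.to_dict()

    def test_equals_flat_concatenation(self):
        scores, labels = self._random_proteins(np.random.default_rng(22))
        pooled = evaluate_scores(scores, labels)
        flat = evaluate_scores([np.concatenate(scores)],
                               [np.concatenate(labels)])
        assert pooled.to_dict() == flat.to_dict()

    def test_unlabeled_scores_never_affect_any_metric(self):
        rng = np.random.default_rng(23)
        scores, labels = self._random_proteins(rng, n=4)
        base = evaluate_scores(scores, labels)
        perturbed = [s.copy() for s in scores]
        for s, l in zip(perturbed, labels):
            s[l == UNLABELED] = rng.random((l == UNLABELED).sum())
        after = evaluate_scores(perturbed, labels)
        assert base.to_dict() == after.to_dict()
        assert base.counts == after.counts  # bit-level on the counts

    def test_counts_cover_exactly_the_labeled_residues(self):
        scores, labels = self._random_proteins(np.random.default_rng(24))
        r = evaluate_scores(scores, labels)
        n_labeled = int(sum((l != UNLABELED).sum() for l in labels))
        assert r.counts.n == n_labeled
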