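"""Evaluation metrics against brute-force oracles and hand computations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tabanom.metrics import (aggregate_runs, aupro, auroc, average_precision,
                             best_f1, evaluate_scores, f1_at, pro,
                             MetricsReport)


# ------------------------------------------------------------------- oracles

def auroc_oracle(scores, labels):
    """All positive-negative pairs; ties count one half."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def ap_oracle(scores, labels):
    """Step integration: precision at each positive's rank."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    labels = np.asarray(labels, int)[order]
    # merge ties: process by distinct score value
    s_sorted = np.asarray(scores, float)[order]
    total_pos = labels.sum()
    ap, tp, seen = 0.0, 0, 0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and s_sorted[j] == s_sorted[i]:
            j += 1
        tp_new = tp + labels[i:j].sum()
        seen_new = seen + (j - i)
        if labels[i:j].sum():
            ap += (tp_new - tp) / total_pos * (tp_new / seen_new)
        tp, seen, i = tp_new, seen_new, j
    return ap


def best_f1_oracle(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    best = 0.0
    for th in np.unique(scores):
        pred = scores >= th
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        if tp:
            p, r = tp / (tp + fp), tp / (tp + fn)
            best = max(best, 2 * p * r / (p + r))
    return best


def _random_vectors(n_cases=200, max_len=50, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_cases):
        n = int(rng.integers(4, max_len + 1))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # mix continuous scores with heavy ties
        if rng.random() < 0.5:
            scores = rng.normal(size=n)
        else:
            scores = rng.integers(0, 5, size=n).astype(float)
        yield scores, labels


class TestOracleEquivalence:
    def test_auroc_matches_pair_counting(self):
        for scores, labels in _random_vectors(seed=1):
            assert abs(auroc(scores, labels) - auroc_oracle(scores, labels)) < 1e-9

    def test_average_precision_matches_rank_sum(self):
        for scores, labels in _random_vectors(seed=2):
            if labels.sum() == 0:
                continue
            assert abs(average_precision(scores, labels)
                       - ap_oracle(scores, labels)) < 1e-9

    def test_best_f1_matches_threshold_scan(self):
        for scores, labels in _random_vectors(seed=3):
            got, _ = best_f1(scores, labels)
            assert abs(got - best_f1_oracle(scores, labels)) < 1e-9


class TestAUROCExamples:
    def test_perfect_and_inverted(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auroc([1, 2, 3, 10, 11], [1, 1, 1, 0, 0]) == 0.0

    def test_hand_value(self):
        np.testing.assert_allclose(
            auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]), 0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestAPExamples:
    def test_positives_first(self):
        assert average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_hand_value(self):
        np.testing.assert_allclose(
            average_precision([0.9, 0.8, 0.7], [1, 0, 1]), 0.5 + 0.5 * 2 / 3)

    def test_single_positive_ranked_last(self):
        for k in (2, 5, 9):
            scores = np.arange(k + 1, 0, -1.0)
            labels = np.zeros(k + 1, int)
            labels[-1] = 1
            np.testing.assert_allclose(average_precision(scores, labels),
                                       1.0 / (k + 1))

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            average_precision([1.0], [0])


class TestF1:
    def test_hand_confusion(self):
        # 8 TP, 2 FP, 2 FN at threshold 0.5
        scores = [0.9] * 8 + [0.9] * 2 + [0.1] * 2 + [0.1] * 8
        labels = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        np.testing.assert_allclose(f1_at(scores, labels, 0.5), 0.8)

    def test_perfect_best_f1(self):
        f1v, _ = best_f1([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert f1v == 1.0

    def test_no_true_positive_guard(self):
        assert f1_at([0.1, 0.2], [1, 0], threshold=5.0) == 0.0


class TestPRO:
    def test_perfect_prediction(self):
        mask = np.zeros((16, 16), bool)
        mask[2:5, 2:5] = True
        mask[10:14, 10:12] = True
        assert pro([mask.astype(float)], [mask], 0.5) == 1.0

    def test_two_region_hand_value(self):
        mask = np.zeros((16, 16), bool)
        mask[0:2, 0:4] = True              # region A: 8 px
        mask[10:12, 10:14] = True          # region B: 8 px
        scoremap = np.zeros((16, 16))
        scoremap[0:2, 0:4] = 1.0           # A fully covered
        scoremap[10:12, 10:12] = 1.0       # B half covered
        np.testing.assert_allclose(pro([scoremap], [mask], 0.5), 0.75)

    def test_empty_prediction_zero(self):
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        assert pro([np.zeros((8, 8))], [mask], 0.5) == 0.0

    def test_no_regions_rejected(self):
        with pytest.raises(ValueError):
            pro([np.zeros((8, 8))], [np.zeros((8, 8), bool)], 0.5)

    def test_eight_connectivity_merges_diagonal(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1] = mask[2, 2] = True     # diagonal touch: one region
        m = np.zeros((6, 6))
        m[1, 1] = 1.0
        np.testing.assert_allclose(pro([m], [mask], 0.5), 0.5)

    def test_threshold_monotonicity(self, rng):
        mask = rng.random((16, 16)) > 0.7
        if not mask.any():
            mask[3, 3] = True
        scoremap = rng.random((16, 16))
        vals = [pro([scoremap], [mask], th) for th in np.linspace(0, 1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_constructed_per_region_overlaps(self):
        """Mean of per-region recovery fractions over 20 constructed pairs."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            mask = np.zeros((24, 24), bool)
            n_regions = int(rng.integers(1, 4))
            placed, expected = 0, []
            for r in range(n_regions):
                y, x = 1 + 7 * r, int(rng.integers(1, 12))
                h, w = int(rng.integers(2, 5)), int(rng.integers(2, 5))
                mask[y:y + h, x:x + w] = True
            from scipy import ndimage
            lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
            scoremap = np.zeros((24, 24))
            fracs = []
            for rr in range(1, n + 1):
                ys, xs = np.nonzero(lab == rr)
                keep = int(rng.integers(0, len(ys) + 1))
                scoremap[ys[:keep], xs[:keep]] = 1.0
                fracs.append(keep / len(ys))
            np.testing.assert_allclose(pro([scoremap], [mask], 0.5),
                                       np.mean(fracs), atol=1e-12)


class TestAUPRO:
    def test_perfect_maps_score_high(self):
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        v = aupro([mask.astype(float)], [mask], fpr_limit=0.3)
        assert v > 0.95

    def test_bad_limit_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[1, 1] = True
        with pytest.raises(ValueError):
            aupro([np.zeros((8, 8))], [mask], fpr_limit=0.0)


class TestRankInvariance:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_preserves_rank_metrics(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        warped = np.exp(3 * scores) + 1
        assert abs(auroc(scores, labels) - auroc(warped, labels)) < 1e-9
        assert abs(average_precision(scores, labels)
                   - average_precision(warped, labels)) < 1e-9
        assert abs(best_f1(scores, labels)[0] - best_f1(warped, labels)[0]) < 1e-9


class TestAggregate:
    def _rep(self, v):
        return MetricsReport(ap=v, f1=v, auroc=v, pro=v, aupro=v)

    def test_identical_reports_zero_sd(self):
        out = aggregate_runs([self._rep(0.7)] * 3)
        np.testing.assert_allclose(out["auroc"], (0.7, 0.0), atol=1e-12)

    def test_hand_mean_sd(self):
        out = aggregate_runs([self._rep(0.9), self._rep(0.8)])
        mean, sd = out["ap"]
        np.testing.assert_allclose(mean, 0.85)
        np.testing.assert_allclose(sd, 0.0707107, atol=1e-6)

    def test_mean_within_bounds_and_empty_rejected(self):
        out = aggregate_runs([self._rep(0.2), self._rep(0.6), self._rep(0.7)])
        assert 0.2 <= out["f1"][0] <= 0.7
        with pytest.raises(ValueError):
            aggregate_runs([])


class TestEvaluateScores:
    def test_schema_and_oracle_maps(self):
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        rep = evaluate_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0],
                              score_maps=[mask.astype(float), mask.astype(float)],
                              masks=[mask, mask])
        assert rep.auroc == 1.0 and rep.ap == 1.0 and rep.f1 == 1.0
        assert rep.pro == 1.0
        assert rep.n_images == 4 and rep.n_regions == 2
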