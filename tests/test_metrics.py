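"""Average precision, PPV@k and the resampling benchmark.

The AP oracle used throughout is an explicit rank walk: sort by
(score desc, input index), accumulate precision at each positive.  It is
deliberately independent of the vectorized implementation.
"""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from mhcassign.metrics import (
    ScoredSet,
    average_precision,
    ppv_at_k,
    pr_curve,
    resample_benchmark,
)


def oracle_average_precision(scores, labels):
    """Brute-force rank walk, one item at a time."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    hits = 0
    precisions = []
    for rank, idx in enumerate(order, start=1):
        if labels[idx] == 1:
            hits += 1
            precisions.append(hits / rank)
    return sum(precisions) / len(precisions)


def oracle_ppv(scores, labels, k):
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return sum(labels[i] for i in order[:k]) / k


def from_ranked(labels):
    """ScoredSet whose canonical order equals the given label order."""
    labels = np.asarray(labels)
    return ScoredSet(np.arange(len(labels), 0, -1, dtype=float), labels)


class TestAveragePrecision:
    @pytest.mark.parametrize(
        "ranked, expected",
        [
            ([1, 1, 0, 0], 1.0),
            ([0, 1], 0.5),
            ([1, 0, 1, 0], (1.0 + 2 / 3) / 2),
        ],
    )
    def test_hand_cases(self, ranked, expected):
        assert average_precision(from_ranked(ranked)) == pytest.approx(expected)

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            average_precision(from_ranked([0, 0, 0]))

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[int(rng.integers(n))] = 1
            # ties are common on purpose: few distinct score levels
            scores = rng.integers(0, 5, size=n).astype(float)
            got = average_precision(ScoredSet(scores, labels))
            want = oracle_average_precision(scores.tolist(), labels.tolist())
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_sklearn_when_scores_distinct(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.permutation(n).astype(float)
            assert average_precision(ScoredSet(scores, labels)) == pytest.approx(
                average_precision_score(labels, scores)
            )

    def test_worst_case_reversed_ranking_equals_oracle_closed_form(self):
        # all negatives ranked above all positives
        p, n = 4, 9
        ranked = [0] * n + [1] * p
        got = average_precision(from_ranked(ranked))
        assert got == pytest.approx(oracle_average_precision(
            list(range(p + n, 0, -1)), ranked
        ))
        # closed form computed by the oracle: mean of i/(n+i) for i=1..p
        closed = np.mean([i / (n + i) for i in range(1, p + 1)])
        assert got == pytest.approx(closed)


class TestPpvAtK:
    def test_hand_case(self):
        scored = ScoredSet(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0]))
        assert ppv_at_k(scored, 2) == pytest.approx(0.5)

    def test_perfect_separation(self):
        scored = from_ranked([1, 1, 1, 0, 0])
        assert ppv_at_k(scored, 3) == 1.0

    def test_all_negative(self):
        scored = ScoredSet(np.arange(4.0), np.zeros(4, dtype=int))
        assert ppv_at_k(scored, 2) == 0.0

    def test_k_out_of_range_raises(self):
        with pytest.raises(ValueError):
            ppv_at_k(from_ranked([1, 0]), 3)

    def test_monotone_under_label_improvement(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            k = int(rng.integers(1, n + 1))
            before = ppv_at_k(ScoredSet(scores, labels), k)
            flip = int(rng.integers(n))
            improved = labels.copy()
            improved[flip] = 1
            after = ppv_at_k(ScoredSet(scores, improved), k)
            assert after >= before - 1e-12

    def test_matches_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(2, 40))
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            k = int(rng.integers(1, n + 1))
            assert ppv_at_k(ScoredSet(scores, labels), k) == pytest.approx(
                oracle_ppv(scores.tolist(), labels.tolist(), k)
            )


class TestResampleBenchmark:
    def _pool(self, n_pos, n_neg, scorer, rng):
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        scores = scorer(labels, rng)
        return ScoredSet(scores, labels)

    def test_oracle_scorer_gives_perfect_ap(self):
        pool = self._pool(50, 2000, lambda y, _: y.astype(float),
                          np.random.default_rng(0))
        res = resample_benchmark(pool, n_iter=10, n_pos=20, neg_ratio=50, seed=1)
        assert res.ap_mean == pytest.approx(1.0)
        assert res.ap_sd == pytest.approx(0.0)
        # PPV@k is 1 whenever the draw holds at least k positives
        assert all(m == 1.0 for k, (m, _) in res.ppv_at_k.items() if k <= 20)

    def test_draw_sizes_match_protocol(self):
        drawn = []

        class Recorder(ScoredSet):
            pass

        pool = self._pool(30, 4000, lambda y, rng: rng.uniform(size=len(y)),
                          np.random.default_rng(2))
        res = resample_benchmark(pool, n_iter=3, n_pos=10, neg_ratio=100, seed=4)
        assert res.n_pos == 10 and res.neg_ratio == 100

    def test_insufficient_pool_reports_requirements(self):
        pool = self._pool(5, 100, lambda y, rng: rng.uniform(size=len(y)),
                          np.random.default_rng(0))
        with pytest.raises(ValueError, match="need 10"):
            resample_benchmark(pool, n_iter=2, n_pos=10, neg_ratio=100, seed=0)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(9)
        pool = self._pool(40, 3000, lambda y, r: r.uniform(size=len(y)), rng)
        a = resample_benchmark(pool, n_iter=5, n_pos=15, neg_ratio=30, seed=77)
        b = resample_benchmark(pool, n_iter=5, n_pos=15, neg_ratio=30, seed=77)
        assert a.ap_mean == b.ap_mean and a.ap_sd == b.ap_sd
        np.testing.assert_array_equal(a.ap_values, b.ap_values)
        np.testing.assert_array_equal(a.pr_precision_mean, b.pr_precision_mean)

    def test_random_scorer_ap_near_prevalence(self):
        # at r:1 imbalance a random ranking's AP concentrates at prevalence
        rng = np.random.default_rng(21)
        ratio = 50
        pool = self._pool(100, 100 * ratio, lambda y, r: r.uniform(size=len(y)), rng)
        res = resample_benchmark(pool, n_iter=30, n_pos=30, neg_ratio=ratio, seed=5)
        prevalence = 1.0 / (ratio + 1)
        assert abs(res.ap_mean - prevalence) < 3 * res.ap_sd / np.sqrt(res.n_iterations) + 0.2 * prevalence


class TestPrCurve:
    def test_recall_monotone_and_endpoints(self):
        scored = from_ranked([1, 0, 1, 1, 0, 0])
        recall, precision = pr_curve(scored)
        assert recall[0] == pytest.approx(1 / 3)
        assert recall[-1] == 1.0
        assert np.all(np.diff(recall) >= 0)
        assert np.all((precision >= 0) & (precision <= 1))
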