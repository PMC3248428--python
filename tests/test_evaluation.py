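from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preylink.evaluation import (
    classify_edges,
    roc_auc,
    running_sum,
    shuffled_null,
    sliding_recall,
)
from preylink.io import ReferenceInteractions

import oracles


def ranked_with_hits(u: int, hit_positions: set[int]):
    """A ranked pair list plus a reference set hitting given 0-based ranks."""
    ranked = [(f"a{i}", f"b{i}") for i in range(u)]
    known = ReferenceInteractions([ranked[i] for i in hit_positions])
    return ranked, known


class TestRunningSum:
    def test_early_hits_walk(self):
        ranked, known = ranked_with_hits(4, {0, 1})
        curve = running_sum(ranked, known)
        assert curve.values.tolist() == [1.0, 2.0, 1.0, 0.0]
        assert curve.peak == 2.0 and curve.peak_rank == 2
        assert (curve.u, curve.t) == (4, 2)

    def test_late_hits_walk(self):
        ranked, known = ranked_with_hits(4, {2, 3})
        curve = running_sum(ranked, known)
        assert curve.values.tolist() == [-1.0, -2.0, -1.0, 0.0]
        assert curve.peak == -2.0 and curve.peak_rank == 2

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(2, 400), st.data())
    def test_final_value_always_zero(self, u, data):
        t = data.draw(st.integers(1, u - 1))
        rng = np.random.default_rng(u * 1000 + t)
        hits = set(rng.choice(u, size=t, replace=False).tolist())
        ranked, known = ranked_with_hits(u, hits)
        curve = running_sum(ranked, known)
        assert curve.final == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("hit_positions", [set(), {0, 1, 2}])
    def test_degenerate_walks_rejected(self, hit_positions):
        ranked, known = ranked_with_hits(3, hit_positions)
        with pytest.raises(ValueError, match="degenerate"):
            running_sum(ranked, known)


class TestRocAuc:
    def test_perfect_and_reversed_rankings(self):
        ranked, known = ranked_with_hits(10, {0, 1, 2})
        assert roc_auc(ranked, known).auc == 1.0
        ranked_rev = list(reversed(ranked))
        assert roc_auc(ranked_rev, known).auc == 0.0

    def test_matches_mann_whitney_normalisation(self):
        rng = np.random.default_rng(3)
        u = 5000
        ranked, known = ranked_with_hits(
            u, set(rng.choice(u, size=400, replace=False).tolist())
        )
        # tied scores exercise the averaged-rank convention
        scores = rng.integers(0, 50, size=u).astype(float)
        order = np.argsort(-scores, kind="stable")
        ranked = [ranked[i] for i in order]
        scores = scores[order]
        labels = [p in known for p in ranked]
        expected = oracles.auc_mannwhitney(scores.tolist(), labels)
        got = roc_auc(ranked, known, scores=scores).auc
        assert got == pytest.approx(expected, abs=1e-9)

    def test_random_ranking_near_half(self):
        rng = np.random.default_rng(11)
        u = 1000
        ranked, known = ranked_with_hits(
            u, set(rng.choice(u, size=200, replace=False).tolist())
        )
        rng.shuffle(ranked)
        auc = roc_auc(ranked, known).auc
        # 3 sigma of the null for n_pos=200, n_neg=800
        sigma = math.sqrt((u + 1) / (12 * 200 * 800))
        assert abs(auc - 0.5) < 3 * sigma

    def test_single_class_rejected(self):
        ranked, known = ranked_with_hits(5, {0, 1, 2, 3, 4})
        with pytest.raises(ValueError):
            roc_auc(ranked, known)

    def test_curve_monotone(self):
        rng = np.random.default_rng(7)
        ranked, known = ranked_with_hits(
            200, set(rng.choice(200, 30, replace=False).tolist())
        )
        curve = roc_auc(ranked, known)
        assert (np.diff(curve.tpr) >= 0).all()
        assert 0.0 <= curve.auc <= 1.0


class TestSlidingRecall:
    def test_full_window_ends_at_overall_precision(self):
        ranked, known = ranked_with_hits(20, set(range(5)))
        rec = sliding_recall(ranked, known, window=20)
        assert rec[-1, 1] == pytest.approx(5 / 20)

    def test_alternating_list_window_two(self):
        ranked, known = ranked_with_hits(10, {0, 2, 4, 6, 8})
        rec = sliding_recall(ranked, known, window=2)
        even_positions = rec[1::2, 1]
        assert np.allclose(even_positions, 0.5)

    def test_all_miss_gives_zeros(self):
        ranked = [(f"a{i}", f"b{i}") for i in range(8)]
        rec = sliding_recall(ranked, ReferenceInteractions(), window=3)
        assert (rec[:, 1] == 0).all()

    def test_oversized_window_warns_single_point(self):
        ranked, known = ranked_with_hits(5, {0})
        with pytest.warns(UserWarning):
            rec = sliding_recall(ranked, known, window=50)
        assert rec.shape == (1, 2) and rec[0, 1] == pytest.approx(0.2)


class TestShuffledNull:
    def test_deterministic_for_fixed_seed(self):
        ranked, known = ranked_with_hits(60, set(range(6)))
        a = shuffled_null(ranked, known, n_shuffles=50, seed=5)
        b = shuffled_null(ranked, known, n_shuffles=50, seed=5)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.lo, b.lo) and np.array_equal(a.hi, b.hi)

    def test_mean_near_zero_and_walks_end_at_zero(self):
        ranked, known = ranked_with_hits(100, set(range(10)))
        null = shuffled_null(ranked, known, n_shuffles=1000, seed=0)
        assert np.abs(null.mean).max() < 0.5
        # every shuffled walk is a bridge: envelope pinched to 0 at the end
        assert null.lo[-1] == pytest.approx(0.0, abs=1e-9)
        assert null.hi[-1] == pytest.approx(0.0, abs=1e-9)

    def test_mean_tightens_with_more_shuffles(self):
        ranked, known = ranked_with_hits(100, set(range(10)))
        few = shuffled_null(ranked, known, n_shuffles=20, seed=1)
        many = shuffled_null(ranked, known, n_shuffles=2000, seed=1)
        assert np.abs(many.mean).mean() < np.abs(few.mean).mean()

    def test_seed_required(self):
        ranked, known = ranked_with_hits(10, {0})
        with pytest.raises(ValueError, match="seed"):
            shuffled_null(ranked, known, n_shuffles=10, seed=None)


class TestClassifyEdges:
    def test_recalled_indirect_novel(self):
        known = ReferenceInteractions([("A", "B"), ("A", "C"), ("C", "D")])
        labels = classify_edges(
            [("A", "B"), ("B", "C"), ("B", "D"), ("X", "Y")], known
        )
        # B-C share neighbour A; B-D have no length-2 path (B-A-C-D is 3)
        assert labels == ["recalled", "indirect", "novel", "novel"]
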