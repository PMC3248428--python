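from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from preylink.io import SpectralCountMatrix
from preylink.scoring import (
    METHODS,
    ab_correlation,
    combine_with_sorensen,
    e3,
    pearson,
    score_all_pairs,
    sorensen,
    top_fraction_intersection,
)

import oracles
from conftest import random_matrix


def matrix_from(spc: dict[str, list[int]],
                mw: dict[str, float] | None = None) -> SpectralCountMatrix:
    proteins = sorted(spc)
    m = len(spc[proteins[0]])
    mw = mw or {p: 1.0 for p in proteins}
    return SpectralCountMatrix(
        spc=pd.DataFrame(
            {f"e{j}": [spc[p][j] for p in proteins] for j in range(m)},
            index=proteins,
        ),
        mw=pd.Series([mw[p] for p in proteins], index=proteins),
    )


class TestSorensen:
    def test_half_overlap(self):
        m = matrix_from({"a": [1, 1, 0], "b": [0, 1, 1], "z": [1, 1, 1]})
        assert sorensen(m, "a", "b") == 0.5

    def test_identical_and_disjoint_profiles(self):
        m = matrix_from({"a": [1, 2], "b": [3, 4], "c": [0, 5], "d": [6, 0]})
        assert sorensen(m, "a", "b") == 1.0
        assert sorensen(m, "c", "d") == 0.0

    def test_never_detected_protein_is_undefined(self):
        m = matrix_from({"a": [1, 1], "b": [0, 0]})
        assert math.isnan(sorensen(m, "a", "b"))


class TestPearson:
    def test_perfect_dependence(self):
        m = matrix_from({"a": [1, 2, 3], "b": [2, 4, 6], "c": [3, 2, 1]})
        assert pearson(m, "a", "b") == pytest.approx(1.0)
        assert pearson(m, "a", "c") == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        spc = {"a": [0, 1, 0, 2], "b": [1, 0, 3, 0]}
        mw = {"a": 2.0, "b": 5.0}
        m = matrix_from(spc, mw)
        expected = oracles.pearson_bf(spc, mw, "a", "b")
        assert pearson(m, "a", "b") == pytest.approx(expected, abs=1e-12)

    def test_uses_abundance_not_raw_counts(self):
        # different MWs rescale rows; correlation of Q differs from SPC
        spc = {"a": [1, 4, 2], "b": [2, 3, 9]}
        m1 = matrix_from(spc, {"a": 1.0, "b": 1.0})
        assert pearson(m1, "a", "b") == pytest.approx(
            oracles.pearson_closed_form([1, 4, 2], [2, 3, 9])
        )

    def test_zero_variance_is_undefined(self):
        m = matrix_from({"a": [2, 2, 2], "b": [1, 2, 3]})
        assert math.isnan(pearson(m, "a", "b"))


class TestE3:
    def test_single_experiment_adjacent_ranks(self):
        # a has the top count, b the second: (10+8)/(1+1) = 9
        m = matrix_from({"a": [10], "b": [8], "c": [5], "d": [1]})
        assert e3(m, "a", "b") == pytest.approx(9.0)

    def test_never_cooccurring_pair_scores_zero(self):
        m = matrix_from({"a": [3, 0], "b": [0, 4]})
        assert e3(m, "a", "b") == 0.0

    def test_doubling_one_experiment_doubles_its_term(self):
        base = {"a": [10, 2], "b": [8, 3], "c": [5, 7]}
        # ranks are scale-invariant, so doubling an experiment's counts
        # doubles exactly that experiment's contribution
        t1_only = {p: [v[0], 0] for p, v in base.items()}
        t1d_only = {p: [v[0] * 2, 0] for p, v in base.items()}
        assert e3(matrix_from(t1d_only), "a", "b") == pytest.approx(
            2 * e3(matrix_from(t1_only), "a", "b")
        )

    def test_denominator_modes(self):
        spc = {"a": [10, 0, 6], "b": [8, 5, 6], "c": [5, 9, 1]}
        m = matrix_from(spc)
        assert e3(m, "a", "b", "all") == pytest.approx(
            oracles.e3_bf(spc, "a", "b", "all")
        )
        assert e3(m, "a", "b", "cooccurring") == pytest.approx(
            oracles.e3_bf(spc, "a", "b", "cooccurring")
        )


class TestAbCorrelation:
    def test_hand_value(self):
        m = matrix_from({"a": [2, 0], "b": [3, 0]})
        assert ab_correlation(m, "a", "b") == pytest.approx(3 / 2.5)

    def test_never_cooccurring_is_zero(self):
        m = matrix_from({"a": [3, 0], "b": [0, 4]})
        assert ab_correlation(m, "a", "b") == 0.0

    def test_all_zero_pair_is_undefined(self):
        m = matrix_from({"a": [0, 0], "b": [0, 0], "c": [1, 1]})
        assert math.isnan(ab_correlation(m, "a", "b"))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_all_methods_symmetric_under_pair_swap(seed):
    m = random_matrix(10, 7, seed=seed)
    a, b = m.protein_ids[1], m.protein_ids[5]
    for fn in (sorensen, pearson, e3, ab_correlation):
        x, y = fn(m, a, b), fn(m, b, a)
        assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y, abs=1e-12)


@pytest.mark.parametrize("seed", [3, 4])
def test_score_all_pairs_matches_brute_force(seed):
    """Vectorised all-pairs scoring equals the per-definition nested loop."""
    m = random_matrix(15, 10, seed=seed)
    spc = {p: m.spc.loc[p].tolist() for p in m.protein_ids}
    mw = m.mw.to_dict()
    table = score_all_pairs(m).set_index(["protein_a", "protein_b"])
    proteins = sorted(m.protein_ids)
    n_pairs_with_cooc = 0
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            cooc = sum(1 for x, y in zip(spc[a], spc[b]) if x > 0 and y > 0)
            if cooc == 0:
                assert (a, b) not in table.index
                continue
            n_pairs_with_cooc += 1
            row = table.loc[(a, b)]
            assert row["sor"] == pytest.approx(
                oracles.sorensen_bf(spc, a, b), abs=1e-12)
            assert row["ab"] == pytest.approx(oracles.ab_bf(spc, a, b), abs=1e-12)
            assert row["e3"] == pytest.approx(
                oracles.e3_bf(spc, a, b, "all"), abs=1e-12)
            expected_pr = oracles.pearson_bf(spc, mw, a, b)
            if math.isnan(expected_pr):
                assert math.isnan(row["pr"])
            else:
                assert row["pr"] == pytest.approx(expected_pr, abs=1e-12)
    assert len(table) == n_pairs_with_cooc


def test_full_replication_of_the_compendium_leaves_scores_unchanged():
    """Appending an exact copy of every experiment changes no method."""
    m = random_matrix(8, 6, seed=9)
    doubled = SpectralCountMatrix(
        spc=pd.concat(
            [m.spc, m.spc.set_axis([f"{c}_rep" for c in m.spc.columns], axis=1)],
            axis=1,
        ),
        mw=m.mw,
    )
    t1 = score_all_pairs(m)
    t2 = score_all_pairs(doubled)
    for meth in METHODS:
        assert np.allclose(t1[meth], t2[meth], atol=1e-12, equal_nan=True)


class TestScoreAllPairs:
    def test_three_proteins_three_pairs(self):
        m = matrix_from({"a": [1, 2], "b": [2, 1], "c": [1, 1]})
        assert len(score_all_pairs(m)) == 3

    def test_min_cooccurrence_monotone(self):
        m = random_matrix(12, 9, seed=6)
        sizes = [len(score_all_pairs(m, min_cooccurrence=k)) for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            score_all_pairs(matrix_from({"a": [1, 1]}))

    def test_ranks_contiguous_with_deterministic_ties(self):
        m = random_matrix(10, 6, seed=8)
        t = score_all_pairs(m)
        for meth in METHODS:
            r = t[f"rank_{meth}"].dropna().sort_values()
            assert r.tolist() == list(range(1, len(r) + 1))


class TestCombineWithSorensen:
    def test_zero_sorensen_annihilates(self):
        m = matrix_from({"a": [1, 0, 1], "b": [1, 1, 0], "c": [0, 1, 1]})
        t = score_all_pairs(m)
        combine_with_sorensen(t, "e3")
        zero_sor = t["sor"] == 0
        if zero_sor.any():
            assert (t.loc[zero_sor, "e3_x_sor"] == 0).all()

    def test_unit_sorensen_preserves_base_order(self):
        # identical presence profiles -> sor = 1 for every pair
        m = matrix_from({"a": [5, 1], "b": [3, 2], "c": [1, 9]})
        t = score_all_pairs(m)
        assert (t["sor"] == 1.0).all()
        combine_with_sorensen(t, "e3")
        assert t["rank_e3_x_sor"].tolist() == t["rank_e3"].tolist()

    def test_unknown_base_rejected(self):
        m = random_matrix(5, 4, seed=1)
        with pytest.raises(ValueError):
            combine_with_sorensen(score_all_pairs(m), "sor")


class TestTopFractionIntersection:
    def test_identical_tables_give_top_fraction(self):
        m = random_matrix(10, 8, seed=12)
        t = score_all_pairs(m)
        top = top_fraction_intersection([(t, "ab"), (t, "ab")], 0.1)
        assert len(top) == math.ceil(0.1 * len(t))

    def test_opposed_rankings_intersect_empty(self):
        t = pd.DataFrame(
            {
                "protein_a": ["a", "a", "b", "c"],
                "protein_b": ["b", "c", "c", "d"],
                "up": [4.0, 3.0, 2.0, 1.0],
                "down": [1.0, 2.0, 3.0, 4.0],
            }
        )
        assert top_fraction_intersection([(t, "up"), (t, "down")], 0.25) == set()

    def test_intersection_bounded_by_smallest_top_list(self):
        m = random_matrix(12, 8, seed=13)
        t = score_all_pairs(m)
        top = top_fraction_intersection([(t, c) for c in ("sor", "ab", "e3")], 0.2)
        assert len(top) <= math.ceil(0.2 * len(t))

    def test_mismatched_universes_rejected(self):
        t1 = pd.DataFrame({"protein_a": ["a"], "protein_b": ["b"], "s": [1.0]})
        t2 = pd.DataFrame({"protein_a": ["a"], "protein_b": ["c"], "s": [1.0]})
        with pytest.raises(ValueError, match="universe"):
            top_fraction_intersection([(t1, "s"), (t2, "s")], 0.5)
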