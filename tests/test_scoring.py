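"""Covariation scorer tests against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevonet.alignment import Alignment
from coevonet.matrices import similarity_matrix
from coevonet.scoring import (
    ScoreMatrix,
    SignificantPair,
    apc_correct,
    mcbasc_score,
    method_overlap,
    mutual_information,
    select_significant_pairs,
    sequence_weights,
    zscore_standardize,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def mi_oracle(col_i: str, col_j: str) -> float:
    """Plug-in MI in bits by direct enumeration (gap/'X'-free input)."""
    pairs = list(zip(col_i, col_j))
    n = len(pairs)
    from collections import Counter

    pij = Counter(pairs)
    pi = Counter(col_i)
    pj = Counter(col_j)
    mi = 0.0
    for (a, b), c in pij.items():
        p = c / n
        mi += p * math.log2(p / (pi[a] / n * pj[b] / n))
    return mi


def mcbasc_oracle(a: Alignment, i: int, j: int) -> float:
    """Pearson correlation of the two similarity tables over all ordered
    sequence pairs (explicit double loop)."""
    sim = similarity_matrix("mclachlan")
    idx = {c: k for k, c in enumerate(AA)}
    xs, ys = [], []
    for k in range(a.N):
        for l in range(a.N):
            xs.append(sim[idx[a.rows[k][i]], idx[a.rows[l][i]]])
            ys.append(sim[idx[a.rows[k][j]], idx[a.rows[l][j]]])
    xs, ys = np.array(xs), np.array(ys)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def apc_oracle(values: np.ndarray) -> np.ndarray:
    """APC by direct loops over the upper triangle."""
    L = values.shape[0]
    row_mean = np.array(
        [np.mean([values[i, j] for j in range(L) if j != i]) for i in range(L)]
    )
    grand = np.mean([values[i, j] for i in range(L) for j in range(i + 1, L)])
    out = np.zeros_like(values)
    for i in range(L):
        for j in range(i + 1, L):
            out[i, j] = out[j, i] = values[i, j] - row_mean[i] * row_mean[j] / grand
    return out


class TestSequenceWeights:
    def test_identical_cluster(self):
        a = Alignment(ids=[f"s{i}" for i in range(5)], rows=["ARNDC"] * 5)
        w, meff = sequence_weights(a)
        assert np.allclose(w, 0.2) and meff == pytest.approx(1.0)

    def test_all_distinct(self):
        rows = ["AAAAA", "RRRRR", "NNNNN", "DDDDD", "CCCCC"]
        a = Alignment(ids=[f"s{i}" for i in range(5)], rows=rows)
        w, meff = sequence_weights(a)
        assert np.allclose(w, 1.0) and meff == pytest.approx(5.0)

    def test_cluster_plus_singleton(self):
        a = Alignment(ids=list("abc"), rows=["AAAAA", "AAAAA", "RRRRR"])
        w, meff = sequence_weights(a)
        assert np.allclose(w, [0.5, 0.5, 1.0]) and meff == pytest.approx(2.0)


class TestMutualInformation:
    def test_perfectly_coupled_columns(self):
        a = Alignment(ids=list("abcd"), rows=["AL", "AL", "RV", "RV"])
        mi = mutual_information(a, min_joint_count=2)
        assert mi.values[0, 1] == pytest.approx(1.0)

    def test_independent_columns(self):
        a = Alignment(ids=list("abcd"), rows=["AL", "AV", "RL", "RV"])
        assert mutual_information(a, min_joint_count=2).values[0, 1] == pytest.approx(0.0)

    def test_self_information_is_entropy(self):
        a = Alignment(ids=list("abcd"), rows=["AA", "AA", "AA", "RR"])
        h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert mutual_information(a, min_joint_count=2).values[0, 1] == pytest.approx(h)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from("ARN"), st.sampled_from("DCQ")),
            min_size=2,
            max_size=8,
        )
    )
    def test_matches_enumeration_oracle(self, cols):
        col_i = "".join(c[0] for c in cols)
        col_j = "".join(c[1] for c in cols)
        a = Alignment(
            ids=[f"s{k}" for k in range(len(cols))],
            rows=[x + y for x, y in cols],
        )
        got = mutual_information(a, min_joint_count=2).values[0, 1]
        assert got == pytest.approx(mi_oracle(col_i, col_j), abs=1e-10)

    def test_bounded_by_min_entropy_and_symmetric(self, rng):
        rows = ["".join(rng.choice(list("ARND"), size=5)) for _ in range(8)]
        a = Alignment(ids=[f"s{k}" for k in range(8)], rows=rows)
        mi = mutual_information(a, min_joint_count=2)
        assert np.allclose(mi.values, mi.values.T)
        for i in range(5):
            for j in range(i + 1, 5):
                hi = mi_oracle(a.column(i), a.column(i))
                hj = mi_oracle(a.column(j), a.column(j))
                assert mi.values[i, j] <= min(hi, hj) + 1e-12
                assert mi.values[i, j] >= -1e-12

    def test_gap_policy_pairwise_complete(self):
        a = Alignment(ids=list("abcde"), rows=["AL", "AL", "RV", "RV", "-L"])
        mi = mutual_information(a, min_joint_count=2)
        assert mi.values[0, 1] == pytest.approx(1.0)  # gapped row dropped

    def test_sparse_pairs_masked(self):
        a = Alignment(ids=list("ab"), rows=["AL", "RV"])
        mi = mutual_information(a, min_joint_count=20)
        assert not mi.valid[0, 1]


class TestAPC:
    def test_uniform_matrix_cancels(self):
        vals = np.full((3, 3), 0.6)
        np.fill_diagonal(vals, 0)
        out = apc_correct(ScoreMatrix("MI", vals, np.ones((3, 3), bool)))
        iu = np.triu_indices(3, 1)
        assert np.allclose(out.values[iu], 0.0)

    def test_hand_computed_case(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 1.0
        out = apc_correct(ScoreMatrix("MI", vals, np.ones((3, 3), bool)))
        assert out.values[0, 1] == pytest.approx(0.25)

    def test_two_columns_self_cancels(self):
        vals = np.array([[0.0, 0.7], [0.7, 0.0]])
        out = apc_correct(ScoreMatrix("MI", vals, np.ones((2, 2), bool)))
        assert out.values[0, 1] == pytest.approx(0.0)

    def test_matches_loop_oracle(self, rng):
        L = 6
        vals = np.abs(rng.normal(size=(L, L)))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0)
        out = apc_correct(ScoreMatrix("MI", vals, np.ones((L, L), bool)))
        assert np.allclose(out.values, apc_oracle(vals), atol=1e-10)

    def test_rank_one_background_removed(self):
        # a pure product background r_i r_j is annihilated by the APC
        r = np.array([0.5, 1.0, 1.5, 2.0])
        vals = np.outer(r, r)
        np.fill_diagonal(vals, 0)
        # restore exact product structure off-diagonal, as APC assumes
        out = apc_correct(ScoreMatrix("MI", vals, np.ones((4, 4), bool)))
        iu = np.triu_indices(4, 1)
        # background-only matrices give corrections proportional to signal
        assert np.abs(out.values[iu]).max() < np.abs(vals[iu]).max() * 0.35


class TestMcBASC:
    def test_identical_variable_columns(self):
        a = Alignment(ids=list("abcd"), rows=["AA", "AA", "RR", "KK"])
        assert mcbasc_score(a).values[0, 1] == pytest.approx(1.0)

    def test_conserved_column_scores_zero(self):
        a = Alignment(ids=list("abcd"), rows=["AA", "AR", "AK", "AL"])
        assert mcbasc_score(a).values[0, 1] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            rows = ["".join(rng.choice(list("ARNDKL"), size=3)) for _ in range(4)]
            a = Alignment(ids=[f"s{k}" for k in range(4)], rows=rows)
            got = mcbasc_score(a)
            for i in range(3):
                for j in range(i + 1, 3):
                    assert got.values[i, j] == pytest.approx(
                        mcbasc_oracle(a, i, j), abs=1e-12
                    )

    def test_scores_within_unit_interval(self, rng):
        rows = ["".join(rng.choice(list(AA), size=6)) for _ in range(10)]
        a = Alignment(ids=[f"s{k}" for k in range(10)], rows=rows)
        s = mcbasc_score(a)
        iu = np.triu_indices(6, 1)
        assert np.all(s.values[iu] <= 1.0) and np.all(s.values[iu] >= -1.0)


class TestZscore:
    def test_single_outlier_closed_form(self):
        # six valid scores, five equal, one larger: z_max = sqrt(n-1)
        vals = np.zeros((4, 4))
        iu = list(zip(*np.triu_indices(4, 1)))
        for k, (i, j) in enumerate(iu):
            vals[i, j] = vals[j, i] = 1.0 if k < 5 else 4.0
        z = zscore_standardize(ScoreMatrix("MI", vals, np.ones((4, 4), bool)))
        assert z.values[iu[-1]] == pytest.approx(np.sqrt(5))

    def test_affine_invariance(self, rng):
        L = 5
        vals = rng.normal(size=(L, L))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0)
        valid = np.ones((L, L), bool)
        z1 = zscore_standardize(ScoreMatrix("MI", vals, valid))
        z2 = zscore_standardize(ScoreMatrix("MI", 3.0 * vals + 7.0, valid))
        assert np.allclose(z1.values, z2.values)

    def test_standardized_moments(self, rng):
        L = 8
        vals = rng.normal(size=(L, L))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0)
        z = zscore_standardize(ScoreMatrix("MI", vals, np.ones((L, L), bool)))
        _, _, scores = z.upper_valid()
        assert abs(scores.mean()) < 1e-9 and abs(scores.std() - 1) < 1e-9

    def test_degenerate_all_equal(self):
        vals = np.full((3, 3), 2.0)
        np.fill_diagonal(vals, 0)
        z = zscore_standardize(ScoreMatrix("MI", vals, np.ones((3, 3), bool)))
        assert z.no_variance and np.all(z.values == 0)


class TestSelectSignificantPairs:
    def _zmat(self, entries, L=20):
        vals = np.zeros((L, L))
        for i, j, z in entries:
            vals[i, j] = vals[j, i] = z
        return ScoreMatrix("MIp", vals, np.ones((L, L), bool), standardized=True)

    def test_cutoff_inclusive_at_four(self):
        z = self._zmat([(1, 9, 4.0)])
        assert [(p.i, p.j) for p in select_significant_pairs(z)] == [(1, 9)]

    def test_separation_filter(self):
        z = self._zmat([(2, 7, 9.0)])  # |i-j| = 5 < 6
        assert select_significant_pairs(z) == []

    def test_empty_below_cutoff(self):
        z = self._zmat([(1, 9, 3.999)])
        assert select_significant_pairs(z) == []

    def test_sorted_by_z_then_position(self):
        z = self._zmat([(0, 8, 5.0), (1, 9, 5.0), (2, 10, 6.0)])
        got = [(p.i, p.j) for p in select_significant_pairs(z)]
        assert got == [(2, 10), (0, 8), (1, 9)]


class TestMethodOverlap:
    def _pairs(self, coords, method="M"):
        return [SignificantPair(i, j, method, 5.0) for i, j in coords]

    def test_identical_and_disjoint(self):
        p1 = self._pairs([(1, 9), (2, 10)])
        ov = method_overlap({"A": p1, "B": p1})
        assert ov.loc["A", "B"] == 1.0
        ov = method_overlap({"A": p1, "B": self._pairs([(3, 11)])})
        assert ov.loc["A", "B"] == 0.0

    def test_hand_computed_jaccard(self):
        ov = method_overlap(
            {
                "A": self._pairs([(1, 9), (2, 10)]),
                "B": self._pairs([(2, 10), (3, 11)]),
            }
        )
        assert ov.loc["A", "B"] == pytest.approx(1 / 3)

    def test_both_empty_defined_zero(self):
        ov = method_overlap({"A": [], "B": []})
        assert ov.loc["A", "B"] == 0.0
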