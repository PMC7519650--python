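import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chemomics import permtest


def enumerate_margin_preserving(matrix: np.ndarray):
    """Brute-force enumeration of all binary matrices with the same margins."""
    n_rows, n_cols = matrix.shape
    row_sums = matrix.sum(axis=1)
    col_sums = tuple(matrix.sum(axis=0))
    out = []
    per_row = [
        list(itertools.combinations(range(n_cols), int(r))) for r in row_sums
    ]
    for choice in itertools.product(*per_row):
        cand = np.zeros((n_rows, n_cols), dtype=int)
        for i, cols in enumerate(choice):
            cand[i, list(cols)] = 1
        if tuple(cand.sum(axis=0)) == col_sums:
            out.append(cand)
    return out


class TestCurveball:
    def test_all_ones_matrix_unchanged(self, rng):
        m = np.ones((3, 4), dtype=int)
        out = permtest.curve_ball_randomize(m, rng=rng)
        assert (out == 1).all()

    def test_margins_conserved_on_random_matrices(self, rng):
        for _ in range(200):
            m = (rng.random((rng.integers(2, 10), rng.integers(2, 12))) < 0.4).astype(int)
            out = permtest.curve_ball_randomize(m, rng=rng)
            assert (out.sum(axis=0) == m.sum(axis=0)).all()
            assert (out.sum(axis=1) == m.sum(axis=1)).all()

    def test_identity_margins_uniform_over_two_states(self, rng):
        """The 2x2 identity margins admit exactly two matrices; each should
        appear with frequency 0.5 +/- 0.02 over 10,000 draws."""
        m = np.eye(2, dtype=int)
        hits = 0
        for _ in range(10_000):
            out = permtest.curve_ball_randomize(m, rng=rng)
            hits += out[0, 0] == 1
        assert abs(hits / 10_000 - 0.5) < 0.02

    def test_non_binary_rejected(self, rng):
        with pytest.raises(ValueError):
            permtest.curve_ball_randomize(np.array([[0, 2], [1, 0]]), rng=rng)

    def test_dataframe_round_trip_keeps_labels(self, rng):
        m = pd.DataFrame(
            (rng.random((4, 6)) < 0.5).astype(int),
            index=list("ABCD"),
            columns=[f"s{i}" for i in range(6)],
        )
        out = permtest.curve_ball_randomize(m, rng=rng)
        assert list(out.index) == list("ABCD")
        assert (out.sum(1) == m.sum(1)).all()


class TestGeneObservedStat:
    def test_full_ties_give_p_one(self):
        p, md = permtest.gene_observed_stat([1, 1, 0, 0], [5.0, 5.0, 5.0, 5.0])
        assert p == pytest.approx(1.0)
        assert md == 0.0

    def test_exact_p_matches_enumeration(self):
        """counts 1..10, mutants = top 3: compare to exhaustive enumeration
        of all C(10,3) mutant assignments."""
        counts = np.arange(1, 11, dtype=float)
        status = np.zeros(10, dtype=bool)
        status[-3:] = True
        p, md = permtest.gene_observed_stat(status, counts)
        obs_w = counts[status].sum()  # rank sum == counts here (distinct ints)
        more_extreme = 0
        total = 0
        mean_w = 3 * 11 / 2
        for cols in itertools.combinations(range(10), 3):
            w = counts[list(cols)].sum()
            total += 1
            if abs(w - mean_w) >= abs(obs_w - mean_w) - 1e-12:
                more_extreme += 1
        assert p == pytest.approx(more_extreme / total, abs=1e-12)
        assert md == pytest.approx(np.median(counts[-3:]) - np.median(counts[:-3]))

    def test_median_shift_invariance(self, rng):
        counts = rng.normal(0, 1, 20)
        status = np.zeros(20, dtype=bool)
        status[:8] = True
        counts[status] += 1000
        _, md = permtest.gene_observed_stat(status, counts)
        assert md == pytest.approx(1000, abs=5)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            permtest.gene_observed_stat([1, 1, 1], [1.0, 2.0, 3.0])


class TestBurdenPermutationTest:
    def test_constant_counts_give_p_one_smoothed(self, rng):
        mat = pd.DataFrame((rng.random((5, 30)) < 0.4).astype(int))
        res = permtest.burden_permutation_test(
            mat, np.full(30, 7.0), n_perm=50, min_freq=0.05, rng=rng
        )
        assert (res["p_final"] == 1.0).all()

    def test_smoothed_p_never_zero_never_above_one(self, rng):
        mat = pd.DataFrame((rng.random((8, 40)) < 0.3).astype(int))
        counts = rng.poisson(50, 40).astype(float)
        res = permtest.burden_permutation_test(mat, counts, n_perm=99, rng=rng)
        assert (res["p_final"] > 0).all() and (res["p_final"] <= 1).all()

    def test_reproducible_under_seed(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        base = np.random.default_rng(0)
        mat = pd.DataFrame((base.random((6, 30)) < 0.4).astype(int))
        counts = base.poisson(80, 30).astype(float)
        r1 = permtest.burden_permutation_test(mat, counts, n_perm=200, rng=rng1)
        r2 = permtest.burden_permutation_test(mat, counts, n_perm=200, rng=rng2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_frequency_filter(self, rng):
        mat = pd.DataFrame(np.zeros((2, 40), dtype=int), index=["rare", "common"])
        mat.iloc[0, :1] = 1  # 2.5% < 5%
        mat.iloc[1, :10] = 1
        counts = rng.poisson(50, 40).astype(float)
        res = permtest.burden_permutation_test(mat, counts, n_perm=20, rng=rng)
        assert list(res.index) == ["common"]

    def test_planted_gene_detected(self, rng):
        """A gene whose mutants get 3x counts should come out on top."""
        n = 100
        mat = pd.DataFrame(
            (rng.random((10, n)) < 0.25).astype(int), index=[f"G{i}" for i in range(10)]
        )
        counts = rng.poisson(100, n).astype(float)
        counts[mat.loc["G0"].values == 1] *= 3
        res = permtest.burden_permutation_test(mat, counts, n_perm=500, rng=rng)
        assert res["p_final"].idxmin() == "G0"

    def test_toy_matrix_matches_exhaustive_null(self, rng):
        """On a 4x6 matrix the Monte-Carlo p_final must sit within 3 MC
        standard errors of the exact value from enumerating every
        margin-preserving matrix."""
        mat = np.array(
            [
                [1, 1, 0, 0, 1, 0],
                [0, 1, 1, 0, 0, 1],
                [1, 0, 1, 1, 0, 0],
                [0, 0, 1, 1, 1, 0],
            ]
        )
        counts = np.array([10.0, 3.0, 7.0, 1.0, 12.0, 5.0])
        universe = enumerate_margin_preserving(mat)
        assert len(universe) > 1
        ranks, tie = permtest._rank_setup(counts)
        n = len(counts)
        p_obs = permtest._asymptotic_p(mat @ ranks, mat.sum(1), n, tie)
        exact = np.zeros(len(mat))
        for cand in universe:
            p_perm = permtest._asymptotic_p(cand @ ranks, cand.sum(1), n, tie)
            exact += p_perm <= p_obs
        exact /= len(universe)

        n_perm = 4000
        res = permtest.burden_permutation_test(
            pd.DataFrame(mat), counts, n_perm=n_perm, min_freq=0.0, rng=rng
        )
        for g in range(len(mat)):
            se = math.sqrt(max(exact[g] * (1 - exact[g]), 1e-6) / n_perm)
            assert abs(res["p_final"].iloc[g] - exact[g]) < 3 * se + 2 / n_perm

    def test_literal_mode_fraction_below(self, rng):
        mat = pd.DataFrame((rng.random((4, 30)) < 0.4).astype(int))
        counts = np.full(30, 3.0)
        res = permtest.burden_permutation_test(
            mat, counts, n_perm=50, rng=rng, mode="literal"
        )
        # constant counts: every p is 1, none strictly below -> p_final 0 (the
        # anti-conservative literal behaviour the smoothed default fixes)
        assert (res["p_final"] == 0.0).all()
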