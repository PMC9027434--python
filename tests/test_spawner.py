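import numpy as np
import pytest

from arspawner import (
    TimeSeries,
    align_to_path,
    merge_aligned,
    spawn,
    split_point,
    suboptimal_path,
)
from arspawner.dtw import WarpingPath, local_cost_matrix
from arspawner.errors import SplitError


class TestSplitPoint:
    def test_ceiling_arithmetic(self):
        # r = 0.5 forced via a generator that returns 0.5 first
        class Fixed:
            def uniform(self, a, b):
                return 0.5

        r, R1, R2 = split_point(10, 7, Fixed())
        assert (r, R1, R2) == (0.5, 5, 4)

    @pytest.mark.parametrize("seed", range(30))
    def test_segments_always_nonempty(self, seed):
        rng = np.random.default_rng(seed)
        L1, L2 = rng.integers(2, 30, 2)
        _, R1, R2 = split_point(int(L1), int(L2), rng)
        assert 1 <= R1 < L1 and 1 <= R2 < L2

    def test_deterministic_under_seed(self):
        a = split_point(15, 9, np.random.default_rng(42))
        b = split_point(15, 9, np.random.default_rng(42))
        assert a == b

    def test_too_short_raises(self):
        with pytest.raises(SplitError):
            split_point(1, 5, np.random.default_rng(0))


def _enumerate_paths_through(cost, R1, R2):
    """Min cost over full-grid paths with the junction step (R1,R2)->(R1+1,R2+1).

    The two-matrix construction aligns the halves independently, so the
    element after the forced split is always the diagonal successor; paths
    that merely pass through (R1, R2) and then move horizontally or
    vertically are not producible and are excluded here.
    """
    L1, L2 = cost.shape
    best = [np.inf]

    def rec(i, j, acc, prev, through):
        acc += cost[i, j]
        here = (i + 1, j + 1)
        # forbid leaving (R1, R2) by any step other than the diagonal
        if prev == (R1, R2) and here != (R1 + 1, R2 + 1):
            return
        through = through or here == (R1, R2)
        if i == L1 - 1 and j == L2 - 1:
            if through:
                best[0] = min(best[0], acc)
            return
        if i + 1 < L1 and j + 1 < L2:
            rec(i + 1, j + 1, acc, here, through)
        if i + 1 < L1:
            rec(i + 1, j, acc, here, through)
        if j + 1 < L2:
            rec(i, j + 1, acc, here, through)

    rec(0, 0, 0.0, None, False)
    return best[0]


class TestSuboptimalPath:
    def test_identical_parents_give_diagonal(self, rng):
        X = rng.normal(size=(8, 2))
        path = suboptimal_path(X, X, 3, 3)
        assert np.array_equal(path.pairs, np.stack([np.arange(1, 9)] * 2, axis=1))

    @pytest.mark.parametrize("seed", range(25))
    def test_contains_forced_split_and_is_admissible(self, seed):
        rng = np.random.default_rng(seed)
        L1, L2 = rng.integers(4, 20, 2)
        X1, X2 = rng.normal(size=(L1, 2)), rng.normal(size=(L2, 2))
        _, R1, R2 = split_point(int(L1), int(L2), rng)
        path = suboptimal_path(X1, X2, R1, R2)
        path.validate(int(L1), int(L2))
        assert any((i, j) == (R1, R2) for i, j in path.pairs)

    def test_matches_constrained_bruteforce_on_toy(self, rng):
        # 4x3 grid, forced split (2, 2); the sub-bands are wide enough to be
        # unrestrictive, so the result must be the best path through (2, 2)
        X1, X2 = rng.normal(size=(4, 1)), rng.normal(size=(3, 1))
        path = suboptimal_path(X1, X2, 2, 2)
        cost = local_cost_matrix(X1, X2)
        i, j = path.pairs[:, 0] - 1, path.pairs[:, 1] - 1
        assert cost[i, j].sum() == pytest.approx(
            _enumerate_paths_through(cost, 2, 2)
        )


class TestAlignToPath:
    def test_diagonal_path_is_identity(self, rng):
        X1, X2 = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        path = WarpingPath(np.stack([np.arange(1, 6)] * 2, axis=1))
        a1, a2 = align_to_path(X1, X2, path)
        assert np.array_equal(a1, X1) and np.array_equal(a2, X2)

    def test_horizontal_step_duplicates_element(self):
        X1 = np.array([[0.0], [1.0]])
        X2 = np.array([[5.0], [6.0], [7.0]])
        path = WarpingPath([(1, 1), (1, 2), (2, 3)])
        a1, a2 = align_to_path(X1, X2, path)
        assert a1[:, 0].tolist() == [0.0, 0.0, 1.0]
        assert a2[:, 0].tolist() == [5.0, 6.0, 7.0]
        assert len(a1) == len(a2) == len(path)


class TestMergeAligned:
    def test_identical_inputs_pass_through(self, rng):
        X = rng.normal(size=(7, 3))
        assert np.array_equal(merge_aligned(X, X, rng), X)

    def test_sampling_law_mean_and_std(self):
        # element x1=0, x2=2 -> mu = 1, sigma = 0.1
        rng = np.random.default_rng(99)
        draws = np.array(
            [merge_aligned(np.zeros((1, 1)), np.full((1, 1), 2.0), rng)[0, 0]
             for _ in range(10_000)]
        )
        assert abs(draws.mean() - 1.0) < 4 * 0.1 / 100  # 4 sigma / sqrt(n)
        assert draws.std() == pytest.approx(0.1, rel=0.05)


class TestSpawn:
    @staticmethod
    def _parents(seed=0, L1=12, L2=9):
        rng = np.random.default_rng(seed)
        return (
            TimeSeries(rng.normal(size=(L1, 2)), "c", "s1", "p1"),
            TimeSeries(rng.normal(size=(L2, 2)), "c", "s2", "p2"),
        )

    def test_identical_parents_reproduce_parent(self, rng):
        X = TimeSeries(rng.normal(size=(10, 2)), "c", "s", "p")
        Y = TimeSeries(X.values, "c", "s", "q")
        cand = spawn(X, Y, np.random.default_rng(1))
        assert np.array_equal(cand.values, X.values)

    def test_candidate_length_bounds_and_label(self):
        p1, p2 = self._parents()
        cand = spawn(p1, p2, np.random.default_rng(5))
        assert max(12, 9) <= len(cand.values) < 12 + 9
        assert cand.label == "c" and cand.parents == ("p1", "p2")

    def test_bit_reproducible_under_seed(self):
        p1, p2 = self._parents()
        a = spawn(p1, p2, np.random.default_rng(17))
        b = spawn(p1, p2, np.random.default_rng(17))
        assert np.array_equal(a.values, b.values)
        assert a.split == b.split

    def test_label_mismatch_refused(self, rng):
        p1 = TimeSeries(rng.normal(size=(5, 1)), "a", "s", "p1")
        p2 = TimeSeries(rng.normal(size=(5, 1)), "b", "s", "p2")
        with pytest.raises(ValueError, match="label"):
            spawn(p1, p2, rng)

    @pytest.mark.parametrize("seed", range(10))
    def test_five_sigma_envelope(self, seed):
        p1, p2 = self._parents(seed)
        cand = spawn(p1, p2, np.random.default_rng(seed))
        a1, a2 = align_to_path(p1.values, p2.values, cand.path)
        lo = np.minimum(a1, a2) - 5 * 0.05 * np.abs(a1 - a2)
        hi = np.maximum(a1, a2) + 5 * 0.05 * np.abs(a1 - a2)
        assert np.all(cand.values >= lo) and np.all(cand.values <= hi)
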