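import numpy as np
import pytest

from aqa.alignment import (
    AlignmentResult,
    QaqaConfig,
    SearchWindow,
    WarpPath,
    acdtw,
    coarsen,
    dtw,
    expand_window,
    med,
    penalty_factor,
    qaqa_align,
)
from aqa.features import FeatureSequence
from oracles import exhaustive_alignment_cost


def random_pair(rng, max_len=8, dim=3):
    a, b = rng.integers(1, max_len + 1, size=2)
    return rng.normal(size=(a, dim)), rng.normal(size=(b, dim))


class TestMed:
    def test_identical_frames(self, rng):
        f = rng.normal(size=27)
        assert med(f, f) == 0.0

    def test_single_feature_delta(self):
        f1 = np.zeros(27)
        f2 = np.zeros(27)
        f2[13] = 0.75
        assert med(f1, f2) == pytest.approx(0.75)

    def test_matches_l2_oracle(self, rng):
        f1, f2 = rng.normal(size=(2, 27))
        assert med(f1, f2) == pytest.approx(np.linalg.norm(f1 - f2), abs=1e-12)
        assert med(f1, f2, "manhattan") == pytest.approx(np.abs(f1 - f2).sum(), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            med(np.zeros(27), np.zeros(26))


class TestPenaltyFactor:
    def test_equal_lengths_give_one(self):
        assert penalty_factor(7, 7) == 1.0

    def test_unbalanced(self):
        assert penalty_factor(3, 1) == pytest.approx(1.5)


class TestClassicDtw:
    def test_identity_alignment(self, rng):
        X = rng.normal(size=(6, 4))
        res = dtw(X, X)
        assert res.distance == pytest.approx(0.0)
        assert res.path.pairs == [(i, i) for i in range(1, 7)]
        assert res.cells_computed == 36

    def test_one_frame_vs_many(self, rng):
        X = rng.normal(size=(1, 4))
        Y = rng.normal(size=(5, 4))
        expected = sum(med(X[0], y) for y in Y)
        assert dtw(X, Y).distance == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw(np.empty((0, 3)), np.zeros((2, 3)))


class TestAcdtw:
    def test_identity_gives_zero_diagonal(self, rng):
        X = rng.normal(size=(9, 5))
        res = acdtw(X, X)
        assert res.distance == pytest.approx(0.0)
        assert res.path.pairs == [(i, i) for i in range(1, 10)]

    def test_never_below_classic_dtw(self, rng):
        for _ in range(20):
            X, Y = random_pair(rng)
            assert acdtw(X, Y).distance >= dtw(X, Y).distance - 1e-12

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            X, Y = random_pair(rng, max_len=6)
            C = penalty_factor(len(X), len(Y))
            assert acdtw(X, Y).distance == pytest.approx(
                exhaustive_alignment_cost(X, Y, C), abs=1e-9
            )

    def test_adaptive_penalty_variant(self, rng):
        X, Y = rng.normal(size=(7, 3)), rng.normal(size=(5, 3))
        res = acdtw(X, Y, penalty="adaptive")
        res.path.validate(7, 5)
        assert res.distance >= 0
        with pytest.raises(ValueError):
            acdtw(X, Y, window=SearchWindow(np.ones(7, int), np.full(7, 5)), penalty="adaptive")

    def test_invalid_window_rejected(self, rng):
        X, Y = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        with pytest.raises(ValueError):
            acdtw(X, Y, window=SearchWindow(np.full(4, 2), np.full(4, 4)))  # misses (1,1)


class TestCoarsen:
    def test_pairs_of_identical_frames(self):
        f = np.arange(5.0)
        F = np.tile(f, (4, 1))
        np.testing.assert_array_equal(coarsen(F), np.tile(f, (2, 1)))

    def test_matches_pairwise_mean_with_odd_tail(self, rng):
        F = rng.normal(size=(7, 3))
        out = coarsen(F)
        assert out.shape == (4, 3)
        np.testing.assert_allclose(out[:3], (F[0:6:2] + F[1:6:2]) / 2)
        np.testing.assert_allclose(out[3], F[6])

    def test_preserves_feature_sequence_type(self, rng):
        F = FeatureSequence(rng.normal(size=(6, 27)), fps=30.0)
        out = coarsen(F)
        assert isinstance(out, FeatureSequence) and len(out) == 3

    def test_too_short(self):
        with pytest.raises(ValueError):
            coarsen(np.zeros((1, 3)))


class TestExpandWindow:
    def test_diagonal_path_radius_zero_gives_block_band(self):
        path = WarpPath([(1, 1), (2, 2), (3, 3)])
        win = expand_window(path, 6, 6, 0)
        for i in range(1, 7):
            block = (i + 1) // 2  # source coarse cell
            assert win.lo[i - 1] == 2 * block - 1
            assert win.hi[i - 1] == 2 * block

    def test_large_radius_saturates_to_full_matrix(self):
        path = WarpPath([(1, 1), (2, 2), (3, 3)])
        win = expand_window(path, 6, 5, 10)
        np.testing.assert_array_equal(win.lo, 1)
        np.testing.assert_array_equal(win.hi, 5)

    def test_contains_projection_and_chebyshev_dilation(self, rng):
        for _ in range(20):
            a, b = rng.integers(4, 30, size=2)
            res = acdtw(rng.normal(size=((a + 1) // 2, 3)), rng.normal(size=((b + 1) // 2, 3)))
            radius = int(rng.integers(0, 4))
            win = expand_window(res.path, a, b, radius)
            win.validate(a, b)
            projected = set()
            for i, j in res.path:
                for r in (2 * i - 1, 2 * i):
                    for c in (2 * j - 1, 2 * j):
                        if r <= a and c <= b:
                            projected.add((r, c))
            for r, c in projected:
                for dr in range(-radius, radius + 1):
                    for dc in range(-radius, radius + 1):
                        rr, cc = r + dr, c + dc
                        if 1 <= rr <= a and 1 <= cc <= b:
                            assert win.contains(rr, cc)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            expand_window(WarpPath([]), 4, 4, 1)


class TestQaqa:
    def test_radius_saturation_reduces_to_full_acdtw(self, rng):
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(33, 6))
        full = acdtw(X, Y)
        q = qaqa_align(X, Y, QaqaConfig(radius=40))
        assert q.distance == full.distance
        assert q.path.pairs == full.path.pairs

    def test_identity_any_radius(self, rng):
        X = rng.normal(size=(50, 6))
        for radius in (1, 3, 10):
            res = qaqa_align(X, X, QaqaConfig(radius=radius))
            assert res.distance == pytest.approx(0.0)
            assert res.path.pairs == [(i, i) for i in range(1, 51)]

    def test_windowed_distance_never_below_full(self, rng):
        for _ in range(10):
            X = rng.normal(size=(int(rng.integers(20, 60)), 4))
            Y = rng.normal(size=(int(rng.integers(20, 60)), 4))
            assert qaqa_align(X, Y, QaqaConfig(radius=2)).distance >= acdtw(X, Y).distance - 1e-9

    def test_path_validity_and_cell_accounting(self, rng):
        X = rng.normal(size=(70, 4))
        Y = rng.normal(size=(55, 4))
        res = qaqa_align(X, Y, QaqaConfig(radius=3))
        res.path.validate(70, 55)
        assert res.levels >= 2
        assert res.cells_computed < 70 * 55  # strictly fewer than the full matrix

    def test_config_validation(self):
        with pytest.raises(ValueError):
            QaqaConfig(radius=0)
        with pytest.raises(ValueError):
            QaqaConfig(distance_metric="cosine")


def test_alignment_result_fields(rng):
    X = rng.normal(size=(5, 3))
    res = dtw(X, X)
    assert isinstance(res, AlignmentResult)
    assert res.levels == 1
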