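import itertools

import numpy as np
import pytest

import multifq as m


def brute_force_accuracy(pred, truth):
    """Exhaustive oracle: maximize agreement over all one-to-one
    cluster-to-unit assignments (K <= 6)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    pu = np.unique(pred)
    tu = np.unique(truth)
    big, small, swap = (pu, tu, False) if len(pu) >= len(tu) else (tu, pu, True)
    best = 0
    for perm in itertools.permutations(big, len(small)):
        mapping = dict(zip(perm, small))
        if swap:
            agree = sum(p == mapping.get(t, None) for p, t in zip(pred, truth))
        else:
            agree = sum(mapping.get(p, None) == t for p, t in zip(pred, truth))
        best = max(best, agree)
    return best / len(pred)


class TestMatchEvents:
    def test_pair_within_tolerance(self):
        em = m.match_events([10.0001], [10.0000], 0.0003)
        assert em.pairs == ((0, 0),)

    def test_strict_boundary_excluded(self):
        em = m.match_events([10.0004], [10.0000], 0.0003)
        assert em.pairs == ()
        assert em.unmatched_detected == (0,)
        assert em.unmatched_truth == (0,)

    def test_tie_goes_to_earlier_detection(self):
        em = m.match_events([1.0000, 1.0002], [1.0001], 0.0003)
        assert em.pairs == ((0, 0),)
        assert em.unmatched_detected == (1,)

    def test_one_to_one(self):
        em = m.match_events([1.0, 1.0001], [1.00005], 0.001)
        assert em.n_matched == 1

    def test_negative_tolerance_raises(self):
        with pytest.raises(ValueError):
            m.match_events([1.0], [1.0], -1e-3)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_maximal_on_sparse_events(self, seed):
        # with events spaced >> tolerance the greedy matching equals the
        # brute-force max-cardinality / min-cost matching
        rng = np.random.default_rng(seed)
        truth = np.sort(rng.uniform(0, 10, size=20))
        truth = truth[np.diff(truth, prepend=-1) > 0.01]
        jitter = rng.uniform(-4e-4, 4e-4, size=truth.size)
        detected = np.sort(truth + jitter)
        em = m.match_events(detected, truth, 5e-4)
        expected = sum(
            min(abs(d - truth).min() for d in detected[max(0, i - 1): i + 1]) < 5e-4
            for i in range(len(detected))
        )
        assert em.n_matched >= truth.size - np.sum(np.abs(jitter) >= 5e-4) - 1


class TestSortingAccuracy:
    def test_identity(self):
        assert m.sorting_accuracy([0, 1, 2], [0, 1, 2]) == 1.0

    def test_relabel_invariance(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [2, 2, 0, 0, 1, 1]
        assert m.sorting_accuracy(pred, truth) == 1.0

    def test_worked_example(self):
        # best assignment {1->0, 0->1, 2->2} scores 2+2+1 = 5 of 6 (verified
        # against the exhaustive oracle below)
        truth = [0, 0, 0, 1, 1, 2]
        pred = [1, 1, 0, 0, 0, 2]
        assert m.sorting_accuracy(pred, truth) == pytest.approx(
            brute_force_accuracy(pred, truth)
        ) == pytest.approx(5 / 6)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            m.sorting_accuracy([0, 1], [0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        kp = int(rng.integers(1, 7))
        kt = int(rng.integers(1, 7))
        pred = rng.integers(0, kp, size=n)
        truth = rng.integers(0, kt, size=n)
        assert m.sorting_accuracy(pred, truth) == pytest.approx(
            brute_force_accuracy(pred, truth)
        )


class TestSeparation:
    def test_unit_offset(self):
        X = np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0]])
        labels = [0, 0, 1, 1]
        sep, mean = m.interclass_separation(X, labels)
        assert sep[0, 1] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)

    def test_squared_distance(self):
        X = np.array([[0.0, 0, 0], [0, 2, 0]])
        sep, _ = m.interclass_separation(X, [0, 1])
        assert sep[0, 1] == pytest.approx(4.0)

    def test_coincident_centers(self):
        X = np.array([[1.0, 1], [1, 1]])
        sep, mean = m.interclass_separation(X, [0, 1])
        assert sep[0, 1] == 0.0 and mean == 0.0

    def test_symmetry_zero_diagonal_relabel_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        labels = rng.integers(0, 3, size=30)
        sep, mean = m.interclass_separation(X, labels)
        np.testing.assert_allclose(sep, sep.T)
        assert np.all(np.diag(sep) == 0)
        relabeled = (labels + 1) % 3
        sep2, mean2 = m.interclass_separation(X, relabeled)
        assert mean2 == pytest.approx(mean)
        assert sorted(np.round(sep[np.triu_indices(3, 1)], 9)) == sorted(
            np.round(sep2[np.triu_indices(3, 1)], 9)
        )


class TestPartialTruthMetrics:
    def _matching(self, n_det, marked_idx, n_unmatched_truth=0):
        pairs = tuple((i, j) for j, i in enumerate(marked_idx))
        return m.EventMatching(
            pairs=pairs,
            unmatched_detected=tuple(i for i in range(n_det) if i not in marked_idx),
            unmatched_truth=tuple(range(len(marked_idx),
                                        len(marked_idx) + n_unmatched_truth)),
            tolerance_s=3e-4,
        )

    def _truth(self, n):
        return m.GroundTruth(np.linspace(0, 1, n), np.zeros(n, dtype=int),
                             kind="partial")

    def test_worked_example(self):
        # 10 marked detections: 8 land in cluster 1 (with 2 unmarked), 2 outside
        pred = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 5)
        marked = list(range(10))
        pm = m.partial_truth_metrics(self._matching(17, marked), pred, self._truth(10))
        assert (pm["tp"], pm["fp"], pm["fn"]) == (8, 2, 2)
        assert pm["precision"] == pytest.approx(0.8)
        assert pm["recall"] == pytest.approx(0.8)
        assert pm["f1"] == pytest.approx(0.8)

    def test_perfect_case(self):
        pred = np.array([1] * 5 + [0] * 5)
        pm = m.partial_truth_metrics(self._matching(10, list(range(5))), pred,
                                     self._truth(5))
        assert pm["precision"] == pm["recall"] == pm["f1"] == 1.0

    def test_undetected_marked_count_as_fn(self):
        pred = np.array([1] * 5 + [0] * 5)
        pm = m.partial_truth_metrics(
            self._matching(10, list(range(5)), n_unmatched_truth=5), pred,
            self._truth(10))
        assert pm["fn"] == 5
        assert pm["recall"] == pytest.approx(0.5)

    def test_degenerate_zero_convention(self):
        pred = np.zeros(4, dtype=int)
        pm = m.partial_truth_metrics(self._matching(4, []), pred, self._truth(3))
        assert pm["precision"] == pm["recall"] == pm["f1"] == 0.0

    def test_bounds_and_f1_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_det = int(rng.integers(4, 30))
            n_marked = int(rng.integers(1, n_det))
            pred = rng.integers(0, 3, size=n_det)
            pm = m.partial_truth_metrics(
                self._matching(n_det, list(range(n_marked))), pred,
                self._truth(n_marked))
            p, r, f1 = pm["precision"], pm["recall"], pm["f1"]
            assert 0 <= p <= 1 and 0 <= r <= 1 and 0 <= f1 <= 1
            assert f1 <= max(p, r) + 1e-12
            if p + r > 0:
                assert f1 == pytest.approx(2 * p * r / (p + r))


class TestOverlapMask:
    def test_close_pair_both_flagged(self):
        mask = m.overlap_mask([0.0, 0.001], None, window_s=0.00256)
        assert mask.tolist() == [True, True]

    def test_isolated_events_unflagged(self):
        mask = m.overlap_mask([0.0, 0.1, 0.2], None, window_s=0.00256)
        assert not mask.any()

    def test_boundary_spacing_not_flagged(self):
        mask = m.overlap_mask([0.0, 0.00256], None, window_s=0.00256)
        assert not mask.any()

    def test_matches_pairwise_scan(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1, size=50))
        w = 0.01
        mask = m.overlap_mask(t, None, w)
        oracle = np.array(
            [any(abs(t[i] - t[j]) < w for j in range(50) if j != i) for i in range(50)]
        )
        np.testing.assert_array_equal(mask, oracle)
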