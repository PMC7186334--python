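"""Connectome tallying and FN-threshold / FA-weighting rules."""

import numpy as np
import pytest

from wmhnet import (Connectome, Parcellation, Streamline, assign_endpoints,
                    build_connectome, threshold_and_weight)


@pytest.fixture
def parcellation():
    labels = np.zeros((10, 4, 4), dtype=np.int32)
    labels[0:2] = 1
    labels[4:6] = 2
    labels[8:10] = 3
    return Parcellation(label_volume=labels, node_names=["A", "B", "C"])


def _line(p0, p1, npts=5):
    return Streamline(points=np.linspace(p0, p1, npts))


class TestAssignEndpoints:
    def test_two_distinct_regions(self, parcellation):
        sl = _line([0.5, 1.0, 1.0], [9.5, 1.0, 1.0])
        assert assign_endpoints(sl, parcellation) == (1, 3)

    def test_endpoint_in_background_discarded(self, parcellation):
        sl = _line([3.0, 1.0, 1.0], [9.5, 1.0, 1.0])  # x=3 is label 0
        assert assign_endpoints(sl, parcellation) is None

    def test_same_region_discarded(self, parcellation):
        sl = _line([0.2, 1.0, 1.0], [1.8, 2.0, 2.0])
        assert assign_endpoints(sl, parcellation) is None

    def test_endpoint_off_grid_discarded(self, parcellation):
        sl = _line([-1.0, 1.0, 1.0], [9.5, 1.0, 1.0])
        assert assign_endpoints(sl, parcellation) is None


class TestBuildConnectome:
    def test_constant_streamlines_give_means_of_constants(self, parcellation):
        fa = np.full((10, 4, 4), 0.5)
        sls = [_line([1.0, 1.0, 1.0], [5.0 + 1e-9, 1.0, 1.0])  # length ~4
               for _ in range(3)]
        conn = build_connectome(sls, parcellation, fa)
        assert conn.fn[0, 1] == 3
        assert conn.length_mean[0, 1] == pytest.approx(4.0, abs=1e-6)
        assert conn.fa_mean[0, 1] == pytest.approx(0.5)

    def test_per_streamline_fa_is_point_mean(self, parcellation):
        fa = np.zeros((10, 4, 4))
        fa[0:5] = 0.4
        fa[5:] = 0.6
        # 4 points: two in the 0.4 half, two in the 0.6 half
        sl = Streamline(points=np.array([[1.5, 1, 1], [4.5, 1, 1],
                                         [5.5, 1, 1], [8.5, 1, 1]]))
        conn = build_connectome([sl], parcellation, fa)
        assert conn.fa_mean[0, 2] == pytest.approx(0.5)

    def test_random_fixture_matches_independent_tally(self, rng,
                                                      parcellation):
        fa = rng.uniform(0.2, 0.8, (10, 4, 4))
        region_x = {1: (0, 2), 2: (4, 6), 3: (8, 10)}
        sls, tally = [], {}
        for _ in range(50):
            i, j = sorted(rng.choice([1, 2, 3], size=2, replace=False))
            p0 = [rng.uniform(*region_x[i]), rng.uniform(0, 4),
                  rng.uniform(0, 4)]
            p1 = [rng.uniform(*region_x[j]), rng.uniform(0, 4),
                  rng.uniform(0, 4)]
            sl = _line(p0, p1, npts=int(rng.integers(3, 9)))
            sls.append(sl)
            vox = np.floor(sl.points).astype(int)
            fa_mean = np.mean([fa[tuple(v)] for v in vox])
            length = sum(np.linalg.norm(sl.points[k + 1] - sl.points[k])
                         for k in range(len(sl) - 1))
            rec = tally.setdefault((i, j), [0, 0.0, 0.0])
            rec[0] += 1
            rec[1] += fa_mean
            rec[2] += length
        conn = build_connectome(sls, parcellation, fa)
        for (i, j), (count, fa_sum, len_sum) in tally.items():
            assert conn.fn[i - 1, j - 1] == count
            assert conn.fa_mean[i - 1, j - 1] == pytest.approx(
                fa_sum / count, abs=1e-10)
            assert conn.length_mean[i - 1, j - 1] == pytest.approx(
                len_sum / count, abs=1e-10)

    def test_grid_mismatch_rejected(self, parcellation):
        with pytest.raises(ValueError, match="does not match"):
            build_connectome([], parcellation, np.zeros((5, 4, 4)))


def _toy_connectome(fn12=4, fa12=0.5):
    fn = np.zeros((3, 3))
    fa = np.zeros((3, 3))
    ln = np.zeros((3, 3))
    fn[0, 1] = fn[1, 0] = fn12
    fa[0, 1] = fa[1, 0] = fa12
    ln[0, 1] = ln[1, 0] = 10.0
    fn[1, 2] = fn[2, 1] = 3
    fa[1, 2] = fa[2, 1] = 0.6
    ln[1, 2] = ln[2, 1] = 20.0
    return Connectome(node_names=["A", "B", "C"], fn=fn, fa_mean=fa,
                      length_mean=ln)


class TestThresholdAndWeight:
    def test_count_equal_to_threshold_is_removed(self):
        graph = threshold_and_weight(_toy_connectome(), fn_threshold=3)
        assert graph.weights[1, 2] == 0.0        # FN = 3 does not survive

    def test_surviving_weight_is_fn_times_fa(self):
        graph = threshold_and_weight(_toy_connectome(fn12=4, fa12=0.5), 3)
        assert graph.weights[0, 1] == pytest.approx(2.0)

    def test_zero_threshold_keeps_fn_support(self):
        conn = _toy_connectome()
        graph = threshold_and_weight(conn, fn_threshold=0)
        np.testing.assert_array_equal(graph.weights > 0, conn.fn > 0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_and_weight(_toy_connectome(), fn_threshold=-1)

    def test_raising_threshold_only_removes_edges(self, rng):
        fn = rng.integers(0, 8, (6, 6)).astype(float)
        fn = np.triu(fn, 1)
        fn = fn + fn.T
        fa = np.where(fn > 0, 0.5, 0.0)
        ln = np.where(fn > 0, 15.0, 0.0)
        conn = Connectome(node_names=list("abcdef"), fn=fn, fa_mean=fa,
                          length_mean=ln)
        prev = None
        for thr in range(0, 8):
            present = threshold_and_weight(conn, thr).weights > 0
            if prev is not None:
                assert np.all(present <= prev)
            prev = present

    def test_commutes_with_node_permutation(self, rng):
        conn = _toy_connectome()
        perm = rng.permutation(3)
        permuted = Connectome(
            node_names=[conn.node_names[p] for p in perm],
            fn=conn.fn[np.ix_(perm, perm)],
            fa_mean=conn.fa_mean[np.ix_(perm, perm)],
            length_mean=conn.length_mean[np.ix_(perm, perm)])
        g1 = threshold_and_weight(conn, 3).weights[np.ix_(perm, perm)]
        g2 = threshold_and_weight(permuted, 3).weights
        np.testing.assert_allclose(g1, g2)


class TestConnectomeValidation:
    def test_rejects_asymmetric_fn(self):
        fn = np.zeros((3, 3))
        fn[0, 1] = 4
        with pytest.raises(ValueError, match="symmetric"):
            Connectome(node_names=["A", "B", "C"], fn=fn,
                       fa_mean=np.zeros((3, 3)), length_mean=np.zeros((3, 3)))

    def test_rejects_support_mismatch(self):
        fn = np.zeros((3, 3))
        fa = np.zeros((3, 3))
        fa[0, 1] = fa[1, 0] = 0.5  # FA without any fibers
        with pytest.raises(ValueError, match="support"):
            Connectome(node_names=["A", "B", "C"], fn=fn, fa_mean=fa,
                       length_mean=np.zeros((3, 3)))

    def test_rejects_noncontiguous_labels(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0] = 7
        with pytest.raises(ValueError, match="labels"):
            Parcellation(label_volume=labels, node_names=["A", "B"])
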