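"""Cluster-based permutation machinery, with an independent brute-force oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

import erspkit as ek
from erspkit.cluster import SubjectDifference, _lattice_adjacency
from conftest import make_diff


# ---------------------------------------------------------------------------
# independent oracle: scipy t maps + networkx connected components

def oracle_max_masses(xa, xb, thresh, adj_ch):
    """Max |cluster mass| for every distinct split, via an implementation
    sharing no code with the package (scipy t-test, networkx components)."""
    pool = np.concatenate([xa, xb])
    n, na = len(pool), len(xa)
    out = []
    for combo in itertools.combinations(range(n), na):
        in_a = np.zeros(n, dtype=bool)
        in_a[list(combo)] = True
        t_map, _ = sps.ttest_ind(pool[in_a], pool[~in_a], axis=0)
        out.append(oracle_max_mass_one(t_map, thresh, adj_ch))
    return np.array(out)


def oracle_max_mass_one(t_map, thresh, adj_ch):
    best = 0.0
    for sign in (1, -1):
        g = nx.Graph()
        pts = [tuple(p) for p in np.argwhere(sign * t_map > thresh)]
        g.add_nodes_from(pts)
        for (c1, f1, t1) in pts:
            for (c2, f2, t2) in pts:
                if (c1, f1, t1) >= (c2, f2, t2):
                    continue
                spatial = adj_ch[c1, c2] and f1 == f2 and t1 == t2
                spectral = c1 == c2 and abs(f1 - f2) == 1 and t1 == t2
                temporal = c1 == c2 and f1 == f2 and abs(t1 - t2) == 1
                if spatial or spectral or temporal:
                    g.add_edge((c1, f1, t1), (c2, f2, t2))
        for comp in nx.connected_components(g):
            mass = abs(sum(t_map[p] for p in comp))
            best = max(best, mass)
    return best


# ---------------------------------------------------------------------------

class TestTriangulationNeighbors:
    def test_three_channels_form_one_triangle(self, layout3):
        ng = ek.triangulation_neighbors(layout3)
        assert ng.adjacency.sum() == 6  # all 3 pairs, both directions

    def test_unit_square_has_five_edges(self):
        lay = ek.ChannelLayout(("a", "b", "c", "d"),
                               np.array([[0, 0, 1.0], [0.3, 0, 1.0],
                                         [0, 0.3, 1.0], [0.3, 0.3, 1.0]]))
        ng = ek.triangulation_neighbors(lay)
        assert ng.adjacency.sum() // 2 == 5  # 4 sides + 1 diagonal

    def test_62_channel_graph_symmetric_irreflexive_connected(self, layout62):
        ng = ek.triangulation_neighbors(layout62)
        a = ng.adjacency
        assert np.array_equal(a, a.T)
        assert not a.diagonal().any()
        assert a.sum(axis=0).min() >= 1
        assert "CP1" in ng.neighbors("CPZ") or "CPZ" in ng.neighbors("CP1")

    def test_collinear_positions_rejected(self):
        lay = ek.ChannelLayout(("a", "b", "c"),
                               np.array([[0, 0, 1.0], [0.1, 0, 1.0], [0.2, 0, 1.0]]))
        with pytest.raises(ValueError):
            ek.triangulation_neighbors(lay)


class TestSubjectDifference:
    freqs = np.array([4.0, 5.0])
    times = np.array([0.0, 0.01, 0.02])

    def _ersp(self, data):
        return ek.TFR(data=data, times=self.times, freqs=self.freqs,
                      ch_names=["x", "y"], per_trial=False, is_db=True)

    def test_identical_inputs_zero(self):
        d = np.random.default_rng(0).random((2, 2, 3))
        out = ek.subject_difference(self._ersp(d), self._ersp(d.copy()))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_constant_offset_recovered(self):
        """S3 = S1 + 0.29 everywhere yields a constant 0.29 difference."""
        d = np.random.default_rng(1).random((2, 2, 3))
        out = ek.subject_difference(self._ersp(d + 0.29), self._ersp(d))
        np.testing.assert_allclose(out.data, 0.29, atol=1e-12)

    def test_antisymmetric(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((2, 2, 3)), rng.random((2, 2, 3))
        fwd = ek.subject_difference(self._ersp(a), self._ersp(b))
        rev = ek.subject_difference(self._ersp(b), self._ersp(a))
        np.testing.assert_allclose(fwd.data, -rev.data)

    def test_shape_mismatch_rejected(self):
        a = self._ersp(np.ones((2, 2, 3)))
        wrong = ek.TFR(data=np.ones((2, 2, 2)), times=self.times[:2],
                       freqs=self.freqs, ch_names=["x", "y"], per_trial=False)
        with pytest.raises(ValueError):
            ek.subject_difference(a, wrong)


class TestPointwiseT:
    def test_hand_computed_value(self):
        a = [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0)]
        b = [np.full((1, 1, 1), v) for v in (4.0, 5.0, 6.0)]
        t_map, df = ek.pointwise_t(a, b)
        assert df == 4
        assert t_map[0, 0, 0] == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups_zero(self):
        rng = np.random.default_rng(3)
        g = [rng.random((2, 2, 2)) for _ in range(3)]
        t_map, _ = ek.pointwise_t(g, [x.copy() for x in g])
        np.testing.assert_allclose(t_map, 0.0, atol=1e-12)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(4)
        a = [rng.random((2, 2, 2)) for _ in range(4)]
        b = [rng.random((2, 2, 2)) for _ in range(4)]
        t1, _ = ek.pointwise_t(a, b)
        t2, _ = ek.pointwise_t(b, a)
        np.testing.assert_allclose(t1, -t2)

    def test_zero_variance_flagged_nan(self):
        a = [np.ones((1, 1, 1)) for _ in range(3)]
        b = [np.ones((1, 1, 1)) for _ in range(3)]
        t_map, _ = ek.pointwise_t(a, b)
        assert np.isnan(t_map[0, 0, 0])


class TestFormClusters:
    def _graph(self, adj):
        n = adj.shape[0]
        return ek.NeighborGraph(tuple(f"c{i}" for i in range(n)), adj)

    def test_no_suprathreshold_points(self):
        ng = self._graph(np.zeros((2, 2), dtype=bool))
        t_map = np.zeros((2, 1, 2))
        out = ek.form_clusters(t_map, df=10, cluster_alpha=0.05, neighbors=ng,
                               freqs=np.array([4.0]), times=np.array([0.0, 0.01]))
        assert out == []

    def test_single_point_cluster_mass(self):
        ng = self._graph(np.zeros((2, 2), dtype=bool))
        t_map = np.zeros((2, 1, 2))
        t_map[1, 0, 1] = 5.0
        out = ek.form_clusters(t_map, df=10, cluster_alpha=0.05, neighbors=ng,
                               freqs=np.array([4.0]), times=np.array([0.0, 0.01]))
        assert len(out) == 1
        assert out[0].mass == pytest.approx(5.0)
        assert out[0].electrodes == ["c1"]

    def test_channel_adjacency_links_or_splits(self):
        t_map = np.zeros((3, 1, 1))
        t_map[0, 0, 0] = t_map[1, 0, 0] = 4.0
        freqs, times = np.array([4.0]), np.array([0.0])
        linked = self._graph(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=bool))
        out = ek.form_clusters(t_map, 10, 0.05, linked, freqs, times)
        assert len(out) == 1 and out[0].mass == pytest.approx(8.0)
        split = self._graph(np.zeros((3, 3), dtype=bool))
        out = ek.form_clusters(t_map, 10, 0.05, split, freqs, times)
        assert len(out) == 2

    def test_mass_recomputable_from_t_map(self, layout3):
        rng = np.random.default_rng(5)
        ng = ek.triangulation_neighbors(layout3)
        t_map = rng.normal(0, 2.0, (3, 4, 6))
        freqs = 4.0 + np.arange(4.0)
        times = 0.01 * np.arange(6)
        for c in ek.form_clusters(t_map, 12, 0.05, ng, freqs, times):
            total = t_map[c.channels, c.freq_idx, c.time_idx].sum()
            assert c.mass == pytest.approx(total)
            assert (np.sign(t_map[c.channels, c.freq_idx, c.time_idx]) == c.sign).all()


class TestPermutationTest:
    freqs = np.array([4.0, 5.0, 6.0])
    times = 0.01 * np.arange(4)

    def _groups(self, layout3, shift, seed=0, n=4):
        rng = np.random.default_rng(seed)
        ga = [make_diff(rng, layout3, self.freqs, self.times, f"a{i}", "A", shift)
              for i in range(n)]
        gb = [make_diff(rng, layout3, self.freqs, self.times, f"b{i}", "B")
              for i in range(n)]
        return ga, gb

    def test_monte_carlo_matches_bruteforce_oracle(self, layout3):
        """4v4 subjects: MC p within 3 binomial SE of exhaustive enumeration
        over all 70 splits, computed by an independent implementation."""
        ng = ek.triangulation_neighbors(layout3)
        ga, gb = self._groups(layout3, shift=1.3, seed=1)
        res = ek.permutation_test(ga, gb, ng, n_perm=2000, seed=11)
        assert res.clusters, "fixture must produce at least one cluster"
        xa = np.stack([d.data for d in ga])
        xb = np.stack([d.data for d in gb])
        null = oracle_max_masses(xa, xb, res.threshold, ng.adjacency)
        for c in res.clusters:
            p_exact = (null >= abs(c.mass) - 1e-9).mean()
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / 2000)
            assert abs(c.p_value - p_exact) < 3 * se + 1.5 / 2001

    def test_exact_mode_matches_oracle_exactly(self, layout3):
        ng = ek.triangulation_neighbors(layout3)
        ga, gb = self._groups(layout3, shift=1.5, seed=2)
        res = ek.permutation_test(ga, gb, ng, method="exact")
        assert res.n_perm == 70
        xa = np.stack([d.data for d in ga])
        xb = np.stack([d.data for d in gb])
        null = oracle_max_masses(xa, xb, res.threshold, ng.adjacency)
        for c in res.clusters:
            p_exact = (null >= abs(c.mass) - 1e-9).mean()
            assert c.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_group_relabel_invariance(self, layout3):
        ng = ek.triangulation_neighbors(layout3)
        ga, gb = self._groups(layout3, shift=1.0, seed=3)
        r1 = ek.permutation_test(ga, gb, ng, method="exact")
        r2 = ek.permutation_test(gb, ga, ng, method="exact")
        p1 = sorted(c.p_value for c in r1.clusters)
        p2 = sorted(c.p_value for c in r2.clusters)
        np.testing.assert_allclose(p1, p2)
        m1 = sorted(c.mass for c in r1.clusters)
        m2 = sorted(-c.mass for c in r2.clusters)
        np.testing.assert_allclose(m1, m2)

    def test_band_restriction_applied(self, layout3):
        ng = ek.triangulation_neighbors(layout3)
        rng = np.random.default_rng(6)
        freqs = np.array([4.0, 5.0, 9.0, 10.0])
        ga = [make_diff(rng, layout3, freqs, self.times, f"a{i}", "A", 2.0)
              for i in range(4)]
        gb = [make_diff(rng, layout3, freqs, self.times, f"b{i}", "B")
              for i in range(4)]
        res = ek.permutation_test(ga, gb, ng, band=ek.BandSpec("theta", 4, 8),
                                  n_perm=50, seed=0)
        np.testing.assert_array_equal(res.freqs, [4.0, 5.0])

    def test_p_never_zero_and_in_unit_interval(self, layout3):
        ng = ek.triangulation_neighbors(layout3)
        ga, gb = self._groups(layout3, shift=3.0, seed=7)
        res = ek.permutation_test(ga, gb, ng, n_perm=100, seed=1)
        for c in res.clusters:
            assert 0.0 < c.p_value <= 1.0

    def test_too_few_subjects_rejected(self, layout3):
        ng = ek.triangulation_neighbors(layout3)
        ga, gb = self._groups(layout3, shift=0.0, seed=8)
        with pytest.raises(ValueError):
            ek.permutation_test(ga[:1], gb, ng, n_perm=10, seed=0)
        with pytest.raises(ValueError):
            ek.permutation_test(ga, gb, ng, n_perm=0, seed=0)


class TestClusterMeanExtract:
    def test_single_point_and_constant_field(self, layout3):
        rng = np.random.default_rng(9)
        freqs = np.array([4.0, 5.0])
        times = np.array([0.0, 0.01])
        d = make_diff(rng, layout3, freqs, times)
        cl = ek.Cluster(channels=np.array([1]), freq_idx=np.array([0]),
                        time_idx=np.array([1]), mass=3.0, sign=1,
                        ch_names=tuple(layout3.channel_names),
                        freqs=freqs[[0]], times=times[[1]])
        assert ek.cluster_mean_extract(d, cl) == pytest.approx(d.data[1, 0, 1])
        const = make_diff(rng, layout3, freqs, times)
        const.data[:] = 0.7
        assert ek.cluster_mean_extract(const, cl) == pytest.approx(0.7)

    def test_extraction_matches_on_band_selected_grid(self, layout3):
        """A cluster found on theta-selected data extracts correctly from the
        full-grid subject matrix (value-based alignment)."""
        rng = np.random.default_rng(10)
        full_freqs = np.array([3.0, 4.0, 5.0, 6.0])
        times = np.array([0.0, 0.01, 0.02])
        d = make_diff(rng, layout3, full_freqs, times)
        cl = ek.Cluster(channels=np.array([0, 2]), freq_idx=np.array([0, 1]),
                        time_idx=np.array([2, 0]), mass=0.0, sign=1,
                        ch_names=tuple(layout3.channel_names),
                        freqs=np.array([4.0, 5.0]), times=times[[2, 0]])
        expect = 0.5 * (d.data[0, 1, 2] + d.data[2, 2, 0])
        assert ek.cluster_mean_extract(d, cl) == pytest.approx(expect)

    def test_empty_cluster_rejected(self, layout3):
        rng = np.random.default_rng(11)
        d = make_diff(rng, layout3, np.array([4.0]), np.array([0.0]))
        cl = ek.Cluster(channels=np.array([], dtype=int),
                        freq_idx=np.array([], dtype=int),
                        time_idx=np.array([], dtype=int), mass=0.0, sign=1,
                        ch_names=tuple(layout3.channel_names),
                        freqs=np.array([]), times=np.array([]))
        with pytest.raises(ValueError):
            ek.cluster_mean_extract(d, cl)


def test_lattice_adjacency_matches_naive_neighborhood(layout3):
    """Sparse lattice adjacency agrees with the literal neighbor definition."""
    ng = ek.triangulation_neighbors(layout3)
    n_f, n_t = 3, 4
    lat = _lattice_adjacency(ng.adjacency, n_f, n_t).toarray()
    n_ch = 3

    def flat(c, f, t):
        return (c * n_f + f) * n_t + t

    for c1 in range(n_ch):
        for f1 in range(n_f):
            for t1 in range(n_t):
                for c2 in range(n_ch):
                    for f2 in range(n_f):
                        for t2 in range(n_t):
                            spatial = ng.adjacency[c1, c2] and f1 == f2 and t1 == t2
                            spectral = c1 == c2 and abs(f1 - f2) == 1 and t1 == t2
                            temporal = c1 == c2 and f1 == f2 and abs(t1 - t2) == 1
                            expect = bool(spatial or spectral or temporal)
                            assert bool(lat[flat(c1, f1, t1), flat(c2, f2, t2)]) == expect
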