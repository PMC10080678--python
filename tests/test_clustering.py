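"""Correlation-distance hierarchical clustering and its UPGMA oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from formose_dyn.clustering import (
    ClusteringError,
    DistanceMatrix,
    average_linkage,
    correlation_distance,
    cut_clusters,
    pairwise_distances,
)
from formose_dyn.crn_sim import TraceSet


def brute_force_upgma(d: np.ndarray):
    """Independent UPGMA: inter-cluster distance recomputed each step as the
    arithmetic mean of the *original* pairwise distances over all member
    pairs (no recursive update); ties broken by lowest (a, b) cluster ids
    in creation order.  Returns merge rows (a, b, d/2 height, size)."""
    n = d.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(members) > 1:
        best = None
        for a, b in itertools.combinations(sorted(members), 2):
            dist = np.mean([d[i, j] for i in members[a] for j in members[b]])
            key = (dist, a, b)
            if best is None or key < best:
                best = key
        dist, a, b = best
        members[next_id] = members.pop(a) + members.pop(b)
        merges.append((a, b, dist / 2.0, len(members[next_id])))
        next_id += 1
    return np.array(merges)


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        u = np.array([1.0, 2.0, 5.0, 3.0])
        assert correlation_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation_two(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlation_distance(u, -u + 10) == pytest.approx(2.0)

    def test_worked_example(self):
        # centred dot product 4.0 over norms sqrt(5)*sqrt(5) -> 1 - 0.8
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, 3.0, 2.0, 4.0])
        assert correlation_distance(u, v) == pytest.approx(0.2)

    def test_constant_trace_is_an_error(self):
        with pytest.raises(ClusteringError, match="constant"):
            correlation_distance(np.ones(5), np.arange(5.0))

    def test_length_validation(self):
        with pytest.raises(ClusteringError):
            correlation_distance(np.arange(2.0), np.arange(2.0))


class TestPairwiseDistances:
    def _ts(self, x):
        x = np.asarray(x, dtype=float)
        return TraceSet(np.arange(x.shape[1], dtype=float), x,
                        [f"c{i}" for i in range(x.shape[0])])

    def test_identical_traces(self):
        ts = self._ts([[1, 2, 3, 1], [1, 2, 3, 1]])
        dm = pairwise_distances(ts)
        np.testing.assert_allclose(dm.d, 0.0, atol=1e-12)

    def test_two_equal_one_anticorrelated(self):
        base = [1.0, 2.0, 3.0, 4.0]
        ts = self._ts([base, base, [10 - x for x in base]])
        dm = pairwise_distances(ts)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dm.d[0, 2] == pytest.approx(2.0)
        assert dm.d[1, 2] == pytest.approx(2.0)

    def test_matches_double_loop_and_scipy(self, rng):
        x = rng.normal(size=(5, 50)) + 10.0
        ts = self._ts(x)
        dm = pairwise_distances(ts)
        # brute-force double loop over the scalar definition
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert dm.d[i, j] == pytest.approx(
                        correlation_distance(x[i], x[j]), abs=1e-12)
        np.testing.assert_allclose(squareform(dm.d),
                                   pdist(x, metric="correlation"), atol=1e-10)

    def test_constant_trace_reported_by_id(self):
        ts = self._ts([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ClusteringError, match="c0"):
            pairwise_distances(ts)


class TestAverageLinkage:
    def test_two_leaves_merge_at_half_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        dend = average_linkage(dm)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.2)

    def test_three_leaf_hand_run(self):
        d = np.array([[0.0, 0.1, 0.5],
                      [0.1, 0.0, 0.5],
                      [0.5, 0.5, 0.0]])
        dend = average_linkage(DistanceMatrix(list("abc"), d))
        # (a, b) merge at 0.05; proportional average to c stays 0.5 -> 0.25
        np.testing.assert_allclose(dend.merges[:, 2], [0.05, 0.25])
        assert tuple(dend.merges[0, :2]) == (0, 1)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_equivalence_with_brute_force_oracle(self, n, rng):
        for _ in range(20):
            d = squareform(rng.uniform(0.05, 2.0, size=n * (n - 1) // 2))
            dend = average_linkage(DistanceMatrix([str(i) for i in range(n)], d))
            oracle = brute_force_upgma(d)
            np.testing.assert_array_equal(dend.merges[:, :2], oracle[:, :2])
            np.testing.assert_allclose(dend.merges[:, 2], oracle[:, 2],
                                       atol=1e-12)
            np.testing.assert_array_equal(dend.merges[:, 3], oracle[:, 3])

    def test_heights_agree_with_scipy_average_linkage(self, rng):
        # scipy records full cophenetic heights; ours are d/2 by convention
        n = 12
        d = squareform(rng.uniform(0.05, 2.0, size=n * (n - 1) // 2))
        dend = average_linkage(DistanceMatrix([str(i) for i in range(n)], d))
        z = sch.linkage(squareform(d), method="average")
        np.testing.assert_allclose(2.0 * dend.merges[:, 2], z[:, 2], atol=1e-10)
        for k in (2, 3, 5):
            ours = cut_clusters(dend, k=k).labels_for([str(i) for i in range(n)])
            theirs = sch.fcluster(z, t=k, criterion="maxclust")
            # partitions agree up to label permutation
            assert len({(a, b) for a, b in zip(ours, theirs)}) == k

    def test_tie_break_by_lowest_creation_index(self):
        # three pairs tied at 0.2: (0,1) must merge first
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        for i, j in ((0, 1), (0, 2), (2, 3)):
            d[i, j] = d[j, i] = 0.2
        dend = average_linkage(DistanceMatrix(list("abcd"), d))
        assert tuple(dend.merges[0, :2]) == (0, 1)


class TestCutClusters:
    def _dend(self, rng, n=6):
        d = squareform(rng.uniform(0.1, 1.9, size=n * (n - 1) // 2))
        return average_linkage(DistanceMatrix([f"c{i}" for i in range(n)], d))

    def test_k_equals_n_gives_singletons(self, rng):
        dend = self._dend(rng)
        cut = cut_clusters(dend, k=6)
        assert len(set(cut.assignment.values())) == 6

    def test_k_equals_one_gives_single_cluster(self, rng):
        dend = self._dend(rng)
        cut = cut_clusters(dend, k=1)
        assert set(cut.assignment.values()) == {1}

    def test_height_cut_matches_k_cut(self, rng):
        dend = self._dend(rng)
        heights = dend.merges[:, 2]
        h = (heights[2] + heights[3]) / 2  # between the 3rd and 4th merge
        by_height = cut_clusters(dend, height=h)
        by_k = cut_clusters(dend, k=dend.n_leaves - 3)
        assert by_height.assignment == by_k.assignment

    def test_parameter_validation(self, rng):
        dend = self._dend(rng)
        with pytest.raises(ClusteringError):
            cut_clusters(dend, k=0)
        with pytest.raises(ClusteringError):
            cut_clusters(dend)
        with pytest.raises(ClusteringError):
            cut_clusters(dend, k=2, height=0.5)

    def test_label_permutation_invariance(self, rng):
        x = rng.normal(size=(6, 40)) + 10.0
        ids = [f"c{i}" for i in range(6)]
        ts = TraceSet(np.arange(40.0), x, ids)
        perm = rng.permutation(6)
        ts_p = TraceSet(np.arange(40.0), x[perm], [ids[i] for i in perm])
        a = cut_clusters(average_linkage(pairwise_distances(ts)), k=3)
        b = cut_clusters(average_linkage(pairwise_distances(ts_p)), k=3)
        # same partition of compound ids, possibly different cluster numbers
        part_a = {frozenset(k for k, v in a.assignment.items() if v == c)
                  for c in set(a.assignment.values())}
        part_b = {frozenset(k for k, v in b.assignment.items() if v == c)
                  for c in set(b.assignment.values())}
        assert part_a == part_b


def test_recovers_planted_modules(default_model, exp013_run):
    """k=5 cut of one EXP013 run recovers the generator's module labels."""
    from sklearn.metrics import adjusted_rand_score

    _, sampled = exp013_run
    dend = average_linkage(pairwise_distances(sampled))
    cut = cut_clusters(dend, k=5)
    truth = [default_model.module_of[c] for c in sampled.compound_ids]
    pred = [cut.assignment[c] for c in sampled.compound_ids]
    assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)


@given(st.integers(0, 10_000))
def test_distance_bounds_property(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(4, 20)) + 10.0
    ts = TraceSet(np.arange(20.0), x, [f"c{i}" for i in range(4)])
    dm = pairwise_distances(ts)
    assert np.all(dm.d >= 0.0) and np.all(dm.d <= 2.0)
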