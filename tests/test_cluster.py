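import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from nomtrait.cluster import (
    LINKAGES,
    Partition,
    cut_tree,
    hierarchical_cluster,
    pam,
)
from nomtrait.distances import DissimilarityMatrix
from nomtrait.evaluate import adjusted_rand

from oracles import naive_agglomerate, pam_brute_force, pam_total_cost


def dmat(values, ids=None) -> DissimilarityMatrix:
    values = np.asarray(values, dtype=float)
    ids = ids if ids is not None else list(range(values.shape[0]))
    return DissimilarityMatrix(values, ids, "test")


def random_dissimilarity(rng: np.random.Generator, n: int) -> DissimilarityMatrix:
    a = rng.random((n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return dmat(d)


class TestHierarchical:
    def test_three_point_example_all_linkages(self):
        # d(1,2)=0.1, d(1,3)=0.9, d(2,3)=0.8: first merge (1,2) at 0.1,
        # second at min/max/mean of {0.9, 0.8}
        d = dmat([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        expected_second = {"single": 0.8, "complete": 0.9, "average": 0.85}
        for link, h2 in expected_second.items():
            dg = hierarchical_cluster(d, link)
            assert dg.merges[0, :2].tolist() == [0, 1]
            assert dg.merges[0, 2] == pytest.approx(0.1)
            assert dg.merges[1, 2] == pytest.approx(h2)

    def test_equal_distances_same_heights_everywhere(self):
        n = 5
        d = np.full((n, n), 0.4)
        np.fill_diagonal(d, 0.0)
        heights = {
            link: hierarchical_cluster(dmat(d), link).heights.tolist()
            for link in LINKAGES
        }
        assert heights["complete"] == pytest.approx(heights["single"])
        assert heights["average"] == pytest.approx(heights["single"])
        assert all(h == pytest.approx(0.4) for h in heights["single"])

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_matches_naive_cross_pair_oracle(self, linkage):
        # 100 random instances per linkage, n <= 10: identical merge tables
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 11))
            d = random_dissimilarity(rng, n)
            dg = hierarchical_cluster(d, linkage)
            oracle = naive_agglomerate(d.values, linkage)
            assert np.allclose(dg.merges, oracle)

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_agrees_with_scipy_on_tie_free_input(self, linkage):
        # continuous random distances are tie-free, so partitions must agree
        # with the independent scipy implementation at every k
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(5, 12))
            d = random_dissimilarity(rng, n)
            dg = hierarchical_cluster(d, linkage)
            Z = scipy_linkage(squareform(d.values), method=linkage)
            assert np.allclose(np.sort(dg.heights), np.sort(Z[:, 2]))
            for k in range(2, n):
                ours = cut_tree(dg, k)
                theirs = Partition(d.ids, fcluster(Z, k, criterion="maxclust"))
                assert adjusted_rand(ours, theirs) == pytest.approx(1.0)

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_heights_non_decreasing(self, linkage):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            d = random_dissimilarity(rng, 12)
            h = hierarchical_cluster(d, linkage).heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_unknown_linkage(self):
        d = random_dissimilarity(np.random.default_rng(0), 4)
        with pytest.raises(ValueError, match="unknown linkage"):
            hierarchical_cluster(d, "ward")


class TestCutTree:
    def test_extreme_cuts(self):
        d = random_dissimilarity(np.random.default_rng(3), 6)
        dg = hierarchical_cluster(d, "average")
        assert cut_tree(dg, 1).k == 1
        p = cut_tree(dg, 6)
        assert p.k == 6 and sorted(p.labels) == list(range(1, 7))
        with pytest.raises(ValueError):
            cut_tree(dg, 0)
        with pytest.raises(ValueError):
            cut_tree(dg, 7)

    def test_cuts_are_nested(self):
        # the k-cluster partition refines the (k-1)-cluster partition
        for seed in range(20):
            d = random_dissimilarity(np.random.default_rng(seed), 10)
            dg = hierarchical_cluster(d, "complete")
            for k in range(2, 10):
                coarse = cut_tree(dg, k - 1).labels
                fine = cut_tree(dg, k).labels
                # every fine cluster sits inside exactly one coarse cluster
                for g in np.unique(fine):
                    assert len(np.unique(coarse[fine == g])) == 1

    def test_newick_export_parses(self):
        d = random_dissimilarity(np.random.default_rng(5), 7)
        dg = hierarchical_cluster(d, "average")
        nwk = dg.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 6


class TestPam:
    def test_two_separated_blobs(self):
        # two blocks of identical rows: cost 0, one medoid per blob
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        p = pam(dmat(d), 2)
        assert p.k == 2
        assert len(set(p.labels[:3])) == 1 and len(set(p.labels[3:])) == 1
        assert p.labels[0] != p.labels[3]

    def test_k_n_minus_one_isolates_closest_pair(self):
        # the brute-force optimum isolates the closest pair as the only
        # size-2 cluster; SWAP must reach it here
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 8))
            d = random_dissimilarity(rng, n)
            p = pam(d, n - 1)
            sizes = np.bincount(p.labels)[1:]
            assert sorted(sizes) == [1] * (n - 2) + [2]
            _, best_cost = pam_brute_force(d.values, n - 1)
            iu = np.triu_indices(n, 1)
            assert best_cost == pytest.approx(d.values[iu].min())
            assert pam_total_cost(d.values, p.medoids) == pytest.approx(best_cost)
            # the pair kept together is exactly the closest pair
            g2 = int(np.argmax(sizes)) + 1
            i, j = np.where(p.labels == g2)[0]
            assert d.values[i, j] == pytest.approx(d.values[iu].min())

    def test_swap_local_optimality(self):
        # no single medoid exchange improves the returned medoid set
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            d = random_dissimilarity(rng, 7)
            p = pam(d, 3)
            meds = list(p.medoids)
            base = pam_total_cost(d.values, meds)
            for mi in range(3):
                for h in range(7):
                    if h in meds:
                        continue
                    trial = list(meds)
                    trial[mi] = h
                    assert pam_total_cost(d.values, trial) >= base - 1e-9

    def test_near_global_on_tiny_instances(self):
        # BUILD+SWAP is a local search; on tiny instances its cost should be
        # the global optimum in the large majority of cases and never wildly
        # off; labels must be the nearest-medoid assignment of its medoids
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(200 + seed)
            n = int(rng.integers(5, 8))
            k = int(rng.integers(2, min(4, n - 1) + 1))
            d = random_dissimilarity(rng, n)
            p = pam(d, k)
            cost = pam_total_cost(d.values, p.medoids)
            _, best = pam_brute_force(d.values, k)
            assert cost >= best - 1e-12
            hits += cost <= best + 1e-9
            lab_idx = np.argmin(d.values[:, p.medoids], axis=1)
            for jm, mm in enumerate(p.medoids):
                lab_idx[mm] = jm
            # nearest-medoid assignment reproduces the returned clusters
            for g in range(k):
                members = np.where(lab_idx == g)[0]
                assert len(np.unique(p.labels[members])) == 1
        assert hits >= 24  # local = global in >= 80% of these instances

    def test_k_validation(self):
        d = random_dissimilarity(np.random.default_rng(1), 5)
        with pytest.raises(ValueError):
            pam(d, 1)
        with pytest.raises(ValueError):
            pam(d, 5)

    def test_deterministic(self):
        d = random_dissimilarity(np.random.default_rng(9), 15)
        a = pam(d, 4)
        b = pam(d, 4)
        assert np.array_equal(a.labels, b.labels)
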