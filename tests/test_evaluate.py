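import math

import numpy as np
import pytest

from nomtrait.cluster import Partition, cut_tree, hierarchical_cluster
from nomtrait.distances import dissimilarity
from nomtrait.evaluate import (
    adjusted_rand,
    delta_wce,
    evaluate_cuts,
    gini_indices,
    gini_within,
    pseudo_f_from_within,
    psfe,
    select_k,
    wce,
)
from nomtrait.synthetic import SyntheticSpec, generate

from conftest import make_tm, random_tm
from oracles import ari_pair_counting, wce_direct

LN2 = math.log(2)


def parts(ids):
    def _p(labels):
        return Partition(list(ids), np.asarray(labels))

    return _p


class TestWce:
    def test_worked_example(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        assert wce(worked_matrix, p([1, 1, 1, 1])) == pytest.approx(1.5 * LN2)
        assert wce(worked_matrix, p([1, 1, 2, 2])) == pytest.approx(0.5 * LN2)

    def test_single_valued_clusters_score_zero(self):
        tm = make_tm({"t1": ["A", "A", "B", "B"], "t2": ["x", "x", "y", "y"]})
        p = parts(tm.species_ids)
        assert wce(tm, p([1, 1, 2, 2])) == 0.0

    def test_all_singletons_score_zero(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        assert wce(worked_matrix, p([1, 2, 3, 4])) == 0.0

    def test_matches_direct_oracle_on_random_data(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            tm = random_tm(rng, n=12, m=4)
            labels = rng.integers(1, 4, size=12)
            labels[:3] = [1, 2, 3]  # all clusters nonempty
            p = Partition(tm.species_ids, labels)
            assert wce(tm, p) == pytest.approx(wce_direct(tm.codes(), labels))

    def test_refinement_never_increases_wce(self):
        # splitting any cluster cannot raise the entropy-based variability
        for seed in range(25):
            rng = np.random.default_rng(seed)
            tm = random_tm(rng, n=14, m=3)
            labels = rng.integers(1, 4, size=14)
            labels[:3] = [1, 2, 3]
            before = wce(tm, Partition(tm.species_ids, labels))
            # split cluster 1 arbitrarily in two
            idx = np.where(labels == 1)[0]
            if len(idx) < 2:
                continue
            split = labels.copy()
            split[idx[: len(idx) // 2]] = labels.max() + 1
            relab = np.unique(split, return_inverse=True)[1] + 1
            after = wce(tm, Partition(tm.species_ids, relab))
            assert after <= before + 1e-12

    def test_id_mismatch_rejected(self, worked_matrix):
        p = Partition(["a", "b", "c", "d"], np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError, match="ids"):
            wce(worked_matrix, p)


class TestPsfe:
    def test_worked_example_is_exactly_four(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        cuts = {1: p([1, 1, 1, 1]), 2: p([1, 1, 2, 2])}
        assert psfe(worked_matrix, cuts)[2] == pytest.approx(4.0)

    def test_no_structure_gives_zero(self):
        # WCE(2) = WCE(1): the between-cluster numerator vanishes
        assert pseudo_f_from_within(0.7, 0.7, 10, 2) == 0.0

    def test_perfect_clusters_rank_above_finite(self):
        assert pseudo_f_from_within(0.7, 0.0, 10, 2) == math.inf

    def test_no_variability_is_undefined(self):
        assert math.isnan(pseudo_f_from_within(0.0, 0.0, 10, 2))

    def test_k1_baseline_derived_when_absent(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        out = psfe(worked_matrix, {2: p([1, 1, 2, 2])})
        assert out[2] == pytest.approx(4.0)


class TestGini:
    def test_worked_example_impurity(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        g1 = gini_within(worked_matrix, p([1, 1, 1, 1]))
        assert g1 == pytest.approx(0.625)  # 1 - (0.25 + 0.0625 + 0.0625)

    def test_single_valued_clusters_zero(self):
        tm = make_tm({"t": ["A", "A", "B", "B"]})
        p = parts(tm.species_ids)
        assert gini_within(tm, p([1, 1, 2, 2])) == 0.0

    def test_same_ordering_as_entropy_on_worked_example(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        w1, w2 = (wce(worked_matrix, p([1, 1, 1, 1])),
                  wce(worked_matrix, p([1, 1, 2, 2])))
        g1, g2 = (gini_within(worked_matrix, p([1, 1, 1, 1])),
                  gini_within(worked_matrix, p([1, 1, 2, 2])))
        assert (w1 > w2) and (g1 > g2)

    def test_gini_pseudo_f_reported(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        gw, gpf = gini_indices(worked_matrix, p([1, 1, 2, 2]))
        assert gw == pytest.approx(0.25)  # cluster {B,C}: 0.5 impurity, half weight
        assert gpf == pytest.approx((4 - 2) * (0.625 - 0.25) / (1 * 0.25))


class TestDeltaWce:
    def test_worked_example_difference(self, worked_matrix):
        p = parts(worked_matrix.species_ids)
        w = {1: wce(worked_matrix, p([1, 1, 1, 1])),
             2: wce(worked_matrix, p([1, 1, 2, 2]))}
        assert delta_wce(w)[2] == pytest.approx(LN2)

    def test_identical_rows_no_improvement(self):
        tm = make_tm({"t": ["A"] * 6}, {"t": ["A", "B"]})
        d = dissimilarity(tm, "sm")
        dg = hierarchical_cluster(d, "average")
        w = {k: wce(tm, cut_tree(dg, k)) for k in (1, 2, 3)}
        dw = delta_wce(w)
        assert dw[2] == 0.0 and dw[3] == 0.0

    def test_nested_cuts_never_negative(self):
        rng = np.random.default_rng(4)
        tm = random_tm(rng, n=15, m=4)
        dg = hierarchical_cluster(dissimilarity(tm, "sm"), "complete")
        w = {k: wce(tm, cut_tree(dg, k)) for k in range(1, 8)}
        assert all(v >= -1e-12 for v in delta_wce(w).values())

    def test_non_consecutive_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            delta_wce({1: 0.5, 3: 0.2})


class TestSelectK:
    def test_argmax_with_smallest_k_tie_break(self):
        assert select_k({2: 1.0, 3: 5.0, 4: 5.0}) == 3
        assert select_k({2: 3.0, 3: 2.0, 4: 1.0}) == 2

    def test_inf_outranks_finite(self):
        assert select_k({2: 10.0, 3: math.inf, 4: 2.0}) == 3

    def test_nan_excluded_and_all_nan_rejected(self):
        assert select_k({2: math.nan, 3: 1.0}) == 3
        with pytest.raises(ValueError):
            select_k({2: math.nan})

    def test_recovers_planted_k_on_synthetic_fixture(self):
        tm, _ = generate(SyntheticSpec(theta=0.9, seed=123))
        dg = hierarchical_cluster(dissimilarity(tm, "goodall"), "average")
        tab = evaluate_cuts(tm, dg, range(2, 11))
        assert int(tab.loc[tab["optimal"], "k"].iloc[0]) == 3


class TestAdjustedRand:
    def test_identical_partitions(self):
        p = Partition(list(range(6)), np.array([1, 1, 2, 2, 3, 3]))
        assert adjusted_rand(p, p) == pytest.approx(1.0)

    def test_label_permutation_and_symmetry(self):
        ids = list(range(8))
        a = Partition(ids, np.array([1, 1, 2, 2, 3, 3, 1, 2]))
        b = Partition(ids, np.array([3, 3, 1, 1, 2, 2, 3, 1]))  # relabeled a
        assert adjusted_rand(a, b) == pytest.approx(1.0)
        c = Partition(ids, np.array([1, 2, 1, 2, 1, 2, 1, 2]))
        assert adjusted_rand(a, c) == pytest.approx(adjusted_rand(c, a))

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 50
            ids = list(range(n))
            la = rng.integers(1, 5, size=n)
            lb = rng.integers(1, 4, size=n)
            la[:4] = [1, 2, 3, 4]
            lb[:3] = [1, 2, 3]
            a, b = Partition(ids, la), Partition(ids, lb)
            assert adjusted_rand(a, b) == pytest.approx(
                ari_pair_counting(la, lb), abs=1e-12
            )

    def test_independent_partitions_average_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(200):
            la = rng.integers(1, 4, size=30)
            lb = rng.integers(1, 4, size=30)
            la[:3] = [1, 2, 3]
            lb[:3] = [1, 2, 3]
            vals.append(ari_pair_counting(la, lb))
        assert abs(np.mean(vals)) < 0.02

    def test_aligns_by_id_and_rejects_mismatch(self):
        a = Partition(["x", "y", "z"], np.array([1, 1, 2]))
        b = Partition(["z", "x", "y"], np.array([2, 1, 1]))  # same partition, reordered
        assert adjusted_rand(a, b) == pytest.approx(1.0)
        c = Partition(["p", "q", "r"], np.array([1, 1, 2]))
        with pytest.raises(ValueError, match="different object"):
            adjusted_rand(a, c)


def test_evaluate_cuts_table_shape_and_flags():
    tm, _ = generate(SyntheticSpec(n_species=40, categories=[4] * 6,
                                   theta=0.85, seed=5))
    dg = hierarchical_cluster(dissimilarity(tm, "iof"), "complete")
    tab = evaluate_cuts(tm, dg, range(2, 8))
    assert list(tab["k"]) == list(range(2, 8))
    assert set(tab.columns) >= {"k", "wce", "psfe", "gini_w", "gini_psf",
                                "delta_wce", "optimal"}
    assert tab["optimal"].sum() == 1
    k_flag = int(tab.loc[tab["optimal"], "k"].iloc[0])
    finite = tab[np.isfinite(tab["psfe"])]
    assert k_flag == int(finite.loc[finite["psfe"].idxmax(), "k"])
    # WCE non-increasing in k along nested cuts
    assert np.all(np.diff(tab["wce"]) <= 1e-12)
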