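"""Null models, modularity, Louvain-style detection, and AMI."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_partition
from prominet import (
    Graph,
    Partition,
    ami,
    backtest,
    graph_snr,
    graph_to_connectome,
    maximize_q,
    modularity_q,
    null_snr,
    sample_fc,
    sample_sbm,
    shuffle_partition,
    planted_partition,
)


def two_cliques(size=5):
    n = 2 * size
    a = np.zeros((n, n))
    a[:size, :size] = 1
    a[size:, size:] = 1
    np.fill_diagonal(a, 0)
    return Graph("binary", a)


class TestShufflePartition:
    def test_sizes_preserved_any_seed(self, rng):
        part = random_partition(rng, 30, 4)
        for seed in range(5):
            np.testing.assert_array_equal(shuffle_partition(part, seed).omega, part.omega)

    def test_k1_partition_unchanged(self):
        part = Partition([1, 1, 1])
        np.testing.assert_array_equal(shuffle_partition(part, 9).sigma, part.sigma)

    def test_same_seed_reproducible(self, rng):
        part = random_partition(rng, 30, 4)
        np.testing.assert_array_equal(
            shuffle_partition(part, 42).sigma, shuffle_partition(part, 42).sigma
        )


class TestNullSNR:
    def test_planted_structure_beats_all_shuffles(self):
        w = np.full((4, 4), 0.02)
        np.fill_diagonal(w, 0.3)
        g, part = sample_sbm([40] * 4, w, seed=1)
        fc = graph_to_connectome(g)
        grid = np.array([0.0, 0.5])
        ens = null_snr(fc, part, grid, n_shuffles=30, seed=0, mode="binary")
        true_snr = graph_snr(g, part).snr
        assert 0.0 <= ens.min_snr
        assert ens.max_snr < true_snr
        assert ens.max_snr < 1.0

    def test_er_graph_null_and_true_both_small(self):
        w = np.full((2, 2), 0.2)
        g, part = sample_sbm([50, 50], w, seed=3)
        fc = graph_to_connectome(g)
        grid = np.array([0.0])
        ens = null_snr(fc, part, grid, n_shuffles=10, seed=0, mode="binary")
        assert ens.max_snr < 1.0
        assert graph_snr(g, part).snr < 1.0

    def test_single_shuffle_ensemble(self, toy_fc, toy_partition):
        ens = null_snr(toy_fc, toy_partition, np.array([0.0]), n_shuffles=1, seed=0)
        assert ens.n_shuffles == 1
        assert len(ens.snr_profiles) == 1


class TestModularity:
    def test_single_community_is_zero(self, rng):
        from conftest import random_connectome
        from prominet import threshold_binarize

        g = threshold_binarize(random_connectome(rng, 12), 0.5)
        assert modularity_q(g, Partition([1] * 12)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            a[i, j] = a[j, i] = 1
        q = modularity_q(Graph("binary", a), Partition([1, 1, 1, 2, 2, 2]))
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_singleton_partition_closed_form(self, rng):
        from conftest import random_connectome
        from prominet import threshold_binarize

        g = threshold_binarize(random_connectome(rng, 10), 0.4)
        deg = g.values.sum(axis=1)
        expected = -np.sum((deg / deg.sum()) ** 2)
        q = modularity_q(g, Partition(np.arange(1, 11)))
        assert q == pytest.approx(expected, abs=1e-12)

    def test_matches_networkx_binary_and_weighted(self, rng):
        from conftest import random_connectome
        from prominet import threshold_binarize, threshold_weighted

        fc = random_connectome(rng, 16)
        part = random_partition(rng, 16, 3)
        comms = [set(np.flatnonzero(part.sigma == i)) for i in range(1, part.k + 1)]
        for g in (threshold_binarize(fc, 0.3), threshold_weighted(fc, 0.3)):
            gx = nx.from_numpy_array(g.values)
            assert modularity_q(g, part) == pytest.approx(
                nx.community.modularity(gx, comms, weight="weight"), abs=1e-10
            )

    def test_invariant_to_node_reordering(self, rng):
        from conftest import random_connectome
        from prominet import threshold_binarize

        fc = random_connectome(rng, 14)
        part = random_partition(rng, 14, 3)
        g = threshold_binarize(fc, 0.3)
        perm = rng.permutation(14)
        g2 = Graph("binary", g.values[np.ix_(perm, perm)])
        part2 = Partition.from_labels(part.sigma[perm])
        assert modularity_q(g, part) == pytest.approx(modularity_q(g2, part2), abs=1e-12)

    def test_alpha_scales_null_term(self):
        g = two_cliques()
        part = Partition([1] * 5 + [2] * 5)
        q1 = modularity_q(g, part, alpha=1.0)
        q0 = modularity_q(g, part, alpha=0.0)
        assert q0 == pytest.approx(1.0)  # all weight within communities
        assert q1 < q0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="no edges"):
            modularity_q(Graph("binary", np.zeros((4, 4))), Partition([1, 1, 2, 2]))


class TestMaximizeQ:
    def test_recovers_two_cliques_exactly(self):
        g = two_cliques()
        part = maximize_q(g, seed=0)
        assert ami(part, Partition([1] * 5 + [2] * 5)) == pytest.approx(1.0)

    def test_never_below_trivial_baselines(self, rng):
        from conftest import random_connectome
        from prominet import threshold_binarize

        for seed in range(3):
            fc = random_connectome(np.random.default_rng(seed), 15)
            g = threshold_binarize(fc, 0.5)
            q = modularity_q(g, maximize_q(g, seed=seed))
            q_single = modularity_q(g, Partition([1] * 15))
            q_singletons = modularity_q(g, Partition(np.arange(1, 16)))
            assert q >= q_single - 1e-12
            assert q >= q_singletons - 1e-12

    def test_strong_planted_two_block_recovered(self):
        w = np.array([[0.3, 0.02], [0.02, 0.3]])
        g, part = sample_sbm([100, 100], w, seed=4)
        detected = maximize_q(g, seed=0)
        assert ami(detected, part) > 0.9


class TestAMI:
    def test_identical_and_relabeled_partitions_give_one(self):
        p = Partition([1, 1, 2, 2, 3, 3])
        assert ami(p, p) == pytest.approx(1.0)
        relabeled = Partition.from_labels([{1: "c", 2: "a", 3: "b"}[s] for s in p.sigma])
        assert ami(p, relabeled) == pytest.approx(1.0)

    def test_crossed_partition_nonpositive(self):
        # MI = 0 but the hypergeometric expectation E[MI] > 0
        assert ami(Partition([1, 1, 2, 2]), Partition([1, 2, 1, 2])) <= 0.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(10):
            p1 = random_partition(rng, 20, 3)
            p2 = random_partition(rng, 20, 4)
            v = ami(p1, p2)
            assert v == pytest.approx(ami(p2, p1), abs=1e-12)
            assert -1.0 < v <= 1.0

    def test_size_mismatch(self):
        with pytest.raises(ValueError, match="size mismatch"):
            ami(Partition([1, 2]), Partition([1, 2, 1]))

    def test_nmi_variant(self):
        p = Partition([1, 1, 2, 2])
        assert ami(p, p, method="nmi") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ami(p, p, method="bogus")


class TestBacktest:
    def test_two_clique_fc_hits_ami_one_at_zero(self):
        fc = graph_to_connectome(two_cliques())
        part = Partition([1] * 5 + [2] * 5)
        rows = backtest(fc, part, np.array([0.0, 0.5]), seed=0)
        assert rows[0]["ami_q"] == pytest.approx(1.0)

    def test_empty_graph_rows_are_nan(self):
        fc = sample_fc([6, 6], mu_within=0.3, mu_between=0.1, sd=0.0, seed=0)
        rows = backtest(fc, planted_partition([6, 6]), np.array([0.0, 0.9]), seed=0)
        assert np.isnan(rows[1]["q_score"]) and np.isnan(rows[1]["ami_q"])
        assert np.isfinite(rows[0]["q_score"])

    def test_snr_and_ami_peaks_concordant_on_planted_fc(self):
        fc = sample_fc([25] * 4, seed=7, label="GA-like")
        part = planted_partition([25] * 4)
        rows = backtest(fc, part, seed=0)
        taus = np.array([r["tau"] for r in rows])
        snrs = np.array([r["snr"] for r in rows])
        amis = np.array([r["ami_q"] for r in rows])
        snr_peak = taus[np.argmax(snrs)]
        ami_max = np.nanmax(amis)
        ami_peaks = taus[np.isclose(amis, ami_max)]
        assert np.min(np.abs(ami_peaks - snr_peak)) <= 0.10 + 1e-12
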