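"""Simulation protocol: topologies, branch lengths, site evolution, gaps."""

import numpy as np
import pytest
from scipy import stats

from phylonj import (GTRParams, apply_deletions, evolve_sequences, gap_ratio,
                     generate_dataset, gtr_rate_matrix, parse_newick,
                     sample_branch_lengths, sample_gtr_params, sample_topology)
from phylonj.simulate import dataset_size, sample_lambda
from phylonj.trees import rf_distance


class TestTopology:
    def test_three_taxa_always_the_star(self, rng):
        t = sample_topology(3, rng=rng)
        assert t.n_leaves == 3 and t.bipartitions() == frozenset()

    def test_rejects_fewer_than_three(self, rng):
        with pytest.raises(ValueError):
            sample_topology(2, rng=rng)

    @pytest.mark.parametrize("n", [4, 8, 15])
    def test_leaf_and_internal_counts(self, n, rng):
        t = sample_topology(n, rng=rng)
        assert t.n_leaves == n
        internal = sum(1 for nd in t.dendropy_tree.preorder_node_iter()
                       if not nd.is_leaf())
        assert internal == n - 2  # unrooted binary (trifurcating root)

    def test_quartet_topologies_uniform(self, rng):
        """The three unrooted quartet shapes appear with frequency ~1/3."""
        refs = [parse_newick(s) for s in
                ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]]
        counts = np.zeros(3)
        n_draws = 3000
        for _ in range(n_draws):
            t = sample_topology(4, labels=list("ABCD"), rng=rng)
            for k, ref in enumerate(refs):
                if rf_distance(t, ref)[0] == 0:
                    counts[k] += 1
                    break
        assert counts.sum() == n_draws
        assert stats.chisquare(counts).pvalue > 0.001


class TestBranchLengths:
    def test_exponential_mean(self, rng):
        lam = 5.0
        tree = sample_topology(30, rng=rng)
        draws = []
        for _ in range(200):
            t = sample_branch_lengths(tree, lam, rng)
            draws.extend(e.length for e in t.dendropy_tree.preorder_edge_iter()
                         if e.head_node.parent_node is not None)
        draws = np.array(draws)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 1 / lam) < 3 * se
        assert np.all(draws > 0)

    def test_lambda_always_in_range(self, rng):
        lams = [sample_lambda(rng) for _ in range(2000)]
        assert all(2.0 <= l <= 5.0 for l in lams)
        # log-uniform: log-lambda roughly uniform over [log 2, log 5]
        logs = np.log(lams)
        assert stats.kstest(logs, "uniform",
                            args=(np.log(2), np.log(5) - np.log(2))).pvalue > 0.001


class TestGTRParams:
    def test_sampled_params_are_valid(self, rng):
        for _ in range(200):
            p = sample_gtr_params(rng)
            assert p.base_freqs.sum() == pytest.approx(1.0, abs=1e-12)
            assert 0.2 <= p.gamma_shape <= 5.0
            assert 0.0 <= p.p_inv < 0.5
            Q = gtr_rate_matrix(p)
            np.testing.assert_allclose(Q.Q.sum(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(Q.pi @ Q.Q, 0.0, atol=1e-12)
            # reversibility: pi_i Q_ij == pi_j Q_ji
            flows = Q.pi[:, None] * Q.Q
            np.testing.assert_allclose(flows, flows.T, atol=1e-12)

    def test_jc_preset_is_jukes_cantor(self):
        Q = gtr_rate_matrix(GTRParams.jc())
        off = Q.Q[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 3, atol=1e-12)


class TestEvolution:
    def test_zero_branch_lengths_copy_root(self, rng):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        a = evolve_sequences(tree, GTRParams.jc(), 50, rng)
        assert len(set(a.sequences)) == 1

    def test_all_invariant_sites_give_constant_columns(self, rng):
        tree, _ = _tree_and_none(6, rng)
        params = GTRParams(np.ones(6), np.full(4, 0.25), gamma_shape=1.0,
                           p_inv=0.999999, n_categories=4)
        a = evolve_sequences(tree, params, 40, rng)
        cols = zip(*a.sequences)
        assert all(len(set(c)) == 1 for c in cols)

    def test_jc_pairwise_divergence_closed_form(self, rng):
        """2 taxa at total path t: P(diff) = (3/4)(1 - exp(-4t/3))."""
        t_total = 0.3
        tree = parse_newick(f"(A:{t_total / 2},B:{t_total / 2});")
        L = 100_000
        a = evolve_sequences(tree, GTRParams.jc(), L, rng)
        diff = np.mean([x != y for x, y in zip(*a.sequences)])
        expected = 0.75 * (1 - np.exp(-4 * t_total / 3))
        se = np.sqrt(expected * (1 - expected) / L)
        assert abs(diff - expected) < 3 * se

    def test_base_composition_converges_to_pi(self, rng):
        params = GTRParams(np.ones(6), np.array([0.4, 0.3, 0.2, 0.1]),
                           gamma_shape=np.inf, n_categories=1)
        tree = parse_newick("(A:0.05,B:0.05);")
        a = evolve_sequences(tree, params, 50_000, rng)
        counts = np.array([a.sequences[0].count(c) for c in "ACGT"]) / 50_000
        for obs, pi in zip(counts, params.base_freqs):
            se = np.sqrt(pi * (1 - pi) / 50_000)
            assert abs(obs - pi) < 4 * se


class TestDeletions:
    def test_rate_zero_is_identity(self, rng, small_instance):
        _, aln = small_instance
        assert apply_deletions(aln, 0.0, rng) is aln

    def test_gap_ratio_matches_nominal_rate(self, rng):
        tree, aln = _sim(20, 400, rng)
        ratios = [gap_ratio(apply_deletions(aln, 0.03, rng))
                  for _ in range(30)]
        assert np.mean(ratios) == pytest.approx(0.03, rel=0.25)

    def test_gap_ratio_monotone_in_rate(self, rng):
        _, aln = _sim(10, 300, rng)
        means = []
        for rate in (0.0, 0.01, 0.02, 0.03):
            means.append(np.mean([gap_ratio(apply_deletions(aln, rate, rng))
                                  for _ in range(40)]))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_extremes(self):
        from phylonj import Alignment
        a = Alignment(["x", "y"], ["AC-T", "ACGT"])
        assert gap_ratio(a) == pytest.approx(1 / 8)


class TestDataset:
    def test_training_and_test_design_sizes(self):
        train_manifest = [(50, L, 1000) for L in range(128, 1025, 32)]
        assert len(train_manifest) == 29
        assert dataset_size(train_manifest) == 29_000
        test_manifest = [(20, 1024, 128), (50, 1024, 128), (100, 1024, 128),
                         (100, 256, 128), (100, 512, 128)]
        assert dataset_size(test_manifest) == 640

    def test_same_seed_reproduces_exactly(self):
        a = list(generate_dataset([(6, 40, 3)], seed=5, model="jc"))
        b = list(generate_dataset([(6, 40, 3)], seed=5, model="jc"))
        for x, y in zip(a, b):
            assert x.alignment.sequences == y.alignment.sequences
            assert x.tree.to_newick() == y.tree.to_newick()

    def test_pairs_are_independent_of_order(self):
        """Counter-derived substreams: pair 2 is identical however many
        pairs precede it in the manifest."""
        long = list(generate_dataset([(6, 40, 3)], seed=5, model="jc"))
        assert long[2].meta["pair_id"] == 2
        short = list(generate_dataset([(6, 40, 3)], seed=5, model="jc"))[2]
        assert long[2].alignment.sequences == short.alignment.sequences

    def test_gap_ratio_stays_below_bound(self):
        for pair in generate_dataset([(10, 128, 5)], seed=3, model="gtr"):
            assert gap_ratio(pair.alignment) < 0.3


def _sim(n, L, rng):
    tree = sample_branch_lengths(sample_topology(n, rng=rng), 3.0, rng)
    return tree, evolve_sequences(tree, GTRParams.jc(), L, rng)


def _tree_and_none(n, rng):
    return sample_branch_lengths(sample_topology(n, rng=rng), 3.0, rng), None
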