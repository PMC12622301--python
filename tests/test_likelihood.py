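"""GTR+I+G transition probabilities and pruning likelihood.

The pruning implementation is checked against an exhaustive oracle that sums
the joint probability over all internal-node state assignments — feasible
only for tiny trees, which is exactly what makes it independent.
"""

import itertools

import numpy as np
import pytest

from phylonj import (Alignment, GTRParams, assign_branch_lengths,
                     evolve_sequences, felsenstein_loglik, gtr_rate_matrix,
                     parse_newick, sample_branch_lengths, sample_gtr_params,
                     sample_topology, transition_probs)
from phylonj.likelihood import site_rates
from phylonj.msa import encode_alignment


def exhaustive_loglik(tree, alignment, params):
    """Independent oracle: sum over all internal-state assignments per site,
    mixed over invariant/gamma-category rates."""
    Q = gtr_rate_matrix(params)
    pi = Q.pi
    rates = site_rates(params)
    codes = encode_alignment(alignment).codes
    row_of = {lab: i for i, lab in enumerate(alignment.labels)}
    dtree = tree.dendropy_tree
    nodes = list(dtree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]

    def site_lik_at_rate(site, rate):
        Ps = {id(n): transition_probs(Q, n.edge.length * rate)
              for n in nodes if n.parent_node is not None}
        total = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            p = pi[state[id(dtree.seed_node)]]
            for n in nodes:
                if n.parent_node is None:
                    continue
                ps = state[id(n.parent_node)]
                if n.is_leaf():
                    obs = codes[row_of[n.taxon.label], site]
                    if obs == 4:
                        p *= 1.0  # missing
                    else:
                        p *= Ps[id(n)][ps, obs]
                else:
                    p *= Ps[id(n)][ps, state[id(n)]]
            total += p
        return total

    def const_lik(site):
        col = codes[:, site]
        obs = col[col != 4]
        if obs.size == 0:
            return 1.0
        if np.all(obs == obs[0]):
            return pi[obs[0]]
        return 0.0

    total_log = 0.0
    for site in range(codes.shape[1]):
        var = np.mean([site_lik_at_rate(site, r) for r in rates])
        lik = params.p_inv * const_lik(site) + (1 - params.p_inv) * var
        if lik == 0:
            return -np.inf
        total_log += np.log(lik)
    return total_log


class TestRateMatrix:
    def test_jc_generator(self):
        Q = gtr_rate_matrix(GTRParams.jc())
        expected = np.full((4, 4), 1 / 3)
        np.fill_diagonal(expected, -1.0)
        np.testing.assert_allclose(Q.Q, expected, atol=1e-12)

    def test_identity_at_zero_time(self, rng):
        Q = gtr_rate_matrix(sample_gtr_params(rng))
        np.testing.assert_allclose(transition_probs(Q, 0.0), np.eye(4),
                                   atol=1e-12)

    def test_rows_are_distributions(self, rng):
        Q = gtr_rate_matrix(sample_gtr_params(rng))
        for t in (0.01, 0.5, 3.0):
            P = transition_probs(Q, t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= 0)

    def test_long_time_reaches_stationarity(self, rng):
        Q = gtr_rate_matrix(sample_gtr_params(rng))
        P = transition_probs(Q, 1000.0)
        np.testing.assert_allclose(P, np.tile(Q.pi, (4, 1)), atol=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probs(gtr_rate_matrix(GTRParams.jc()), -0.1)

    @pytest.mark.parametrize("t", [0.05, 0.3, 1.7])
    def test_jc_closed_form(self, t):
        P = transition_probs(gtr_rate_matrix(GTRParams.jc()), t)
        diag = 0.25 + 0.75 * np.exp(-4 * t / 3)
        np.testing.assert_allclose(np.diag(P), diag, atol=1e-12)


class TestPruning:
    def test_identical_zero_branch_pair(self):
        tree = parse_newick("(A:0,B:0);")
        aln = Alignment(["A", "B"], ["AAA", "AAA"])
        ll = felsenstein_loglik(tree, aln, GTRParams.jc())
        assert ll == pytest.approx(3 * np.log(0.25))

    def test_impossible_observation(self):
        tree = parse_newick("(A:0,B:0);")
        aln = Alignment(["A", "B"], ["A", "C"])
        assert felsenstein_loglik(tree, aln, GTRParams.jc()) == -np.inf

    def test_label_mismatch_error(self):
        tree = parse_newick("(A:1,B:1);")
        aln = Alignment(["A", "X"], ["AC", "GT"])
        with pytest.raises(ValueError, match="X"):
            felsenstein_loglik(tree, aln, GTRParams.jc())

    def test_gap_only_column_contributes_nothing(self, rng):
        tree = sample_branch_lengths(sample_topology(4, rng=rng), 2.0, rng)
        params = sample_gtr_params(rng)
        aln = evolve_sequences(tree, params, 6, rng)
        labels = aln.labels
        padded = Alignment(labels, [s + "-" for s in aln.sequences])
        l0 = felsenstein_loglik(tree, aln, params)
        l1 = felsenstein_loglik(tree, padded, params)
        assert l1 == pytest.approx(l0, abs=1e-9)

    @pytest.mark.parametrize("n_leaves,n_sites", [(3, 2), (4, 2), (5, 3)])
    def test_matches_exhaustive_oracle(self, n_leaves, n_sites, rng):
        for _ in range(5):
            tree = sample_branch_lengths(sample_topology(n_leaves, rng=rng),
                                         2.0, rng)
            params = sample_gtr_params(rng)
            aln = evolve_sequences(tree, params, n_sites, rng)
            ours = felsenstein_loglik(tree, aln, params)
            oracle = exhaustive_loglik(tree, aln, params)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_rerooting_invariance(self, rng):
        """Reversibility (pulley principle): the likelihood does not depend
        on where the traversal is rooted."""
        tree = sample_branch_lengths(sample_topology(7, rng=rng), 2.0, rng)
        params = sample_gtr_params(rng)
        aln = evolve_sequences(tree, params, 20, rng)
        base = felsenstein_loglik(tree, aln, params)
        rerooted = tree.copy()
        dt = rerooted.dendropy_tree
        target = [n for n in dt.preorder_node_iter()
                  if not n.is_leaf() and n.parent_node is not None][1]
        dt.reroot_at_node(target, update_bipartitions=False)
        assert felsenstein_loglik(rerooted, aln, params) == pytest.approx(
            base, abs=1e-8)


class TestBranchLengths:
    def test_fixed_mode_sets_default(self, small_instance):
        tree, aln = small_instance
        out = assign_branch_lengths(tree, aln, GTRParams.jc(), mode="fixed")
        lengths = [e.length for e in out.dendropy_tree.preorder_edge_iter()
                   if e.head_node.parent_node is not None]
        assert all(l == pytest.approx(0.1) for l in lengths)

    def test_optimize_improves_on_fixed(self, small_instance):
        tree, aln = small_instance
        params = GTRParams.jc()
        fixed = assign_branch_lengths(tree, aln, params, mode="fixed")
        opt = assign_branch_lengths(tree, aln, params, mode="optimize",
                                    max_sweeps=2)
        assert felsenstein_loglik(opt, aln, params) >= felsenstein_loglik(
            fixed, aln, params)

    def test_two_taxon_ml_recovers_distance(self, rng):
        true_t = 0.4
        tree = parse_newick(f"(A:{true_t / 2},B:{true_t / 2});")
        aln = evolve_sequences(tree, GTRParams.jc(), 10_000, rng)
        opt = assign_branch_lengths(tree, aln, GTRParams.jc(), mode="optimize")
        total = sum(e.length for e in opt.dendropy_tree.preorder_edge_iter()
                    if e.head_node.parent_node is not None)
        assert total == pytest.approx(true_t, rel=0.10)
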