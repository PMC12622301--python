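import numpy as np
import pytest

from phylonj import (EncoderConfig, GTRParams, NeuralJoinModel,
                     evolve_sequences, sample_branch_lengths, sample_topology)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def quartet_ab_cd():
    from phylonj import parse_newick
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def quartet_ac_bd():
    from phylonj import parse_newick
    return parse_newick("((A:1,C:1):1,(B:1,D:1):1);")


@pytest.fixture
def tiny_cfg():
    return EncoderConfig(d_model=16, n_layers=1, n_heads=2, hidden_mult=2,
                         max_len=64)


@pytest.fixture
def tiny_model(tiny_cfg):
    return NeuralJoinModel(tiny_cfg, seed=0)


def random_instance(n_taxa, L, seed, lam=3.0):
    """One simulated (tree, alignment) pair under Jukes-Cantor."""
    r = np.random.default_rng(seed)
    tree = sample_branch_lengths(sample_topology(n_taxa, rng=r), lam, r)
    aln = evolve_sequences(tree, GTRParams.jc(), L, r)
    return tree, aln


@pytest.fixture
def small_instance():
    return random_instance(8, 32, seed=11)
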