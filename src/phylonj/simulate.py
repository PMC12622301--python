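"""Synthetic tree–MSA generation: the training and evaluation backbone.

The protocol emulated here is: (i) uniform random labelled binary topologies,
built by inserting each new leaf on a uniformly chosen existing edge;
(ii) i.i.d. exponential branch lengths whose rate lambda is drawn
log-uniformly from [2, 5] (one lambda per tree); (iii) site evolution under
GTR+I+G with parameters sampled from broad documented priors; and
(iv) lineage-wise deletion events (geometric lengths, mean 3) producing gap
patterns whose overall ratio stays below 0.3 for the default rate grid
{0, 0.01, 0.02, 0.03}.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .likelihood import GTRParams, gtr_rate_matrix, site_rates, transition_probs
from .msa import ALPHABET, Alignment
from .trees import PhyloTree

__all__ = [
    "SimConfig",
    "SimulatedPair",
    "sample_topology",
    "sample_branch_lengths",
    "sample_lambda",
    "sample_gtr_params",
    "evolve_sequences",
    "apply_deletions",
    "gap_ratio",
    "generate_dataset",
    "simulate_pair",
]

DEFAULT_DELETION_GRID = (0.0, 0.01, 0.02, 0.03)
MEAN_DELETION_LENGTH = 3.0


@dataclass
class SimConfig:
    """Configuration of one simulation condition."""

    n_taxa: int = 50
    seq_length: int = 512
    lambda_range: tuple[float, float] = (2.0, 5.0)
    deletion_grid: Sequence[float] = DEFAULT_DELETION_GRID
    model: str = "gtr"  # "gtr" (sampled GTR+I+G) or "jc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.seq_length < 1:
            raise ValueError("sequence length must be positive")
        lo, hi = self.lambda_range
        if not (0 < lo <= hi):
            raise ValueError("lambda range must be positive and ordered")
        if any(not (0 <= r < 1) for r in self.deletion_grid):
            raise ValueError("deletion rates must lie in [0, 1)")


@dataclass
class SimulatedPair:
    tree: PhyloTree
    alignment: Alignment
    meta: dict = field(default_factory=dict)


def sample_topology(n_taxa: int, labels: Sequence[str] | None = None,
                    rng: np.random.Generator | None = None) -> PhyloTree:
    """Draw a uniform random unrooted binary topology on ``n_taxa`` leaves.

    Sequential construction: start from the unique 3-leaf star and insert each
    subsequent leaf on an edge chosen uniformly at random, which yields the
    uniform distribution over labelled binary topologies.
    """
    if n_taxa < 3:
        raise ValueError(f"need >= 3 taxa, got {n_taxa}")
    rng = rng or np.random.default_rng()
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("label count != n_taxa")

    # adjacency over integer node ids; 0..n_taxa-1 are leaves
    next_id = n_taxa
    center = next_id
    next_id += 1
    edges: list[tuple[int, int]] = [(0, center), (1, center), (2, center)]
    for leaf in range(3, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        mid = next_id
        next_id += 1
        edges.remove((u, v))
        edges.extend([(u, mid), (v, mid), (leaf, mid)])

    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def newick(node: int, parent: int) -> str:
        children = [w for w in adj[node] if w != parent]
        if not children:
            return labels[node]
        return "(" + ",".join(newick(c, node) for c in children) + ")"

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n_taxa + 100))
    try:
        text = newick(center, -1) + ";"
    finally:
        sys.setrecursionlimit(old)
    return PhyloTree.from_newick(text)


def sample_branch_lengths(tree: PhyloTree, lam: float,
                          rng: np.random.Generator | None = None) -> PhyloTree:
    """Assign i.i.d. Exponential(lam) lengths (mean 1/lam) to every branch."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = rng or np.random.default_rng()
    out = tree.copy()
    for edge in out.dendropy_tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.exponential(1.0 / lam))
    return out


def sample_lambda(rng: np.random.Generator,
                  lambda_range: tuple[float, float] = (2.0, 5.0)) -> float:
    """Draw the per-tree branch-length rate log-uniformly from the range."""
    lo, hi = np.log(lambda_range[0]), np.log(lambda_range[1])
    return float(np.exp(rng.uniform(lo, hi)))


def sample_gtr_params(rng: np.random.Generator | None = None) -> GTRParams:
    """Sample GTR+I+G parameters from broad priors.

    pi ~ Dirichlet(5,5,5,5); exchangeabilities log-uniform on [0.1, 10] with
    r_GT fixed to 1; alpha ~ Uniform(0.2, 5); p_inv ~ Uniform(0, 0.5); four
    gamma categories.
    """
    rng = rng or np.random.default_rng()
    pi = rng.dirichlet(np.full(4, 5.0))
    r = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=6))
    r[5] = 1.0  # GT reference rate
    alpha = rng.uniform(0.2, 5.0)
    p_inv = rng.uniform(0.0, 0.5)
    return GTRParams(r, pi, gamma_shape=alpha, p_inv=p_inv, n_categories=4)


def evolve_sequences(tree: PhyloTree, params: GTRParams, L: int,
                     rng: np.random.Generator | None = None) -> Alignment:
    """Simulate site evolution along the tree; returns the leaf alignment.

    The root sequence is drawn from the stationary distribution; each site is
    invariant with probability p_inv, otherwise assigned a discrete gamma rate
    category; child states are drawn from exp(Q * r_c * t) along each branch.
    """
    if L < 1:
        raise ValueError("L must be positive")
    if not tree.has_branch_lengths():
        raise ValueError("tree must have branch lengths")
    rng = rng or np.random.default_rng()

    Q = gtr_rate_matrix(params)
    cat_rates = site_rates(params)
    # per-site rate: 0 for invariant sites, else a gamma category
    invariant = rng.random(L) < params.p_inv
    cats = rng.integers(len(cat_rates), size=L)
    rate_per_site = np.where(invariant, 0.0, cat_rates[cats])

    dtree = tree.dendropy_tree
    root_states = rng.choice(4, size=L, p=Q.pi)
    states: dict[int, np.ndarray] = {id(dtree.seed_node): root_states}
    labels, rows = [], []
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            parent_states = states[id(node.parent_node)]
            child_states = parent_states.copy()
            for rate in np.unique(rate_per_site):
                if rate == 0.0:
                    continue
                mask = rate_per_site == rate
                P = transition_probs(Q, node.edge.length * rate)
                cum = P.cumsum(axis=1)
                u = rng.random(mask.sum())
                ps = parent_states[mask]
                child_states[mask] = (u[:, None] > cum[ps]).sum(axis=1)
            states[id(node)] = child_states
        if node.is_leaf():
            labels.append(node.taxon.label)
            rows.append("".join(ALPHABET[s] for s in states[id(node)]))
    return Alignment(labels, rows)


def apply_deletions(alignment: Alignment, deletion_rate: float,
                    rng: np.random.Generator | None = None) -> Alignment:
    """Introduce per-lineage deletion events (positions become '-').

    Events have geometric lengths with mean 3; the event count per sequence is
    Poisson with mean ``deletion_rate * L / 3`` so the expected deleted
    fraction per sequence equals the nominal rate.  Column count is unchanged.
    """
    if not (0 <= deletion_rate < 1):
        raise ValueError("deletion_rate must lie in [0, 1)")
    if deletion_rate == 0:
        return alignment
    rng = rng or np.random.default_rng()
    L = alignment.length
    new_seqs = []
    for seq in alignment.sequences:
        chars = np.array(list(seq))
        n_events = rng.poisson(deletion_rate * L / MEAN_DELETION_LENGTH)
        for _ in range(n_events):
            start = int(rng.integers(L))
            length = int(rng.geometric(1.0 / MEAN_DELETION_LENGTH))
            chars[start:start + length] = "-"
        new_seqs.append("".join(chars))
    return Alignment(list(alignment.labels), new_seqs)


def gap_ratio(alignment: Alignment) -> float:
    """Fraction of gap symbols over all N*L alignment cells."""
    return alignment.gap_ratio()


def simulate_pair(cfg: SimConfig, rng: np.random.Generator) -> SimulatedPair:
    """Simulate one independent tree–MSA pair under the configured condition."""
    lam = sample_lambda(rng, cfg.lambda_range)
    topo = sample_topology(cfg.n_taxa, rng=rng)
    tree = sample_branch_lengths(topo, lam, rng)
    params = GTRParams.jc() if cfg.model == "jc" else sample_gtr_params(rng)
    aln = evolve_sequences(tree, params, cfg.seq_length, rng)
    rate = float(cfg.deletion_grid[rng.integers(len(cfg.deletion_grid))])
    aln = apply_deletions(aln, rate, rng)
    meta = {"lambda": lam, "deletion_rate": rate, "n_taxa": cfg.n_taxa,
            "seq_length": cfg.seq_length, "model": cfg.model}
    return SimulatedPair(tree, aln, meta)


def generate_dataset(manifest: Sequence[tuple[int, int, int]], seed: int,
                     model: str = "gtr",
                     deletion_grid: Sequence[float] = DEFAULT_DELETION_GRID,
                     ) -> Iterator[SimulatedPair]:
    """Stream independent pairs for a manifest of (n_taxa, L, count) entries.

    Each pair gets its own counter-derived substream, so the output is a pure
    function of (manifest, seed) and pairs are order-independent.
    """
    counter = 0
    for n_taxa, L, count in manifest:
        cfg = SimConfig(n_taxa=n_taxa, seq_length=L, model=model,
                        deletion_grid=deletion_grid, seed=seed)
        for _ in range(count):
            rng = np.random.default_rng([seed, counter])
            pair = simulate_pair(cfg, rng)
            pair.meta["pair_id"] = counter
            yield pair
            counter += 1


def dataset_size(manifest: Sequence[tuple[int, int, int]]) -> int:
    return sum(c for _, _, c in manifest)
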