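"""Iterative tree construction from scored candidate joins.

Three selection strategies share the same build loop: greedy argmax over
priority scores, temperature-scaled softmax sampling (the Monte-Carlo
variant, which draws several trees and keeps the one with the highest
pruning likelihood), and the sampled trajectories used by the REINFORCE
fine-tuning loop.  Starting from N singleton subtrees, N-2 scored joins are
performed; the final two subtrees are connected by an unscored forced edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .decoder import CandidateSet, SubtreeState
from .likelihood import GTRParams, assign_branch_lengths, felsenstein_loglik
from .msa import Alignment
from .trees import PhyloTree

__all__ = ["JoinRecord", "SamplingPolicy", "greedy_build",
           "select_probabilities", "sample_build", "mc_search",
           "OracleScorer", "RandomScorer"]


@dataclass
class JoinRecord:
    left: tuple[str, ...]
    right: tuple[str, ...]
    score: float


@dataclass
class SamplingPolicy:
    """Temperature and sample count for stochastic construction."""

    gamma: float = 1.0
    n_samples: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("sampling temperature must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be nonnegative")


def _finalize(states: list[SubtreeState]) -> PhyloTree:
    assert len(states) == 2
    a, b = sorted(states, key=lambda s: s.key)
    return PhyloTree.from_newick(f"({a.frag},{b.frag});")


def greedy_build(alignment: Alignment, model,
                 ) -> tuple[PhyloTree, list[JoinRecord]]:
    """Construct a topology by always joining the highest-scoring pair.

    Ties go to the lowest canonical pair (candidates are enumerated in
    canonical order, so the first argmax wins).  Returns the unrooted binary
    topology (no branch lengths) and the trace of scored joins.
    """
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    states = model.initial_states(alignment)
    trace: list[JoinRecord] = []
    while len(states) > 2:
        cands = model.candidates(states)
        scores = _score_values(cands)
        best = int(np.argmax(scores))
        trace.append(JoinRecord(cands.keys[best][0], cands.keys[best][1],
                                float(scores[best])))
        states = _execute(states, cands, best, model)
    return _finalize(states), trace


def select_probabilities(scores, gamma: float) -> np.ndarray:
    """Temperature-scaled softmax over candidate scores."""
    if gamma <= 0:
        raise ValueError("sampling temperature must be positive")
    s = np.asarray(scores, dtype=float) / gamma
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


def sample_build(alignment: Alignment, model, policy: SamplingPolicy,
                 rng: np.random.Generator | None = None,
                 collect_logp: bool = False,
                 ) -> tuple[PhyloTree, list[JoinRecord], float | Tensor]:
    """Sample one construction trajectory from the softmax policy.

    Returns the tree, the trace, and the trajectory log-probability
    log p(tau | theta) = sum_t log pi(a_t | S_t).  With ``collect_logp`` the
    log-probability is a differentiable :class:`Tensor` (used by REINFORCE);
    otherwise it is a float.
    """
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = rng or np.random.default_rng(policy.seed)
    states = model.initial_states(alignment)
    trace: list[JoinRecord] = []
    logp_terms: list = []
    while len(states) > 2:
        cands = model.candidates(states)
        scores = _score_values(cands)
        probs = select_probabilities(scores, policy.gamma)
        choice = int(rng.choice(len(probs), p=probs))
        if collect_logp and isinstance(cands.scores, Tensor):
            logits = cands.scores * (1.0 / policy.gamma)
            logp_terms.append(logits.softmax(axis=-1)[choice].log())
        else:
            logp_terms.append(float(np.log(probs[choice])))
        trace.append(JoinRecord(cands.keys[choice][0], cands.keys[choice][1],
                                float(scores[choice])))
        states = _execute(states, cands, choice, model)
    if collect_logp and logp_terms and isinstance(logp_terms[0], Tensor):
        total = logp_terms[0]
        for term in logp_terms[1:]:
            total = total + term
    else:
        total = float(sum(logp_terms))
    return _finalize(states), trace, total


def mc_search(alignment: Alignment, model, policy: SamplingPolicy,
              params: GTRParams | None = None,
              branch_length_mode: str = "fixed",
              ) -> tuple[PhyloTree, float]:
    """Likelihood-guided Monte-Carlo search over sampled constructions.

    Draws ``policy.n_samples`` trees from the softmax policy plus the greedy
    tree, assigns branch lengths (``fixed`` or ``optimize``), and returns the
    topology maximizing the pruning log-likelihood together with that
    log-likelihood.  Ties prefer the greedy tree, then earlier samples.
    """
    params = params or GTRParams.jc()
    rng = np.random.default_rng(policy.seed)
    with no_grad():
        pool: list[PhyloTree] = [greedy_build(alignment, model)[0]]
        for _ in range(policy.n_samples):
            tree, _, _ = sample_build(alignment, model, policy, rng)
            pool.append(tree)
    best_tree, best_ll = None, -np.inf
    for tree in pool:
        with_lengths = assign_branch_lengths(tree, alignment, params,
                                             mode=branch_length_mode)
        ll = felsenstein_loglik(with_lengths, alignment, params)
        if ll > best_ll:
            best_tree, best_ll = with_lengths, ll
    return best_tree, float(best_ll)


def _score_values(cands: CandidateSet) -> np.ndarray:
    if cands.scores is None:
        raise RuntimeError("forced join reached inside the scored loop")
    if isinstance(cands.scores, Tensor):
        return cands.scores.data
    return np.asarray(cands.scores, dtype=float)


def _execute(states: list[SubtreeState], cands: CandidateSet, idx: int, model):
    l, r = cands.pairs[idx]
    new = model.join_state(states, cands, idx)
    return [s for i, s in enumerate(states) if i not in (l, r)] + [new]


# -- non-neural scorers (oracles and baselines) ------------------------------


class _ScoreOnlyModel:
    """Shared build-loop plumbing for models that score member sets directly."""

    def initial_states(self, alignment: Alignment) -> list[SubtreeState]:
        return [SubtreeState(frozenset([lab]), None, lab)
                for lab in alignment.labels]

    def candidates(self, states: list[SubtreeState]) -> CandidateSet:
        k = len(states)
        if k < 2:
            raise ValueError("need at least 2 active subtrees")
        pairs = []
        for i in range(k):
            for j in range(i + 1, k):
                li, ri = (i, j) if states[i].key <= states[j].key else (j, i)
                pairs.append((li, ri))
        pairs.sort(key=lambda p: (states[p[0]].key, states[p[1]].key))
        keys = [(states[l].key, states[r].key) for l, r in pairs]
        if k == 2:
            return CandidateSet(pairs, None, None, keys)
        scores = np.array([self.score_pair(states[l].members, states[r].members)
                           for l, r in pairs])
        return CandidateSet(pairs, scores, None, keys)

    def join_state(self, states, cands, idx) -> SubtreeState:
        l, r = cands.pairs[idx]
        a, b = states[l], states[r]
        return SubtreeState(a.members | b.members, None, f"({a.frag},{b.frag})")

    def score_pair(self, left: frozenset, right: frozenset) -> float:
        raise NotImplementedError


class OracleScorer(_ScoreOnlyModel):
    """Scores 1 when the pair's union is a clade side of the reference tree.

    Driving the greedy loop with this scorer must reconstruct the reference
    topology exactly — the correctness contract of the construction loop.
    """

    def __init__(self, reference: PhyloTree):
        universe = frozenset(reference.leaf_labels)
        compatible: set[frozenset] = {universe}
        for lab in universe:
            compatible.add(frozenset([lab]))
        for side in reference.bipartitions():
            compatible.add(side)
            compatible.add(universe - side)
        self.compatible = compatible

    def score_pair(self, left: frozenset, right: frozenset) -> float:
        return 1.0 if (left | right) in self.compatible else 0.0


class RandomScorer(_ScoreOnlyModel):
    """Uniform random scores: the join-at-random baseline."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.rng = rng or np.random.default_rng()

    def score_pair(self, left: frozenset, right: frozenset) -> float:
        return float(self.rng.random())
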