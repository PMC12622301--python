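"""Tree decoder: parent-node representation estimation and join scoring.

For a candidate pair of subtrees with per-site representations ``h_l`` and
``h_r`` (each L x d), the parent representation is estimated in two gated
stages:

  stage 1 (descendant fusion):   z_j = sigmoid(Linear(h_l_j - h_r_j)),
                                 h~_j = z_j * h_l_j + (1 - z_j) * h_r_j
  stage 2 (ancestral context):   w_j = sigmoid(Linear(h_rest_j)),
                                 h_x_j = w_j * h~_j + (1 - w_j) * h_rest_j

where ``h_rest`` aggregates the remaining active subtrees through
cross-attention with h~ as the query.  The keys/values are the site-mean
pooled subtree representations, so the context step costs O(k * L * d) for k
active subtrees.  A per-site MLP then maps h_x to scalars whose mean over
sites is the join priority score.

Pairs are canonicalized (the side with the lexicographically smaller member
set is "left"), making scores independent of enumeration order even though
stage 1 is antisymmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack
from .encoder import EncoderConfig, MSAEncoder
from .msa import Alignment, encode_alignment
from .nnet import MLP, Linear, Module

__all__ = ["SubtreeState", "CandidateSet", "JoinScorer", "NeuralJoinModel",
           "fuse_children", "ancestral_context", "integrate_context",
           "score_subtree", "enumerate_candidates", "canonical_pair_key"]


@dataclass
class SubtreeState:
    """One active subtree during construction: its members, its L x d
    representation, and the Newick fragment built so far."""

    members: frozenset[str]
    rep: Tensor | None
    frag: str

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def canonical_pair_key(a: SubtreeState, b: SubtreeState
                       ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Deterministic (left, right) ordering for a candidate pair."""
    return (a.key, b.key) if a.key <= b.key else (b.key, a.key)


@dataclass
class CandidateSet:
    """All unordered pairs at one construction step, scored in a batch."""

    pairs: list[tuple[int, int]]           # (left, right) indices into states
    scores: Tensor | None                  # (P,) — None for the forced join
    parents: Tensor | None                 # (P, L, d) parent representations
    keys: list[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


class JoinScorer(Module):
    """Gating networks, context cross-attention, and the per-site evaluator."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.gate_fuse = Linear(d, d, rng)
        self.gate_ctx = Linear(d, d, rng)
        self.ctx_q = Linear(d, d, rng)
        self.ctx_k = Linear(d, d, rng)
        self.ctx_v = Linear(d, d, rng)
        self.ctx_out = Linear(d, d, rng)
        self.eval_mlp = MLP(d, d, 1, rng)  # per-site scorer; d-wide hidden keeps
        # the candidate sweep (the hot loop) linear in d^2
        self._d = d

    # stage 1 -----------------------------------------------------------------

    def fuse(self, h_l: Tensor, h_r: Tensor) -> tuple[Tensor, Tensor]:
        if h_l.shape != h_r.shape:
            raise ValueError(f"shape mismatch: {h_l.shape} vs {h_r.shape}")
        z = self.gate_fuse(h_l - h_r).sigmoid()
        h_tilde = z * h_l + (1.0 - z) * h_r
        return z, h_tilde

    # stage 2 -----------------------------------------------------------------

    def context(self, h_tilde: Tensor, pooled: Tensor,
                mask: np.ndarray) -> Tensor:
        """Cross-attention from h~ (P, L, d) onto pooled subtree keys (k, d).

        ``mask`` is (P, k) with 0 for admissible others and -inf for the
        pair's own two subtrees.
        """
        if np.any(~np.isfinite(mask).any(axis=-1)):
            raise ValueError("context requires at least one other subtree")
        q = self.ctx_q(h_tilde)                       # (P, L, d)
        k = self.ctx_k(pooled)                        # (k, d)
        v = self.ctx_v(pooled)                        # (k, d)
        logits = (q @ k.swapaxes(0, 1)) * (1.0 / np.sqrt(self._d))  # (P, L, k)
        attn = logits.softmax(axis=-1, mask=mask[:, None, :])
        return self.ctx_out(attn @ v)                 # (P, L, d)

    def integrate(self, h_tilde: Tensor, h_rest: Tensor) -> tuple[Tensor, Tensor]:
        if h_tilde.shape != h_rest.shape:
            raise ValueError(f"shape mismatch: {h_tilde.shape} vs {h_rest.shape}")
        w = self.gate_ctx(h_rest).sigmoid()
        h_x = w * h_tilde + (1.0 - w) * h_rest
        return w, h_x

    # evaluator ---------------------------------------------------------------

    def score(self, h_x: Tensor) -> Tensor:
        """Mean over sites of the per-site scalar evaluation -> (...,) scores."""
        per_site = self.eval_mlp(h_x)                 # (..., L, 1)
        return per_site.mean(axis=-2).reshape(*per_site.shape[:-2])


class NeuralJoinModel(Module):
    """Encoder + join scorer: the full learnable tree-construction model."""

    def __init__(self, cfg: EncoderConfig | None = None,
                 seed: int = 0):
        self.cfg = cfg or EncoderConfig()
        rng = np.random.default_rng(seed)
        self.encoder = MSAEncoder(self.cfg, rng)
        self.scorer = JoinScorer(self.cfg, rng)

    def initial_states(self, alignment: Alignment) -> list[SubtreeState]:
        """Leaf subtree states: encoder output rows, one per species."""
        H = self.encoder(encode_alignment(alignment).codes)
        return [SubtreeState(frozenset([lab]), H[i], lab)
                for i, lab in enumerate(alignment.labels)]

    def candidates(self, states: list[SubtreeState]) -> CandidateSet:
        """Score every unordered pair of active subtrees.

        With exactly two subtrees left the join is forced: no context set
        exists and no score is produced.
        """
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

        h_l = stack([states[l].rep for l, _ in pairs])   # (P, L, d)
        h_r = stack([states[r].rep for _, r in pairs])
        _, h_tilde = self.scorer.fuse(h_l, h_r)

        pooled = stack([s.rep for s in states]).mean(axis=1)  # (k, d)
        mask = np.zeros((len(pairs), k))
        for p, (l, r) in enumerate(pairs):
            mask[p, l] = mask[p, r] = -np.inf
        h_rest = self.scorer.context(h_tilde, pooled, mask)
        _, h_x = self.scorer.integrate(h_tilde, h_rest)
        scores = self.scorer.score(h_x)                  # (P,)
        return CandidateSet(pairs, scores, h_x, keys)

    def join_state(self, states: list[SubtreeState], cands: CandidateSet,
                   pair_idx: int) -> SubtreeState:
        l, r = cands.pairs[pair_idx]
        a, b = states[l], states[r]
        members = a.members | b.members
        frag = f"({a.frag},{b.frag})"
        rep = cands.parents[pair_idx] if cands.parents is not None else None
        return SubtreeState(members, rep, frag)


# -- functional wrappers (single pair, unbatched) ----------------------------


def fuse_children(h_l: Tensor, h_r: Tensor, scorer: JoinScorer
                  ) -> tuple[Tensor, Tensor]:
    return scorer.fuse(h_l, h_r)


def ancestral_context(h_tilde: Tensor, others: list[Tensor],
                      scorer: JoinScorer) -> Tensor:
    if not others:
        raise ValueError("ancestral context needs a nonempty set of other "
                         "subtrees (the final join is forced and unscored)")
    pooled = stack(others).mean(axis=1)      # (k, d)
    single = h_tilde.reshape(1, *h_tilde.shape)
    mask = np.zeros((1, len(others)))
    out = scorer.context(single, pooled, mask)
    return out.reshape(*h_tilde.shape)


def integrate_context(h_tilde: Tensor, h_rest: Tensor, scorer: JoinScorer
                      ) -> tuple[Tensor, Tensor]:
    return scorer.integrate(h_tilde, h_rest)


def score_subtree(h_x: Tensor, scorer: JoinScorer) -> Tensor:
    single = h_x.reshape(1, *h_x.shape)
    return scorer.score(single)[0]


def enumerate_candidates(states: list[SubtreeState],
                         model: NeuralJoinModel) -> CandidateSet:
    return model.candidates(states)
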