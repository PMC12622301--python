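"""Supervised margin-ranking training and REINFORCE fine-tuning.

Supervised phase: each reference tree is reconstructed by teacher forcing —
at every step all candidate pairs are scored, labelled correct (their union
is a clade side of the reference topology) or incorrect, and a hinge
ranking loss pushes every correct score at least a margin ``m`` above the
top-scoring incorrect candidates (selective negative penalization).  The
executed join is always the canonically smallest correct candidate, so the
rollout follows the reference tree.  When the loss reaches zero with full
negative coverage, the argmax candidate is necessarily correct, so greedy
construction reproduces the reference topology.

Reinforced phase: trajectories are sampled from the softmax policy, rewarded
by the pruning log-likelihood of the finished topology, and the policy
gradient -E[(R - b) d log p] is followed with the previous epoch's mean
reward as baseline b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad, relu
from .construct import SamplingPolicy, greedy_build, sample_build
from .decoder import CandidateSet, NeuralJoinModel, SubtreeState
from .likelihood import GTRParams, assign_branch_lengths, felsenstein_loglik
from .msa import Alignment
from .nnet import Adam
from .trees import PhyloTree, rf_distance

logger = logging.getLogger("phylonj.train")

__all__ = ["TrainConfig", "RLConfig", "label_candidates", "step_ranking_loss",
           "sample_loss", "supervised_train", "reinforce_finetune",
           "evaluate_mean_rf"]


@dataclass
class TrainConfig:
    margin: float = 1.0
    lr: float = 1e-3
    batch_size: int = 8
    negatives_per_positive: int = 4
    max_epochs: int = 10
    val_interval: int = 50          # batches between validation checks
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.negatives_per_positive < 1:
            raise ValueError("need at least one negative per positive")


@dataclass
class RLConfig:
    n_trajectories: int = 8
    epochs: int = 20
    gamma: float = 1.0
    lr: float = 1e-4
    branch_length_mode: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory per epoch")


def compatible_sets(tree: PhyloTree) -> set[frozenset]:
    """All clade sides of an unrooted tree, including the trivial ones."""
    universe = frozenset(tree.leaf_labels)
    out: set[frozenset] = {universe}
    for lab in universe:
        out.add(frozenset([lab]))
    for side in tree.bipartitions():
        out.add(side)
        out.add(universe - side)
    return out


def label_candidates(states: list[SubtreeState], cands: CandidateSet,
                     tau_gt: PhyloTree | set[frozenset]
                     ) -> tuple[list[int], list[int]]:
    """Split candidate indices into (correct, incorrect) w.r.t. the reference.

    A pair is correct iff the union of its member sets is one side of a
    bipartition of the reference tree (trivial sides included).
    """
    compat = tau_gt if isinstance(tau_gt, set) else compatible_sets(tau_gt)
    members = set().union(*(s.members for s in states))
    universe = max(compat, key=len)
    if not members <= universe:
        raise ValueError(f"subtree members not in reference tree: "
                         f"{sorted(members - universe)}")
    correct, incorrect = [], []
    for idx, (l, r) in enumerate(cands.pairs):
        union = states[l].members | states[r].members
        (correct if union in compat else incorrect).append(idx)
    return correct, incorrect


def step_ranking_loss(scores: Tensor, correct: list[int], incorrect: list[int],
                      margin: float, negatives_per_positive: int) -> Tensor:
    """Hinge ranking loss over (correct, selected-negative) pairs.

    Negatives are the top-K-scoring incorrect candidates (selective
    penalization); the loss is the mean of max(m - (s_a - s_b), 0) over all
    pairs of correct a and selected negative b.  Zero when there is nothing
    to rank against.
    """
    if not correct or not incorrect:
        return Tensor(0.0)
    vals = scores.data
    order = sorted(incorrect, key=lambda i: -vals[i])
    selected = order[:min(negatives_per_positive, len(order))]
    s_pos = scores[np.array(correct)].reshape(len(correct), 1)
    s_neg = scores[np.array(selected)].reshape(1, len(selected))
    return relu(margin - (s_pos - s_neg)).mean()


def sample_loss(model: NeuralJoinModel, alignment: Alignment,
                tau_gt: PhyloTree, cfg: TrainConfig) -> Tensor:
    """Teacher-forced mean step loss for one (alignment, reference) pair.

    Executes, among the correct candidates at each step, the canonically
    smallest one; averages the ranking loss over the N-2 scored steps.
    """
    compat = compatible_sets(tau_gt)
    states = model.initial_states(alignment)
    step_losses: list[Tensor] = []
    while len(states) > 2:
        cands = model.candidates(states)
        correct, incorrect = label_candidates(states, cands, compat)
        if not correct:
            raise RuntimeError("teacher-forced rollout left the reference tree")
        step_losses.append(step_ranking_loss(
            cands.scores, correct, incorrect,
            cfg.margin, cfg.negatives_per_positive))
        exec_idx = correct[0]  # candidates are in canonical order
        l, r = cands.pairs[exec_idx]
        new = model.join_state(states, cands, exec_idx)
        states = [s for i, s in enumerate(states) if i not in (l, r)] + [new]
    total = step_losses[0]
    for term in step_losses[1:]:
        total = total + term
    return total * (1.0 / len(step_losses))


def evaluate_mean_rf(model, pairs: list[tuple[Alignment, PhyloTree]]) -> float:
    """Mean normalized RF of greedy construction over (alignment, tree) pairs."""
    with no_grad():
        vals = []
        for aln, gt in pairs:
            pred, _ = greedy_build(aln, model)
            vals.append(rf_distance(pred, gt)[1])
    return float(np.mean(vals))


def supervised_train(model: NeuralJoinModel,
                     train_pairs: list[tuple[Alignment, PhyloTree]],
                     val_pairs: list[tuple[Alignment, PhyloTree]],
                     cfg: TrainConfig) -> dict:
    """Train the model with the batched ranking objective.

    The loss is averaged over batch samples and construction steps; early
    stopping triggers after ``patience`` consecutive validation checks
    without improvement of the mean normalized RF on the validation split.
    Returns a history dict; the model is left holding the best-validation
    weights.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = {"loss": [], "val_rf": [], "epochs_run": 0}
    best_rf = np.inf
    best_state = model.state_dict()
    checks_since_best = 0
    batches_since_check = 0
    stop = False

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_pairs))
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_pairs[i] for i in order[start:start + cfg.batch_size]]
            losses = [sample_loss(model, aln, gt, cfg) for aln, gt in batch]
            total = losses[0]
            for term in losses[1:]:
                total = total + term
            total = total * (1.0 / len(losses))
            opt.zero_grad()
            total.backward()
            opt.step()
            history["loss"].append(total.item())

            batches_since_check += 1
            if batches_since_check >= cfg.val_interval:
                batches_since_check = 0
                val_rf = evaluate_mean_rf(model, val_pairs)
                history["val_rf"].append(val_rf)
                logger.info("epoch %d loss %.4f val_rf %.4f",
                            epoch, total.item(), val_rf)
                if val_rf < best_rf - 1e-9:
                    best_rf = val_rf
                    best_state = model.state_dict()
                    checks_since_best = 0
                else:
                    checks_since_best += 1
                    if checks_since_best >= cfg.patience:
                        stop = True
                        break
        history["epochs_run"] = epoch + 1
        if stop:
            break

    # final check so short runs still validate at least once
    if not history["val_rf"]:
        val_rf = evaluate_mean_rf(model, val_pairs)
        history["val_rf"].append(val_rf)
        if val_rf < best_rf:
            best_rf = val_rf
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    history["best_val_rf"] = float(best_rf)
    return history


def reinforce_finetune(model: NeuralJoinModel, alignment: Alignment,
                       cfg: RLConfig, params: GTRParams | None = None
                       ) -> tuple[PhyloTree, dict]:
    """Fine-tune the policy on one alignment with likelihood reward.

    Per epoch: sample M trajectories, reward each finished topology with its
    pruning log-likelihood (branch lengths per ``cfg.branch_length_mode``),
    form advantages R - b with b the previous epoch's mean reward (first
    epoch: the current batch mean), and take one policy-gradient step on
    -(1/M) sum_i log p(tau_i | theta) (R_i - b).  Returns the highest-reward
    tree seen and a history dict.
    """
    params = params or GTRParams.jc()
    policy = SamplingPolicy(gamma=cfg.gamma, n_samples=cfg.n_trajectories,
                            seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    baseline = None
    best_tree, best_reward = None, -np.inf
    history = {"mean_reward": [], "grad_norm": []}

    for epoch in range(cfg.epochs):
        logps: list[Tensor] = []
        rewards: list[float] = []
        for _ in range(cfg.n_trajectories):
            tree, _, logp = sample_build(alignment, model, policy, rng,
                                         collect_logp=True)
            with_lengths = assign_branch_lengths(
                tree, alignment, params, mode=cfg.branch_length_mode)
            reward = felsenstein_loglik(with_lengths, alignment, params)
            logps.append(logp)
            rewards.append(reward)
            if reward > best_reward:
                best_reward, best_tree = reward, with_lengths
        batch_mean = float(np.mean(rewards))
        b = batch_mean if baseline is None else baseline
        advantages = [r - b for r in rewards]
        loss = logps[0] * (-advantages[0])
        for lp, adv in zip(logps[1:], advantages[1:]):
            loss = loss + lp * (-adv)
        loss = loss * (1.0 / len(logps))
        opt.zero_grad()
        loss.backward()
        norm = opt.step()
        baseline = batch_mean
        history["mean_reward"].append(batch_mean)
        history["grad_norm"].append(norm)
        logger.info("rl epoch %d mean reward %.3f best %.3f",
                    epoch, batch_mean, best_reward)
    history["best_reward"] = float(best_reward)
    return best_tree, history
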