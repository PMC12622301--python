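"""Ranking loss, teacher forcing, supervised training, REINFORCE."""

import numpy as np
import pytest

from phylonj import (NeuralJoinModel, RLConfig, TrainConfig,
                     parse_newick, reinforce_finetune,
                     supervised_train)
from phylonj.autodiff import Tensor
from phylonj.construct import OracleScorer
from phylonj.decoder import SubtreeState
from phylonj.train import (compatible_sets, evaluate_mean_rf,
                           label_candidates, sample_loss, step_ranking_loss)
from conftest import random_instance
import phylonj.train as train_mod


def _states(labels):
    return [SubtreeState(frozenset([l]), None, l) for l in labels]


def _cands(states):
    return OracleScorer.candidates(_DummyScore(), states)


class _DummyScore:
    def score_pair(self, left, right):
        return 0.0


class TestLabeling:
    def test_quartet_step_zero(self):
        gt = parse_newick("((A,B),(C,D));")
        states = _states("ABCD")
        cands = _cands(states)
        correct, incorrect = label_candidates(states, cands, gt)
        correct_keys = {cands.keys[i] for i in correct}
        assert correct_keys == {(("A",), ("B",)), (("C",), ("D",))}
        assert len(incorrect) == 4

    def test_final_step_always_correct(self):
        gt = parse_newick("((A,B),(C,D));")
        states = [SubtreeState(frozenset("AB"), None, "(A,B)"),
                  SubtreeState(frozenset("CD"), None, "(C,D)")]
        cands = _cands(states)
        correct, incorrect = label_candidates(states, cands, gt)
        assert len(correct) == 1 and not incorrect

    def test_leaf_mismatch_rejected(self):
        gt = parse_newick("((A,B),(C,D));")
        states = _states("ABCE")
        with pytest.raises(ValueError, match="E"):
            label_candidates(states, _cands(states), gt)

    @pytest.mark.parametrize("n", [5, 9])
    def test_reference_path_always_has_correct_candidate(self, n):
        """Following the reference tree, every step keeps at least one
        correct candidate available (inductive consistency)."""
        tree, aln = random_instance(n, 16, seed=50 + n)
        compat = compatible_sets(tree)
        model = OracleScorer(tree)
        states = model.initial_states(aln)
        while len(states) > 2:
            cands = model.candidates(states)
            correct, _ = label_candidates(states, cands, compat)
            assert correct
            l, r = cands.pairs[correct[0]]
            new = model.join_state(states, cands, correct[0])
            states = [s for i, s in enumerate(states)
                      if i not in (l, r)] + [new]


class TestRankingLoss:
    def _loss(self, scores, correct, incorrect, m=1.0, k=10):
        t = Tensor(np.asarray(scores, dtype=float), requires_grad=True)
        return step_ranking_loss(t, correct, incorrect, m, k).item()

    def test_satisfied_margin_is_zero(self):
        assert self._loss([2.0, 0.0], [0], [1]) == 0.0

    def test_partial_margin(self):
        assert self._loss([0.5, 0.0], [0], [1]) == pytest.approx(0.5)

    def test_two_positives_averaged(self):
        # correct {1.5, 0.2}, negative {0}, m=1 -> (0 + 0.8)/2
        assert self._loss([1.5, 0.2, 0.0], [0, 1], [2]) == pytest.approx(0.4)

    def test_top_k_negative_selection(self):
        # K=1 keeps only the hardest negative (score 0.9)
        val = self._loss([1.0, 0.9, -5.0], [0], [1, 2], m=1.0, k=1)
        assert val == pytest.approx(0.9)

    def test_empty_sides_give_zero(self):
        assert self._loss([1.0, 2.0], [], [0, 1]) == 0.0
        assert self._loss([1.0, 2.0], [0, 1], []) == 0.0

    @pytest.mark.parametrize("trial", range(5))
    def test_margin_implies_correct_argmax(self, trial):
        """Zero loss with full negative coverage forces the argmax into the
        correct set (the guarantee behind greedy selection)."""
        rng = np.random.default_rng(trial)
        n = 10
        scores = rng.normal(size=n)
        correct = sorted(rng.choice(n, size=3, replace=False).tolist())
        incorrect = [i for i in range(n) if i not in correct]
        loss = self._loss(scores, correct, incorrect, m=0.5, k=len(incorrect))
        if loss == 0.0:
            assert int(np.argmax(scores)) in correct


class TestSupervised:
    def test_loss_decreases_on_tiny_dataset(self):
        pairs = [random_instance(5, 24, seed=200 + i) for i in range(12)]
        pairs = [(a, t) for t, a in pairs]
        from phylonj.encoder import EncoderConfig
        cfg = EncoderConfig(d_model=16, n_layers=1, n_heads=2, hidden_mult=2,
                            max_len=32)
        model = NeuralJoinModel(cfg, seed=0)
        tcfg = TrainConfig(batch_size=4, val_interval=100, max_epochs=8,
                           seed=0)
        first = np.mean([sample_loss(model, a, t, tcfg).item()
                         for a, t in pairs[:8]])
        hist = supervised_train(model, pairs[:8], pairs[8:], tcfg)
        last = np.mean([sample_loss(model, a, t, tcfg).item()
                        for a, t in pairs[:8]])
        assert last < first
        assert hist["val_rf"]

    def test_early_stopping_honors_patience(self, tiny_model, monkeypatch):
        pairs = [random_instance(4, 16, seed=300 + i) for i in range(6)]
        pairs = [(a, t) for t, a in pairs]
        calls = []

        def fake_eval(model, val_pairs):
            calls.append(1)
            return 0.5  # never improves after the first check

        monkeypatch.setattr(train_mod, "evaluate_mean_rf", fake_eval)
        cfg = TrainConfig(batch_size=2, val_interval=1, max_epochs=50,
                          patience=3, seed=0)
        supervised_train(tiny_model, pairs[:4], pairs[4:], cfg)
        # first check sets the best; `patience` further checks then stop
        assert len(calls) == cfg.patience + 1


class TestReinforce:
    def test_constant_reward_gives_zero_update(self, tiny_model, monkeypatch):
        """With a flat reward landscape the batch-mean baseline zeroes every
        advantage, so the policy gradient vanishes."""
        monkeypatch.setattr(train_mod, "felsenstein_loglik",
                            lambda *a, **k: -10.0)
        _, aln = random_instance(5, 16, seed=400)
        cfg = RLConfig(n_trajectories=4, epochs=2, seed=0)
        _, hist = reinforce_finetune(tiny_model, aln, cfg)
        assert hist["grad_norm"][0] == pytest.approx(0.0, abs=1e-12)
        assert hist["grad_norm"][1] == pytest.approx(0.0, abs=1e-12)

    def test_advantages_center_to_zero(self):
        rewards = np.random.default_rng(0).normal(size=16)
        adv = rewards - rewards.mean()
        assert adv.sum() == pytest.approx(0.0, abs=1e-9)

    def test_best_reward_is_running_max(self, tiny_model):
        _, aln = random_instance(5, 16, seed=401)
        one = reinforce_finetune(NeuralJoinModel(tiny_model.cfg, seed=1), aln,
                                 RLConfig(n_trajectories=2, epochs=1, seed=3))
        many = reinforce_finetune(NeuralJoinModel(tiny_model.cfg, seed=1), aln,
                                  RLConfig(n_trajectories=2, epochs=4, seed=3))
        assert many[1]["best_reward"] >= one[1]["best_reward"]


def test_evaluate_mean_rf_range(tiny_model):
    pairs = [random_instance(5, 16, seed=500 + i) for i in range(3)]
    pairs = [(a, t) for t, a in pairs]
    val = evaluate_mean_rf(tiny_model, pairs)
    assert 0.0 <= val <= 1.0
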