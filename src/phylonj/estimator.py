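"""Scikit-learn style estimator wrapping the learnable join-scoring model.

``LearnedNJ.fit`` takes alignments with their reference trees (typically
simulated), trains the encoder/decoder with the margin-ranking objective,
and ``predict`` reconstructs topologies by greedy or Monte-Carlo
construction.  ``score`` returns mean topological similarity
(1 - normalized RF), so that larger is better as sklearn expects.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .construct import SamplingPolicy, greedy_build, mc_search
from .decoder import NeuralJoinModel
from .encoder import EncoderConfig
from .likelihood import GTRParams
from .msa import Alignment
from .train import TrainConfig, evaluate_mean_rf, supervised_train
from .trees import PhyloTree

__all__ = ["LearnedNJ"]


class LearnedNJ(BaseEstimator):
    """Learnable neighbor joining as a fit/predict estimator.

    Parameters mirror the encoder and training configurations; all have
    desk-scale defaults.  Fitted attributes: ``model_`` (the trained
    encoder/decoder), ``history_`` (loss / validation trajectory) and
    ``n_features_in_`` is not applicable (inputs are alignments, not a
    feature matrix).
    """

    def __init__(self, d_model: int = 64, n_layers: int = 2, n_heads: int = 4,
                 hidden_mult: int = 4, max_len: int = 1024,
                 margin: float = 1.0, negatives_per_positive: int = 4,
                 lr: float = 1e-3, batch_size: int = 8, max_epochs: int = 10,
                 val_interval: int = 50, patience: int = 5,
                 val_fraction: float = 0.1, mode: str = "greedy",
                 gamma: float = 1.0, n_samples: int = 32,
                 random_state: int = 0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.hidden_mult = hidden_mult
        self.max_len = max_len
        self.margin = margin
        self.negatives_per_positive = negatives_per_positive
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.val_interval = val_interval
        self.patience = patience
        self.val_fraction = val_fraction
        self.mode = mode
        self.gamma = gamma
        self.n_samples = n_samples
        self.random_state = random_state

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X: list[Alignment], y: list[PhyloTree],
            X_val: list[Alignment] | None = None,
            y_val: list[PhyloTree] | None = None) -> "LearnedNJ":
        X, y = self._validate_pairs(X, y)
        cfg = EncoderConfig(self.d_model, self.n_layers, self.n_heads,
                            self.hidden_mult, self.max_len)
        self.model_ = NeuralJoinModel(cfg, seed=self.random_state)
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * len(X))))
            if len(X) <= n_val:
                raise ValueError("not enough samples to hold out validation")
            rng = np.random.default_rng(self.random_state)
            idx = rng.permutation(len(X))
            val_idx, train_idx = idx[:n_val], idx[n_val:]
            train_pairs = [(X[i], y[i]) for i in train_idx]
            val_pairs = [(X[i], y[i]) for i in val_idx]
        else:
            X_val, y_val = self._validate_pairs(X_val, y_val)
            train_pairs = list(zip(X, y))
            val_pairs = list(zip(X_val, y_val))
        tcfg = TrainConfig(margin=self.margin, lr=self.lr,
                           batch_size=self.batch_size,
                           negatives_per_positive=self.negatives_per_positive,
                           max_epochs=self.max_epochs,
                           val_interval=self.val_interval,
                           patience=self.patience, seed=self.random_state)
        self.history_ = supervised_train(self.model_, train_pairs, val_pairs, tcfg)
        return self

    def predict(self, X: list[Alignment],
                params: GTRParams | None = None) -> list[PhyloTree]:
        self._check_fitted()
        out = []
        for aln in X:
            if self.mode == "greedy":
                tree, _ = greedy_build(aln, self.model_)
            elif self.mode == "mc":
                policy = SamplingPolicy(gamma=self.gamma,
                                        n_samples=self.n_samples,
                                        seed=self.random_state)
                tree, _ = mc_search(aln, self.model_, policy, params)
            else:
                raise ValueError(f"unknown mode {self.mode!r}")
            out.append(tree)
        return out

    def score(self, X: list[Alignment], y: list[PhyloTree]) -> float:
        """Mean (1 - normalized RF) between predictions and references."""
        self._check_fitted()
        X, y = self._validate_pairs(X, y)
        return 1.0 - evaluate_mean_rf(self.model_, list(zip(X, y)))

    # -- helpers -------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("this LearnedNJ instance is not fitted yet")

    @staticmethod
    def _validate_pairs(X, y):
        X, y = list(X), list(y)
        if len(X) != len(y):
            raise ValueError(f"{len(X)} alignments but {len(y)} trees")
        if not X:
            raise ValueError("empty dataset")
        for aln, tree in zip(X, y):
            if not isinstance(aln, Alignment):
                raise TypeError("X must contain Alignment objects")
            if not isinstance(tree, PhyloTree):
                raise TypeError("y must contain PhyloTree objects")
            if set(aln.labels) != set(tree.leaf_labels):
                raise ValueError("alignment labels do not match tree leaves")
        return X, y
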