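"""MSA encoder: symbol embedding plus stacked axial attention.

Each input alignment (N species x L sites) is embedded per site through a
GELU MLP and refined by ``n_layers`` axial blocks, each applying tied row
attention (one L x L attention map per head, shared across species), column
attention (self-attention over the N species at each site), and a
position-wise feed-forward, all as pre-norm residual blocks.  No operation
materializes an (N*L) x (N*L) attention map: memory stays O(L*N^2 + L^2)
per head.

Species-permutation equivariance holds end to end: there is no positional
signal along the species axis, so permuting input rows permutes the output
representations identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .msa import Alignment, EncodedAlignment, encode_alignment
from .nnet import MLP, LayerNorm, Linear, Module

__all__ = ["EncoderConfig", "MSAEncoder", "embed_sites", "column_attention",
           "tied_row_attention", "encode", "largest_attention_entries",
           "reset_attention_instrumentation"]

# instrumentation: size (entry count) of the largest attention map built
_LARGEST_ATTENTION = [0]


def largest_attention_entries() -> int:
    return _LARGEST_ATTENTION[0]


def reset_attention_instrumentation() -> None:
    _LARGEST_ATTENTION[0] = 0


def _record_attention(shape) -> None:
    n = int(np.prod(shape))
    if n > _LARGEST_ATTENTION[0]:
        _LARGEST_ATTENTION[0] = n


@dataclass
class EncoderConfig:
    """Encoder hyperparameters (desk-scale defaults, all overridable)."""

    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    hidden_mult: int = 4
    max_len: int = 1024

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.d_model, self.n_layers, self.n_heads,
               self.hidden_mult, self.max_len) < 1:
            raise ValueError("all encoder dimensions must be positive")


class SiteEmbedding(Module):
    """One-hot symbol + learned site-position embedding -> GELU MLP -> d_model."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.pos = Tensor(rng.normal(0, 0.02, size=(cfg.max_len, 5)),
                          requires_grad=True)
        self.mlp = MLP(5, cfg.hidden_mult * cfg.d_model, cfg.d_model, rng)
        self._cfg = cfg

    def __call__(self, codes: np.ndarray) -> Tensor:
        N, L = codes.shape
        if L > self._cfg.max_len:
            raise ValueError(f"alignment length {L} exceeds max_len "
                             f"{self._cfg.max_len}")
        onehot = np.eye(5)[codes]                     # (N, L, 5)
        x = Tensor(onehot) + self.pos[np.arange(L)]   # broadcast over species
        return self.mlp(x)


class ColumnAttention(Module):
    """Multi-head self-attention over species at each alignment site."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)
        self.h = cfg.n_heads
        self.dh = d // cfg.n_heads

    def __call__(self, H: Tensor) -> Tensor:
        N, L, d = H.shape
        # (L, heads, N, dh) with L as the batch axis
        def heads(t: Tensor) -> Tensor:
            return (t.swapaxes(0, 1)            # (L, N, d)
                     .reshape(L, N, self.h, self.dh)
                     .swapaxes(1, 2))           # (L, h, N, dh)
        q, k, v = heads(self.q(H)), heads(self.k(H)), heads(self.v(H))
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
        _record_attention(logits.shape)
        attn = logits.softmax(axis=-1)
        ctx = attn @ v                          # (L, h, N, dh)
        merged = ctx.swapaxes(1, 2).reshape(L, N, d).swapaxes(0, 1)
        return self.out(merged)


class TiedRowAttention(Module):
    """Self-attention over sites with one attention map shared across species.

    Query-key logits are summed over species and scaled by 1/sqrt(N * d_head),
    then the resulting L x L map (per head) is applied to every species row.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)
        self.h = cfg.n_heads
        self.dh = d // cfg.n_heads

    def __call__(self, H: Tensor) -> Tensor:
        N, L, d = H.shape
        def heads(t: Tensor) -> Tensor:
            return t.reshape(N, L, self.h, self.dh).swapaxes(1, 2)  # (N,h,L,dh)
        q, k, v = heads(self.q(H)), heads(self.k(H)), heads(self.v(H))
        logits = (q @ k.swapaxes(-1, -2)).sum(axis=0) * (1.0 / np.sqrt(N * self.dh))
        _record_attention(logits.shape)         # (h, L, L), tied across species
        attn = logits.softmax(axis=-1)
        ctx = attn @ v                          # broadcast: (N, h, L, dh)
        return self.out(ctx.swapaxes(1, 2).reshape(N, L, d))


class AxialBlock(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.row = TiedRowAttention(cfg, rng)
        self.col = ColumnAttention(cfg, rng)
        self.ffn = MLP(cfg.d_model, cfg.hidden_mult * cfg.d_model,
                       cfg.d_model, rng)
        self.ln_row = LayerNorm(cfg.d_model)
        self.ln_col = LayerNorm(cfg.d_model)
        self.ln_ffn = LayerNorm(cfg.d_model)

    def __call__(self, H: Tensor) -> Tensor:
        H = H + self.row(self.ln_row(H))
        H = H + self.col(self.ln_col(H))
        H = H + self.ffn(self.ln_ffn(H))
        return H


class MSAEncoder(Module):
    """Full encoder: embedding followed by a cascade of axial blocks."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.embed = SiteEmbedding(cfg, rng)
        self.blocks = [AxialBlock(cfg, rng) for _ in range(cfg.n_layers)]
        self.ln_final = LayerNorm(cfg.d_model)

    def __call__(self, codes: np.ndarray) -> Tensor:
        H = self.embed(codes)
        for block in self.blocks:
            H = block(H)
        return self.ln_final(H)


# -- functional wrappers -----------------------------------------------------


def embed_sites(codes: EncodedAlignment, encoder: MSAEncoder) -> Tensor:
    return encoder.embed(codes.codes)


def column_attention(H: Tensor, encoder: MSAEncoder, layer: int = 0) -> Tensor:
    return encoder.blocks[layer].col(H)


def tied_row_attention(H: Tensor, encoder: MSAEncoder, layer: int = 0) -> Tensor:
    return encoder.blocks[layer].row(H)


def encode(a: Alignment, encoder: MSAEncoder) -> Tensor:
    """Alignment -> (N, L, d_model) representations, in alignment row order."""
    return encoder(encode_alignment(a).codes)
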