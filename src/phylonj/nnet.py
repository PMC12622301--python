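"""Small neural-network layer library on top of :mod:`phylonj.autodiff`.

Provides parameter containers, Linear / LayerNorm / MLP building blocks and
an Adam optimizer with gradient clipping.  Checkpoints serialize to a single
``.npz`` archive with a format-version field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "MLP", "Adam",
           "save_checkpoint", "load_checkpoint", "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1


class Module:
    """Base class: children and parameters discovered via attributes."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"checkpoint mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = np.array(state[k], dtype=np.float64)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self._eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class MLP(Module):
    """Linear -> GELU -> Linear."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def grad_norm(self) -> float:
        total = 0.0
        for p in self.params.values():
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        return float(np.sqrt(total))

    def step(self) -> float:
        """Apply one update; returns the (pre-clip) gradient norm."""
        norm = self.grad_norm()
        scale = 1.0
        if self.clip_norm is not None and norm > self.clip_norm > 0:
            scale = self.clip_norm / (norm + 1e-12)
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return norm

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def save_checkpoint(path: str | Path, module: Module, extra: dict | None = None) -> None:
    """Save weights (plus optional config metadata) as one .npz archive."""
    payload = {f"param/{k}": v for k, v in module.state_dict().items()}
    payload["version"] = np.array(CHECKPOINT_VERSION)
    if extra:
        for k, v in extra.items():
            payload[f"extra/{k}"] = np.asarray(v)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Return (state_dict, extra-metadata) from a checkpoint archive."""
    with np.load(path, allow_pickle=False) as z:
        version = int(z["version"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        extra = {k[len("extra/"):]: z[k] for k in z.files if k.startswith("extra/")}
    return state, extra
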