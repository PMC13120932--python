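"""Modules and primitive layers built on the autodiff engine.

Layout convention for image-like data is channels-last, ``(B, H, W, C)``;
token matrices are ``(B, N, C)``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "DepthwiseConv3x3",
    "avg_pool2d",
    "softmax",
    "masked_softmax",
    "cross_entropy",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch for parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    # He-style scaling; adequate for the shallow nets used here
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_init(rng, in_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def _conv2d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """3x3 stride-1 same-padding convolution on (B,H,W,Cin) with weight (3,3,Cin,Cout).

    Forward via im2col + matmul; backward scatters column gradients back with
    nine slice-adds (cheap and exact for a fixed 3x3 kernel).
    """
    B, H, W, Cin = x.shape
    kh, kw, _, Cout = weight.shape
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # cols: (B,H,W,Cin,kh,kw) -> (B*H*W, kh*kw*Cin) matching weight flatten order
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3)).reshape(B * H * W, kh * kw * Cin)
    wmat = weight.data.reshape(kh * kw * Cin, Cout)
    out_data = (cols @ wmat).reshape(B, H, W, Cout)
    if bias is not None:
        out_data = out_data + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)

    def backward(g):
        gmat = g.reshape(B * H * W, Cout)
        if weight.requires_grad:
            weight._accumulate((cols.T @ gmat).reshape(kh, kw, Cin, Cout))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(B, H, W, kh, kw, Cin)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + H, j : j + W, :] += dcols[:, :, :, i, j, :]
            x._accumulate(dxp[:, 1 : 1 + H, 1 : 1 + W, :])

    out._backward = backward
    return out


class Conv2d(Module):
    """3x3, stride 1, same padding, channels-last."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.weight = Parameter(_init(rng, 9 * in_ch, (3, 3, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return _conv2d(x, self.weight, self.bias)


class DepthwiseConv3x3(Module):
    """Per-channel 3x3 convolution (zero padding) on the token grid.

    Implemented as nine shifted elementwise products so the autodiff engine
    handles the backward pass; weights default to zero so the surrounding
    residual branch starts as an exact identity.
    """

    def __init__(self, channels: int, zero_init: bool = True,
                 rng: np.random.Generator | None = None):
        if zero_init:
            w = np.zeros((3, 3, channels))
        else:
            w = _init(rng, 9, (3, 3, channels))
        self.weight = Parameter(w)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        xp = x.pad(((0, 0), (1, 1), (1, 1), (0, 0)))
        out = None
        for i in range(3):
            for j in range(3):
                term = xp[:, i : i + H, j : j + W, :] * self.weight[i, j]
                out = term if out is None else out + term
        return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    B, H, W, C = x.shape
    assert H % k == 0 and W % k == 0
    return x.reshape(B, H // k, k, W // k, k, C).mean(axis=(2, 4))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # detached stabiliser
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax restricted to `mask` support; empty-support rows are all-zero.

    `mask` is a constant 0/1 array broadcastable to ``x.shape``. The row
    maximum over the support is subtracted (detached) for stability.
    """
    mask = np.broadcast_to(np.asarray(mask, dtype=np.float64), x.shape)
    neg = np.where(mask > 0, 0.0, -np.inf)
    stab = np.max(x.data + neg, axis=axis, keepdims=True)
    stab = np.where(np.isfinite(stab), stab, 0.0)  # empty support rows
    e = (x - stab).exp() * mask
    denom = e.sum(axis=axis, keepdims=True)
    safe = denom + Tensor((denom.data == 0).astype(np.float64))
    return e / safe


def cross_entropy(probs: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted cross-entropy on probability outputs (B, K).

    Weighted mean over the batch: sum(w_y * -log p_y) / sum(w_y).
    """
    B, K = probs.shape
    labels = np.asarray(labels, dtype=int)
    onehot = np.zeros((B, K))
    onehot[np.arange(B), labels] = 1.0
    logp = (probs + 1e-12).log()
    per_sample = -(logp * onehot).sum(axis=1)
    if class_weights is None:
        return per_sample.mean()
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    return (per_sample * w).sum() * (1.0 / w.sum())
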